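"""Orientation statistics of an ideal pore: radial angle, chi1, wheel, bend.

Decorates residue 171 of a six-helix bundle with a phenylalanine side chain
at chi1 = -88 degrees (the closed-state crystal rotamer) and prints the
orientation statistics the analysis computes on real structures.
"""

import poregate as pg

spec = pg.IdealPoreSpec(
    decorated_residues={171: pg.SideChainTemplate("PHE", "CG", chi1=-88.0)}
)
pore = pg.build_ideal_pore(spec)
frame = pg.pore_frame(pore)  # origin at pore-helix CA centre of mass

angle = pg.radial_angle(pore, frame, "A", 171)
print(f"radial angle of residue 171 (chain A): {angle:6.1f} deg "
      "(0 = pore-facing, 180 = lipid-facing)")

chi = pg.chi1(pore, "A", 171)
print(f"chi1 of residue 171 (chain A)        : {chi:6.1f} deg "
      f"(rotamer {pg.rotamer_populations([chi]).populations})")

wheel = pg.HelicalWheel()
sep = pg.wheel_angle_between(wheel, 98, 99)
print(f"helical-wheel separation G98/F99     : {sep:6.1f} deg "
      "(opposite faces of the pore helix)")

bend = pg.helix_bend(pore, "A", hinge=158, arm_length=7)
print(f"helix bend at residue 158            : {bend.bend_deg:6.3f} deg "
      "(straight ideal helix: ~0)")

swap = pg.minimal_exposure_swap_rotation(pore, frame, "A", 150, 152)
print(f"smallest rotation concealing 150 while revealing 152: "
      f"{swap.rotation_deg:+.1f} deg")
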