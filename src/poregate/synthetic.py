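"""Synthetic inputs with known ground truth for every analysis stage.

Generates (i) ideal six-fold α-helical pore bundles with controllable
per-subunit azimuthal rotation, (ii) multi-frame trajectories with imposed
rotation trajectories, thermal (Gaussian) coordinate noise and water/ion
pseudo-atoms drawn from a prescribed axial density, (iii) two-state
open↔blocked current traces under a blocker-concentration step, (iv) ramp
I–V traces with linear leak and a known reversal potential, and (v)
three-cube FRET image triplets built by inverting the E-FRET forward model so
the analysis recovers the imposed efficiency exactly in the noiseless case.

Ground truth is always explicit in the spec objects; seeds are mandatory and
all randomness flows through ``numpy.random.default_rng(seed)`` (no global
state).  These generators emulate the *study conditions* — an idealised pore
geometry and simple noise — not physically realistic water structure or
membrane energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .structure import Structure, Trajectory

# ideal alpha-helix geometry
CA_RADIUS = 2.3  # Å, Cα distance from the helix axis
N_RADIUS = 1.5  # Å, backbone N distance from the helix axis (approx. ideal)
N_PHASE_DEG = -28.0  # azimuthal offset of N relative to Cα of the same residue
N_RISE = -0.9  # Å, axial offset of N relative to Cα
CB_BOND = 1.53  # Å, Cα-Cβ
G_BOND = 1.52  # Å, Cβ-γ
TETRAHEDRAL_DEG = 109.5


@dataclass(frozen=True)
class SideChainTemplate:
    """Minimal side-chain decoration: Cβ plus one γ atom.

    With ``chi1`` None the γ atom points radially outward from the local helix
    axis (tilted by the tetrahedral angle toward the helix C-terminus);
    otherwise it is placed at the requested χ1 torsion by ideal internal
    coordinates.
    """

    resname: str = "PHE"
    gamma_atom: str = "CG"
    chi1: float | None = None


@dataclass(frozen=True)
class IdealPoreSpec:
    """Geometry of an ideal n-fold α-helical pore bundle.

    ``helix_rotation`` is the azimuthal rotation of each helix about its own
    axis in degrees: a scalar applies to all subunits, a sequence gives one
    value per subunit.  ``twist_per_residue`` of 100° corresponds to the
    canonical 3.6 residues/turn helical wheel.
    """

    n_subunits: int = 6
    helix_length: int = 34
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    bundle_radius: float = 10.0
    helix_rotation: float | tuple[float, ...] = 0.0
    first_resid: int = 141
    decorated_residues: Mapping[int, SideChainTemplate] = field(default_factory=dict)
    seed: int = 0

    def rotations(self) -> np.ndarray:
        r = np.asarray(self.helix_rotation, dtype=float)
        if r.ndim == 0:
            return np.full(self.n_subunits, float(r))
        if r.shape != (self.n_subunits,):
            raise ParameterError(
                f"helix_rotation must be scalar or length {self.n_subunits}"
            )
        return r

    def validate(self) -> None:
        if self.n_subunits < 3:
            raise ParameterError("n_subunits must be >= 3")
        if self.helix_length < 8:
            raise ParameterError("helix_length must be >= 8")
        for name in ("rise_per_residue", "twist_per_residue", "bundle_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        self.rotations()


def _chain_letters(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def build_ideal_pore(spec: IdealPoreSpec) -> Structure:
    """Build the ideal pore bundle along +z (extracellular = +z).

    Chain k sits at azimuth k·360/n about the pore axis at ``bundle_radius``;
    within each helix, residue i has Cα at axial position i·rise and azimuth
    i·twist (+ the subunit's ``helix_rotation``) about the helix's own axis.
    With equal per-subunit rotations the bundle has exact n-fold symmetry.
    """
    from .geometry import place_by_internal_coords  # local import, no cycle at module load

    spec.validate()
    rots = spec.rotations()
    chain_ids, resids, resnames, atom_names, elements, coords = [], [], [], [], [], []
    zhat = np.array([0.0, 0.0, 1.0])
    for k, chain in enumerate(_chain_letters(spec.n_subunits)):
        phi_k = np.radians(360.0 * k / spec.n_subunits)
        axis_xy = spec.bundle_radius * np.array([np.cos(phi_k), np.sin(phi_k), 0.0])
        for i in range(spec.helix_length):
            resid = spec.first_resid + i
            template = spec.decorated_residues.get(resid)
            resname = template.resname if template else "ALA"
            alpha = phi_k + np.radians(i * spec.twist_per_residue + rots[k])
            u = np.array([np.cos(alpha), np.sin(alpha), 0.0])  # radial, outward
            z = i * spec.rise_per_residue
            ca = axis_xy + CA_RADIUS * u + z * zhat
            alpha_n = alpha + np.radians(N_PHASE_DEG)
            un = np.array([np.cos(alpha_n), np.sin(alpha_n), 0.0])
            n_at = axis_xy + N_RADIUS * un + (z + N_RISE) * zhat

            def add(name, el, xyz):
                chain_ids.append(chain)
                resids.append(resid)
                resnames.append(resname)
                atom_names.append(name)
                elements.append(el)
                coords.append(xyz)

            add("N", "N", n_at)
            add("CA", "C", ca)
            if template is not None:
                cb = ca + CB_BOND * u
                if template.chi1 is None:
                    tilt = np.radians(180.0 - TETRAHEDRAL_DEG)
                    g = cb + G_BOND * (np.cos(tilt) * u + np.sin(tilt) * zhat)
                else:
                    g = place_by_internal_coords(
                        n_at, ca, cb, G_BOND, TETRAHEDRAL_DEG, template.chi1
                    )
                add("CB", "C", cb)
                el = "S" if template.gamma_atom.startswith("S") else (
                    "O" if template.gamma_atom.startswith("O") else "C"
                )
                add(template.gamma_atom, el, g)
    return Structure(
        chain_ids=chain_ids,
        resids=resids,
        resnames=resnames,
        atom_names=atom_names,
        elements=elements,
        coords=np.asarray(coords),
        is_hetero=np.zeros(len(coords), dtype=bool),
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityTable:
    """Piecewise-constant axial number density (particles per Å).

    ``z_edges`` (M+1 values, Å, relative to the pore-helix Cα centre of mass)
    bound M bins with density ``lam`` each.
    """

    z_edges: tuple[float, ...]
    lam: tuple[float, ...]

    def validate(self) -> None:
        ze = np.asarray(self.z_edges, float)
        la = np.asarray(self.lam, float)
        if ze.ndim != 1 or la.shape != (ze.size - 1,):
            raise ParameterError("density table shape mismatch")
        if np.any(np.diff(ze) <= 0):
            raise ParameterError("z_edges must be strictly increasing")
        if np.any(la < 0):
            raise ParameterError("density values must be non-negative")

    @property
    def total(self) -> float:
        ze = np.asarray(self.z_edges, float)
        return float(np.sum(np.asarray(self.lam, float) * np.diff(ze)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ze = np.asarray(self.z_edges, float)
        la = np.asarray(self.lam, float)
        mass = la * np.diff(ze)
        p = mass / mass.sum()
        bins = rng.choice(len(la), size=n, p=p)
        return rng.uniform(ze[bins], ze[bins + 1])

    @classmethod
    def uniform(cls, lam: float, z_min: float, z_max: float) -> "DensityTable":
        return cls(z_edges=(z_min, z_max), lam=(lam,))


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """A trajectory of ideal-pore frames with imposed ground truth.

    ``rotation_offsets`` is the imposed helix-rotation trajectory in degrees:
    a scalar, one value per frame, or an (n_frames, n_subunits) array.  The
    per-frame water count is the rounded integral of ``water_axial_density``;
    water positions are redrawn i.i.d. each frame, uniform radially and
    azimuthally inside ``cylinder_radius``.
    """

    pore: IdealPoreSpec = field(default_factory=IdealPoreSpec)
    n_frames: int = 100
    rotation_offsets: float | tuple = 0.0
    coordinate_noise_sd: float = 0.0
    water_axial_density: DensityTable | None = None
    ion_counts: Mapping[str, int] = field(default_factory=dict)
    cylinder_radius: float = 10.0
    frame_spacing_ns: float = 0.5
    repeat_id: str = "repeat-0"
    seed: int = 0

    def offsets(self) -> np.ndarray:
        off = np.asarray(self.rotation_offsets, dtype=float)
        if off.ndim == 0:
            return np.full((self.n_frames, self.pore.n_subunits), float(off))
        if off.ndim == 1:
            if off.shape != (self.n_frames,):
                raise ParameterError("per-frame rotation_offsets length mismatch")
            return np.repeat(off[:, None], self.pore.n_subunits, axis=1)
        if off.shape != (self.n_frames, self.pore.n_subunits):
            raise ParameterError("rotation_offsets shape mismatch")
        return off


_ION_ATOM = {"Na": ("NA", "NA", "NA"), "Cl": ("CL", "CL", "CL")}


def generate_trajectory(spec: SyntheticTrajectorySpec) -> Trajectory:
    """Generate a synthetic trajectory; deterministic under a fixed seed."""
    if spec.n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if spec.water_axial_density is not None:
        spec.water_axial_density.validate()
    offsets = spec.offsets()
    rng = np.random.default_rng(spec.seed)
    base_rots = spec.pore.rotations()

    n_waters = (
        0
        if spec.water_axial_density is None
        else int(round(spec.water_axial_density.total))
    )
    # reference (offset-free) pore fixes the water frame origin: the water
    # density is defined relative to the pore-helix CA centre of mass
    ref = build_ideal_pore(spec.pore)
    ca_com = ref.select(atom_names="CA").coords.mean(axis=0)

    frames = []
    topology = None
    for f in range(spec.n_frames):
        pore = build_ideal_pore(
            IdealPoreSpec(
                **{
                    **spec.pore.__dict__,
                    "helix_rotation": tuple(base_rots + offsets[f]),
                }
            )
        )
        coords = pore.coords.copy()
        if spec.coordinate_noise_sd > 0:
            coords += rng.normal(0.0, spec.coordinate_noise_sd, coords.shape)
        extra_names, extra_res, extra_el, extra_xyz = [], [], [], []
        if n_waters:
            z = spec.water_axial_density.sample(n_waters, rng)
            r = spec.cylinder_radius * np.sqrt(rng.uniform(size=n_waters))
            th = rng.uniform(0, 2 * np.pi, size=n_waters)
            xyz = np.c_[r * np.cos(th), r * np.sin(th), z] + ca_com
            for j in range(n_waters):
                extra_names.append("O")
                extra_res.append("HOH")
                extra_el.append("O")
                extra_xyz.append(xyz[j])
        for species, count in spec.ion_counts.items():
            if species not in _ION_ATOM:
                raise ParameterError(f"unknown ion species {species!r}")
            resname, atom, el = _ION_ATOM[species]
            if spec.water_axial_density is not None:
                z = spec.water_axial_density.sample(count, rng)
            else:
                half = spec.pore.helix_length * spec.pore.rise_per_residue / 2
                z = rng.uniform(-half, half, size=count)
            r = spec.cylinder_radius * np.sqrt(rng.uniform(size=count))
            th = rng.uniform(0, 2 * np.pi, size=count)
            xyz = np.c_[r * np.cos(th), r * np.sin(th), z] + ca_com
            for j in range(count):
                extra_names.append(atom)
                extra_res.append(resname)
                extra_el.append(el)
                extra_xyz.append(xyz[j])
        if extra_xyz:
            n_extra = len(extra_xyz)
            full = Structure(
                chain_ids=np.r_[pore.chain_ids, np.array(["W"] * n_extra, object)],
                resids=np.r_[pore.resids, np.arange(1, n_extra + 1)],
                resnames=np.r_[pore.resnames, np.array(extra_res, object)],
                atom_names=np.r_[pore.atom_names, np.array(extra_names, object)],
                elements=np.r_[pore.elements, np.array(extra_el, object)],
                coords=np.vstack([coords, np.asarray(extra_xyz)]),
                is_hetero=np.r_[
                    np.zeros(pore.n_atoms, bool), np.ones(n_extra, bool)
                ],
            )
        else:
            full = pore.with_coords(coords)
        if topology is None:
            topology = full
        frames.append(full.coords)
    return Trajectory(
        topology=topology,
        frames=np.stack(frames),
        frame_spacing_ns=spec.frame_spacing_ns,
        repeat_id=spec.repeat_id,
    )


# ---------------------------------------------------------------------------
# block traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Two-state open↔blocked current under a blocker-concentration step.

    The unblocked fraction follows the single-site scheme: during blocker
    application it relaxes mono-exponentially with τ = 1/(kon·[B]+koff) to the
    steady state koff/(kon·[B]+koff) (blocked fraction kon·[B]/(kon·[B]+koff));
    after washout it recovers with time constant 1/koff.
    """

    kon: float = 8.0e4  # M^-1 s^-1
    koff: float = 0.1  # s^-1
    blocker_concentration: float = 5.0e-6  # M
    application_window: tuple[float, float] = (10.0, 40.0)  # s
    baseline_current: float = -100.0  # pA at the -100 mV step
    noise_sd: float = 0.0  # pA
    sample_rate: float = 1.0  # Hz (protocol delivers one sweep per second)
    duration: float = 60.0  # s
    voltage_mV: float = -100.0
    seed: int = 0


def unblocked_fraction(spec: SyntheticTraceSpec, t: np.ndarray) -> np.ndarray:
    """Closed-form unblocked fraction of the two-state scheme at times t."""
    if spec.kon < 0 or spec.koff < 0 or spec.blocker_concentration < 0:
        raise ParameterError("rates and concentration must be non-negative")
    t = np.asarray(t, dtype=float)
    t_on, t_off = spec.application_window
    if t_off <= t_on:
        raise ParameterError("application window must have t_off > t_on")
    rate_on = spec.kon * spec.blocker_concentration + spec.koff
    u = np.ones_like(t)
    during = (t >= t_on) & (t < t_off)
    after = t >= t_off
    if rate_on > 0:
        u_ss = spec.koff / rate_on
        u[during] = u_ss + (1 - u_ss) * np.exp(-(t[during] - t_on) * rate_on)
        u_end = u_ss + (1 - u_ss) * np.exp(-(t_off - t_on) * rate_on)
    else:  # no blocker and no unbinding: nothing happens
        u_end = 1.0
    if spec.koff > 0:
        u[after] = 1 + (u_end - 1) * np.exp(-(t[after] - t_off) * spec.koff)
    else:
        u[after] = u_end
    return u


def generate_block_trace(spec: SyntheticTraceSpec):
    """Synthetic blockade time course (one sample per sweep by default)."""
    from .kinetics import CurrentTrace

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    current = spec.baseline_current * unblocked_fraction(spec, t)
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=n)
    return CurrentTrace(
        time_s=t,
        current_pA=current,
        voltage_mV=np.full(n, spec.voltage_mV),
        annotations={
            "blocker_window_s": list(spec.application_window),
            "concentration_M": spec.blocker_concentration,
            "truth": {"kon": spec.kon, "koff": spec.koff},
        },
    )


# ---------------------------------------------------------------------------
# I-V ramps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticRampSpec:
    """Ramp I–V sweeps: channel current with known Vrev plus linear leak.

    With ``rectification_mV`` set, the channel conductance is scaled by a
    Boltzmann factor that falls off toward positive potentials (inward
    rectification, as for CRAC currents); the factor is strictly positive so
    the zero crossing stays at ``vrev_mV``.
    """

    vrev_mV: float = 52.0
    channel_conductance_nS: float = 2.0
    leak_conductance_nS: float = 0.0
    n_sweeps: int = 5
    v_min_mV: float = -100.0
    v_max_mV: float = 100.0
    n_points: int = 201
    noise_sd_pA: float = 0.0
    rectification_mV: float | None = None
    seed: int = 0


def generate_iv_ramps(spec: SyntheticRampSpec):
    """List of (channel+leak) sweeps and the matching leak-only sweep."""
    from .kinetics import CurrentTrace

    rng = np.random.default_rng(spec.seed)
    v = np.linspace(spec.v_min_mV, spec.v_max_mV, spec.n_points)
    t = np.linspace(0.0, 0.1, spec.n_points)  # 100-ms ramp
    factor = (
        np.ones_like(v)
        if spec.rectification_mV is None
        else 1.0 / (1.0 + np.exp(v / spec.rectification_mV))
    )
    i_channel = spec.channel_conductance_nS * (v - spec.vrev_mV) * factor
    i_leak = spec.leak_conductance_nS * v
    sweeps = []
    for _ in range(spec.n_sweeps):
        i = i_channel + i_leak
        if spec.noise_sd_pA > 0:
            i = i + rng.normal(0.0, spec.noise_sd_pA, size=v.size)
        sweeps.append(
            CurrentTrace(time_s=t, current_pA=i, voltage_mV=v,
                         annotations={"truth_vrev_mV": spec.vrev_mV})
        )
    leak = CurrentTrace(time_s=t, current_pA=i_leak, voltage_mV=v,
                        annotations={"solution": "La3+"})
    return sweeps, leak


# ---------------------------------------------------------------------------
# FRET image triplets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticFretSpec:
    """Three-cube FRET images from known abundances and efficiency.

    The forward model inverts the E-FRET analysis: donor emission is quenched
    by E, sensitized emission is G·D·E, and the FRET channel adds the a·I_AA
    and d·I_DD bleed-through terms, so the analysis recovers ``true_efficiency``
    exactly in the noiseless case.
    """

    donor_abundance: float = 1000.0
    acceptor_abundance: float = 3000.0
    true_efficiency: float = 0.3
    background: float = 0.0
    poisson_noise: bool = False
    image_shape: tuple[int, int] = (64, 64)
    seed: int = 0
    # bleed-through constants live in efret.EFretConstants; None = defaults
    constants: object | None = None


def generate_fret_images(spec: SyntheticFretSpec):
    """Build an ImageTriplet (plus ground-truth dict) from the forward model."""
    from .efret import EFretConstants, ImageTriplet

    if not (0.0 <= spec.true_efficiency <= 1.0):
        raise ParameterError("true_efficiency must be within [0, 1]")
    k = spec.constants if spec.constants is not None else EFretConstants()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    d = np.full(shape, float(spec.donor_abundance))
    a = np.full(shape, float(spec.acceptor_abundance))
    e = spec.true_efficiency
    i_dd = d * (1.0 - e)
    i_aa = a
    i_da = k.G * d * e + k.a * i_aa + k.d * i_dd
    images = [i_dd + spec.background, i_aa + spec.background, i_da + spec.background]
    if spec.poisson_noise:
        images = [rng.poisson(np.clip(im, 0, None)).astype(float) for im in images]
    triplet = ImageTriplet(
        I_DD=images[0] - spec.background,
        I_AA=images[1] - spec.background,
        I_DA=images[2] - spec.background,
        background={"I_DD": spec.background, "I_AA": spec.background,
                    "I_DA": spec.background},
        background_subtracted=True,
    )
    truth = {
        "true_efficiency": e,
        "donor_abundance": spec.donor_abundance,
        "acceptor_abundance": spec.acceptor_abundance,
        "constants": {"a": k.a, "b": k.b, "c": k.c, "d": k.d, "G": k.G},
    }
    return triplet, truth
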