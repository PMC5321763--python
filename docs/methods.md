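# Methods

This note records the models, conventions and numerical choices behind
`poregate`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what the
synthetic tests do and do not demonstrate.

## Pore frame and axial coordinates

All axial quantities are measured in a per-structure frame whose origin is
the unweighted mean of the pore-helix Cα atoms (residues 141–174 in
*Drosophila* Orai author numbering — the numbering is used verbatim; a
`ResidueMap` with offset +72 converts human Orai1 numbers, e.g. F99→F171).
The axis is the principal (largest-variance) direction of that Cα cloud —
for a six-helix bundle ~50 Å long and ~20 Å wide this direction is
unambiguous, and a degenerate SVD spectrum raises a geometry error rather
than returning an arbitrary axis. The sign is fixed so +axis points
extracellular: toward the selectivity-filter glutamate ring (residue 178 /
E106) when that residue is present, otherwise toward increasing residue
number, which is equivalent for TM1 (cytosolic N-terminus, extracellular
C-terminus). For trajectories the frame is recomputed every frame because
the bundle drifts.

## Radial angle

The orientation statistic for a pore-lining residue *i* is the angle at the
vertex M — the centre of mass of the Cα atoms of the "two helical turns"
centred on *i* — between the perpendicular foot of M on the pore axis and
Cα_i. Two turns of a 3.6-residue/turn helix is 7.2 residues; the closest
odd Cα window is *i*−3…*i*+3 (7 residues ≈ 1.94 turns), which is the
default; the window half-width is a parameter. Using the perpendicular foot
(rather than, say, the frame origin) makes the statistic independent of the
residue's axial position. 0° means the Cα points straight at the pore axis;
180° straight away. If M falls on the axis the angle is undefined and is
returned as NaN (never silently 0).

## Helix rotation

Rotation is measured about the **local per-chain helix axis**, not the pore
axis, so that lateral helix displacement does not masquerade as rotation.
The local axis of a 7-residue Cα window is estimated by the
second-difference construction: for an ideal helix the second differences
of consecutive Cα positions are exactly radial, so cross products of
successive second differences lie exactly along the helix axis; the
estimator averages these (sign-aligned) cross products and is exact on
ideal geometry. Windows shorter than four residues fall back to the
principal component. The statistic is the azimuth of (Cα − window
centroid) projected into the plane normal to the local axis, measured
relative to the same azimuth in a reference structure after aligning the
two local axes by the minimal rotation. Sign: positive = counter-clockwise
viewed from the extracellular (+axis) side, the convention in which the
STIM1-driven and spontaneous rotations of the pore helix are positive.

Radial angles and rotations are averaged with circular means over chains
and frames within a repeat; the quoted error is the SEM across independent
repeats (repeat-level means treated linearly around the grand circular
mean — valid because repeat means are tightly concentrated). SEM is `None`
when only one repeat is supplied, never a silent zero. Burn-in and stride
are expressed in frames; callers with a known frame spacing can convert
from time (the analysis convention for the MD ensembles this mirrors is
0.5 ns spacing after discarding the first 10 ns).

## χ1, rotamers, bend, contacts, metal bridges

χ1 is the N–Cα–Cβ–γ torsion in the standard (IUPAC) sign convention, with
the γ reference atom per residue type (Cγ for Phe/Tyr/Leu…, Cγ1 for
Val/Ile, Sγ for Cys, Oγ/Oγ1 for Ser/Thr). The implementation was verified
against an independent normal-vector formula and against `biotite`'s
dihedral during development. Rotamer classes use half-open bins
g+ (0°, 120°], t (120°, 180°] ∪ (−180°, −120°], g− (−120°, 0°]; a value of
exactly +120° is g+ by the half-open rule.

Helix bend about a hinge residue is the angle between the axes of the two
flanking arms (hinge±1…hinge±`arm_length`, default 7, minimum 3), each
fitted with the same local-axis estimator and oriented along increasing
residue number; an unbent ideal helix yields numerically zero.

Inter-subunit contact distances are minimum heavy-atom distances between
two residues on adjacent chains, with adjacency taken as the cyclic
azimuthal order of chains about the pore axis, and both orientations of
each pair reported. Metal-bridge feasibility asks whether a point exists
within a bond length (default 2.5 Å, the S–Cd²⁺ bond) of at least
`min_coordination` (default 2) Sγ atoms; this is the smallest-enclosing-ball
(minimax) problem for the coordinating subset, solved analytically for one
or two sites and by SLSQP (a convex program) otherwise, and validated
against a dense 0.1 Å grid search in tests. When a position is not a native
cysteine, Sγ is modelled 1.81 Å from Cβ along the native Cβ→γ direction —
orientation, not rotamer energetics, is the quantity of interest.

The minimal exposure-swap rotation — the smallest rigid rotation of one
helix about its own axis that pushes one residue's radial angle above a
threshold (default 90°, a parameter because the geometric estimate leaves
it implicit) while pulling another's below it — is found by a 0.5° scan
over ±180°, ties between +Δφ and −Δφ resolving counter-clockwise. Jointly
unsatisfiable conditions are reported as infeasible, not raised.

## Occupancy profiles

Axial histograms count species atoms (water oxygens; Na⁺/Cl⁻ by element)
whose radial distance from the axis is ≤ the cylinder radius (default
10 Å), in 1 Å bins over ±30 Å by default. The output is **counts per frame
per bin** (not per unit length); the normalization is recorded in the
profile metadata. Per-repeat averaging precedes the cross-repeat SEM.
Hydrophobic-stretch occupancy integrates the profile between the mean
axial Cα positions of two bounding residues (default 167–174, the
L95–V102 stretch in human numbering), with fractional bins included.

## Synthetic generators: what they emulate

The generators produce the study conditions, not physical realism:

- **Ideal pore**: n (default 6) parallel ideal α-helices (rise 1.5 Å/res,
  twist 100°/res, Cα radius 2.3 Å) at a bundle radius of 10 Å, with exact
  n-fold symmetry; per-subunit azimuthal rotation about each helix's own
  axis is the controllable ground truth. Side-chain decoration is minimal —
  Cβ and a single γ atom at ideal bond lengths (1.53/1.52 Å), either
  radial or placed at an imposed χ1 — because only angles, not energetics,
  are analysed. Backbone N atoms are placed at approximate ideal helix
  positions; they enter only the χ1 torsion.
- **Trajectories**: per-frame imposed rotations, i.i.d. isotropic Gaussian
  coordinate noise on protein atoms (the simplest model that exercises the
  circular statistics), and water/ion pseudo-atoms redrawn i.i.d. each
  frame from a prescribed axial density, uniform radially/azimuthally in
  the cylinder. The per-frame water count is fixed at the rounded density
  integral so frames share a topology (writable as multi-model PDB);
  per-bin counts are then multinomial, which is what the sampling tests
  assume. Waters are single O points — the histogram counts oxygens only.
- **Block traces**: the closed-form two-state relaxation (verified against
  numerical ODE integration), sampled at the protocol rate with Gaussian
  current noise.
- **I–V ramps**: linear channel conductance with a known reversal plus
  linear leak; an optional strictly positive Boltzmann factor produces
  inward rectification without moving the zero crossing, and pushing the
  nominal reversal outside the ramp yields the asymptotic no-crossing case.
- **FRET triplets**: the E-FRET forward model inverted exactly — donor
  emission quenched by E, sensitized emission G·D·E, bleed-through a·I_AA
  and d·I_DD added to the FRET channel — so noiseless analysis recovers E
  to machine precision; optional Poisson shot noise and background.

Seeds are mandatory fields and all randomness flows through
`numpy.random.default_rng`; identical specs and seeds give bit-identical
outputs. Passing these tests demonstrates that the estimators are unbiased
and correctly signed under the stated noise model; it does **not**
demonstrate robustness to force-field artefacts, correlated thermal motion,
membrane deformation, instrument drift or segmentation error in real data.

## Electrophysiology conventions

Fractional blockade is 1 − mean(I_b)/mean(I_ctrl) over stated windows,
restricted to samples at the −100 mV step when the trace has a varying
command; a control current at the noise floor (default 3× the pre-window
SD) makes the blockade undefined and raises. The blockade time constant is
a least-squares mono-exponential on the per-sweep current series (one
sweep per second in the standard protocol; the sweep interval is a
parameter), and a relaxation amplitude within 2 residual SDs of zero is a
fit error rather than a spurious τ. On the fitted (τ, f) the identities
k_on = f/(τ[B]), k_off = (1−f)/τ, 1/τ = k_on[B]+k_off hold exactly. A
maximal-block correction is not applied (full block when fully reacted is
assumed); `derive_rate_constants` tolerates 2% overshoot of f outside
[0, 1] from fit noise and rejects more.

Reversal potentials: sweeps (typically 4–6) are averaged point-wise after
leak subtraction (point-wise subtraction of a La³⁺ trace with a matching
voltage protocol); the junction correction (default −10 mV) is applied to
the voltage axis only; Vrev is the linearly interpolated zero-current
crossing. With several crossings (noisy, near-flat I–V) the one nearest
their median is taken and flagged. The +80 mV sentinel fires only when
there is no crossing and |I| at the positive end is below 5% (configurable)
of |I| at the negative end — an operational reading of "asymptotically
approaches the voltage axis" — and the result is flagged `assigned`.
"Peak current during the −100 mV pulse" is the largest-|I| sample after a
10 ms settle time, to skip the capacitive transient.

## E-FRET conventions

The displayed correction uses constants a and d only
(F_c = I_DA − a·I_AA − d·I_DD); b and c are carried and logged as
instrument metadata but are not guessed into the formula, since the
correction as printed does not use them. ROI efficiencies are
ratio-of-means (mean F_c and mean I_DD before the ratio), which is more
stable than averaging pixel-wise ratios. A non-positive denominator yields
a flagged NaN; E_app outside [0, 1] is flagged, never clipped. Background
subtraction uses per-channel background means, flooring negative pixels at
zero with the floored count logged. Gating keeps ROIs with mean I_AA/I_DD
in [2, 6] by default. Membrane segmentation is the caller's concern: ROI
label images are inputs.

## Amino-acid scales

The hydrophobicity table is the Radzicka–Wolfenden water→cyclohexane
side-chain-analogue transfer free-energy scale (Ile/Leu 4.92, Val 4.04,
Phe 2.98 kcal/mol); these four values are pinned in regression tests.
Proline has no analogue in the scale and lookups for it raise. Side-chain
accessible surface areas are the Miller et al. (1987) Gly-X-Gly
standard-state values; the source of the surface-area axis in the
mutational analyses this supports is not uniquely pinned down, so the
table is swappable. Both ship as CSV files with citations in their
headers. The mutational scatter reports a Spearman rank correlation
between scale value and a conducting flag (|density| ≥ 1 pA/pF by
default); the correlation is reported descriptively, not tested against a
reference value, because the underlying claims are qualitative.

## Pipeline

A run is a static, explicitly ordered stage list in a YAML config — no
auto-discovery, so an analysis is auditable from its config alone. Stage
seeds derive deterministically from the run seed and stage index; a failed
stage is recorded and its dependents skipped; the manifest (config hash,
seeds, package version, per-stage status and wall time) plus the config
suffice to reproduce every output, and deterministic stages re-run to
byte-identical CSVs.

## Problem sizes and limitations

The test suite and examples use desk-scale problems chosen to make the
statistical assertions sharp: 50–125 frames per repeat and 2–16 repeats for
trajectory statistics, 10⁴-pixel images, and a 3×3 rate grid with the
blocker concentration set for f = 0.8 (so both τ and f are well resolved at
2% current noise). Real simulation ensembles are orders of magnitude
larger; the estimators are O(frames × chains) and stream frame by frame,
but this package deliberately does not implement free-energy profiles,
wetting/dewetting kinetics, pore-radius (HOLE-style) profiling, rotamer
repacking, raw amplifier-file parsing, or image segmentation. Binary
trajectory formats (DCD/XTC) are supported through an optional MDAnalysis
adapter behind the same Trajectory contract; multi-model PDB is the
reference dialect. Insertion codes and mmCIF are out of scope for the PDB
reader; altlocs resolve to ' '/'A'.
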