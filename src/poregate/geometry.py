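"""Pore-frame and pore-helix orientation statistics.

This module implements the orientation statistics used to characterise
hydrophobic gating of the Orai/CRAC channel pore:

* the **pore frame** (origin at the centre of mass of the pore-helix Cα atoms,
  residues 141-174 in Drosophila Orai numbering; axis along the pore, with the
  extracellular side positive);
* the **radial angle** of a residue: the angle at the centre of mass of the
  two helical turns centred on that residue (a 7-residue Cα window), between
  the perpendicular foot of that point on the pore axis and the residue's own
  Cα.  Small angles mean the Cα points at the pore axis (pore-facing), angles
  near 180° mean lipid-facing.  The dOrai crystal value for F171 is ~31°;
* **helix rotation** of a residue's azimuth about the local helix axis
  relative to a reference structure, counter-clockwise positive as viewed
  from the extracellular side (the convention in which STIM1-driven rotation
  is ~+15-20°);
* **χ1 side-chain torsions** (N-Cα-Cβ-γ, IUPAC convention) and their
  g+/t/g- rotamer populations;
* **helix bend** about a hinge residue (e.g. G170);
* inter-subunit contact distances and Cd²⁺ metal-bridge feasibility between
  engineered cysteines (~2.5 Å S-Cd bonds);
* the minimal rigid helix rotation that conceals one residue from the pore
  while revealing another (the "~20°" geometric estimate for F99/G98).

Summary statistics follow the simulation conventions: circular means over
frames/chains within a repeat, and SEM across independent repeats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import circmean as _circmean

from .errors import GeometryError, ParameterError, SelectionError
from .structure import Structure, Trajectory

# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector")
    return v / n


def wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(a) or np.ndim(a) == 0 else w


def circ_mean_deg(values: Iterable[float]) -> float:
    """Circular mean of angles in degrees, returned in (-180, 180]."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ParameterError("empty angle series")
    return wrap_deg(float(_circmean(v, high=180.0, low=-180.0)))


def circ_sem_over_groups(group_means: Sequence[float]) -> float | None:
    """SEM of circular group means (None for a single group).

    Deviations are measured on the circle around the grand circular mean, then
    treated linearly — valid for the concentrated distributions produced by
    repeat-level averaging.
    """
    m = np.asarray(group_means, dtype=float)
    if m.size < 2:
        return None
    grand = circ_mean_deg(m)
    dev = wrap_deg(m - grand)
    return float(np.std(dev, ddof=1) / np.sqrt(m.size))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation by ``angle_deg`` about ``axis`` (Rodrigues)."""
    a = _unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]], dtype=float
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return rotation_matrix(perp, 180.0)
    return rotation_matrix(w, np.degrees(np.arctan2(s, c)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in (-180, 180], IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_deg(np.degrees(np.arctan2(y, x)))


def place_by_internal_coords(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d with given |c-d|, angle(b,c,d) and torsion(a,b,c,d).

    Inverse of :func:`dihedral_deg`: ``dihedral_deg(a, b, c, d) == torsion_deg``.
    """
    ang = np.radians(bond_angle_deg)
    tor = np.radians(torsion_deg)
    bc = _unit(np.asarray(c, float) - b)
    n = _unit(np.cross(np.asarray(b, float) - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return np.asarray(c, float) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# pore frame
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoreFrame:
    """Coordinate frame of the pore: origin, unit axis (+ = extracellular)."""

    origin: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-9:
            axis = axis / n
        object.__setattr__(self, "axis", axis)

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Signed axial coordinate(s) relative to the origin."""
        d = np.atleast_2d(coords) - self.origin
        z = d @ self.axis
        return z if np.ndim(coords) > 1 else float(z[0])

    def radial(self, coords: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(coords) - self.origin
        z = (d @ self.axis)[:, None] * self.axis
        r = np.linalg.norm(d - z, axis=1)
        return r if np.ndim(coords) > 1 else float(r[0])

    def foot(self, point: np.ndarray) -> np.ndarray:
        """Perpendicular foot of ``point`` on the pore axis."""
        d = np.asarray(point, dtype=float) - self.origin
        return self.origin + np.dot(d, self.axis) * self.axis


def pore_frame(
    structure: Structure,
    pore_residues: tuple[int, int] = (141, 174),
    chains: Iterable[str] | None = None,
    extracellular_residue: int | None = None,
) -> PoreFrame:
    """Pore frame from the pore-helix Cα atoms.

    Origin is the unweighted mean of the selected Cα coordinates; the axis is
    the principal (largest-variance) direction of the selection.  The sign is
    chosen so +axis points extracellular: toward the selectivity-filter ring
    ``extracellular_residue`` when given, else toward increasing residue
    numbers (TM1 runs cytosolic N-terminus to extracellular C-terminus).
    """
    sel = structure.select(chains=chains, residues=pore_residues, atom_names="CA")
    per_chain = pd.Series(sel.resids).groupby(pd.Series(sel.chain_ids)).nunique()
    if (per_chain >= 3).sum() < 3:
        raise SelectionError(
            "pore frame needs >=3 residues per chain on >=3 chains; got "
            + str(dict(per_chain))
        )
    coords = sel.coords
    origin = coords.mean(axis=0)
    centered = coords - origin
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9 or (s[0] - s[1]) / s[0] < 1e-6:
        raise GeometryError("degenerate geometry: no unique principal axis")
    axis = vt[0]
    # orient extracellular
    if extracellular_residue is not None:
        ring = structure.select(residues=extracellular_residue, atom_names="CA")
        ref = ring.coords.mean(axis=0) - origin
        if np.dot(ref, axis) < 0:
            axis = -axis
    else:
        z = centered @ axis
        slope = np.corrcoef(sel.resids.astype(float), z)[0, 1]
        if slope < 0:
            axis = -axis
    return PoreFrame(origin=origin, axis=axis)


# ---------------------------------------------------------------------------
# local helix axis
# ---------------------------------------------------------------------------


def local_helix_axis(ca: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    """Axis of a short helical Cα segment.

    Uses the second-difference construction (successive second differences of
    an ideal helix are radial, so their cross products lie exactly along the
    axis); falls back to the principal component for fewer than 4 points.
    ``orient``: vector whose direction fixes the sign (default: first-to-last
    Cα, i.e. increasing residue number).
    """
    ca = np.asarray(ca, dtype=float)
    if ca.shape[0] < 3:
        raise ParameterError("need at least 3 CA atoms to fit a helix axis")
    if orient is None:
        orient = ca[-1] - ca[0]
    if ca.shape[0] >= 4:
        d2 = ca[:-2] - 2 * ca[1:-1] + ca[2:]
        axes = np.cross(d2[:-1], d2[1:])
        norms = np.linalg.norm(axes, axis=1)
        good = norms > 1e-9
        if good.any():
            axes = axes[good] / norms[good][:, None]
            signs = np.sign(axes @ orient)
            signs[signs == 0] = 1.0
            mean_axis = (axes * signs[:, None]).mean(axis=0)
            if np.linalg.norm(mean_axis) > 1e-9:
                return _unit(mean_axis)
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    return axis if np.dot(axis, orient) >= 0 else -axis


def _window_ca(
    structure: Structure, chain: str, residue: int, window: int
) -> np.ndarray:
    resids = list(range(residue - window, residue + window + 1))
    coords = []
    for r in resids:
        m = structure.mask(chains=chain, residues=r, atom_names="CA")
        if not m.any():
            raise SelectionError(
                f"missing CA of residue {r} on chain {chain!r} "
                f"(window {residue}±{window})"
            )
        coords.append(structure.coords[np.flatnonzero(m)[0]])
    return np.asarray(coords)


# ---------------------------------------------------------------------------
# radial angle
# ---------------------------------------------------------------------------


def radial_angle(
    structure: Structure,
    frame: PoreFrame,
    chain: str,
    residue: int,
    window: int = 3,
) -> float:
    """Radial angle of a residue's Cα, in degrees [0, 180].

    Vertex M is the centre of mass of the Cα atoms of the two helical turns
    centred on the residue (the ``residue±window`` Cα window, default 7
    residues ≈ 1.94 turns); the angle is ∠(A, M, Cα) where A is the
    perpendicular foot of M on the pore axis.  0° = pore-facing,
    180° = lipid-facing.  Returns NaN when M lies on the axis (undefined).
    """
    ca_w = _window_ca(structure, chain, residue, window)
    m = ca_w.mean(axis=0)
    a = frame.foot(m)
    v1 = a - m
    v2 = structure.atom_coord(chain, residue, "CA") - m
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-6 or n2 < 1e-12:
        return float("nan")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclass
class RadialAngleSeries:
    """Per-(repeat, frame, chain) radial angles with repeat-level summary."""

    residue: int
    values: pd.DataFrame  # columns: repeat, frame, chain, angle_deg
    per_repeat_mean: pd.Series
    mean: float
    sem: float | None


@dataclass
class RotationSeries:
    """Signed helix rotations vs a reference (CCW positive from outside)."""

    residue: int
    values: pd.DataFrame  # columns: repeat, frame, chain, rotation_deg
    per_repeat_mean: pd.Series
    mean: float
    sem: float | None
    reference_id: str = "reference"


def _summarize_circular(df: pd.DataFrame, column: str):
    per_repeat = df.groupby("repeat")[column].apply(
        lambda s: circ_mean_deg(s.to_numpy())
    )
    mean = circ_mean_deg(per_repeat.to_numpy())
    sem = circ_sem_over_groups(per_repeat.to_numpy())
    return per_repeat, mean, sem


def _iter_frames(traj: Trajectory, burn_in: int, stride: int):
    for i in range(burn_in, traj.n_frames, stride):
        yield i, traj.frame(i)


def radial_angle_series(
    trajectories: Trajectory | Sequence[Trajectory],
    residue: int,
    chains: Iterable[str] | None = None,
    window: int = 3,
    pore_residues: tuple[int, int] = (141, 174),
    burn_in: int = 0,
    stride: int = 1,
) -> RadialAngleSeries:
    """Radial-angle statistics over one or more simulation repeats.

    The pore frame is recomputed for every frame (the bundle drifts); the
    circular mean is taken per repeat, and the SEM across repeats.
    """
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    rows = []
    for traj in trajs:
        cs = (
            list(chains)
            if chains is not None
            else _chains_with_residue(traj.topology, residue)
        )
        for i, struct in _iter_frames(traj, burn_in, stride):
            pf = pore_frame(struct, pore_residues=pore_residues)
            for c in cs:
                rows.append(
                    (traj.repeat_id, i, c, radial_angle(struct, pf, c, residue, window))
                )
    df = pd.DataFrame(rows, columns=["repeat", "frame", "chain", "angle_deg"]).dropna()
    per_repeat, mean, sem = _summarize_circular(df, "angle_deg")
    return RadialAngleSeries(residue, df, per_repeat, mean, sem)


# ---------------------------------------------------------------------------
# helix rotation
# ---------------------------------------------------------------------------


def helix_rotation_angle(
    structure: Structure,
    reference: Structure,
    chain: str,
    residue: int,
    pore_axis: np.ndarray,
    ref_pore_axis: np.ndarray,
    window: int = 3,
) -> float:
    """Signed azimuthal rotation of a residue about its local helix axis.

    The azimuth of (Cα − window centroid), projected into the plane normal to
    the local helix axis, is compared to the same azimuth in ``reference``
    after aligning the two local axes; positive = counter-clockwise as viewed
    from the extracellular (+pore axis) side.
    """
    ca_w = _window_ca(structure, chain, residue, window)
    ca_wr = _window_ca(reference, chain, residue, window)
    a = local_helix_axis(ca_w)
    ar = local_helix_axis(ca_wr)
    if np.dot(a, pore_axis) < 0:
        a = -a
    if np.dot(ar, ref_pore_axis) < 0:
        ar = -ar
    v = structure.atom_coord(chain, residue, "CA") - ca_w.mean(axis=0)
    vr = reference.atom_coord(chain, residue, "CA") - ca_wr.mean(axis=0)
    v = v - np.dot(v, a) * a
    vr = vr - np.dot(vr, ar) * ar
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(vr) < 1e-9:
        return float("nan")
    vr_aligned = _align_rotation(ar, a) @ vr
    y = np.dot(np.cross(vr_aligned, v), a)
    x = np.dot(vr_aligned, v)
    return wrap_deg(np.degrees(np.arctan2(y, x)))


def helix_rotation(
    trajectories: Trajectory | Sequence[Trajectory],
    reference: Structure,
    residue: int,
    chains: Iterable[str] | None = None,
    window: int = 3,
    pore_residues: tuple[int, int] = (141, 174),
    burn_in: int = 0,
    stride: int = 1,
) -> RotationSeries:
    """Helix-rotation statistics vs a reference structure, per repeat."""
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    ref_pf = pore_frame(reference, pore_residues=pore_residues)
    rows = []
    for traj in trajs:
        cs = (
            list(chains)
            if chains is not None
            else _chains_with_residue(traj.topology, residue)
        )
        for i, struct in _iter_frames(traj, burn_in, stride):
            pf = pore_frame(struct, pore_residues=pore_residues)
            for c in cs:
                rows.append(
                    (
                        traj.repeat_id,
                        i,
                        c,
                        helix_rotation_angle(
                            struct, reference, c, residue, pf.axis, ref_pf.axis, window
                        ),
                    )
                )
    df = pd.DataFrame(rows, columns=["repeat", "frame", "chain", "rotation_deg"]).dropna()
    per_repeat, mean, sem = _summarize_circular(df, "rotation_deg")
    return RotationSeries(residue, df, per_repeat, mean, sem)


# ---------------------------------------------------------------------------
# chi1 torsions and rotamers
# ---------------------------------------------------------------------------

#: IUPAC reference gamma atom defining chi1 per residue type
GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "CYS": "SG", "SER": "OG", "THR": "OG1",
}


def chi1(structure: Structure, chain: str, residue: int) -> float:
    """χ1 torsion (N-Cα-Cβ-γ) of a residue in degrees, (-180, 180]."""
    m = structure.mask(chains=chain, residues=residue)
    if not m.any():
        raise SelectionError(f"residue {residue} not found on chain {chain!r}")
    resname = str(structure.resnames[np.flatnonzero(m)[0]]).upper()
    gamma = GAMMA_ATOM.get(resname)
    if gamma is None:
        raise SelectionError(f"residue type {resname} has no chi1 gamma atom")
    pts = []
    for name in ("N", "CA", "CB", gamma):
        mm = structure.mask(chains=chain, residues=residue, atom_names=name)
        if not mm.any():
            raise SelectionError(
                f"missing atom {name!r} in residue {residue} chain {chain!r}"
            )
        pts.append(structure.coords[np.flatnonzero(mm)[0]])
    return dihedral_deg(*pts)


@dataclass
class Chi1Distribution:
    """χ1 series with g+/t/g- rotamer populations (per repeat and pooled)."""

    residue: int
    values: pd.DataFrame  # columns: repeat, chi1_deg
    per_repeat: pd.DataFrame  # index repeat, columns g+, t, g-
    populations: dict = field(default_factory=dict)


def rotamer_bin(angle_deg: float) -> str:
    """Rotamer class of a χ1 angle: g+ (0,120], t (120,180]∪(-180,-120], g- (-120,0]."""
    a = wrap_deg(angle_deg)
    if 0.0 < a <= 120.0:
        return "g+"
    if -120.0 < a <= 0.0:
        return "g-"
    return "t"


def rotamer_populations(
    chi1_series: Iterable[float] | Mapping[str, Iterable[float]],
    residue: int = 0,
) -> Chi1Distribution:
    """Bin χ1 angles into rotamer classes; populations sum to 1 per repeat."""
    if isinstance(chi1_series, Mapping):
        groups = {k: np.asarray(list(v), float) for k, v in chi1_series.items()}
    else:
        groups = {"repeat-0": np.asarray(list(chi1_series), float)}
    rows = []
    pops = {}
    for rep, vals in groups.items():
        if vals.size == 0:
            raise ParameterError(f"empty chi1 series for repeat {rep!r}")
        rows.extend((rep, float(v)) for v in vals)
        bins = pd.Series([rotamer_bin(v) for v in vals])
        counts = bins.value_counts().reindex(["g+", "t", "g-"], fill_value=0)
        pops[rep] = counts / counts.sum()
    per_repeat = pd.DataFrame(pops).T
    pooled = per_repeat.mean(axis=0)
    return Chi1Distribution(
        residue=residue,
        values=pd.DataFrame(rows, columns=["repeat", "chi1_deg"]),
        per_repeat=per_repeat,
        populations=pooled.to_dict(),
    )


# ---------------------------------------------------------------------------
# helix bend
# ---------------------------------------------------------------------------


@dataclass
class BendResult:
    hinge: int
    bend_deg: float
    arm_axes: tuple[np.ndarray, np.ndarray]


def helix_bend(
    structure: Structure,
    chain: str,
    hinge: int,
    arm_length: int = 7,
) -> BendResult:
    """Bend angle at a hinge residue between the flanking sub-helix axes.

    Arms span ``hinge±1 … hinge±arm_length``; each arm's axis is fitted with
    :func:`local_helix_axis` and oriented along increasing residue number.
    A straight ideal helix gives a bend well below 1°.
    """
    if arm_length < 3:
        raise ParameterError("arm_length must be >= 3")
    lower = np.asarray(
        [
            structure.atom_coord(chain, r, "CA")
            for r in range(hinge - arm_length, hinge)
        ]
    )
    upper = np.asarray(
        [
            structure.atom_coord(chain, r, "CA")
            for r in range(hinge + 1, hinge + arm_length + 1)
        ]
    )
    a1 = local_helix_axis(lower)
    a2 = local_helix_axis(upper)
    c = float(np.clip(np.dot(a1, a2), -1.0, 1.0))
    return BendResult(hinge=hinge, bend_deg=float(np.degrees(np.arccos(c))), arm_axes=(a1, a2))


# ---------------------------------------------------------------------------
# inter-subunit contacts and metal bridges
# ---------------------------------------------------------------------------


def _heavy_mask(structure: Structure) -> np.ndarray:
    return np.array(
        [
            not (el.upper() == "H" or (not el and an.startswith("H")))
            for el, an in zip(structure.elements, structure.atom_names)
        ],
        dtype=bool,
    )


@dataclass
class MinDistanceReport:
    residue_a: int
    residue_b: int
    per_pair: pd.DataFrame  # columns chain_a, chain_b, distance_A
    minimum: float


def intersubunit_min_distance(
    structure: Structure,
    residue_a: int,
    residue_b: int,
    chains: Sequence[str] | None = None,
    frame: PoreFrame | None = None,
) -> MinDistanceReport:
    """Closest heavy-atom distance between residue_a and residue_b on adjacent
    subunits (both directions around the ring), plus the overall minimum.

    Adjacency is the cyclic order of chains by azimuth about the pore axis.
    """
    cs = (
        list(chains)
        if chains is not None
        else _chains_with_residue(structure, residue_a)
    )
    if len(cs) < 2:
        raise SelectionError("need at least two chains")
    if len(cs) == 2:
        ordered = cs
        return _min_distance_report(structure, residue_a, residue_b, ordered)
    if frame is None:
        try:
            frame = pore_frame(structure)
        except (SelectionError, GeometryError):
            ca = structure.select(atom_names="CA")
            origin = ca.coords.mean(axis=0)
            _, _, vt = np.linalg.svd(ca.coords - origin)
            frame = PoreFrame(origin=origin, axis=vt[0])
    # azimuthal order of chains about the pore axis
    ref = None
    az = {}
    for c in cs:
        com = structure.select(chains=c).coords.mean(axis=0) - frame.origin
        com -= np.dot(com, frame.axis) * frame.axis
        if ref is None:
            ref = _unit(com)
            perp = np.cross(frame.axis, ref)
        az[c] = np.degrees(np.arctan2(np.dot(com, perp), np.dot(com, ref))) % 360
    ordered = sorted(cs, key=lambda c: az[c])
    return _min_distance_report(structure, residue_a, residue_b, ordered)


def _chains_with_residue(structure: Structure, residue: int) -> list[str]:
    m = structure.mask(residues=residue)
    seen: dict[str, None] = {}
    for c in structure.chain_ids[m]:
        seen.setdefault(c)
    if not seen:
        raise SelectionError(f"residue {residue} not found on any chain")
    return list(seen)


def _min_distance_report(
    structure: Structure, residue_a: int, residue_b: int, ordered: Sequence[str]
) -> MinDistanceReport:
    from scipy.spatial.distance import cdist

    rows = []
    n = len(ordered)
    pairs = set()
    for i, ca_id in enumerate(ordered):
        cb_id = ordered[(i + 1) % n]
        for c1, c2 in ((ca_id, cb_id), (cb_id, ca_id)):
            if (c1, c2) in pairs or c1 == c2:
                continue
            pairs.add((c1, c2))
            ma = structure.mask(chains=c1, residues=residue_a)
            mb = structure.mask(chains=c2, residues=residue_b)
            if not ma.any() or not mb.any():
                continue  # residue absent in this direction of the pair
            sa = structure.select(chains=c1, residues=residue_a)
            sb = structure.select(chains=c2, residues=residue_b)
            xa = sa.coords[_heavy_mask(sa)]
            xb = sb.coords[_heavy_mask(sb)]
            if len(xa) == 0 or len(xb) == 0:
                raise SelectionError("no heavy atoms in requested residues")
            rows.append((c1, c2, float(cdist(xa, xb).min())))
    if not rows:
        raise SelectionError(
            f"residues {residue_a}/{residue_b} never co-occur on adjacent chains"
        )
    df = pd.DataFrame(rows, columns=["chain_a", "chain_b", "distance_A"])
    return MinDistanceReport(residue_a, residue_b, df, float(df["distance_A"].min()))


def smallest_enclosing_ball(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre and radius of the minimax ball of a small point set."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 1:
        return pts[0], 0.0
    if len(pts) == 2:
        centre = pts.mean(axis=0)
        return centre, float(np.linalg.norm(pts[0] - centre))
    x0 = np.r_[pts.mean(axis=0), np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()]
    cons = [
        {
            "type": "ineq",
            "fun": (lambda x, p=p: x[3] - np.linalg.norm(x[:3] - p)),
        }
        for p in pts
    ]
    res = optimize.minimize(
        lambda x: x[3], x0, constraints=cons, method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    centre = res.x[:3]
    radius = float(np.linalg.norm(pts - centre, axis=1).max())
    return centre, radius


def sgamma_coord(structure: Structure, chain: str, residue: int) -> np.ndarray:
    """Sγ coordinate of a (possibly in-silico) cysteine at this position.

    Uses the native Sγ when present; otherwise models a cysteine substitution
    by placing Sγ 1.81 Å from Cβ along the native Cβ→γ direction (orientation,
    not rotamer search, is the quantity of interest).
    """
    m = structure.mask(chains=chain, residues=residue, atom_names="SG")
    if m.any():
        return structure.coords[np.flatnonzero(m)[0]]
    mm = structure.mask(chains=chain, residues=residue)
    if not mm.any():
        raise SelectionError(f"residue {residue} not found on chain {chain!r}")
    resname = str(structure.resnames[np.flatnonzero(mm)[0]]).upper()
    gamma = GAMMA_ATOM.get(resname)
    if gamma is None:
        raise SelectionError(
            f"cannot model Sγ at {resname} {residue}: no gamma atom to orient by"
        )
    cb = structure.atom_coord(chain, residue, "CB")
    g = structure.atom_coord(chain, residue, gamma)
    return cb + 1.81 * _unit(g - cb)


@dataclass
class BridgeReport:
    feasible: bool
    bond_length: float
    metal_position: np.ndarray | None
    minimax_radius: float
    distances: pd.DataFrame  # columns: site, distance_A


def metal_bridge_feasibility(
    structure: Structure,
    cys_positions: Sequence[tuple[str, int]],
    bond_length: float = 2.5,
    min_coordination: int = 2,
    tolerance: float = 0.0,
) -> BridgeReport:
    """Can a metal ion bridge the given (engineered) cysteine Sγ sites?

    Feasible iff some point lies within ``bond_length (+tolerance)`` of at
    least ``min_coordination`` Sγ atoms.  The best metal position is the
    minimax point of the best coordinating subset (smallest enclosing ball),
    solved by direct optimisation; per-site distances from that point are
    reported.
    """
    if len(cys_positions) < 2:
        raise ParameterError("need at least 2 candidate cysteine positions")
    if min_coordination < 2 or min_coordination > len(cys_positions):
        raise ParameterError("min_coordination out of range")
    labels = [f"{c}:{r}" for c, r in cys_positions]
    sg = np.asarray([sgamma_coord(structure, c, r) for c, r in cys_positions])
    best = None
    for subset in itertools.combinations(range(len(sg)), min_coordination):
        centre, radius = smallest_enclosing_ball(sg[list(subset)])
        if best is None or radius < best[1]:
            best = (centre, radius)
    centre, radius = best
    dists = pd.DataFrame(
        {"site": labels, "distance_A": np.linalg.norm(sg - centre, axis=1)}
    )
    return BridgeReport(
        feasible=bool(radius <= bond_length + tolerance),
        bond_length=bond_length,
        metal_position=centre,
        minimax_radius=float(radius),
        distances=dists,
    )


# ---------------------------------------------------------------------------
# minimal exposure-swap rotation
# ---------------------------------------------------------------------------


@dataclass
class SwapRotationResult:
    feasible: bool
    rotation_deg: float | None
    threshold_deg: float
    curves: pd.DataFrame  # columns: delta_deg, angle_conceal, angle_reveal


def minimal_exposure_swap_rotation(
    structure: Structure,
    frame: PoreFrame,
    chain: str,
    residue_conceal: int,
    residue_reveal: int,
    threshold_deg: float = 90.0,
    step_deg: float = 0.5,
    window: int = 3,
) -> SwapRotationResult:
    """Smallest rigid helix rotation concealing one residue, revealing another.

    The chain is rotated rigidly about its own helix axis in ``step_deg``
    increments over ±180°; the result is the smallest |Δφ| at which the radial
    angle of ``residue_conceal`` exceeds ``threshold_deg`` (pushed off the
    pore) while that of ``residue_reveal`` drops below it (brought onto the
    pore).  Infeasibility is reported, not raised.  Ties between +Δφ and −Δφ
    resolve to the counter-clockwise (positive) rotation.
    """
    chain_ca = structure.select(chains=chain, atom_names="CA")
    axis = local_helix_axis(chain_ca.coords)
    if np.dot(axis, frame.axis) < 0:
        axis = -axis
    point = chain_ca.coords.mean(axis=0)

    # only the two CA windows are needed; rotate those
    sub = structure.select(
        chains=chain,
        residues=range(
            min(residue_conceal, residue_reveal) - window,
            max(residue_conceal, residue_reveal) + window + 1,
        ),
    )
    deltas = np.arange(-180.0, 180.0 + step_deg / 2, step_deg)
    rows = []
    for d in deltas:
        rot = rotation_matrix(axis, d)
        coords = (sub.coords - point) @ rot.T + point
        rotated = sub.with_coords(coords)
        ac = radial_angle(rotated, frame, chain, residue_conceal, window)
        ar = radial_angle(rotated, frame, chain, residue_reveal, window)
        rows.append((float(d), ac, ar))
    curves = pd.DataFrame(rows, columns=["delta_deg", "angle_conceal", "angle_reveal"])
    ok = (curves["angle_conceal"] > threshold_deg) & (
        curves["angle_reveal"] < threshold_deg
    )
    if not ok.any():
        return SwapRotationResult(False, None, threshold_deg, curves)
    cand = curves.loc[ok, "delta_deg"].to_numpy()
    order = np.lexsort((-np.sign(cand), np.abs(cand)))  # |Δφ| asc, + before −
    return SwapRotationResult(True, float(cand[order[0]]), threshold_deg, curves)
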