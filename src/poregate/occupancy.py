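"""Axial occupancy profiles of water and ions inside the pore cylinder.

Counts species atoms (water oxygens, Na+, Cl-) whose radial distance from the
pore axis is within a cylinder (default radius 10 Å) and histograms their
axial coordinates relative to the pore-helix Cα centre of mass, extracellular
positive.  Frames are averaged within each simulation repeat first; the
reported error is the SEM across repeats (absent for a single repeat).  The
pore frame is recomputed per frame because the bundle drifts.

Profiles are per-frame counts per bin (not per unit length); this convention
is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .geometry import pore_frame
from .structure import Structure, Trajectory


@dataclass
class AxialProfile:
    """Binned axial occupancy of one species inside the pore cylinder."""

    species: str
    bin_edges: np.ndarray
    mean: np.ndarray  # mean count per frame per bin
    sem: np.ndarray | None  # SEM over repeats; None for a single repeat
    per_repeat: pd.DataFrame  # index: repeat id, columns: bin centres
    radius: float
    metadata: dict

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total(self) -> float:
        """Mean number of in-cylinder particles per frame (histogram mass)."""
        return float(self.mean.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"bin_centre_A": self.bin_centres, "mean_count": self.mean}
        )
        df["sem"] = np.nan if self.sem is None else self.sem
        df["species"] = self.species
        return df


def _species_mask(struct: Structure, species: str) -> np.ndarray:
    return struct.species == species


def axial_profile(
    trajectories: Trajectory | Sequence[Trajectory],
    species: str = "water",
    bin_edges: np.ndarray | None = None,
    radius: float = 10.0,
    burn_in: int = 0,
    stride: int = 1,
    pore_residues: tuple[int, int] = (141, 174),
) -> AxialProfile:
    """Axial histogram of a species within the pore cylinder, mean±SEM.

    ``species`` is one of ``"water"`` (water oxygens), ``"Na"`` or ``"Cl"``.
    """
    if bin_edges is None:
        bin_edges = np.arange(-30.0, 30.0 + 1e-9, 1.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin_edges must be increasing with width > 0")
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    if not trajs:
        raise ParameterError("need at least one repeat")
    per_repeat = {}
    for traj in trajs:
        mask = _species_mask(traj.topology, species)
        if not mask.any():
            raise SelectionError(f"species {species!r} absent from topology")
        counts = []
        for i in range(burn_in, traj.n_frames, stride):
            struct = traj.frame(i)
            pf = pore_frame(struct, pore_residues=pore_residues)
            xyz = struct.coords[mask]
            d = xyz - pf.origin
            z = d @ pf.axis
            r = np.linalg.norm(d - z[:, None] * pf.axis, axis=1)
            counts.append(np.histogram(z[r <= radius], bins=bin_edges)[0])
        per_repeat[traj.repeat_id] = np.mean(counts, axis=0)
    table = pd.DataFrame(per_repeat).T
    table.columns = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    mean = table.mean(axis=0).to_numpy()
    sem = (
        None
        if len(trajs) < 2
        else (table.std(axis=0, ddof=1) / np.sqrt(len(trajs))).to_numpy()
    )
    return AxialProfile(
        species=species,
        bin_edges=bin_edges,
        mean=mean,
        sem=sem,
        per_repeat=table,
        radius=radius,
        metadata={
            "normalization": "counts per frame per bin",
            "n_repeats": len(trajs),
            "burn_in_frames": burn_in,
            "stride_frames": stride,
        },
    )


def residue_axial_positions(
    trajectories: Trajectory | Sequence[Trajectory],
    residues: Iterable[int],
    burn_in: int = 0,
    stride: int = 1,
    pore_residues: tuple[int, int] = (141, 174),
) -> pd.DataFrame:
    """Mean axial Cα position per residue (over frames and chains), ±SEM over repeats."""
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    residues = list(residues)
    per_repeat = {}
    for traj in trajs:
        sums = {r: [] for r in residues}
        for i in range(burn_in, traj.n_frames, stride):
            struct = traj.frame(i)
            pf = pore_frame(struct, pore_residues=pore_residues)
            for r in residues:
                sel = struct.select(residues=r, atom_names="CA")
                sums[r].append(np.mean(pf.axial(sel.coords)))
        per_repeat[traj.repeat_id] = {r: float(np.mean(v)) for r, v in sums.items()}
    table = pd.DataFrame(per_repeat).T  # rows: repeat, cols: residue
    out = pd.DataFrame(
        {
            "residue": residues,
            "mean_z_A": [table[r].mean() for r in residues],
            "sem_z_A": [
                table[r].std(ddof=1) / np.sqrt(len(trajs)) if len(trajs) > 1 else np.nan
                for r in residues
            ],
        }
    )
    return out


@dataclass
class StretchOccupancy:
    """Water count within the axial window of the hydrophobic stretch."""

    z_window: tuple[float, float]
    mean: float
    sem: float | None
    per_repeat: pd.Series


def stretch_occupancy(
    profile: AxialProfile,
    z_window: tuple[float, float],
) -> StretchOccupancy:
    """Integrate an axial profile over a window (fractional bins included).

    The window is typically bounded by the mean axial Cα positions of the
    residues flanking the hydrophobic stretch (dOrai L167-V174, hOrai1
    L95-V102); see :func:`window_from_residues`.
    """
    lo, hi = z_window
    if hi <= lo:
        raise ParameterError("inverted window: upper bound below lower bound")
    edges = profile.bin_edges
    widths = np.diff(edges)
    overlap = np.clip(
        np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None
    )
    frac = overlap / widths
    per_repeat = profile.per_repeat.to_numpy() @ frac
    per_repeat = pd.Series(per_repeat, index=profile.per_repeat.index)
    sem = (
        None
        if per_repeat.size < 2
        else float(per_repeat.std(ddof=1) / np.sqrt(per_repeat.size))
    )
    return StretchOccupancy(
        z_window=(float(lo), float(hi)),
        mean=float(per_repeat.mean()),
        sem=sem,
        per_repeat=per_repeat,
    )


def window_from_residues(
    trajectories: Trajectory | Sequence[Trajectory],
    residue_lo: int,
    residue_hi: int,
    **kwargs,
) -> tuple[float, float]:
    """Axial window between two residues' mean Cα positions."""
    df = residue_axial_positions(trajectories, [residue_lo, residue_hi], **kwargs)
    z = sorted(df["mean_z_A"].to_list())
    return (float(z[0]), float(z[1]))


def plot_profile(profile: AxialProfile, ax=None):
    """Plot mean±SEM occupancy vs axial position (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = profile.bin_centres
    ax.plot(x, profile.mean, label=profile.species)
    if profile.sem is not None:
        ax.fill_between(x, profile.mean - profile.sem, profile.mean + profile.sem,
                        alpha=0.3)
    ax.set_xlabel("axial position (Å, extracellular +)")
    ax.set_ylabel("count per frame per bin")
    ax.legend()
    return ax
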