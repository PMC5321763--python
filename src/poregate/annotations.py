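"""Helical-wheel geometry and amino-acid scales for mutational-series analysis.

A canonical α-helix has 3.6 residues per turn, so consecutive residues are
100° apart on the helical wheel; F99 and G98 of hOrai1 TM1 thus sit on
opposite faces of the pore helix.  The hydrophobicity scale is the
water→cyclohexane side-chain-analogue transfer free-energy table (Ile/Leu
4.92, Val 4.04, Phe 2.98 kcal/mol); side-chain accessible surface areas come
from the Miller et al. (1987) standard-state table.  Both ship as CSV data
files with citations in their headers and are swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class HelicalWheel:
    """Residue → wheel-angle map for an α-helix (angles mod 360°)."""

    reference_residue: int = 99
    reference_angle: float = 0.0
    twist_per_residue: float = 100.0

    def __post_init__(self):
        if self.twist_per_residue <= 0:
            raise ParameterError("twist_per_residue must be positive")

    def angle(self, residue: int) -> float:
        return float(
            (self.reference_angle
             + (residue - self.reference_residue) * self.twist_per_residue) % 360.0
        )


def wheel_angle_between(wheel: HelicalWheel, residue_a: int, residue_b: int) -> float:
    """Minimal circular separation of two residues' wheel angles, in [0, 180]."""
    d = abs(wheel.angle(residue_a) - wheel.angle(residue_b)) % 360.0
    return float(min(d, 360.0 - d))


@dataclass(frozen=True)
class AminoAcidScale:
    """Named per-residue scale (one-letter keyed), with units and citation."""

    name: str
    units: str
    values: Mapping[str, float] = field(default_factory=dict)
    citation: str = ""

    def __getitem__(self, residue: str) -> float:
        key = residue.upper()
        key = THREE_TO_ONE.get(key, key)
        if key not in self.values:
            raise InputError(
                f"scale {self.name!r} has no entry for residue {residue!r}"
            )
        return self.values[key]

    def __contains__(self, residue: str) -> bool:
        key = residue.upper()
        return THREE_TO_ONE.get(key, key) in self.values


def _load_scale(filename: str, name: str, units: str) -> AminoAcidScale:
    path = resources.files("poregate.data").joinpath(filename)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
        with open(p) as fh:
            citation = " ".join(
                line.lstrip("# ").strip() for line in fh if line.startswith("#")
            )
    col = [c for c in df.columns if c.startswith("value")][0]
    return AminoAcidScale(
        name=name,
        units=units,
        values=dict(zip(df["one_letter"], df[col].astype(float))),
        citation=citation,
    )


def transfer_free_energy_scale() -> AminoAcidScale:
    """Water→cyclohexane side-chain transfer free energies (kcal/mol)."""
    return _load_scale(
        "transfer_free_energy.csv", "transfer_free_energy", "kcal/mol"
    )


def sidechain_asa_scale() -> AminoAcidScale:
    """Side-chain accessible surface areas (Å², Gly-X-Gly standard state)."""
    return _load_scale("sidechain_asa.csv", "sidechain_asa", "A^2")


def parse_mutant(label: str) -> tuple[str, int, str]:
    """Split a mutant label like 'F99I' into (native, position, substituted)."""
    import re

    m = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", label.strip())
    if m is None:
        raise InputError(f"cannot parse mutant label {label!r} (expect e.g. 'F99I')")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def scale_scatter(
    current_densities: Mapping[str, float] | pd.DataFrame,
    scale: AminoAcidScale,
    conducting_threshold: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Tidy (mutant, scale value, current density, conducting) table.

    ``current_densities`` maps mutant labels (e.g. ``F99I``) to current
    densities in pA/pF; the substituted residue's scale value is attached and
    a boolean conducting flag is set where |density| ≥ threshold.  Returns the
    table and the Spearman rank correlation between scale value and the
    conducting flag (a summary of the mutational trend; the underlying claims
    are qualitative).  Row order does not affect the correlation.
    """
    if isinstance(current_densities, pd.DataFrame):
        items = list(
            zip(current_densities["mutant"], current_densities["current_density_pA_pF"])
        )
    else:
        items = list(current_densities.items())
    missing = [
        lab for lab, _ in items if parse_mutant(lab)[2] not in scale
    ]
    if missing:
        raise InputError(
            f"scale {scale.name!r} missing entries for substituted residues of: "
            + ", ".join(missing)
        )
    rows = []
    for lab, dens in items:
        _, _, sub = parse_mutant(lab)
        rows.append(
            {
                "mutant": lab,
                "substituted": sub,
                "scale_value": scale[sub],
                "current_density_pA_pF": float(dens),
                "conducting": abs(float(dens)) >= conducting_threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["mutant", "substituted", "scale_value",
                 "current_density_pA_pF", "conducting"],
    )
    if len(df) == 0 or df["conducting"].nunique() < 2 or df["scale_value"].nunique() < 2:
        corr = float("nan")
    else:
        from scipy.stats import spearmanr

        corr = float(
            spearmanr(df["scale_value"], df["conducting"].astype(int)).statistic
        )
    return df, corr
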