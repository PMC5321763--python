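"""Three-cube E-FRET quantification with bleed-through correction.

The sensitized-emission (FRET) channel is corrected for donor and acceptor
bleed-through with the instrument constants measured from donor-only and
acceptor-only cells:

    Fc = I_DA − a·I_AA − d·I_DD

and the apparent FRET efficiency follows the E-FRET formalism with the
instrument G factor:

    E_app = Fc / (Fc + G·I_DD)

Default constants: a=0.10, b=0.008, c=0.002, d=0.38, G=1.75.  The b and c
constants are carried as metadata (logged) but do not enter the displayed
correction.  ROI statistics use means of Fc and I_DD before the ratio
(ratio-of-sums stability), and analysis is gated to ROIs whose acceptor/donor
(YFP/CFP) intensity ratio lies within [2, 6] by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EFretConstants:
    """Microscope bleed-through constants and G factor (all non-negative)."""

    a: float = 0.10
    b: float = 0.008
    c: float = 0.002
    d: float = 0.38
    G: float = 1.75

    def __post_init__(self):
        for name in ("a", "b", "c", "d", "G"):
            if getattr(self, name) < 0:
                raise ParameterError(f"constant {name} must be non-negative")
        if self.G <= 0:
            raise ParameterError("G must be positive")


@dataclass
class ImageTriplet:
    """Background-subtracted I_DD (CFP), I_AA (YFP) and I_DA (FRET) images."""

    I_DD: np.ndarray
    I_AA: np.ndarray
    I_DA: np.ndarray
    roi_labels: np.ndarray | None = None
    background: dict = field(default_factory=dict)
    background_subtracted: bool = True

    def __post_init__(self):
        self.I_DD = np.asarray(self.I_DD, dtype=float)
        self.I_AA = np.asarray(self.I_AA, dtype=float)
        self.I_DA = np.asarray(self.I_DA, dtype=float)
        if not (self.I_DD.shape == self.I_AA.shape == self.I_DA.shape):
            raise InputError("channel images must share a shape")
        if self.roi_labels is not None:
            self.roi_labels = np.asarray(self.roi_labels)
            if self.roi_labels.shape != self.I_DD.shape:
                raise InputError("ROI label image must match channel shape")

    def subtract_background(self, background: dict) -> "ImageTriplet":
        """Subtract per-channel background means; negatives floored at 0."""
        out = {}
        floored_total = 0
        for name in ("I_DD", "I_AA", "I_DA"):
            img = getattr(self, name) - float(background[name])
            floored = int((img < 0).sum())
            floored_total += floored
            out[name] = np.clip(img, 0.0, None)
        if floored_total:
            logger.info("background subtraction floored %d negative pixels",
                        floored_total)
        return ImageTriplet(
            I_DD=out["I_DD"], I_AA=out["I_AA"], I_DA=out["I_DA"],
            roi_labels=self.roi_labels, background=dict(background),
            background_subtracted=True,
        )


@dataclass
class EFretResult:
    """Fc image plus per-ROI efficiencies, ratios and gating flags."""

    fc_image: np.ndarray
    table: pd.DataFrame  # roi, E_app, ratio, kept, flags...
    constants: EFretConstants


def corrected_fret(triplet: ImageTriplet, constants: EFretConstants | None = None
                   ) -> np.ndarray:
    """Pixel-wise corrected FRET signal Fc = I_DA − a·I_AA − d·I_DD."""
    k = constants or EFretConstants()
    logger.debug("constants b=%g, c=%g carried as metadata only", k.b, k.c)
    return triplet.I_DA - k.a * triplet.I_AA - k.d * triplet.I_DD


def _roi_iter(triplet: ImageTriplet):
    if triplet.roi_labels is None:
        yield 1, np.ones(triplet.I_DD.shape, dtype=bool)
        return
    labels = np.unique(triplet.roi_labels)
    for lab in labels[labels > 0]:
        yield int(lab), triplet.roi_labels == lab


def efret_efficiency(
    fc: np.ndarray,
    i_dd: np.ndarray,
    G: float = 1.75,
    roi_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI apparent efficiency E_app = mean(Fc)/(mean(Fc) + G·mean(I_DD)).

    A non-positive denominator yields a flagged missing value (NaN), never a
    silently clipped efficiency.
    """
    if G <= 0:
        raise ParameterError("G must be positive")
    fc = np.asarray(fc, dtype=float)
    i_dd = np.asarray(i_dd, dtype=float)
    if roi_labels is None:
        rois = [(1, np.ones(fc.shape, dtype=bool))]
    else:
        roi_labels = np.asarray(roi_labels)
        rois = [
            (int(lab), roi_labels == lab)
            for lab in np.unique(roi_labels)
            if lab > 0
        ]
    if not rois:
        raise InputError("empty ROI set")
    rows = []
    for lab, mask in rois:
        fc_m = float(fc[mask].mean())
        dd_m = float(i_dd[mask].mean())
        denom = fc_m + G * dd_m
        if denom <= 0:
            rows.append((lab, np.nan, fc_m, dd_m, "denominator<=0"))
            continue
        e = fc_m / denom
        flag = "" if 0.0 <= e <= 1.0 else "E_app outside [0,1]"
        if flag:
            logger.warning("ROI %d: %s (E_app=%.3g)", lab, flag, e)
        rows.append((lab, e, fc_m, dd_m, flag))
    return pd.DataFrame(
        rows, columns=["roi", "E_app", "Fc_mean", "I_DD_mean", "flag"]
    )


def gate_rois(
    triplet: ImageTriplet,
    ratio_bounds: tuple[float, float] = (2.0, 6.0),
) -> pd.DataFrame:
    """Keep ROIs with acceptor/donor (I_AA/I_DD) mean ratio inside the bounds.

    Returns one row per ROI with the ratio, a kept flag and the exclusion
    reason ('ratio<min' / 'ratio>max') for rejected ROIs.
    """
    lo, hi = ratio_bounds
    if hi < lo:
        raise ParameterError("ratio bounds inverted")
    rows = []
    any_roi = False
    for lab, mask in _roi_iter(triplet):
        any_roi = True
        dd = float(triplet.I_DD[mask].mean())
        aa = float(triplet.I_AA[mask].mean())
        ratio = np.inf if dd == 0 else aa / dd
        if ratio < lo:
            rows.append((lab, ratio, False, "ratio<min"))
        elif ratio > hi:
            rows.append((lab, ratio, False, "ratio>max"))
        else:
            rows.append((lab, ratio, True, ""))
    if not any_roi:
        raise InputError("empty ROI set")
    return pd.DataFrame(rows, columns=["roi", "ratio", "kept", "reason"])


def compute_efret(
    triplet: ImageTriplet,
    constants: EFretConstants | None = None,
    ratio_bounds: tuple[float, float] = (2.0, 6.0),
) -> EFretResult:
    """Full three-cube analysis: Fc image, gating, per-ROI E_app."""
    k = constants or EFretConstants()
    fc = corrected_fret(triplet, k)
    eff = efret_efficiency(fc, triplet.I_DD, k.G, triplet.roi_labels)
    gates = gate_rois(triplet, ratio_bounds)
    table = eff.merge(gates, on="roi", how="left")
    return EFretResult(fc_image=fc, table=table, constants=k)


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------


def write_triplet(
    directory: str | Path,
    triplet: ImageTriplet,
    sidecar: dict | None = None,
    stem: str = "fret",
) -> dict:
    """Write 16-bit TIFFs (one per channel) plus a JSON ground-truth sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("I_DD", "I_AA", "I_DA"):
        img = np.clip(np.round(getattr(triplet, name)), 0, 65535).astype(np.uint16)
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(p, img)
        paths[name] = str(p)
    if sidecar is not None:
        p = directory / f"{stem}_truth.json"
        with open(p, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        paths["sidecar"] = str(p)
    return paths


def read_triplet(directory: str | Path, stem: str = "fret") -> ImageTriplet:
    """Read a channel triplet written by :func:`write_triplet`."""
    import tifffile

    directory = Path(directory)
    imgs = {}
    for name in ("I_DD", "I_AA", "I_DA"):
        p = directory / f"{stem}_{name}.tif"
        if not p.exists():
            raise InputError(f"missing channel image {p}")
        imgs[name] = tifffile.imread(p).astype(float)
    return ImageTriplet(**imgs)
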