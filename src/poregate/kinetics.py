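"""Whole-cell blocker kinetics, fractional blockade, I–V analysis.

The blocker model is the single-site scheme in which a blocker (e.g. Cd²⁺)
binds an extracellularly accessible site with second-order rate constant
``kon`` and leaves with ``koff``.  Blockade then develops mono-exponentially
with time constant

    τ = 1 / (kon·[B] + koff)

to a steady blocked fraction

    f = kon·[B] / (kon·[B] + koff),

so the rates follow from a fitted (τ, f):  kon = f/(τ·[B]), koff = (1−f)/τ.

I–V conventions follow standard whole-cell CRAC recordings: a 100-ms step to
−100 mV then a 100-ms ramp from −100 to +100 mV once per second; voltages are
corrected for a −10 mV liquid junction potential; leak is subtracted using
traces collected in La³⁺; the reversal potential is the interpolated
zero-current crossing of the averaged leak-subtracted ramp, and when the
curve only approaches the voltage axis asymptotically with no crossing it is
assigned the +80 mV sentinel (flagged as assigned, not measured).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    AlignmentError,
    FitError,
    ParameterError,
    UndefinedBlockError,
)


@dataclass
class CurrentTrace:
    """A time/current/voltage table with annotations.

    ``annotations`` carries protocol metadata: blocker application window (s),
    blocker concentration (M), membrane capacitance (pF), solutions, etc.
    """

    time_s: np.ndarray
    current_pA: np.ndarray
    voltage_mV: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        n = self.time_s.size
        if self.current_pA.size != n or self.voltage_mV.size != n:
            raise ParameterError("time/current/voltage columns must be equal length")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ParameterError("time must be strictly increasing")

    def window(self, t0: float, t1: float) -> np.ndarray:
        return (self.time_s >= t0) & (self.time_s <= t1)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "voltage_mV": self.voltage_mV,
                "current_pA": self.current_pA,
            }
        ).to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, annotations: dict | None = None) -> "CurrentTrace":
        df = pd.read_csv(path)
        sep = "\t" if len(df.columns) == 1 else ","
        if len(df.columns) == 1:
            df = pd.read_csv(path, sep=sep)
        return cls(
            time_s=df["time_s"].to_numpy(),
            current_pA=df["current_pA"].to_numpy(),
            voltage_mV=df["voltage_mV"].to_numpy(),
            annotations=annotations or {},
        )


@dataclass
class BlockKineticsFit:
    """Fitted single-site blocker kinetics.

    Invariants: kon = f/(τ·[B]), koff = (1−f)/τ and hence 1/τ = kon·[B]+koff
    hold exactly on the fitted values.
    """

    tau_s: float
    blocked_fraction: float
    kon_per_M_per_s: float | None = None
    koff_per_s: float | None = None
    concentration_M: float | None = None
    residual_sd_pA: float | None = None
    tau_ci95_s: tuple[float, float] | None = None


def fractional_block(
    trace: CurrentTrace,
    pre_window: tuple[float, float],
    block_window: tuple[float, float],
    step_voltage_mV: float | None = -100.0,
    voltage_tol_mV: float = 1.0,
    noise_floor_pA: float | None = None,
) -> float:
    """Fractional blockade f = 1 − mean(I_block)/mean(I_control).

    Means are taken over the two time windows, restricted to samples at the
    −100 mV step when the trace contains a varying voltage command.  Raises
    :class:`UndefinedBlockError` when the control current is at the noise
    floor.
    """
    vm = (
        np.abs(trace.voltage_mV - step_voltage_mV) <= voltage_tol_mV
        if step_voltage_mV is not None
        else np.ones(trace.time_s.size, dtype=bool)
    )
    pre = trace.window(*pre_window) & vm
    blk = trace.window(*block_window) & vm
    if not pre.any() or not blk.any():
        raise ParameterError("empty pre/block window after voltage filtering")
    i_ctrl = float(trace.current_pA[pre].mean())
    i_b = float(trace.current_pA[blk].mean())
    floor = noise_floor_pA
    if floor is None:
        floor = 3.0 * float(np.std(trace.current_pA[pre])) if pre.sum() > 2 else 0.0
    if abs(i_ctrl) <= floor:
        raise UndefinedBlockError(
            f"control current {i_ctrl:.3g} pA is at the noise floor ({floor:.3g} pA)"
        )
    return 1.0 - i_b / i_ctrl


def _sweep_series(
    trace: CurrentTrace,
    window: tuple[float, float],
    sweep_interval_s: float,
    step_voltage_mV: float | None,
    voltage_tol_mV: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sweep current series: one sample per protocol sweep in the window."""
    t0, t1 = window
    vm = (
        np.abs(trace.voltage_mV - step_voltage_mV) <= voltage_tol_mV
        if step_voltage_mV is not None
        else np.ones(trace.time_s.size, dtype=bool)
    )
    dt = np.median(np.diff(trace.time_s)) if trace.time_s.size > 1 else sweep_interval_s
    if dt >= 0.99 * sweep_interval_s:
        m = trace.window(t0, t1) & vm
        return trace.time_s[m], trace.current_pA[m]
    times, currents = [], []
    k0 = int(np.ceil(t0 / sweep_interval_s))
    k1 = int(np.floor(t1 / sweep_interval_s))
    for k in range(k0, k1 + 1):
        tc = k * sweep_interval_s
        m = trace.window(tc - sweep_interval_s / 4, tc + sweep_interval_s / 4) & vm
        if m.any():
            times.append(tc)
            currents.append(float(trace.current_pA[m].mean()))
    return np.asarray(times), np.asarray(currents)


def fit_block_time_constant(
    trace: CurrentTrace,
    block_window: tuple[float, float],
    sweep_interval_s: float = 1.0,
    step_voltage_mV: float | None = -100.0,
) -> BlockKineticsFit:
    """Mono-exponential fit of blockade development at the −100 mV step.

    Fits I(t) = I_∞ + (I₀ − I_∞)·exp(−(t−t₀)/τ) on the per-sweep current
    series inside the window and returns τ with the implied steady blocked
    fraction f = 1 − I_∞/I₀.  A relaxation indistinguishable from noise (flat
    trace) raises :class:`FitError` rather than returning a spurious τ.
    """
    t, i = _sweep_series(trace, block_window, sweep_interval_s, step_voltage_mV)
    if t.size < 10:
        raise ParameterError(
            f"need >=10 samples in the block window, got {t.size}"
        )
    t_rel = t - t[0]

    def model(tt, i_inf, i0, tau):
        return i_inf + (i0 - i_inf) * np.exp(-tt / tau)

    span = max(t_rel[-1], sweep_interval_s)
    p0 = (i[-1], i[0], span / 3.0)
    try:
        popt, pcov = curve_fit(
            model, t_rel, i, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    i_inf, i0, tau = popt
    resid = i - model(t_rel, *popt)
    rsd = float(np.std(resid, ddof=min(3, t.size - 1)))
    if abs(i0 - i_inf) <= 2.0 * rsd or abs(i0) < 1e-12:
        raise FitError(
            "no significant relaxation in the block window "
            f"(amplitude {abs(i0 - i_inf):.3g} pA vs residual SD {rsd:.3g} pA)"
        )
    tau_sd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return BlockKineticsFit(
        tau_s=float(tau),
        blocked_fraction=float(1.0 - i_inf / i0),
        residual_sd_pA=rsd,
        tau_ci95_s=(float(tau - 1.96 * tau_sd), float(tau + 1.96 * tau_sd)),
    )


def derive_rate_constants(
    tau_s: float, blocked_fraction: float, concentration_M: float,
    tolerance: float = 0.02,
) -> tuple[float, float]:
    """kon = f/(τ·[B]) and koff = (1−f)/τ from a fitted (τ, f).

    ``tolerance`` forgives small fit overshoot of f outside [0, 1] (clipped);
    larger excursions raise :class:`ParameterError`.
    """
    if tau_s <= 0:
        raise ParameterError("tau must be positive")
    if concentration_M <= 0:
        raise ParameterError("blocker concentration must be positive")
    f = float(blocked_fraction)
    if f < -tolerance or f > 1 + tolerance:
        raise ParameterError(f"blocked fraction {f:.3g} outside [0, 1]")
    f = float(np.clip(f, 0.0, 1.0))
    return f / (tau_s * concentration_M), (1.0 - f) / tau_s


def fit_block_kinetics(
    trace: CurrentTrace,
    block_window: tuple[float, float],
    concentration_M: float,
    sweep_interval_s: float = 1.0,
    step_voltage_mV: float | None = -100.0,
) -> BlockKineticsFit:
    """Fit τ and f, then derive kon/koff at the given blocker concentration."""
    fit = fit_block_time_constant(
        trace, block_window, sweep_interval_s, step_voltage_mV
    )
    kon, koff = derive_rate_constants(fit.tau_s, fit.blocked_fraction, concentration_M)
    fit.kon_per_M_per_s = kon
    fit.koff_per_s = koff
    fit.concentration_M = concentration_M
    return fit


def leak_subtract(trace: CurrentTrace, leak: CurrentTrace,
                  voltage_tol_mV: float = 1e-6) -> CurrentTrace:
    """Point-wise leak subtraction after aligning by voltage sample."""
    if trace.time_s.size != leak.time_s.size:
        raise AlignmentError("trace and leak have different lengths")
    if np.max(np.abs(trace.voltage_mV - leak.voltage_mV)) > voltage_tol_mV:
        raise AlignmentError("voltage protocols do not match")
    return CurrentTrace(
        time_s=trace.time_s,
        current_pA=trace.current_pA - leak.current_pA,
        voltage_mV=trace.voltage_mV,
        annotations={**trace.annotations, "leak_subtracted": True},
    )


@dataclass
class IVRamp:
    """Averaged, junction-corrected I–V ramp with its reversal potential."""

    voltage_mV: np.ndarray
    current_pA: np.ndarray
    vrev_mV: float
    assigned: bool  # True when the +80 mV sentinel rule fired
    flags: list = field(default_factory=list)


def reversal_potential(
    sweeps: Sequence[CurrentTrace],
    junction_mV: float = -10.0,
    sentinel_mV: float = 80.0,
    asymptote_fraction: float = 0.05,
) -> IVRamp:
    """Reversal potential from averaged leak-subtracted ramp sweeps.

    Sweeps (typically 4-6) are averaged point-wise; the junction correction is
    added to the voltage axis; Vrev is the linearly interpolated zero-current
    crossing.  With no crossing and |I| at the positive end below
    ``asymptote_fraction``·|I| at the negative end (the curve "asymptotically
    approaches the x axis"), Vrev is assigned the sentinel (+80 mV), flagged.
    Multiple crossings (noisy near-flat I–V) resolve to the crossing nearest
    the median crossing, flagged.
    """
    if not sweeps:
        raise ParameterError("need at least one sweep")
    n = sweeps[0].time_s.size
    v0 = sweeps[0].voltage_mV
    for s in sweeps[1:]:
        if s.time_s.size != n:
            raise AlignmentError("sweeps of unequal length")
        if np.max(np.abs(s.voltage_mV - v0)) > 1e-6:
            raise AlignmentError("sweep voltage protocols do not match")
    i_mean = np.mean([s.current_pA for s in sweeps], axis=0)
    v = v0 + junction_mV
    order = np.argsort(v)
    v, i_mean = v[order], i_mean[order]
    flags: list[str] = []
    sign = np.sign(i_mean)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    vrev_candidates = [float(x) for x in v[i_mean == 0]]
    for k in crossings:
        dv = v[k + 1] - v[k]
        vrev_candidates.append(
            float(v[k] - i_mean[k] * dv / (i_mean[k + 1] - i_mean[k]))
        )
    if vrev_candidates:
        if len(vrev_candidates) > 1:
            med = float(np.median(vrev_candidates))
            vrev = min(vrev_candidates, key=lambda x: abs(x - med))
            flags.append(f"multiple zero crossings ({len(vrev_candidates)}); "
                         "chose the one nearest their median")
        else:
            vrev = float(vrev_candidates[0])
        return IVRamp(v, i_mean, vrev, assigned=False, flags=flags)
    i_neg = abs(float(i_mean[0]))
    i_pos = abs(float(i_mean[-1]))
    if i_neg > 0 and i_pos <= asymptote_fraction * i_neg:
        flags.append(f"no zero crossing; asymptotic I-V, Vrev assigned {sentinel_mV} mV")
        return IVRamp(v, i_mean, float(sentinel_mV), assigned=True, flags=flags)
    raise FitError(
        "no zero crossing and the I-V does not approach the voltage axis "
        f"(|I| at +end is {i_pos:.3g} vs {i_neg:.3g} pA at -end)"
    )


def peak_current(
    trace: CurrentTrace,
    step_window: tuple[float, float],
    settle_s: float = 0.010,
) -> float:
    """Peak (largest-|I|) current in a voltage-step window after settling."""
    t0, t1 = step_window
    m = trace.window(t0 + settle_s, t1)
    if not m.any():
        raise ParameterError("empty step window after settle time")
    i = trace.current_pA[m]
    return float(i[np.argmax(np.abs(i))])


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Signed current density (pA/pF); capacitance must be positive."""
    if capacitance_pF <= 0:
        raise ParameterError("capacitance must be positive")
    return peak_pA / capacitance_pF
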