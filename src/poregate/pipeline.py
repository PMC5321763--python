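"""End-to-end orchestration: synthesize → analyze → summarize.

A run is described by a serializable :class:`RunConfig` (YAML-friendly):
a seed, an output directory, and a static, explicitly ordered list of stages.
Each stage has a ``kind`` (registry below), a ``name``, optional ``needs``
(names of upstream stages whose in-memory products it consumes) and a
``params`` mapping.  Stages execute in the declared order; a failing stage is
recorded and its dependents are skipped; the first hard error is reflected in
the run report status.  A run manifest (config echo, package version, seeds,
parameter hash) plus per-stage CSV/JSON outputs make a completed run
reproducible: the same config and seed give byte-identical CSV outputs for
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import __version__
from .errors import InputError, PoregateError

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Fully serializable description of a pipeline run."""

    outdir: str
    seed: int = 0
    stages: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise InputError("config must define 'outdir'")
        return cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"outdir": self.outdir, "seed": self.seed, "stages": self.stages},
                fh, sort_keys=False,
            )

    def parameter_hash(self) -> str:
        canon = yaml.safe_dump(
            {"seed": self.seed, "stages": self.stages}, sort_keys=True
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    name: str
    kind: str
    status: str  # ok | error | skipped
    wall_time_s: float = 0.0
    error: str | None = None
    outputs: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)


@dataclass
class RunReport:
    config: RunConfig
    stages: list[StageResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages)

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# stage registry
# ---------------------------------------------------------------------------

StageFn = Callable[[dict, dict, Path, int], tuple[dict, dict, Any]]
_REGISTRY: dict[str, StageFn] = {}


def register(kind: str):
    def deco(fn: StageFn) -> StageFn:
        _REGISTRY[kind] = fn
        return fn
    return deco


def _stage_seed(base_seed: int, index: int) -> int:
    return (base_seed * 1009 + 17 * index) % (2**31 - 1)


@register("build_pore")
def _stage_build_pore(params, ctx, outdir, seed):
    from .structure import write_pdb
    from .synthetic import IdealPoreSpec, SideChainTemplate, build_ideal_pore

    decorated = {
        int(k): SideChainTemplate(**v)
        for k, v in dict(params.pop("decorated_residues", {})).items()
    }
    spec = IdealPoreSpec(decorated_residues=decorated, seed=seed, **params)
    pore = build_ideal_pore(spec)
    path = outdir / "pore.pdb"
    write_pdb(path, pore)
    return {"pdb": str(path)}, {"n_atoms": pore.n_atoms}, pore


@register("trajectory")
def _stage_trajectory(params, ctx, outdir, seed):
    from .structure import write_pdb
    from .synthetic import (
        DensityTable, IdealPoreSpec, SideChainTemplate, SyntheticTrajectorySpec,
        generate_trajectory,
    )

    pore_params = dict(params.pop("pore", {}))
    decorated = {
        int(k): SideChainTemplate(**v)
        for k, v in dict(pore_params.pop("decorated_residues", {})).items()
    }
    pore = IdealPoreSpec(decorated_residues=decorated, seed=seed, **pore_params)
    density = params.pop("water_axial_density", None)
    if density is not None:
        density = DensityTable(
            z_edges=tuple(density["z_edges"]), lam=tuple(density["lam"])
        )
    offsets = params.pop("rotation_offsets", 0.0)
    if isinstance(offsets, list):
        offsets = tuple(
            tuple(o) if isinstance(o, list) else o for o in offsets
        )
    spec = SyntheticTrajectorySpec(
        pore=pore, water_axial_density=density, rotation_offsets=offsets,
        seed=seed, **params,
    )
    traj = generate_trajectory(spec)
    path = outdir / f"{spec.repeat_id}.pdb"
    write_pdb(path, traj)
    return {"pdb": str(path)}, {"n_frames": traj.n_frames}, traj


@register("rotation")
def _stage_rotation(params, ctx, outdir, seed):
    from .geometry import helix_rotation
    from .structure import Structure

    traj = ctx[params.pop("trajectory")]
    ref = ctx[params.pop("reference")]
    if not isinstance(ref, Structure):
        ref = ref.topology if hasattr(ref, "topology") else ref
    pore_residues = tuple(params.pop("pore_residues", (141, 174)))
    series = helix_rotation(traj, ref, pore_residues=pore_residues, **params)
    csv = outdir / "rotation.csv"
    series.values.to_csv(csv, index=False, float_format=_FLOAT_FMT)
    summary = {
        "residue": series.residue,
        "mean_deg": series.mean,
        "sem_deg": series.sem,
    }
    with open(outdir / "rotation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"csv": str(csv), "json": str(outdir / "rotation.json")}, summary, series


@register("radial_angle")
def _stage_radial_angle(params, ctx, outdir, seed):
    from .geometry import radial_angle_series

    traj = ctx[params.pop("trajectory")]
    pore_residues = tuple(params.pop("pore_residues", (141, 174)))
    series = radial_angle_series(traj, pore_residues=pore_residues, **params)
    csv = outdir / "radial_angle.csv"
    series.values.to_csv(csv, index=False, float_format=_FLOAT_FMT)
    summary = {
        "residue": series.residue,
        "mean_deg": series.mean,
        "sem_deg": series.sem,
    }
    with open(outdir / "radial_angle.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"csv": str(csv)}, summary, series


@register("occupancy")
def _stage_occupancy(params, ctx, outdir, seed):
    from .occupancy import axial_profile

    names = params.pop("trajectories")
    trajs = [ctx[n] for n in (names if isinstance(names, list) else [names])]
    if "bin_edges" in params:
        params["bin_edges"] = np.asarray(params["bin_edges"], dtype=float)
    pore_residues = tuple(params.pop("pore_residues", (141, 174)))
    profile = axial_profile(trajs, pore_residues=pore_residues, **params)
    csv = outdir / f"occupancy_{profile.species}.csv"
    profile.to_frame().to_csv(csv, index=False, float_format=_FLOAT_FMT)
    summary = {"species": profile.species, "total_per_frame": profile.total()}
    return {"csv": str(csv)}, summary, profile


@register("block_trace")
def _stage_block_trace(params, ctx, outdir, seed):
    from .synthetic import SyntheticTraceSpec, generate_block_trace

    spec = SyntheticTraceSpec(seed=seed, **{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in params.items()
    })
    trace = generate_block_trace(spec)
    csv = outdir / "block_trace.csv"
    trace.to_csv(csv)
    return {"csv": str(csv)}, {"n_samples": trace.time_s.size}, trace


@register("block_kinetics")
def _stage_block_kinetics(params, ctx, outdir, seed):
    from .kinetics import fit_block_kinetics

    trace = ctx[params.pop("trace")]
    window = tuple(params.pop("block_window"))
    fit = fit_block_kinetics(trace, window, **params)
    summary = {
        "tau_s": fit.tau_s,
        "blocked_fraction": fit.blocked_fraction,
        "kon_per_M_per_s": fit.kon_per_M_per_s,
        "koff_per_s": fit.koff_per_s,
    }
    with open(outdir / "block_kinetics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"json": str(outdir / "block_kinetics.json")}, summary, fit


@register("iv_ramps")
def _stage_iv_ramps(params, ctx, outdir, seed):
    from .synthetic import SyntheticRampSpec, generate_iv_ramps

    spec = SyntheticRampSpec(seed=seed, **params)
    sweeps, leak = generate_iv_ramps(spec)
    return {}, {"n_sweeps": len(sweeps)}, (sweeps, leak)


@register("reversal")
def _stage_reversal(params, ctx, outdir, seed):
    from .kinetics import leak_subtract, reversal_potential

    sweeps, leak = ctx[params.pop("ramps")]
    if params.pop("leak_subtract", True):
        sweeps = [leak_subtract(s, leak) for s in sweeps]
    ramp = reversal_potential(sweeps, **params)
    summary = {"vrev_mV": ramp.vrev_mV, "assigned": ramp.assigned,
               "flags": ramp.flags}
    with open(outdir / "reversal.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"json": str(outdir / "reversal.json")}, summary, ramp


@register("fret_images")
def _stage_fret_images(params, ctx, outdir, seed):
    from .synthetic import SyntheticFretSpec, generate_fret_images
    from .efret import write_triplet

    spec = SyntheticFretSpec(seed=seed, **{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in params.items()
    })
    triplet, truth = generate_fret_images(spec)
    paths = write_triplet(outdir, triplet, sidecar=truth)
    return paths, {"true_efficiency": truth["true_efficiency"]}, triplet


@register("efret")
def _stage_efret(params, ctx, outdir, seed):
    from .efret import EFretConstants, compute_efret

    triplet = ctx[params.pop("images")]
    constants = EFretConstants(**params.pop("constants", {}))
    result = compute_efret(triplet, constants, **params)
    csv = outdir / "efret.csv"
    result.table.to_csv(csv, index=False, float_format=_FLOAT_FMT)
    mean_e = float(result.table.loc[result.table["kept"] == True, "E_app"].mean())
    return {"csv": str(csv)}, {"mean_E_app": mean_e}, result


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order; fail-fast per dependency chain."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    ctx: dict[str, Any] = {}
    failed: set[str] = set()
    for index, stage in enumerate(config.stages):
        stage = dict(stage)
        name = stage.get("name", f"stage-{index}")
        kind = stage.get("kind")
        needs = list(stage.get("needs", []))
        params = dict(stage.get("params", {}))
        if kind not in _REGISTRY:
            report.stages.append(
                StageResult(name, str(kind), "error", error=f"unknown stage kind {kind!r}")
            )
            failed.add(name)
            continue
        if set(needs) & failed:
            report.stages.append(
                StageResult(name, kind, "skipped",
                            error=f"upstream failure in {sorted(set(needs) & failed)}")
            )
            failed.add(name)
            continue
        missing = [n for n in needs if n not in ctx]
        if missing:
            report.stages.append(
                StageResult(name, kind, "error",
                            error=f"missing inputs {missing} (not yet run?)")
            )
            failed.add(name)
            continue
        stage_dir = outdir / name
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        try:
            outputs, values, product = _REGISTRY[kind](
                params, ctx, stage_dir, _stage_seed(config.seed, index)
            )
            ctx[name] = product
            report.stages.append(
                StageResult(name, kind, "ok",
                            wall_time_s=time.perf_counter() - t0,
                            outputs=outputs, values=values)
            )
        except (PoregateError, KeyError, TypeError) as exc:
            report.stages.append(
                StageResult(name, kind, "error",
                            wall_time_s=time.perf_counter() - t0,
                            error=f"{type(exc).__name__}: {exc}")
            )
            failed.add(name)
    manifest = {
        "poregate_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": [
            {"name": s.name, "kind": s.kind, "status": s.status,
             "wall_time_s": round(s.wall_time_s, 4), "error": s.error,
             "outputs": s.outputs, "values": s.values}
            for s in report.stages
        ],
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
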