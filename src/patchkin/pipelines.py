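"""End-to-end analysis pipelines.

Bind the stages into the three standard analyses — spontaneous-activity
kinetic fitting, blocker concentration series, and electrical
fingerprinting — plus a simulation pipeline that writes synthetic event
files.  Each run is deterministic given its seed and emits a provenance
record (config echo, seed, package version, per-stage counts) sufficient to
reproduce every number in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .block import BlockSeries, block_signatures, fit_block_series
from .dwells import fit_exp_mixture, select_component_count
from .errors import ConfigurationError
from .events import BurstSet, EventList
from .fingerprint import (
    class_mean_regression,
    ebah,
    fit_amplitude_classes,
    infer_subunit_count,
)
from .io import read_events, write_events
from .mil import FitProblem, FitResult, global_fit
from .preprocess import define_bursts, determine_tau_crit, impose_dead_time
from .presets import scheme_preset
from .schemes import KineticScheme
from .simulate import SimulationConfig, simulate_recording

DEFAULT_DEAD_TIME = 18.83e-6       # s
FINGERPRINT_TAU_CRIT = 2e-3        # s, uniform burst cutoff for amplitudes


@dataclass
class RunConfig:
    pipeline: str                  # simulate | spontaneous | block | fingerprint
    seed: int
    scheme: KineticScheme | str | None = None
    inputs: Sequence[str | Path] = ()
    concentrations: Mapping[str, float] = field(default_factory=dict)
    dead_time: float = DEFAULT_DEAD_TIME
    tau_crit: float | str = "auto"
    n_events: int = 10_000
    n_recordings: int = 3
    output_dir: str | Path | None = None
    extra: dict = field(default_factory=dict)


def _resolve_scheme(spec: KineticScheme | str | None) -> KineticScheme:
    if isinstance(spec, KineticScheme):
        return spec
    if isinstance(spec, str):
        if spec.upper() in ("S1", "S2", "S3", "S4", "S5"):
            return scheme_preset(spec)
        import yaml

        with open(spec) as fh:
            return KineticScheme.from_dict(yaml.safe_load(fh))
    raise ConfigurationError("pipeline requires a scheme (preset name, "
                             "config file, or KineticScheme)")


def _load_events(config: RunConfig) -> list[EventList]:
    if config.inputs:
        return [read_events(p) for p in config.inputs]
    # no files: generate the default synthetic condition (three recordings)
    scheme = _resolve_scheme(config.scheme)
    out = []
    for r in range(config.n_recordings):
        cfg = SimulationConfig(
            scheme=scheme,
            seed=config.seed + 1000 * r,
            concentrations=config.concentrations,
            n_events=config.n_events,
        )
        ev = simulate_recording(cfg)
        ev.meta["recording_id"] = f"sim{r}"
        out.append(ev)
    return out


def auto_tau_crit(
    recordings: Sequence[EventList], dead_time: float, seed: int
) -> tuple[float, object]:
    """Critical shut duration from a two-component fit of pooled shut dwells."""
    shuts = np.concatenate([ev.shut_durations() for ev in recordings])
    fit = fit_exp_mixture(shuts, 2, dead_time=dead_time, seed=seed)
    return determine_tau_crit(fit.components), fit


def run_pipeline(config: RunConfig) -> dict:
    """Execute one pipeline; returns a report dict (and writes files).

    The report always carries a ``provenance`` block; numeric results are
    plain Python/numpy scalars, reproducible from the provenance alone.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "pipeline": config.pipeline,
            "seed": config.seed,
            "version": __version__,
            "dead_time_s": config.dead_time,
            "tau_crit": config.tau_crit,
            "n_events": config.n_events,
            "n_recordings": config.n_recordings,
            "inputs": [str(p) for p in config.inputs],
        }
    }
    if config.pipeline == "simulate":
        recordings = _load_events(config)
        paths = []
        for ev in recordings:
            if out_dir:
                p = out_dir / f"{ev.meta.get('recording_id', 'rec')}.tsv"
                ev.meta["dead_time_s"] = config.dead_time
                write_events(ev, p)
                paths.append(str(p))
        report["n_recordings"] = len(recordings)
        report["n_events"] = [len(ev) for ev in recordings]
        report["files"] = paths
    elif config.pipeline == "spontaneous":
        report.update(_run_spontaneous(config))
    elif config.pipeline == "block":
        report.update(_run_block(config))
    elif config.pipeline == "fingerprint":
        report.update(_run_fingerprint(config))
    else:
        raise ConfigurationError(f"unknown pipeline {config.pipeline!r}")
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _fit_report(res: FitResult) -> dict:
    return {
        "rates": {s: {"value": v, "se": se} for s, (v, se) in
                  res.estimates.items()},
        "fixed": dict(res.fixed),
        "loglik": res.loglik,
        "converged": res.converged,
        "n_dwells": res.n_dwells,
        "derived": {
            "K_prime": res.derived.K_prime,
            "Theta": res.derived.Theta,
            "K": res.derived.K,
            "K_B": res.derived.K_B,
        },
    }


def _run_spontaneous(config: RunConfig) -> dict:
    scheme = _resolve_scheme(config.scheme)
    recordings = [impose_dead_time(ev, config.dead_time)
                  for ev in _load_events(config)]
    if config.tau_crit == "auto":
        tau_crit, shut_fit = auto_tau_crit(recordings, config.dead_time,
                                           config.seed)
    else:
        tau_crit, shut_fit = float(config.tau_crit), None
    burst_stats = []
    for ev in recordings:
        bs = define_bursts(ev, tau_crit)
        burst_stats.append({
            "n_bursts": len(bs),
            "mean_popen": float(np.mean(bs.popen)) if len(bs) else np.nan,
            "mean_openings": float(np.mean(bs.openings_per_burst()))
            if len(bs) else np.nan,
        })
    # fit on the full conditioned dwell sequences (one segment each)
    datasets = [(BurstSet([ev], np.inf), config.concentrations)
                for ev in recordings]
    problem = FitProblem(scheme=scheme, datasets=datasets,
                         dead_time=config.dead_time, seed=config.seed)
    res = global_fit(problem)
    open_dwells = np.concatenate([ev.open_durations() for ev in recordings])
    n_open, _ = select_component_count(open_dwells, 4, config.dead_time,
                                       seed=config.seed)
    return {
        "tau_crit_s": tau_crit,
        "shut_components": None if shut_fit is None else shut_fit.components,
        "bursts": burst_stats,
        "open_component_count": n_open,
        "fit": _fit_report(res),
    }


def _run_block(config: RunConfig) -> dict:
    scheme = _resolve_scheme(config.scheme)
    blocker = config.extra.get("blocker")
    series_spec = config.extra.get("series")   # list of (paths|conc, ...)
    if blocker is None or series_spec is None:
        raise ConfigurationError(
            "block pipeline needs extra={'blocker': name, "
            "'series': [(concentration_uM, [event files]), ...]}"
        )
    datasets = []
    for conc, paths in series_spec:
        for p in paths:
            ev = impose_dead_time(read_events(p), config.dead_time)
            datasets.append((BurstSet([ev], np.inf), float(conc)))
    series = BlockSeries(blocker=blocker, scheme=scheme, datasets=datasets,
                         dead_time=config.dead_time)
    core_rates = config.extra.get("core_rates")
    fits = fit_block_series(series, core_rates=core_rates, seed=config.seed)
    return {
        "signatures": block_signatures(series).to_dict(orient="records"),
        "fits": {name: _fit_report(res) for name, res in fits.items()},
    }


def _run_fingerprint(config: RunConfig) -> dict:
    if config.inputs:
        amplitudes = []
        for p in config.inputs:
            ev = read_events(p)
            bs = define_bursts(ev, FINGERPRINT_TAU_CRIT)
            amplitudes.append(bs.amplitudes[~np.isnan(bs.amplitudes)])
        amps = np.concatenate(amplitudes)
    else:
        from .simulate import PentamerAssemblyConfig, simulate_fingerprint_bursts

        cfg = PentamerAssemblyConfig(seed=config.seed,
                                     **config.extra.get("assembly", {}))
        amps, _ = simulate_fingerprint_bursts(cfg)
    model = fit_amplitude_classes(amps, seed=config.seed)
    endpoints = config.extra.get("endpoints", (1.5, 16.0))
    inference = infer_subunit_count(model, endpoints)
    edges, fractions = ebah(amps)
    out = {
        "n_bursts": int(amps.size),
        "classes": {
            "means_pA": model.means.tolist(),
            "weights": model.weights.tolist(),
            "sd_pA": float(model.sds[0]),
        },
        "inference": inference,
        "ebah": {"edges_pA": edges.tolist(), "fractions": fractions.tolist()},
    }
    if model.n_classes >= 3:
        slope, intercept, resid = class_mean_regression(model)
        out["linearity"] = {"slope_pA_per_subunit": slope,
                            "intercept_pA": intercept,
                            "residual_sd_pA": resid}
    return out
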