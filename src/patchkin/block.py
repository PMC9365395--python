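"""Open-channel block analysis across a blocker concentration series.

A blocker (acetylcholine at high concentration, or QX-222) transiently
occludes the open pore: openings shorten with concentration while brief
intra-burst closings multiply.  The analysis extends a core scheme with a
single non-conducting blocked state off an open state, fits the pooled
multi-concentration dwell data globally (optionally with the core rates
constrained to an agonist-free fit), and reports the blocking rate
constants and the block dissociation constant K_B = k_minusB / k_plusB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemeError
from .events import BurstSet
from .mil import FitProblem, FitResult, global_fit
from .schemes import (
    OPEN,
    SHUT,
    KineticScheme,
    State,
    Transition,
    build_generator,
    mean_dwell,
)


def extend_with_block(
    core: KineticScheme,
    blocker: str,
    from_open_state: str,
    k_plusB: float = 100.0,
    k_minusB: float = 10000.0,
    blocked_state: str | None = None,
    symbol_suffix: str = "",
) -> KineticScheme:
    """Append a blocked (non-conducting) state to an open state.

    The forward rate carries units uM^-1 s^-1 and scales with the blocker
    concentration.  Extending twice with different suffixes yields two
    distinct blocked states (e.g. coexisting ACh and QX-222 block).
    """
    by_name = {s.name: s for s in core.states}
    if from_open_state not in by_name:
        raise SchemeError(f"unknown state {from_open_state!r}")
    if by_name[from_open_state].conductance != OPEN:
        raise SchemeError(f"{from_open_state!r} is not an open state")
    bname = blocked_state or f"{from_open_state}_B{symbol_suffix}"
    if bname in by_name:
        raise SchemeError(f"state name {bname!r} already in use")
    suff = f"_{symbol_suffix}" if symbol_suffix else ""
    states = core.states + (State(bname, SHUT, role="open-blocked"),)
    transitions = core.transitions + (
        Transition(from_open_state, bname, f"k_plusB{suff}", k_plusB,
                   ligand=blocker),
        Transition(bname, from_open_state, f"k_minusB{suff}", k_minusB),
    )
    return KineticScheme(f"{core.name}+block({blocker})", states, transitions)


@dataclass
class BlockSeries:
    """Recordings of one channel over a range of blocker concentrations."""

    blocker: str
    scheme: KineticScheme            # already extended with the blocked state
    datasets: Sequence[tuple[BurstSet, float]]   # (bursts, blocker conc uM)
    dead_time: float = 0.0
    extra_concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        concs = {c for _, c in self.datasets}
        if len(concs) < 2:
            raise SchemeError(
                "a block series needs at least two distinct concentrations"
            )

    def fit_problem(self, **kwargs) -> FitProblem:
        return FitProblem(
            scheme=self.scheme,
            datasets=[
                (bs, {**self.extra_concentrations, self.blocker: conc})
                for bs, conc in self.datasets
            ],
            dead_time=self.dead_time,
            **kwargs,
        )


def fit_block_series(
    series: BlockSeries,
    core_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, FitResult]:
    """Global constrained and unconstrained fits of a blocker series.

    The constrained fit holds the core (non-block) rates at ``core_rates``
    (e.g. the agonist-free estimates) and estimates only the blocking rate
    constants; the free fit estimates everything.  Returns
    ``{"constrained": ..., "free": ...}`` (constrained omitted when no core
    rates are given).  K_B appears in each result's derived constants, in uM.
    """
    out: dict[str, FitResult] = {}
    block_syms = {t.symbol for t in series.scheme.transitions
                  if t.ligand == series.blocker or t.symbol.startswith("k_minusB")}
    if core_rates is not None:
        core = {s: v for s, v in core_rates.items() if s not in block_syms}
        problem_c = series.fit_problem(fixed_symbols=core, seed=seed)
        out["constrained"] = global_fit(problem_c, **fit_kwargs)
    problem_f = series.fit_problem(seed=seed)
    out["free"] = global_fit(problem_f, **fit_kwargs)
    return out


def block_signatures(
    series: BlockSeries,
) -> pd.DataFrame:
    """Concentration dependence of the open-channel-block fingerprint.

    Per concentration: mean apparent open duration and the frequency of
    intra-burst closings per second of open time.  Under simple sequential
    block the open-time reciprocal grows linearly in blocker concentration
    with slope k_plusB, and the closing frequency rises in step.
    """
    rows = []
    for bs, conc in series.datasets:
        opens = np.concatenate([b.open_durations() for b in bs])
        shuts = [b.shut_durations() for b in bs]
        n_closings = int(sum(s.size for s in shuts))
        open_time = float(opens.sum())
        rows.append({
            "concentration_uM": conc,
            "n_bursts": len(bs),
            "mean_open_s": float(opens.mean()) if opens.size else np.nan,
            "closing_rate_per_open_s": n_closings / open_time
            if open_time > 0 else np.nan,
        })
    return pd.DataFrame(rows).sort_values("concentration_uM",
                                          ignore_index=True)


def ideal_mean_open_time(
    scheme: KineticScheme,
    concentrations: Mapping[str, float],
) -> float:
    """Exact mean open dwell (s) of a scheme at given concentrations."""
    return mean_dwell(build_generator(scheme, concentrations), OPEN)
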