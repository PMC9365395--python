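"""Synthetic single-channel data with known ground truth.

Everything the downstream stages consume can be generated here from a
kinetic scheme: exact stochastic state paths (Gillespie), idealized event
lists, Gaussian-filtered noisy current traces, and burst-amplitude
populations from binomial assembly of high- and low-conductance subunits
into pentamers.  The hidden truth (state path, subunit counts) is kept
alongside each output so estimators can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, SchemeError
from .events import OPEN_CLASS, SHUT_CLASS, EventList
from .schemes import (
    OPEN,
    GeneratorMatrix,
    KineticScheme,
    build_generator,
    equilibrium_occupancy,
)

#: time-domain sigma of a Gaussian filter with -3 dB cutoff fc, times fc
_SIGMA_FC = np.sqrt(np.log(2.0)) / (2.0 * np.pi)


@dataclass
class SimulationConfig:
    """Settings for one simulated recording.

    ``n_events`` counts aggregated (class-alternating) events.  Amplitudes:
    ``amplitude_model`` maps the class (0 shut / 1 open) to (mean pA, SD pA).
    Trace mode adds a sample rate, filter cutoff and white-noise SD.
    """

    scheme: KineticScheme
    seed: int
    concentrations: Mapping[str, float] = field(default_factory=dict)
    n_events: int | None = None
    duration: float | None = None          # seconds
    amplitude_model: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {SHUT_CLASS: (0.0, 0.0), OPEN_CLASS: (16.0, 0.0)}
    )
    sample_rate: float = 100_000.0         # Hz
    filter_fc: float | None = 10_000.0     # Hz; None = unfiltered
    noise_sd: float = 0.0                  # pA

    def __post_init__(self) -> None:
        if self.n_events is None and self.duration is None:
            raise ConfigurationError("set n_events or duration")
        if self.n_events is not None and self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if self.duration is not None and self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.filter_fc is not None and self.filter_fc > self.sample_rate / 2:
            raise ConfigurationError(
                "filter_fc must not exceed the Nyquist frequency"
            )


def simulate_state_path(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic simulation of the state chain.

    Returns (states, sojourns): integer state indices into the scheme's
    state order, and exponential sojourn times in seconds.  The start state
    is drawn from the equilibrium occupancy, so the record emulates a
    steady-state recording.  Identical seeds give identical paths.
    """
    g = build_generator(cfg.scheme, cfg.concentrations)
    rng = np.random.default_rng(cfg.seed)
    n_states = g.q.shape[0]
    exit_rates = -np.diag(g.q)
    if np.any(exit_rates <= 0):
        dead = [g.state_order[i] for i in np.where(exit_rates <= 0)[0]]
        raise SchemeError(f"absorbing state(s) {dead}: scheme not irreducible")
    # per-state successor distributions
    probs = g.q / exit_rates[:, None]
    np.fill_diagonal(probs, 0.0)
    cum = np.cumsum(probs, axis=1)
    is_open = np.zeros(n_states, dtype=bool)
    is_open[g.class_indices(OPEN)] = True

    state = int(rng.choice(n_states, p=equilibrium_occupancy(g)))
    states: list[int] = []
    sojourns: list[float] = []
    # stop once enough class alternations (events) or enough time
    target_events = cfg.n_events if cfg.n_events is not None else None
    target_time = cfg.duration if cfg.duration is not None else None
    n_events = 0
    t_total = 0.0
    last_class: bool | None = None
    while True:
        dt = rng.exponential(1.0 / exit_rates[state])
        states.append(state)
        sojourns.append(dt)
        t_total += dt
        cls = bool(is_open[state])
        if cls is not last_class:
            n_events += 1
            last_class = cls
        if target_events is not None and n_events >= target_events:
            # finish the current event: run until the class changes once more
            while True:
                nxt = int(np.searchsorted(cum[state], rng.random()))
                if bool(is_open[nxt]) != cls:
                    break
                dt = rng.exponential(1.0 / exit_rates[nxt])
                states.append(nxt)
                sojourns.append(dt)
                state = nxt
            break
        if target_time is not None and t_total >= target_time:
            break
        state = int(np.searchsorted(cum[state], rng.random()))
    return np.array(states, dtype=int), np.array(sojourns)


def aggregate_to_events(
    states: np.ndarray,
    sojourns: np.ndarray,
    scheme: KineticScheme,
    meta: Mapping | None = None,
) -> EventList:
    """Merge consecutive same-class sojourns into alternating events."""
    if len(states) == 0:
        raise ValueError("empty state path")
    is_open = np.zeros(len(scheme.states), dtype=bool)
    is_open[scheme.class_indices(OPEN)] = True
    cls = is_open[states].astype(np.int8)
    # boundaries where the class changes
    change = np.flatnonzero(np.diff(cls)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(cls)]))
    durations = np.add.reduceat(sojourns, starts)
    # reduceat handles contiguous segments; verify conservation
    assert abs(durations.sum() - sojourns.sum()) <= 1e-12 * max(sojourns.sum(), 1.0)
    del ends
    return EventList(cls[starts], durations, None, dict(meta or {}))


def simulate_recording(
    cfg: SimulationConfig, annotate_amplitudes: bool = False
) -> EventList:
    """Simulate one recording straight to an idealized event list."""
    states, sojourns = simulate_state_path(cfg)
    meta = {
        "scheme": cfg.scheme.name,
        "seed": cfg.seed,
        "concentrations": dict(cfg.concentrations),
    }
    ev = aggregate_to_events(states, sojourns, cfg.scheme, meta)
    if annotate_amplitudes:
        rng = np.random.default_rng(cfg.seed + 0x5EED)
        amp = np.full(len(ev), np.nan)
        for cls, (mu, sd) in cfg.amplitude_model.items():
            m = ev.classes == cls
            amp[m] = mu + sd * rng.standard_normal(int(m.sum()))
        ev.amplitudes = amp
    return ev


def filter_sigma_samples(filter_fc: float, sample_rate: float) -> float:
    """Gaussian-filter time-domain sigma, in samples, for a -3 dB cutoff."""
    return _SIGMA_FC / filter_fc * sample_rate


def simulate_trace(
    events: EventList, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render an event list as a sampled, filtered, noisy current trace.

    Returns (t, current_pA) at ``cfg.sample_rate``.  The ideal rectangular
    trace (class mean amplitudes) is convolved with a Gaussian filter of
    cutoff ``cfg.filter_fc`` and white Gaussian noise of SD ``cfg.noise_sd``
    is added.  A Gaussian stands in for the recording hardware's Bessel
    filter; only its step-response risetime matters downstream.
    """
    for cls in np.unique(events.classes):
        if int(cls) not in cfg.amplitude_model:
            raise ConfigurationError(f"amplitude_model missing class {cls}")
    dt = 1.0 / cfg.sample_rate
    edges = np.concatenate(([0.0], np.cumsum(events.durations)))
    n = int(np.ceil(edges[-1] / dt))
    t = np.arange(n) * dt
    level = np.array(
        [cfg.amplitude_model[int(c)][0] for c in events.classes]
    )
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(level) - 1)
    trace = level[idx]
    if cfg.filter_fc is not None:
        trace = gaussian_filter1d(
            trace, filter_sigma_samples(cfg.filter_fc, cfg.sample_rate)
        )
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed + 0x7A3CE)
        trace = trace + cfg.noise_sd * rng.standard_normal(n)
    return t, trace


# ---------------------------------------------------------------------------
# Electrical-fingerprinting populations
# ---------------------------------------------------------------------------

@dataclass
class PentamerAssemblyConfig:
    """Binomial assembly of high-/low-conductance subunits into channels.

    Each channel draws its number of HC subunits k ~ Binomial(n_subunits,
    p_hc); its mean burst amplitude interpolates linearly between the all-LC
    and all-HC amplitudes, with Gaussian within-class jitter of ``class_sd``.
    Defaults follow the fingerprinting conditions: pentamers, ~16 pA all-HC
    and ~1.5 pA all-LC endpoint amplitudes.
    """

    seed: int
    n_bursts: int = 500
    n_subunits: int = 5
    p_hc: float = 0.5
    amp_lc: float = 1.5     # pA
    amp_hc: float = 16.0    # pA
    class_sd: float = 0.3   # pA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hc <= 1.0:
            raise ConfigurationError("p_hc must lie in [0, 1]")
        if not self.amp_hc > self.amp_lc > 0:
            raise ConfigurationError("need amp_hc > amp_lc > 0")
        if self.n_subunits < 2:
            raise ConfigurationError("n_subunits must be >= 2")


def class_means(cfg: PentamerAssemblyConfig) -> np.ndarray:
    """Expected amplitude of each class, k = 0..n_subunits HC subunits."""
    k = np.arange(cfg.n_subunits + 1)
    return cfg.amp_lc + k * (cfg.amp_hc - cfg.amp_lc) / cfg.n_subunits


def simulate_fingerprint_bursts(
    cfg: PentamerAssemblyConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw burst amplitudes (pA) plus the hidden per-burst HC counts."""
    rng = np.random.default_rng(cfg.seed)
    k = rng.binomial(cfg.n_subunits, cfg.p_hc, size=cfg.n_bursts)
    means = class_means(cfg)[k]
    amps = means + cfg.class_sd * rng.standard_normal(cfg.n_bursts)
    return amps, k
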