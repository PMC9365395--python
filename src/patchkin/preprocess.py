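"""From raw traces or raw event lists to burst-structured dwell sequences.

The conditioning chain mirrors standard single-channel practice: 50 %
threshold idealization, correction of brief-event durations for filter
risetime, imposition of a dead time (events shorter than the resolution
limit are treated as missed and folded into their neighbours), burst
definition by a critical shut duration, and an open-probability filter that
keeps the homogeneous core of the burst population.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError
from .events import OPEN_CLASS, SHUT_CLASS, BurstSet, EventList
from .simulate import _SIGMA_FC


def idealize_trace(
    trace: np.ndarray,
    sample_rate: float,
    open_amplitude: float,
    baseline: float = 0.0,
) -> EventList:
    """Half-amplitude threshold idealization of a sampled current trace.

    Transitions are placed where the trace crosses the midpoint between
    baseline and open level, with linear interpolation between samples.
    Swapping baseline and open level (inverted polarity) yields the same
    events.
    """
    if open_amplitude == baseline:
        raise ConfigurationError("open_amplitude must differ from baseline")
    s = (np.asarray(trace, float) - baseline) / (open_amplitude - baseline)
    above = s > 0.5
    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    if flips.size == 0:
        warnings.warn("trace never crosses the half-amplitude threshold",
                      stacklevel=2)
        return EventList(np.empty(0, dtype=int), np.empty(0), None, {})
    dt = 1.0 / sample_rate
    # linear interpolation of the crossing instant inside sample interval i
    frac = (0.5 - s[flips]) / (s[flips + 1] - s[flips])
    t_cross = (flips + frac) * dt
    t_end = (len(s) - 1) * dt
    bounds = np.concatenate(([0.0], t_cross, [t_end]))
    durations = np.diff(bounds)
    first_class = OPEN_CLASS if above[0] else SHUT_CLASS
    classes = (np.arange(len(durations)) + first_class) % 2
    keep = durations > 0
    return EventList(classes[keep], durations[keep], None,
                     {"sample_rate_Hz": sample_rate})


# ---------------------------------------------------------------------------
# Filter-risetime duration correction
# ---------------------------------------------------------------------------
# A rectangular pulse of true duration d through a Gaussian filter of
# time-domain sigma comes out as Phi(t/sigma) - Phi((t-d)/sigma).  Detected
# at half the full amplitude, its apparent width w is below d for brief
# pulses (the filtered peak barely clears the threshold) and converges to d
# for long ones.  The dimensionless map a = d/(2 sigma) -> v = w/(2 sigma)
# is tabulated once and inverted by monotone interpolation.

_A_MIN = norm.ppf(0.75)  # shortest detectable pulse: peak exactly at 50 %


def _apparent_halfwidth(a: float) -> float:
    """v such that Phi(a + v) + Phi(a - v) - 1 = 0.5, for a > _A_MIN."""
    # f decreases in v; f(0) > 0 for a > _A_MIN and f(a) = Phi(2a) - 1 <= 0
    f = lambda v: norm.cdf(a + v) + norm.cdf(a - v) - 1.5
    return brentq(f, 0.0, a, xtol=1e-14)


_A_GRID = np.concatenate([
    _A_MIN + np.geomspace(1e-6, 0.5, 200),
    np.linspace(_A_MIN + 0.5, 8.0, 200),
])
_V_GRID = np.array([_apparent_halfwidth(a) for a in _A_GRID])


def correct_risetime(events: EventList, filter_fc: float) -> EventList:
    """Correct brief-event durations for Gaussian-filter attenuation.

    Inverts the apparent-vs-true duration relation of half-amplitude
    detection.  Events much longer than the filter risetime (v > 8,
    i.e. > ~3 risetimes) pass through unchanged; the correction is monotone,
    growing as apparent durations shrink, and vanishes as filter_fc -> inf.
    """
    if filter_fc <= 0:
        raise ConfigurationError("filter_fc must be positive")
    sigma = _SIGMA_FC / filter_fc
    v = events.durations / (2.0 * sigma)
    d = events.durations.copy()
    short = v < _V_GRID[-1]
    if np.any(short):
        a = np.interp(v[short], _V_GRID, _A_GRID)
        d[short] = 2.0 * sigma * a
    return EventList(events.classes.copy(), d,
                     None if events.amplitudes is None
                     else events.amplitudes.copy(),
                     {**events.meta, "risetime_corrected_fc_Hz": filter_fc})


def impose_dead_time(events: EventList, t_d: float) -> EventList:
    """Remove events shorter than the dead time, merging across them.

    A sub-resolution event is deleted and its duration is added to the
    merge of its two neighbours (which share a class) — the missed-event
    convention assumed by the corrected likelihood.  Leading events shorter
    than ``t_d`` have no left neighbour and are dropped.  The operation is
    idempotent and, apart from dropped leading events, conserves total
    duration.
    """
    if t_d < 0:
        raise ConfigurationError("dead time must be >= 0")
    if t_d == 0 or len(events) == 0:
        return events
    cls_out: list[int] = []
    dur_out: list[float] = []
    i = 0
    n = len(events)
    while i < n and events.durations[i] < t_d:
        i += 1  # unmergeable leading short events are dropped
    if i == n:
        warnings.warn("dead time swallowed the entire record", stacklevel=2)
        return EventList(np.empty(0, dtype=int), np.empty(0), None,
                         dict(events.meta))
    cur_cls = int(events.classes[i])
    cur_dur = float(events.durations[i])
    for j in range(i + 1, n):
        c = int(events.classes[j])
        d = float(events.durations[j])
        if d < t_d or c == cur_cls:
            cur_dur += d  # absorbed (missed event) or same-class merge
        else:
            cls_out.append(cur_cls)
            dur_out.append(cur_dur)
            cur_cls, cur_dur = c, d
    cls_out.append(cur_cls)
    dur_out.append(cur_dur)
    meta = {**events.meta, "dead_time_s": t_d}
    return EventList(np.array(cls_out), np.array(dur_out), None, meta)


def determine_tau_crit(
    shut_components: list[tuple[float, float]],
    split_index: int | None = None,
) -> float:
    """Critical shut duration from the intersection of two components.

    ``shut_components`` is a list of (area, tau seconds).  The boundary is
    drawn between the slowest intra-burst component and the fastest
    inter-burst component; ``split_index`` is the index (after sorting by
    tau) of the slowest intra-burst component and defaults to the
    penultimate component.  tau_crit solves
    a1/tau1 * exp(-t/tau1) = a2/tau2 * exp(-t/tau2), i.e. the duration at
    which an event is equally likely to belong to either component.
    """
    comps = sorted(shut_components, key=lambda at: at[1])
    if len(comps) < 2:
        raise ValueError("need at least two shut components")
    k = len(comps) - 2 if split_index is None else split_index
    if not 0 <= k < len(comps) - 1:
        raise ValueError(f"split_index {k} out of range")
    (a1, tau1), (a2, tau2) = comps[k], comps[k + 1]
    if tau1 >= tau2:
        raise ValueError("components must have distinct time constants")
    ratio = (a1 * tau2) / (a2 * tau1)
    if ratio <= 1.0:
        raise ValueError("component densities do not intersect at t > 0")
    t = math.log(ratio) / (1.0 / tau1 - 1.0 / tau2)
    return t


def define_bursts(events: EventList, tau_crit: float) -> BurstSet:
    """Partition a record into bursts separated by long shut dwells.

    Shut dwells longer than ``tau_crit`` are inter-burst gaps and are
    excluded from within-burst data.  Bursts with fewer than three events
    are omitted.
    """
    sep = (events.classes == SHUT_CLASS) & (events.durations > tau_crit)
    bursts: list[EventList] = []
    start = 0
    boundaries = list(np.flatnonzero(sep)) + [len(events)]
    for b in boundaries:
        frag = events[start:b]
        start = b + 1
        if len(frag) == 0:
            continue
        # a burst starts and ends with an open event
        inner = np.flatnonzero(frag.classes == OPEN_CLASS)
        if inner.size == 0:
            continue
        frag = frag[int(inner[0]):int(inner[-1]) + 1]
        if len(frag) >= 3:
            bursts.append(frag)
    return BurstSet(bursts, tau_crit, meta=dict(events.meta))


def filter_bursts_by_popen(
    bursts: BurstSet, n_sigma: float = 2.0, mad_k: float = 5.0
) -> BurstSet:
    """Keep the homogeneous core of the burst P_open distribution.

    Two passes: (1) robust outlier removal at median +/- ``mad_k`` scaled
    MADs, then (2) a Gaussian fit to the survivors, retaining bursts within
    ``n_sigma`` standard deviations of the mean.  Pass sizes are recorded in
    the returned set's metadata.  With fewer than five bursts the set is
    returned unchanged (warning).
    """
    if len(bursts) < 5:
        warnings.warn("too few bursts for P_open filtering; passing through",
                      stacklevel=2)
        return bursts
    p = bursts.popen
    med = np.median(p)
    mad = 1.4826 * np.median(np.abs(p - med))
    keep1 = np.abs(p - med) <= mad_k * mad if mad > 0 else np.ones_like(p, bool)
    survivors = p[keep1]
    mu, sd = float(np.mean(survivors)), float(np.std(survivors))
    keep2 = keep1 & (np.abs(p - mu) <= n_sigma * sd) if sd > 0 else keep1
    kept = [b for b, k in zip(bursts.bursts, keep2) if k]
    meta = {
        **bursts.meta,
        "popen_filter": {
            "n_input": len(bursts),
            "removed_outlier_pass": int(len(bursts) - keep1.sum()),
            "removed_gaussian_pass": int(keep1.sum() - keep2.sum()),
            "gaussian_mu": mu,
            "gaussian_sd": sd,
        },
    }
    return BurstSet(kept, bursts.tau_crit, meta=meta)
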