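"""Dwell-duration histograms and exponential-mixture fits.

Apparent open and shut dwell durations of an aggregated Markov channel are
mixtures of exponentials.  Components are estimated by maximum likelihood
on the raw (unbinned) durations, left-truncated at the recording dead time;
histograms (log-spaced bins, optional square-root ordinate) are for display
only.  The component count is chosen as the smallest number of exponentials
such that one more fails a likelihood-ratio improvement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .errors import FitError


@dataclass
class DwellHistogram:
    bin_edges: np.ndarray      # seconds, log-spaced
    counts: np.ndarray
    conductance: str = ""
    sqrt_ordinate: bool = True

    @property
    def display_counts(self) -> np.ndarray:
        return np.sqrt(self.counts) if self.sqrt_ordinate else self.counts


def log_bin_histogram(
    dwells: np.ndarray,
    bins_per_decade: int = 10,
    conductance: str = "",
) -> DwellHistogram:
    """Histogram dwell durations into logarithmically spaced bins."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("no dwells to histogram")
    if np.any(d <= 0):
        raise ValueError("dwell durations must be positive")
    lo = np.floor(np.log10(d.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(d.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[0] = min(edges[0], d.min())   # guard against rounding at the ends
    edges[-1] = max(edges[-1], d.max())
    counts, _ = np.histogram(d, bins=edges)
    assert counts.sum() == d.size
    return DwellHistogram(edges, counts, conductance)


@dataclass
class ExpMixtureFit:
    components: list[tuple[float, float]]   # (area, tau seconds), tau ascending
    loglik: float
    n: int
    dead_time: float = 0.0
    converged: bool = True
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_components = len(self.components)

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


def _mixture_loglik(theta: np.ndarray, t: np.ndarray, k: int,
                    dead_time: float) -> float:
    log_tau = theta[:k]
    w = softmax(np.concatenate((theta[k:], [0.0])))
    tau = np.exp(log_tau)
    # log f(t) for the truncated mixture, vectorised over dwells
    log_terms = np.log(w)[None, :] - log_tau[None, :] - t[:, None] / tau[None, :]
    ll = logsumexp(log_terms, axis=1).sum()
    log_z = logsumexp(np.log(w) - dead_time / tau)
    return ll - t.size * log_z


def fit_exp_mixture(
    dwells: np.ndarray,
    n_components: int,
    dead_time: float = 0.0,
    seed: int = 0,
    n_starts: int = 4,
    init: ExpMixtureFit | None = None,
) -> ExpMixtureFit:
    """Maximum-likelihood exponential mixture on left-truncated dwells.

    Optimises log time constants and softmax component weights with
    multi-start quasi-Newton; starts are spread over the quantiles of the
    log durations plus seeded jitter, and optionally the solution of a
    smaller fit with one extra component (which makes the log-likelihood
    non-decreasing in the component count).
    """
    t = np.asarray(dwells, dtype=float)
    if t.size == 0:
        raise ValueError("no dwells to fit")
    if np.any(t < dead_time):
        raise ValueError("dwells shorter than the dead time present")
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k == 1:
        # closed form: truncated exponential MLE is (sample mean - dead time)
        tau_hat = float(np.mean(t) - dead_time)
        if tau_hat <= 0:
            raise FitError("degenerate single-exponential fit")
        ll = _mixture_loglik(np.array([np.log(tau_hat)]), t, 1, dead_time)
        return ExpMixtureFit([(1.0, tau_hat)], float(ll), t.size, dead_time)

    rng = np.random.default_rng(seed)
    qs = np.quantile(np.log(t), np.linspace(0.1, 0.9, k))
    starts = [np.concatenate((qs, np.zeros(k - 1)))]
    for _ in range(n_starts - 1):
        starts.append(np.concatenate((
            qs + rng.normal(0, 0.8, size=k), rng.normal(0, 0.5, size=k - 1)
        )))
    if init is not None and init.n_components == k - 1:
        # grow the previous solution by a small extra component
        tau0 = np.concatenate((init.taus, [init.taus[-1] * 3.0]))
        w0 = np.concatenate((init.areas * 0.99, [0.01]))
        order = np.argsort(tau0)
        tau0, w0 = tau0[order], w0[order]
        logits = np.log(w0[:-1]) - np.log(w0[-1])
        starts.append(np.concatenate((np.log(tau0), logits)))

    best = None
    for x0 in starts:
        res = minimize(
            lambda th: -_mixture_loglik(th, t, k, dead_time),
            x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("exponential mixture fit failed to converge")
    tau = np.exp(best.x[:k])
    w = softmax(np.concatenate((best.x[k:], [0.0])))
    order = np.argsort(tau)
    comps = [(float(w[i]), float(tau[i])) for i in order]
    return ExpMixtureFit(comps, float(-best.fun), t.size, dead_time,
                         converged=bool(best.success))


def select_component_count(
    dwells: np.ndarray,
    max_components: int = 4,
    dead_time: float = 0.0,
    seed: int = 0,
    lrt_threshold: float = 10.0,
) -> tuple[int, list[ExpMixtureFit]]:
    """Smallest component count whose extension fails a likelihood-ratio test.

    An extra component is accepted while 2 * (logL(k+1) - logL(k)) exceeds
    ``lrt_threshold`` (conventional single-channel practice).  Returns the
    selected count and the fits for k = 1..k_selected(+1).
    """
    fits: list[ExpMixtureFit] = []
    prev: ExpMixtureFit | None = None
    for k in range(1, max_components + 1):
        fit = fit_exp_mixture(dwells, k, dead_time, seed=seed, init=prev)
        if prev is not None and 2.0 * (fit.loglik - prev.loglik) <= lrt_threshold:
            fits.append(fit)
            return prev.n_components, fits
        fits.append(fit)
        prev = fit
    return max_components, fits
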