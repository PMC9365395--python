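"""Electrical fingerprinting: subunit counting from burst amplitudes.

Co-expressing high-conductance (HC) and low-conductance (LC) variants of a
subunit yields channels whose unitary amplitude depends on how many HC
copies assembled.  If each of n subunit positions contributes equally to
conductance, burst amplitudes segregate into n + 1 classes whose means are
evenly spaced between the all-LC and all-HC amplitudes.  This module builds
event-based amplitude histograms (EBAHs), fits Gaussian mixture classes,
infers the subunit count from the class count anchored to the pure-HC and
pure-LC endpoints, and quantifies the linearity of class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError


def ebah(
    burst_amplitudes: np.ndarray, bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Event-based amplitude histogram, one entry per burst.

    Returns (bin_edges, fractions); bin heights are normalised to the total
    number of bursts so that histograms pooled across patches remain
    comparable.  Pooling patches is simply concatenating their amplitudes.
    """
    a = np.asarray(burst_amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("no burst amplitudes")
    lo = np.floor(a.min() / bin_width) * bin_width
    hi = np.ceil(a.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    return edges, counts / a.size


@dataclass
class AmplitudeClassModel:
    """Gaussian amplitude classes and the subunit count they imply."""

    means: np.ndarray         # pA, strictly increasing
    sds: np.ndarray           # pA (shared SD under the equal-variance model)
    weights: np.ndarray       # sum to 1
    n: int                    # bursts fitted
    bic: float
    meta: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.means)

    @property
    def inferred_subunits(self) -> int:
        return self.n_classes - 1


def fit_amplitude_classes(
    burst_amplitudes: np.ndarray,
    max_classes: int = 8,
    seed: int = 0,
) -> AmplitudeClassModel:
    """Equal-variance Gaussian mixture with BIC class-count selection.

    Mixtures with k = 1..max_classes components are fitted (tied variance —
    the class spread reflects shared measurement noise) and the k with the
    lowest Bayesian information criterion is kept.  Deterministic for a
    given seed.
    """
    a = np.asarray(burst_amplitudes, dtype=float).reshape(-1, 1)
    if a.shape[0] < 10:
        raise ConfigurationError("need at least 10 bursts to fit classes")
    best: GaussianMixture | None = None
    best_bic = np.inf
    bics = {}
    lo, hi = float(a.min()), float(a.max())
    for k in range(1, max_classes + 1):
        # two initialisations per k: k-means, and an even grid over the
        # amplitude range (classes of a subunit-counting experiment are
        # near-equally spaced, and tiny extreme classes defeat k-means)
        inits = [{"init_params": "kmeans", "n_init": 5}]
        if k > 1:
            grid = np.linspace(lo, hi, k).reshape(-1, 1)
            inits.append({"means_init": grid, "n_init": 1})
        gm_k = None
        for kw in inits:
            try:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="tied",
                    random_state=seed,
                    max_iter=500,
                    **kw,
                ).fit(a)
            except ValueError:
                continue
            if gm_k is None or gm.lower_bound_ > gm_k.lower_bound_:
                gm_k = gm
        if gm_k is None:
            continue
        bic = gm_k.bic(a)
        bics[k] = float(bic)
        if bic < best_bic:
            best, best_bic = gm_k, bic
    if best is None:
        raise ConfigurationError("no mixture size converged")
    order = np.argsort(best.means_.ravel())
    sd = float(np.sqrt(best.covariances_.ravel()[0]))
    return AmplitudeClassModel(
        means=best.means_.ravel()[order],
        sds=np.full(best.n_components, sd),
        weights=best.weights_[order],
        n=a.shape[0],
        bic=float(best_bic),
        meta={"bic_by_k": bics, "seed": seed},
    )


def infer_subunit_count(
    model: AmplitudeClassModel,
    endpoint_amplitudes: tuple[float, float],
    endpoint_tolerance: float = 0.20,
) -> dict:
    """Subunit count from the class count, anchored to pure populations.

    ``endpoint_amplitudes`` are the all-LC and all-HC amplitudes measured
    from pure-population patches.  The extreme class means must match them
    within ``endpoint_tolerance`` (relative); otherwise inference is refused
    — the class count alone is ambiguous when extreme classes are missing.
    Diagnostics include the equal-step test (maximum deviation of successive
    class-mean differences from the mean step).
    """
    lo, hi = sorted(endpoint_amplitudes)
    means = model.means
    err_lo = abs(means[0] - lo) / abs(lo)
    err_hi = abs(means[-1] - hi) / abs(hi)
    steps = np.diff(means)
    mean_step = float(steps.mean()) if steps.size else np.nan
    diag = {
        "endpoint_error_low": float(err_lo),
        "endpoint_error_high": float(err_hi),
        "mean_step_pA": mean_step,
        "max_step_deviation_pA": float(np.max(np.abs(steps - mean_step)))
        if steps.size else 0.0,
        "n_classes": model.n_classes,
    }
    if err_lo > endpoint_tolerance or err_hi > endpoint_tolerance:
        return {
            "subunits": None,
            "refused": True,
            "reason": "extreme amplitude classes do not match the pure-LC/"
                      "pure-HC endpoint amplitudes",
            **diag,
        }
    out = {"subunits": model.inferred_subunits, "refused": False, **diag}
    if model.n_classes < 3:
        out["implausible"] = (
            "fewer than three classes: consistent with unmixed populations"
        )
    return out


def class_mean_regression(
    model: AmplitudeClassModel,
) -> tuple[float, float, float]:
    """Least-squares line through (HC count, class mean).

    Returns (slope pA/subunit, intercept pA, residual SD pA).  A straight
    line with small residual indicates approximately equal per-subunit
    contributions to conductance.
    """
    if model.n_classes < 3:
        raise ConfigurationError("need at least 3 classes for a regression")
    k = np.arange(model.n_classes, dtype=float)
    res = linregress(k, model.means)
    fitted = res.intercept + res.slope * k
    resid_sd = float(np.sqrt(np.mean((model.means - fitted) ** 2)))
    return float(res.slope), float(res.intercept), resid_sd
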