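"""Missed-event-corrected maximum-likelihood fitting of dwell sequences.

The estimator re-implements the classic MIL approach: the dwell sequence of
each burst is scored with aggregated-Markov semi-Markov kernels in which
sojourns in the opposite conductance class shorter than the dead time t_d
are treated as unobserved.  The first-order correction replaces each
within-class sub-generator Q_aa by

    Q'_aa = Q_aa + Q_ab (I - expm(Q_bb t_d)) (-Q_bb)^-1 Q_ba

(brief, undetected excursions into class b are folded into the running class-a
dwell) and each cross-class transition factor by Q_ab expm(Q_bb t_d) (the
entered class-b sojourn must survive the dead time to be detected).  Recorded
dwells are >= t_d, so propagators act on (t - t_d); at t_d = 0 every kernel
reduces exactly to the ideal aggregated-Markov likelihood.

Rates are optimised on the log scale with box bounds; standard errors come
from the inverse observed information (numerical Hessian in log-rate space,
delta method back to natural units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

from ._scan import scan_loglik
from .errors import FitError, SchemeError
from .events import BurstSet
from .schemes import (
    OPEN,
    SHUT,
    DerivedConstants,
    GeneratorMatrix,
    KineticScheme,
    build_generator,
    class_entry_vector,
    derived_constants,
)

_LOG_RATE_BOUNDS = (np.log(1e-2), np.log(1e7))


# ---------------------------------------------------------------------------
# Corrected kernels
# ---------------------------------------------------------------------------

@dataclass
class CorrectedKernels:
    """Dead-time-corrected dwell machinery for one generator matrix."""

    g: GeneratorMatrix
    t_d: float
    q_corr: dict[str, np.ndarray]      # class -> corrected sub-generator
    transfer: dict[str, np.ndarray]    # class -> Q_ab expm(Q_bb t_d)

    def entry_vector(self, conductance: str) -> np.ndarray:
        return class_entry_vector(self.g, conductance)

    def apparent_density(
        self, conductance: str, t: float | np.ndarray
    ) -> np.ndarray:
        """Apparent dwell density of one class, supported on t >= t_d."""
        phi = self.entry_vector(conductance)
        qc = self.q_corr[conductance]
        tr = self.transfer[conductance]
        ones = np.ones(tr.shape[1])
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(ts.shape)
        ok = ts >= self.t_d
        for i in np.flatnonzero(ok):
            out[i] = phi @ scipy.linalg.expm(qc * (ts[i] - self.t_d)) @ tr @ ones
        return out if np.ndim(t) else float(out[0])

    def apparent_mean_dwell(self, conductance: str) -> float:
        """Mean apparent dwell: t_d + phi (-Q'_aa)^-1 1 (normalised exit)."""
        phi = self.entry_vector(conductance)
        qc = self.q_corr[conductance]
        tr = self.transfer[conductance]
        ones_b = np.ones(tr.shape[1])
        norm = phi @ np.linalg.solve(-qc, tr @ ones_b)
        mean = phi @ np.linalg.solve(-qc, np.linalg.solve(-qc, tr @ ones_b))
        return self.t_d + float(mean / norm)


def corrected_semi_markov_kernels(
    g: GeneratorMatrix, t_d: float
) -> CorrectedKernels:
    """First-order missed-event-corrected kernels for a generator."""
    if t_d < 0:
        raise ValueError("dead time must be >= 0")
    exit_rates = -np.diag(g.q)
    shortest = 1.0 / exit_rates.max()
    if t_d >= 10.0 * shortest:
        warnings.warn(
            "dead time is an order of magnitude above the shortest mean "
            "sojourn; the first-order missed-event correction is unreliable",
            stacklevel=2,
        )
    q_corr: dict[str, np.ndarray] = {}
    transfer: dict[str, np.ndarray] = {}
    for a, b in ((OPEN, SHUT), (SHUT, OPEN)):
        qaa = g.sub(a, a)
        qab = g.sub(a, b)
        qba = g.sub(b, a)
        qbb = g.sub(b, b)
        if t_d == 0:
            q_corr[a] = qaa.copy()
            transfer[a] = qab.copy()
        else:
            ebb = scipy.linalg.expm(qbb * t_d)
            fold = qab @ (np.eye(qbb.shape[0]) - ebb) @ np.linalg.solve(-qbb,
                                                                        qba)
            q_corr[a] = qaa + fold
            transfer[a] = qab @ ebb
    return CorrectedKernels(g=g, t_d=t_d, q_corr=q_corr, transfer=transfer)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclass
class FitProblem:
    """A (possibly multi-recording, multi-concentration) fitting task.

    ``datasets`` pairs each burst set with the ligand concentrations (uM) at
    which it was recorded; all datasets share the same free rate symbols.
    """

    scheme: KineticScheme
    datasets: Sequence[tuple[BurstSet, Mapping[str, float]]]
    dead_time: float = 0.0
    fixed_symbols: Mapping[str, float] = field(default_factory=dict)
    free_symbols: frozenset[str] | None = None
    start_values: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    entry: str = "equilibrium"      # burst start vector convention

    def __post_init__(self) -> None:
        all_syms = set(self.scheme.rates())
        unknown = set(self.fixed_symbols) - all_syms
        if unknown:
            raise SchemeError(f"fixed symbols not in scheme: {sorted(unknown)}")
        if self.free_symbols is None:
            self.free_symbols = frozenset(all_syms - set(self.fixed_symbols))
        else:
            self.free_symbols = frozenset(self.free_symbols)
            overlap = self.free_symbols & set(self.fixed_symbols)
            if overlap:
                raise SchemeError(f"symbols both free and fixed: {sorted(overlap)}")
            if self.free_symbols | set(self.fixed_symbols) != all_syms:
                raise SchemeError("free + fixed must cover all scheme symbols")

    @property
    def n_dwells(self) -> int:
        return int(sum(sum(len(b) for b in bs) for bs, _ in self.datasets))

    def full_rates(self, free_values: Mapping[str, float]) -> dict[str, float]:
        rates = dict(self.scheme.rates())
        rates.update(self.fixed_symbols)
        rates.update(free_values)
        return rates


def _dataset_scan_arrays(
    bursts: BurstSet,
    concentrations: Mapping[str, float],
):
    """Pre-pack the dwell sequence of one dataset for the likelihood scan.

    Returns static arrays (classes, durations, burst boundaries) — these do
    not depend on the rates — so only the spectral quantities are rebuilt
    per likelihood evaluation.
    """
    classes_l: list[np.ndarray] = []
    durs_l: list[np.ndarray] = []
    starts, stops, first = [], [], []
    pos = 0
    for b in bursts:
        if len(b) == 0:
            continue
        if not b.is_alternating:
            raise FitError("burst events must strictly alternate; condition "
                           "the record first")
        classes_l.append(b.classes)
        durs_l.append(b.durations)
        starts.append(pos)
        pos += len(b)
        stops.append(pos)
        first.append(int(b.classes[0]))
    if not starts:
        raise FitError("dataset contains no bursts")
    return {
        "classes": np.concatenate(classes_l).astype(np.int8),
        "durations": np.concatenate(durs_l),
        "starts": np.array(starts, dtype=np.int64),
        "stops": np.array(stops, dtype=np.int64),
        "first": np.array(first, dtype=np.int8),
        "concentrations": dict(concentrations),
    }


def _spectral_pack(kern: CorrectedKernels, d_max: int, entry: str):
    """Eigen-decompose corrected kernels; pad everything to d_max."""
    g = kern.g
    lam_pad = np.zeros((2, d_max), dtype=np.complex128)
    u0 = np.zeros((2, d_max), dtype=np.complex128)
    transfer = np.zeros((2, d_max, d_max), dtype=np.complex128)
    w_end = np.zeros((2, d_max), dtype=np.complex128)
    vecs: dict[str, np.ndarray] = {}
    vinvs: dict[str, np.ndarray] = {}
    for cls in (SHUT, OPEN):
        qc = kern.q_corr[cls]
        lam, vec = np.linalg.eig(qc)
        if np.linalg.cond(vec) > 1e12:
            raise np.linalg.LinAlgError("defective corrected sub-generator")
        vecs[cls] = vec
        vinvs[cls] = np.linalg.inv(vec)
    for cls, ci in ((SHUT, 0), (OPEN, 1)):
        other = OPEN if cls == SHUT else SHUT
        qc = kern.q_corr[cls]
        lam = np.diag(vinvs[cls] @ qc @ vecs[cls]).copy()
        da = qc.shape[0]
        db = kern.q_corr[other].shape[0]
        lam_pad[ci, :da] = lam
        if entry == "uniform":
            phi = np.full(da, 1.0 / da)
        else:
            phi = kern.entry_vector(cls)
        u0[ci, :da] = phi @ vecs[cls]
        trans = vinvs[cls] @ kern.transfer[cls] @ vecs[other]
        transfer[ci, :da, :db] = trans
        w_end[ci, :da] = vinvs[cls] @ kern.transfer[cls] @ np.ones(db)
    return lam_pad, u0, transfer, w_end


def sequence_loglik(
    problem: FitProblem,
    rates: Mapping[str, float] | None = None,
    _prepacked=None,
) -> float:
    """Log-likelihood of all burst dwell sequences at the given rates.

    Per burst: entry_vector . prod_i [expm(Q'_{a_i}(t_i - t_d))
    (Q_{a_i b_i} expm(Q_{b_i} t_d))] . end, summed over bursts and datasets;
    each dataset's generator is built at its own concentrations from the
    shared rate set.
    """
    scheme = problem.scheme if rates is None else problem.scheme.with_rates(
        dict(rates))
    d_max = max(len(scheme.class_indices(SHUT)),
                len(scheme.class_indices(OPEN)))
    packs = _prepacked or [
        _dataset_scan_arrays(bs, conc) for bs, conc in problem.datasets
    ]
    total = 0.0
    for pack in packs:
        g = build_generator(scheme, pack["concentrations"])
        kern = corrected_semi_markov_kernels(g, problem.dead_time)
        try:
            lam, u0, transfer, w_end = _spectral_pack(kern, d_max,
                                                      problem.entry)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"spectral decomposition failed: {exc}") from exc
        tshift = pack["durations"] - problem.dead_time
        if np.any(tshift < -1e-12):
            raise FitError("dwells shorter than the dead time present; "
                           "apply impose_dead_time first")
        efacs = np.exp(lam[pack["classes"]] * np.clip(tshift, 0.0,
                                                      None)[:, None])
        ll = scan_loglik(u0, pack["first"], pack["starts"], pack["stops"],
                         pack["classes"], efacs, transfer, w_end)
        if not np.isfinite(ll):
            raise FitError(
                "non-finite likelihood (first offending dataset with "
                f"concentrations {pack['concentrations']})"
            )
        total += ll
    return float(total)


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted rate constants with standard errors and derived constants."""

    estimates: dict[str, tuple[float, float]]   # symbol -> (value, SE)
    fixed: dict[str, float]
    loglik: float
    converged: bool
    n_dwells: int
    derived: DerivedConstants
    settings: dict = field(default_factory=dict)

    def rate(self, symbol: str) -> float:
        if symbol in self.estimates:
            return self.estimates[symbol][0]
        return self.fixed[symbol]

    def se(self, symbol: str) -> float:
        return self.estimates[symbol][1]

    def all_rates(self) -> dict[str, float]:
        out = {s: v for s, (v, _) in self.estimates.items()}
        out.update(self.fixed)
        return out

    def table(self):
        import pandas as pd

        rows = [
            {"symbol": s, "value": v, "se": se, "fixed": False}
            for s, (v, se) in self.estimates.items()
        ] + [
            {"symbol": s, "value": v, "se": np.nan, "fixed": True}
            for s, v in self.fixed.items()
        ]
        return pd.DataFrame(rows)


def _hessian_log_space(fun, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = np.empty((n, n))
    f0 = fun(x0)
    steps = np.full(n, step)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        fpp = fun(x0 + ei)
        fmm = fun(x0 - ei)
        h[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            fpq = fun(x0 + ei + ej)
            fmq = fun(x0 - ei + ej)
            fpm = fun(x0 + ei - ej)
            fm2 = fun(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpq - fmq - fpm + fm2) / (
                4 * steps[i] * steps[j]
            )
    return h


def global_fit(
    problem: FitProblem,
    n_starts: int = 2,
    compute_se: bool = True,
) -> FitResult:
    """Maximise the corrected dwell-sequence likelihood over free rates.

    Optimisation runs on log(rate) with box bounds [1e-2, 1e7] s^-1,
    multi-start (seeded perturbations around the start values).  Standard
    errors come from the inverse numerical Hessian of the log-likelihood in
    log-rate space, mapped to natural units by the delta method.
    """
    free = sorted(problem.free_symbols)
    scheme_rates = problem.scheme.rates()
    start = {
        s: problem.start_values.get(s, scheme_rates[s]) for s in free
    }
    if any(v <= 0 for v in start.values()):
        raise FitError("start values must be positive")
    if not free:
        ll = sequence_loglik(problem, problem.full_rates({}))
        return FitResult({}, dict(problem.fixed_symbols), ll, True,
                         problem.n_dwells,
                         derived_constants(problem.full_rates({})),
                         {"dead_time": problem.dead_time})

    packs = [
        _dataset_scan_arrays(bs, conc) for bs, conc in problem.datasets
    ]

    def neg_loglik(x: np.ndarray) -> float:
        rates = problem.full_rates(dict(zip(free, np.exp(x))))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # transient extreme rates
                return -sequence_loglik(problem, rates, _prepacked=packs)
        except FitError:
            return 1e12

    rng = np.random.default_rng(problem.seed)
    x_start = np.log([start[s] for s in free])
    starts = [x_start]
    for _ in range(n_starts - 1):
        starts.append(x_start + rng.normal(0.0, 0.3, size=len(free)))
    best = None
    bounds = [_LOG_RATE_BOUNDS] * len(free)
    for x0 in starts:
        res = minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 1000, "ftol": 1e-11})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e11
    if not converged:
        warnings.warn(f"global fit did not converge: {best.message}",
                      stacklevel=2)
    x_hat = best.x
    values = dict(zip(free, np.exp(x_hat)))
    ses = {s: np.nan for s in free}
    if compute_se and converged:
        try:
            h = _hessian_log_space(neg_loglik, x_hat)
            cov = np.linalg.inv(h)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            for s, var in zip(free, diag):
                ses[s] = values[s] * float(np.sqrt(var))  # delta method
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; SEs unavailable",
                          stacklevel=2)
    estimates = {s: (values[s], ses[s]) for s in free}
    all_rates = problem.full_rates(values)
    return FitResult(
        estimates=estimates,
        fixed=dict(problem.fixed_symbols),
        loglik=float(-best.fun),
        converged=converged,
        n_dwells=problem.n_dwells,
        derived=derived_constants(all_rates),
        settings={
            "dead_time": problem.dead_time,
            "seed": problem.seed,
            "entry": problem.entry,
            "n_starts": n_starts,
            "starts": start,
        },
    )


def constrained_refit(
    problem: FitProblem,
    constrain: Mapping[str, float],
    **fit_kwargs,
) -> tuple[FitResult, FitResult]:
    """Fit with extra symbols held fixed, alongside the unconstrained fit.

    Returns (constrained, free) results for side-by-side comparison.
    """
    unknown = set(constrain) - set(problem.scheme.rates())
    if unknown:
        raise SchemeError(f"constraint symbols not in scheme: {sorted(unknown)}")
    fixed = {**problem.fixed_symbols, **constrain}
    constrained_problem = FitProblem(
        scheme=problem.scheme.with_rates(dict(constrain)),
        datasets=problem.datasets,
        dead_time=problem.dead_time,
        fixed_symbols=fixed,
        start_values=dict(problem.start_values),
        seed=problem.seed,
        entry=problem.entry,
    )
    res_constrained = global_fit(constrained_problem, **fit_kwargs)
    res_free = global_fit(problem, **fit_kwargs)
    return res_constrained, res_free
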