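"""Forward-scan kernels for the dwell-sequence likelihood.

The likelihood of a burst is a product of small complex matrices (the
within-class propagators in the eigenbasis of the corrected sub-generators,
interleaved with cross-class transfer matrices).  The scan is sequential;
a numba-compiled version is used when numba imports, with an equivalent
pure-numpy fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _scan_impl(u0_by_class, first_class, starts, stops, classes, efacs,
               transfer, w_end):
    """Sum of per-burst log-likelihoods.

    u0_by_class : (2, d) complex entry vectors (eigenbasis coordinates)
    first_class : (n_bursts,) int8 class of each burst's first dwell
    starts/stops : (n_bursts,) int64 dwell index ranges
    classes : (n_dwells,) int8 dwell classes
    efacs : (n_dwells, d) complex exp(lambda * (t - t_d)), padded with ones
    transfer : (2, d, d) complex eigenbasis-to-eigenbasis transfer matrices
    w_end : (2, d) complex end vectors
    """
    total = 0.0
    d = efacs.shape[1]
    for b in range(len(starts)):
        u = u0_by_class[first_class[b]].copy()
        log_scale = 0.0
        for i in range(starts[b], stops[b]):
            c = classes[i]
            v = u * efacs[i]
            if i == stops[b] - 1:
                val = 0.0 + 0.0j
                for j in range(d):
                    val += v[j] * w_end[c, j]
                lik = val.real
                if lik <= 0.0:
                    return -np.inf
                total += log_scale + np.log(lik)
            else:
                u = v @ transfer[c]
                m = 0.0
                for j in range(d):
                    a = abs(u[j])
                    if a > m:
                        m = a
                if m <= 0.0 or not np.isfinite(m):
                    return -np.inf
                u = u / m
                log_scale += np.log(m)
    return total


if HAVE_NUMBA:
    scan_loglik = numba.njit(cache=False)(_scan_impl)
else:  # pragma: no cover
    scan_loglik = _scan_impl
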