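"""Statistical primitives: vectorized two-sided Fisher's exact test and BH.

The Fisher test is the site-level engine for differential methylation; it
must run over ~10^5-10^6 2x2 tables per dataset, so it is implemented as a
vectorized hypergeometric tail sum rather than a per-table loop.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# scipy-compatible relative tolerance for two-sided tie detection
_LOG_TIE_TOL = np.log1p(1e-7)


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(
    meth_a, unmeth_a, meth_b, unmeth_b, chunk: int = 4096
) -> np.ndarray:
    """Two-sided Fisher's exact p-values for arrays of 2x2 count tables.

    Table layout per element: [[meth_a, unmeth_a], [meth_b, unmeth_b]].
    The two-sided p-value sums hypergeometric probabilities of all tables
    (with the observed margins) no more likely than the observed one, the
    same convention as ``scipy.stats.fisher_exact``.

    Raises ValueError on any all-zero table (the test is undefined there).
    """
    a = np.atleast_1d(np.asarray(meth_a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(unmeth_a, dtype=np.int64))
    c = np.atleast_1d(np.asarray(meth_b, dtype=np.int64))
    d = np.atleast_1d(np.asarray(unmeth_b, dtype=np.int64))
    a, b, c, d = np.broadcast_arrays(a, b, c, d)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative counts in 2x2 table")
    n1 = a + b
    n2 = c + d
    total = n1 + n2
    if np.any(total == 0):
        raise ValueError("all-zero 2x2 table")
    K = a + c  # methylated margin
    p = np.ones(a.shape, dtype=np.float64)
    for start in range(0, a.size, chunk):
        sl = slice(start, min(start + chunk, a.size))
        p.ravel()[sl] = _fisher_chunk(
            a.ravel()[sl], n1.ravel()[sl], n2.ravel()[sl], K.ravel()[sl]
        )
    return p


def _fisher_chunk(a, n1, n2, K):
    lo = np.maximum(0, K - n2)
    hi = np.minimum(K, n1)
    width = int((hi - lo).max()) + 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xc = np.where(valid, x, lo[:, None])
    lpmf = (
        _log_comb(n1[:, None], xc)
        + _log_comb(n2[:, None], K[:, None] - xc)
        - _log_comb((n1 + n2)[:, None], K[:, None])
    )
    lobs = (
        _log_comb(n1, a)
        + _log_comb(n2, K - a)
        - _log_comb(n1 + n2, K)
    )
    include = valid & (lpmf <= lobs[:, None] + _LOG_TIE_TOL)
    p = np.where(include, np.exp(lpmf), 0.0).sum(axis=1)
    return np.clip(p, 0.0, 1.0)


def fisher_exact_single(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    return float(fisher_exact_2x2([meth_a], [unmeth_a], [meth_b], [unmeth_b])[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [0,1])."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
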