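"""Shared correlation primitives.

All correlation work in the package goes through standardized column scores:
for Pearson the z-scored intensities, for Spearman the z-scored column ranks
(midranks for ties).  With scores ``z``, the sample correlation of two
variables is ``z_i @ z_j / (n - 1)``.  A zero-variance (constant) column gets
an all-zero score vector, which makes every correlation involving it exactly
0 — constant columns carry no covariance across samples and must neither seed
nor extend clusters.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError

VALID_METHODS = ("pearson", "spearman")


def column_scores(X: np.ndarray, method: str) -> np.ndarray:
    """Standardized column scores so that corr(i, j) = z_i @ z_j / (n-1)."""
    if method not in VALID_METHODS:
        raise ParameterError(f"correlation method must be one of {VALID_METHODS}")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ParameterError("correlations require at least 3 samples")
    if method == "spearman":
        X = rankdata(X, axis=0)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    z = np.zeros_like(Xc)
    ok = sd > 0
    z[:, ok] = Xc[:, ok] / sd[ok]
    return z


def vector_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation of two 1D vectors; 0 if either is constant."""
    if method not in VALID_METHODS:
        raise ParameterError(f"correlation method must be one of {VALID_METHODS}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        return 0.0
    am, bm = a - a.mean(), b - b.mean()
    return float(am @ bm / ((a.size - 1) * sa * sb))
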