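"""Evaluation battery for binned spectra.

Three instruments, mirroring how binning methods are compared in practice:

* Cross-correlation of binned features against externally quantified
  metabolite concentrations (e.g. GC-MS): for each metabolite, the best
  Spearman correlation over the features (optionally restricted to the
  metabolite's known resonance window).  A metabolite with no feature in its
  window is "not detected" (ND).
* A paired Wilcoxon signed-rank test comparing two methods' per-metabolite
  coefficients; ND metabolites are dropped pairwise, because a paired test
  needs both coefficients.
* PCA diagnostics (scores, loadings, cumulative explained variance, 95%
  Hotelling ellipse) on mean-centred or unit-variance-scaled matrices —
  noise-free binning should concentrate biological variance in the leading
  components, visibly so under unit-variance scaling where every noise
  variable is inflated to unit weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._corr import column_scores
from .errors import DegenerateTestError, ParameterError, SpectraDataError
from .io import BinnedSet, SpectraSet

__all__ = [
    "MetaboliteTable",
    "read_metabolites",
    "CrossCorResult",
    "cross_correlate",
    "compare_methods_paired",
    "PcaResult",
    "pca_diagnostics",
]

Features = Union[BinnedSet, SpectraSet]


@dataclass
class MetaboliteTable:
    """External concentrations: samples x metabolites with identifiers."""

    sample_ids: list[str]
    concentrations: np.ndarray
    metabolite_names: list[str]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.sample_ids), len(self.metabolite_names)):
            raise SpectraDataError("concentration matrix shape mismatch")


def read_metabolites(path: str) -> MetaboliteTable:
    """CSV with sample ids in column 1 and one column per metabolite."""
    df = pd.read_csv(path, index_col=0)
    return MetaboliteTable([str(i) for i in df.index],
                           df.to_numpy(dtype=float),
                           [str(c) for c in df.columns])


@dataclass
class CrossCorResult:
    """Per-metabolite best coefficient, position of the best feature, and
    detection flag; ``coefficients`` is indexed by metabolite name."""

    table: pd.DataFrame  # columns: coefficient, best_ppm, detected

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coefficient"]

    def coefficient_vector(self) -> np.ndarray:
        return self.table["coefficient"].to_numpy()


def _feature_matrix(features) -> tuple[np.ndarray, list[tuple[float, float]], list[str]]:
    """Matrix, per-feature ppm ranges and sample ids from any feature container.

    Accepts a BinnedSet, a SpectraSet, or a cluster-table DataFrame as written
    by :func:`jbabin.io.write_bins` (meta columns then one column per sample).
    """
    if isinstance(features, BinnedSet):
        return features.Y, features.cluster_ppm_ranges(), list(features.sample_ids)
    if isinstance(features, pd.DataFrame):
        meta = ["cluster_id", "ppm_start", "ppm_end", "n_variables",
                "seed_ppm", "mean_window_correlation"]
        sample_cols = [c for c in features.columns if c not in meta]
        ranges = list(zip(features["ppm_start"].astype(float),
                          features["ppm_end"].astype(float)))
        return (features[sample_cols].to_numpy(dtype=float).T, ranges,
                [str(c) for c in sample_cols])
    return features.X, [(float(p), float(p)) for p in features.ppm], list(features.sample_ids)


def cross_correlate(features: Features, met: MetaboliteTable,
                    match: Optional[dict[str, list[tuple[float, float]]]] = None
                    ) -> CrossCorResult:
    """Best Spearman correlation of each metabolite with the binned features.

    Correlations are computed over the samples shared between the two tables
    (at least 3 required).  With ``match`` given, a metabolite only considers
    features whose ppm range intersects one of its windows; none in range
    means ND.  The best match is the maximum coefficient, not maximum
    absolute value — concentrations and resonance intensities rise together.
    """
    F, ranges, fids = _feature_matrix(features)
    shared = [sid for sid in fids if sid in set(met.sample_ids)]
    if len(shared) < 3:
        raise SpectraDataError("fewer than 3 shared samples")
    frow = {sid: i for i, sid in enumerate(fids)}
    mrow = {sid: i for i, sid in enumerate(met.sample_ids)}
    Fs = F[[frow[s] for s in shared]]
    Ms = met.concentrations[[mrow[s] for s in shared]]

    zf = column_scores(Fs, "spearman")
    zm = column_scores(Ms, "spearman")
    R = zm.T @ zf / (len(shared) - 1)  # metabolites x features

    rows = []
    for j, name in enumerate(met.metabolite_names):
        if match is not None and name in match:
            windows = match[name]
            cand = [i for i, (lo, hi) in enumerate(ranges)
                    if any(hi >= wlo and lo <= whi for wlo, whi in windows)]
        else:
            cand = list(range(len(ranges)))
        if not cand:
            rows.append({"metabolite": name, "coefficient": np.nan,
                         "best_ppm": np.nan, "detected": False})
            continue
        sub = R[j, cand]
        best = int(np.argmax(sub))
        lo, hi = ranges[cand[best]]
        rows.append({"metabolite": name, "coefficient": float(sub[best]),
                     "best_ppm": 0.5 * (lo + hi), "detected": True})
    return CrossCorResult(pd.DataFrame(rows).set_index("metabolite"))


def compare_methods_paired(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-metabolite coefficients.

    Pairs with a missing (ND) value are dropped.  The exact null distribution
    is used for n <= 25 when the differences are free of zeros and tied
    magnitudes; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 5:
        raise ParameterError("need at least 5 complete pairs")
    d = a - b
    if np.all(d == 0):
        raise DegenerateTestError("all paired differences are zero")
    nz = d[d != 0]
    exact = (nz.size <= 25 and np.all(d != 0)
             and np.unique(np.abs(nz)).size == nz.size)
    res = stats.wilcoxon(a, b, alternative="two-sided",
                         method="exact" if exact else "approx")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "n_pairs": int(a.size), "method": "exact" if exact else "approx"}


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray
    hotelling_t2_crit: float
    ellipse_semiaxes: tuple[float, float]
    kept_columns: np.ndarray


def pca_diagnostics(features: Features, scaling: str = "mean_center",
                    n_pc: int = 10) -> PcaResult:
    """PCA on the (scaled) feature matrix via singular value decomposition.

    ``mean_center`` subtracts column means; ``unit_variance`` additionally
    divides by the column standard deviation (zero-variance columns are
    dropped with a warning).  Explained-variance fractions come from the
    squared singular values over their total.  The 95% Hotelling T-squared
    ellipse for the first two scores has semi-axes
    sqrt(var_pc * 2(n-1)/(n-2) * F_{0.95; 2, n-2}).
    """
    if scaling not in ("mean_center", "unit_variance"):
        raise ParameterError("scaling must be 'mean_center' or 'unit_variance'")
    M, _, _ = _feature_matrix(features)
    n = M.shape[0]
    if n_pc < 2 or n <= n_pc:
        raise ParameterError("need n_samples > n_pc >= 2")
    sd = M.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0) if scaling == "unit_variance" else np.arange(M.shape[1])
    if scaling == "unit_variance" and kept.size < M.shape[1]:
        warnings.warn(f"dropping {M.shape[1] - kept.size} zero-variance columns")
    if kept.size < 2:
        raise SpectraDataError("fewer than 2 non-degenerate columns")
    A = M[:, kept] - M[:, kept].mean(axis=0)
    if scaling == "unit_variance":
        A = A / sd[kept]
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    r = min(n_pc, S.size)
    ratio = S ** 2 / np.sum(S ** 2)
    scores = U[:, :r] * S[:r]
    t2 = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(0.95, 2, n - 2)
    var12 = S[:2] ** 2 / (n - 1)
    semi = (float(np.sqrt(var12[0] * t2)), float(np.sqrt(var12[1] * t2)))
    return PcaResult(scores=scores, loadings=Vt[:r].T,
                     explained_variance_ratio=ratio[:r],
                     cumulative_variance=np.cumsum(ratio)[:r],
                     hotelling_t2_crit=float(t2), ellipse_semiaxes=semi,
                     kept_columns=kept)
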