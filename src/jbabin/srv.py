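"""Statistical recoupling of variables (SRV).

SRV bins a spectrum by scanning the "spectral dependency landscape" — the
covariance/correlation ratio of each pair of adjacent variables, which for a
non-degenerate pair equals the product of the two sample standard deviations.
Local minima of the landscape mark cluster edges; segments between edges with
at least ``minsize`` variables are kept as clusters, smaller ones discarded.
Finally, neighbouring clusters whose aggregated intensities have Pearson
correlation above ``super_r`` are fused into superclusters, each ideally one
NMR signal.

Unlike JBA, the landscape is intensity-driven (standard deviations), so
regions of locally correlated noise can also form clusters; that contrast is
the point of carrying SRV as a comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._corr import column_scores
from .errors import ParameterError
from .io import BinnedSet, Cluster, SpectraSet
from .jba import _AGGS, _mean_pairwise, _merge_pass

__all__ = [
    "SrvParams",
    "DependencyLandscape",
    "dependency_landscape",
    "srv_clusters",
    "superclusters",
    "run_srv",
]


@dataclass
class SrvParams:
    """``minsize``: minimum variables per retained cluster (the number of points
    sampling a well-resolved singlet, default 10); ``agg``: intensity statistic;
    ``super_r``: Pearson threshold for supercluster fusion."""

    minsize: int = 10
    agg: str = "sum"
    super_r: float = 0.90

    def __post_init__(self) -> None:
        if self.minsize < 2:
            raise ParameterError("minsize must be >= 2")
        if self.agg not in _AGGS:
            raise ParameterError(f"agg must be one of {tuple(_AGGS)}")
        if not 0.0 <= self.super_r <= 1.0:
            raise ParameterError("super_r must lie in [0, 1]")

    def record(self) -> dict:
        return {"minsize": self.minsize, "agg": self.agg, "super_r": self.super_r}


@dataclass
class DependencyLandscape:
    """Covariance/correlation ratio per adjacent variable pair.

    ``values[i]`` belongs to the pair (i, i+1) and is aligned to the lower-ppm
    member; length is ``n_variables - 1``.
    """

    ppm: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


def dependency_landscape(s: SpectraSet) -> DependencyLandscape:
    """Covariance / Pearson-correlation ratio for each adjacent pair.

    Sample covariance and standard deviation use the n-1 denominator, so for a
    non-degenerate pair the ratio reduces to sd_i * sd_{i+1}.  Pairs with a
    zero-variance member or exactly zero correlation get value 0: dead regions
    of the spectrum must present edges, not plateaus.
    """
    if s.n_samples < 3:
        raise ParameterError("dependency landscape requires at least 3 samples")
    X = s.X
    n = s.n_samples
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    cov = (Xc[:, :-1] * Xc[:, 1:]).sum(axis=0) / (n - 1)
    sdprod = sd[:-1] * sd[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(sdprod > 0, cov / sdprod, 0.0)
    values = np.where(cor != 0, np.divide(cov, cor, out=np.zeros_like(cov),
                                          where=cor != 0), 0.0)
    return DependencyLandscape(s.ppm[:-1].copy(), values)


def _minima_edges(values: np.ndarray) -> list[int]:
    """Indices of strict local minima (plateaus: lowest-ppm index of the run)."""
    from .jba import _equal_runs

    if values.size == 0:
        return []
    runs = _equal_runs(values)
    edges = []
    for j, (a, b) in enumerate(runs):
        left_ok = j > 0 and values[runs[j - 1][1]] > values[a]
        right_ok = j < len(runs) - 1 and values[runs[j + 1][0]] > values[a]
        if left_ok and right_ok:  # interior minima only: axis ends are implicit edges
            edges.append(int(a))
    return edges


def srv_clusters(s: SpectraSet, p: SrvParams) -> BinnedSet:
    """Segment the axis at dependency-landscape minima and keep large segments.

    An edge at landscape position *i* separates variables *i* and *i+1*.  The
    axis ends act as implicit edges.  Segments with at least ``minsize``
    variables become clusters; smaller ones are neglected.
    """
    land = dependency_landscape(s)
    edges = _minima_edges(land.values)
    bounds = [-1] + edges + [s.n_variables - 1]
    Z = column_scores(s.X, "pearson")
    denom = s.n_samples - 1
    clusters = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start, end = lo + 1, hi
        if end - start + 1 >= p.minsize:
            members = np.arange(start, end + 1)
            clusters.append(Cluster(start, end,
                                    r_bar=_mean_pairwise(Z, members, denom)))
    if clusters:
        Y = np.column_stack([_AGGS[p.agg](s.X[:, c.members], axis=1) for c in clusters])
    else:
        Y = np.empty((s.n_samples, 0))
    return BinnedSet(clusters, Y, "SRV", p.record(), s.ppm, list(s.sample_ids))


def superclusters(s: SpectraSet, b: BinnedSet, p: SrvParams) -> BinnedSet:
    """Fuse consecutive retained clusters with Pearson correlation > ``super_r``.

    Same mechanics as JBA's neighbour merging, with Pearson fixed and no gap
    limit: discarded small segments may separate two clusters that belong to
    the same NMR signal.  Iterated to a fixpoint.
    """
    if len(b.clusters) < 2:
        return b
    Z = column_scores(s.X, "pearson")
    clusters = list(b.clusters)
    Y = b.Y
    while True:
        clusters, Y, changed = _merge_pass(clusters, Y, s, p.agg, "pearson",
                                           p.super_r, None, Z)
        if not changed:
            break
    return BinnedSet(clusters, Y, b.method, b.params, b.ppm, b.sample_ids)


def run_srv(s: SpectraSet, p: SrvParams) -> BinnedSet:
    """Full SRV pipeline: landscape segmentation then supercluster fusion."""
    return superclusters(s, srv_clusters(s, p), p)
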