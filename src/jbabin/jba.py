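"""The pJRES binning algorithm (JBA).

The method exploits the fact that adjacent spectral variables sampling the
same NMR resonance are strongly correlated across samples, while variables in
electronic-noise regions are only weakly correlated (even in pJRES spectra,
where apodization leaves the noise locally correlated rather than i.i.d.).

Three stages:

1. Slide a window of ``st`` adjacent variables along the axis (step one) and
   compute each window's average correlation — a "pseudo-NMR spectrum" whose
   peaks mark metabolic signals.
2. Local maxima of that spectrum at or above the threshold ``ct`` become
   seeds; each seed window is grown downfield and upfield, one variable at a
   time, while (i) the cluster's average correlation stays at or above ``ct``
   and (ii)/(iii) the candidate correlates at least as strongly with its
   neighbour towards the cluster as with its neighbour away from it.
3. Cluster intensities are aggregated (sum/mean/median/max) and neighbouring
   clusters whose intensity profiles correlate above ``merge_r`` are fused,
   recovering peaks split by misalignment or overlap.

"Average correlation" of a set of variables means the mean over all
``k*(k-1)/2`` pairwise correlations (method ``cm``), with correlations
involving a constant variable defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._corr import VALID_METHODS, column_scores, vector_corr
from .errors import ParameterError
from .io import BinnedSet, Cluster, SpectraSet

__all__ = [
    "JbaParams",
    "CorrelationSpectrum",
    "window_correlations",
    "find_seeds",
    "expand_seed",
    "aggregate_intensity",
    "merge_neighbours",
    "run_jba",
]

_AGGS = {"sum": np.sum, "mean": np.mean, "median": np.median, "max": np.max}


@dataclass
class JbaParams:
    """User-facing JBA parameters.

    ``st``: window size = minimum cluster size, set by how many data points
    sample a peak width.  ``ct``: minimum average correlation for a metabolic
    cluster (select with :func:`jbabin.threshold.select_ct`).  ``cm``:
    correlation method.  ``agg``: cluster intensity statistic.  ``merge_r``:
    threshold above which neighbouring clusters are fused; ``merge_gap_ppm``:
    maximum ppm distance between the facing edge variables of two clusters for
    them to count as neighbours (0 = index-adjacent only).
    """

    ct: float
    st: int = 4
    cm: str = "pearson"
    agg: str = "sum"
    merge_r: float = 0.90
    merge_gap_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.st < 2:
            raise ParameterError("st must be >= 2")
        if not -1.0 <= self.ct <= 1.0:
            raise ParameterError("ct must lie in [-1, 1]")
        if self.cm not in VALID_METHODS:
            raise ParameterError(f"cm must be one of {VALID_METHODS}")
        if self.agg not in _AGGS:
            raise ParameterError(f"agg must be one of {tuple(_AGGS)}")
        if not 0.0 <= self.merge_r <= 1.0:
            raise ParameterError("merge_r must lie in [0, 1]")
        if self.merge_gap_ppm < 0:
            raise ParameterError("merge_gap_ppm must be >= 0")

    def record(self) -> dict:
        return {"st": self.st, "ct": self.ct, "cm": self.cm, "agg": self.agg,
                "merge_r": self.merge_r, "merge_gap_ppm": self.merge_gap_ppm}


@dataclass
class CorrelationSpectrum:
    """Average window correlations aligned to the ppm axis.

    ``ppm_anchor[i]`` is the chemical shift of window *i*'s first (lowest
    ppm) variable; ``r_bar[i]`` the mean of all pairwise correlations among
    the ``st`` variables of that window.
    """

    ppm_anchor: np.ndarray
    r_bar: np.ndarray
    st: int
    cm: str

    def __len__(self) -> int:
        return self.r_bar.size


def window_correlations(s: SpectraSet, st: int, cm: str = "pearson") -> CorrelationSpectrum:
    """Average correlation of every run of ``st`` adjacent variables.

    Window *i* covers variables ``i .. i + st - 1``; its value is the mean of
    the ``st*(st-1)/2`` pairwise correlations among them.
    """
    if st < 2:
        raise ParameterError("st must be >= 2")
    if st > s.n_variables:
        raise ParameterError(f"st={st} exceeds {s.n_variables} variables")
    z = column_scores(s.X, cm)
    denom = s.n_samples - 1
    n_win = s.n_variables - st + 1
    total = np.zeros(n_win)
    for k in range(1, st):
        lag = (z[:, :-k] * z[:, k:]).sum(axis=0) / denom
        total += np.lib.stride_tricks.sliding_window_view(lag, st - k).sum(axis=1)
    r_bar = total / (st * (st - 1) // 2)
    return CorrelationSpectrum(s.ppm[:n_win].copy(), r_bar, st, cm)


def _equal_runs(v: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal consecutive values, as (start, end) inclusive."""
    breaks = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [v.size - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def find_seeds(c: CorrelationSpectrum, ct: float) -> list[int]:
    """Anchors of local maxima of the correlation spectrum at or above ``ct``.

    A plateau (run of equal values) strictly above both flanking values yields
    a single seed at its lowest-ppm anchor; runs at the spectrum edges only
    need to exceed their one existing neighbour.  Returned sorted by ppm.
    """
    v = c.r_bar
    if v.size == 0:
        return []
    runs = _equal_runs(v)
    seeds = []
    for j, (a, b) in enumerate(runs):
        if v[a] < ct:
            continue
        left_ok = j == 0 or v[runs[j - 1][1]] < v[a]
        right_ok = j == len(runs) - 1 or v[runs[j + 1][0]] < v[a]
        if left_ok and right_ok:
            seeds.append(int(a))
    return seeds


def expand_seed(s: SpectraSet, seed: int, p: JbaParams,
                occupied: Optional[np.ndarray] = None,
                _scores: Optional[np.ndarray] = None) -> Optional[Cluster]:
    """Grow a seed window into a cluster; ``None`` if the window is already claimed.

    Growth alternates sides, downfield (higher ppm) candidate first.  A side
    closes permanently at the spectrum edge, at a claimed variable, when the
    directional condition fails, or when admitting the candidate would drop
    the cluster's average correlation below ``ct``.

    Directional conditions, with indices in increasing-ppm order: a downfield
    candidate ``v_i`` must satisfy corr(v_i, v_{i+1}) <= corr(v_i, v_{i-1})
    (it clings to the cluster, not to what lies beyond); an upfield candidate
    must satisfy corr(v_i, v_{i+1}) >= corr(v_i, v_{i-1}).  A missing
    outer neighbour (spectrum edge) leaves the condition satisfied.
    """
    nv = s.n_variables
    start, end = seed, seed + p.st - 1
    if seed < 0 or end >= nv:
        raise ParameterError("seed window outside the axis")
    if occupied is None:
        occupied = np.zeros(nv, dtype=bool)
    if occupied[start:end + 1].any():
        return None
    Z = column_scores(s.X, p.cm) if _scores is None else _scores
    denom = s.n_samples - 1

    def corr(i: int, j: int) -> float:
        return float(Z[:, i] @ Z[:, j]) / denom

    zsum = Z[:, start:end + 1].sum(axis=1)
    diag = float(np.einsum("ij,ij->", Z[:, start:end + 1], Z[:, start:end + 1])) / denom
    pair_sum = (float(zsum @ zsum) / denom - diag) / 2.0
    k = p.st

    open_side = {"down": True, "up": True}  # down = higher ppm
    turn = "down"
    while open_side["down"] or open_side["up"]:
        side = turn
        turn = "up" if turn == "down" else "down"
        if not open_side[side]:
            continue
        # ties pass "equal or higher/lower" with a 1e-12 slack: correlations
        # that are mathematically equal (e.g. exact rank-1 regions) differ by
        # ~1 ulp in floating point and must not flip the comparison
        if side == "down":
            cand, inner, outer = end + 1, end, end + 2
            if cand >= nv or occupied[cand]:
                open_side[side] = False
                continue
            directional = outer >= nv or corr(cand, outer) <= corr(cand, inner) + 1e-12
        else:
            cand, inner, outer = start - 1, start, start - 2
            if cand < 0 or occupied[cand]:
                open_side[side] = False
                continue
            directional = outer < 0 or corr(cand, inner) >= corr(cand, outer) - 1e-12
        if not directional:
            open_side[side] = False
            continue
        add = float(Z[:, cand] @ zsum) / denom
        new_mean = (pair_sum + add) / ((k + 1) * k / 2.0)
        if new_mean < p.ct:
            open_side[side] = False
            continue
        pair_sum += add
        k += 1
        zsum = zsum + Z[:, cand]
        if side == "down":
            end = cand
        else:
            start = cand
    r_bar = pair_sum / (k * (k - 1) / 2.0)
    return Cluster(start, end, r_bar=r_bar, seed_idx=seed)


def aggregate_intensity(s: SpectraSet, cl: Cluster, agg: str = "sum") -> np.ndarray:
    """Per-sample aggregated intensity over the cluster's member variables."""
    if agg not in _AGGS:
        raise ParameterError(f"agg must be one of {tuple(_AGGS)}")
    return _AGGS[agg](s.X[:, cl.members], axis=1)


def _mean_pairwise(Z: np.ndarray, members: np.ndarray, denom: int) -> float:
    """Mean pairwise correlation over a member set (constant columns count 0)."""
    if members.size < 2:
        return 1.0
    sub = Z[:, members]
    zsum = sub.sum(axis=1)
    diag = float(np.einsum("ij,ij->", sub, sub)) / denom
    pair_sum = (float(zsum @ zsum) / denom - diag) / 2.0
    m = members.size
    return pair_sum / (m * (m - 1) / 2.0)


def _merge_pass(clusters: list[Cluster], Y: np.ndarray, s: SpectraSet,
                agg: str, cm: str, merge_r: float,
                gap_ppm: Optional[float], Z: np.ndarray) -> tuple[list[Cluster], np.ndarray, bool]:
    """One left-to-right pass fusing eligible neighbour pairs (chains included)."""
    denom = s.n_samples - 1
    out: list[Cluster] = []
    cols: list[np.ndarray] = []
    cur = clusters[0]
    cur_y = Y[:, 0]
    changed = False
    for j in range(1, len(clusters)):
        nxt, nxt_y = clusters[j], Y[:, j]
        if gap_ppm is None:  # any pair of consecutive clusters counts as neighbours
            adjacent = True
        else:
            adjacent = (nxt.start_idx == cur.end_idx + 1 or
                        s.ppm[nxt.start_idx] - s.ppm[cur.end_idx] <= gap_ppm + 1e-12)
        if adjacent and vector_corr(cur_y, nxt_y, cm) > merge_r:
            members = np.concatenate((cur.members, nxt.members))
            cur = Cluster(cur.start_idx, nxt.end_idx,
                          r_bar=_mean_pairwise(Z, members, denom),
                          seed_idx=cur.seed_idx if cur.seed_idx is not None else nxt.seed_idx,
                          members=members)
            cur_y = _AGGS[agg](s.X[:, members], axis=1)
            changed = True
        else:
            out.append(cur)
            cols.append(cur_y)
            cur, cur_y = nxt, nxt_y
    out.append(cur)
    cols.append(cur_y)
    return out, np.column_stack(cols), changed


def merge_neighbours(s: SpectraSet, b: BinnedSet, p: JbaParams) -> BinnedSet:
    """Fuse neighbouring clusters whose intensity profiles correlate above ``merge_r``.

    Misalignment or overlap can split one NMR peak into several clusters; the
    fragments remain driven by the same underlying concentrations, so their
    aggregated intensities are near-collinear.  Passes repeat until none
    merges.  The fused cluster aggregates the union of the member variables
    (any unclustered gap variables stay out), so sum aggregation is conserved.
    """
    if len(b.clusters) < 2:
        return b
    Z = column_scores(s.X, p.cm)
    clusters = list(b.clusters)
    Y = b.Y
    while True:
        clusters, Y, changed = _merge_pass(clusters, Y, s, p.agg, p.cm,
                                           p.merge_r, float(p.merge_gap_ppm), Z)
        if not changed:
            break
    return BinnedSet(clusters, Y, b.method, b.params, b.ppm, b.sample_ids)


def run_jba(s: SpectraSet, p: JbaParams) -> BinnedSet:
    """Full JBA pipeline: window correlations, seeds, expansion, aggregation, merging.

    Seeds are processed in order of decreasing window correlation (ties: lower
    ppm first); variables claimed by an earlier cluster are unavailable, and a
    seed whose window is partly claimed is dropped.  The result is therefore
    independent of storage order: strongest evidence wins.
    """
    cs = window_correlations(s, p.st, p.cm)
    seeds = find_seeds(cs, p.ct)
    order = sorted(seeds, key=lambda a: (-cs.r_bar[a], a))
    Z = column_scores(s.X, p.cm)
    occupied = np.zeros(s.n_variables, dtype=bool)
    clusters: list[Cluster] = []
    for seed in order:
        cl = expand_seed(s, seed, p, occupied, _scores=Z)
        if cl is None:
            continue
        occupied[cl.start_idx:cl.end_idx + 1] = True
        clusters.append(cl)
    clusters.sort(key=lambda c: c.start_idx)
    if clusters:
        Y = np.column_stack([aggregate_intensity(s, c, p.agg) for c in clusters])
    else:
        Y = np.empty((s.n_samples, 0))
    b = BinnedSet(clusters, Y, "JBA", p.record(), s.ppm, list(s.sample_ids))
    return merge_neighbours(s, b, p)
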