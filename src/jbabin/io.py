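"""Containers and file I/O for spectra matrices, region masks and bin tables.

The universal input is a samples x variables intensity matrix with a ppm
(chemical shift) axis.  Internally the axis is always stored in strictly
increasing ppm order; "downfield" means higher ppm and "upfield" lower ppm,
following standard NMR convention.  All scanning operations in the other
modules rely on this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, SpectraDataError, SpectraFormatError

__all__ = [
    "SpectraSet",
    "RegionMask",
    "Cluster",
    "BinnedSet",
    "read_spectra",
    "write_spectra",
    "apply_mask",
    "write_bins",
    "read_bins",
]


@dataclass
class SpectraSet:
    """A set of 1D spectra on a common chemical-shift axis.

    Parameters
    ----------
    ppm:
        Chemical shifts in ppm, strictly increasing, no duplicates.
    X:
        Intensity matrix of shape (n_samples, n_variables), arbitrary units.
    sample_ids:
        One identifier per spectrum (row of ``X``).
    qc_flags:
        Optional boolean vector marking pooled quality-control samples.
    """

    ppm: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    qc_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise SpectraDataError("X must be a 2D samples x variables matrix")
        if self.ppm.ndim != 1 or self.ppm.size != self.X.shape[1]:
            raise SpectraDataError(
                f"ppm axis length {self.ppm.size} does not match "
                f"{self.X.shape[1]} intensity columns"
            )
        if np.unique(self.ppm).size != self.ppm.size:
            raise SpectraFormatError("duplicate ppm values on the axis")
        if np.any(np.diff(self.ppm) <= 0):
            raise SpectraDataError("ppm axis must be strictly increasing")
        if len(self.sample_ids) != self.X.shape[0]:
            raise SpectraDataError("one sample id required per spectrum")
        if not np.all(np.isfinite(self.X)):
            raise SpectraDataError("missing or non-finite intensities")
        if self.qc_flags is not None:
            self.qc_flags = np.asarray(self.qc_flags, dtype=bool)
            if self.qc_flags.size != self.X.shape[0]:
                raise SpectraDataError("qc_flags length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def subset_variables(self, idx: np.ndarray) -> "SpectraSet":
        """Return a new set restricted to the variable indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return SpectraSet(self.ppm[idx], self.X[:, idx], list(self.sample_ids),
                          None if self.qc_flags is None else self.qc_flags)


@dataclass
class RegionMask:
    """A union of closed ppm intervals, e.g. water/EDTA exclusion regions.

    Intervals are normalized on construction: validated (lo <= hi), sorted,
    and overlapping or touching intervals merged.
    """

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        norm: list[tuple[float, float]] = []
        for lo, hi in self.intervals:
            if hi < lo:
                raise ParameterError(f"interval ({lo}, {hi}) has hi < lo")
            norm.append((float(lo), float(hi)))
        norm.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in norm:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        self.intervals = merged

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean array: which ppm values fall inside any (closed) interval."""
        ppm = np.asarray(ppm, dtype=float)
        inside = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.intervals:
            inside |= (ppm >= lo) & (ppm <= hi)
        return inside


@dataclass
class Cluster:
    """A contiguous run of spectral variables treated as one feature.

    ``start_idx``/``end_idx`` are inclusive variable indices on the increasing
    ppm axis.  ``members`` lists the variable indices whose intensities are
    aggregated; for a freshly formed cluster this is the full contiguous run,
    but after merging across a small unclustered gap it can be a strict subset
    of the span (the gap variables are never aggregated).  ``seed_idx`` is the
    anchor of the originating correlation-window local maximum (JBA only).
    """

    start_idx: int
    end_idx: int
    r_bar: float
    seed_idx: Optional[int] = None
    members: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.end_idx < self.start_idx:
            raise ParameterError("cluster end_idx precedes start_idx")
        if self.members is None:
            self.members = np.arange(self.start_idx, self.end_idx + 1)
        else:
            self.members = np.asarray(self.members, dtype=int)

    @property
    def n_variables(self) -> int:
        return int(self.members.size)


@dataclass
class BinnedSet:
    """Ordered clusters plus the samples x clusters aggregated-intensity matrix."""

    clusters: list[Cluster]
    Y: np.ndarray
    method: str  # "JBA", "SRV" or "SB"
    params: dict
    ppm: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.clusters):
            raise SpectraDataError("Y must have one column per cluster")
        starts = [c.start_idx for c in self.clusters]
        if starts != sorted(starts):
            raise SpectraDataError("clusters must be ordered by start ppm")
        for a, b in zip(self.clusters, self.clusters[1:]):
            if b.start_idx <= a.end_idx:
                raise SpectraDataError("cluster index ranges overlap")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_ppm_ranges(self) -> list[tuple[float, float]]:
        return [(float(self.ppm[c.start_idx]), float(self.ppm[c.end_idx]))
                for c in self.clusters]


def _infer_sep(path: str, dialect: Optional[str]) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_spectra(path: str, dialect: Optional[str] = None) -> SpectraSet:
    """Read a spectra matrix from delimited text.

    Layout: row 1 holds numeric ppm values, column 1 holds sample identifiers,
    remaining cells the intensities.  The axis is re-oriented to increasing
    ppm if the file stores it decreasing (the common instrument convention).
    """
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        ppm = np.array([float(c) for c in df.columns])
    except (TypeError, ValueError) as exc:
        raise SpectraFormatError(f"non-numeric ppm header in {path}") from exc
    if np.unique(ppm).size != ppm.size:
        raise SpectraFormatError(f"duplicate ppm values in header of {path}")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise SpectraDataError("need at least 2 samples and 2 variables")
    X = df.to_numpy(dtype=float, na_value=np.nan)
    if np.any(~np.isfinite(X)):
        raise SpectraDataError(f"missing intensities in {path}")
    order = np.argsort(ppm)
    return SpectraSet(ppm[order], X[:, order], [str(i) for i in df.index])


def write_spectra(s: SpectraSet, path: str, dialect: Optional[str] = None) -> None:
    """Write a spectra matrix as delimited text (full double precision)."""
    sep = _infer_sep(path, dialect)
    df = pd.DataFrame(s.X, index=s.sample_ids,
                      columns=[repr(float(p)) for p in s.ppm])
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def apply_mask(s: SpectraSet, m: RegionMask,
               mode: Literal["exclude", "select"] = "exclude") -> SpectraSet:
    """Remove (``exclude``) or retain (``select``) variables inside the mask.

    Intervals are closed on both ends; variable order is preserved.
    """
    if mode not in ("exclude", "select"):
        raise ParameterError(f"unknown mask mode {mode!r}")
    inside = m.contains(s.ppm)
    keep = inside if mode == "select" else ~inside
    if keep.sum() < 2:
        raise SpectraDataError("mask leaves fewer than 2 variables")
    return s.subset_variables(np.flatnonzero(keep))


_BIN_META_COLS = ["cluster_id", "ppm_start", "ppm_end", "n_variables",
                  "seed_ppm", "mean_window_correlation"]


def write_bins(b: BinnedSet, path: str) -> None:
    """Write the cluster table: one row per cluster, one intensity column per sample.

    Columns (deterministic order): cluster_id, ppm_start, ppm_end,
    n_variables, seed_ppm (empty for non-JBA methods), mean_window_correlation,
    then the per-sample aggregated intensities.
    """
    rows = []
    for k, c in enumerate(b.clusters):
        rows.append({
            "cluster_id": k + 1,
            "ppm_start": repr(float(b.ppm[c.start_idx])),
            "ppm_end": repr(float(b.ppm[c.end_idx])),
            "n_variables": c.n_variables,
            "seed_ppm": "" if c.seed_idx is None else repr(float(b.ppm[c.seed_idx])),
            "mean_window_correlation": repr(float(c.r_bar)),
        })
    df = pd.DataFrame(rows, columns=_BIN_META_COLS)
    for j, sid in enumerate(b.sample_ids):
        df[sid] = [repr(float(v)) for v in b.Y[j]] if len(rows) else []
    df.to_csv(path, index=False)


def read_bins(path: str) -> pd.DataFrame:
    """Read back a cluster table written by :func:`write_bins`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _BIN_META_COLS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"cluster table missing columns {missing}")
    return df
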