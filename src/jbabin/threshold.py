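"""Data-driven selection of the JBA correlation threshold ``ct``.

The idea: compute the window average correlations in a spectral region known
to hold only electronic noise (for plasma pJRES, e.g. δ 9.72-9.99) and in one
dense with metabolic resonances (e.g. δ 3.50-3.97), and place ``ct`` where
the empirical CDF of the noise sample reaches 1 — i.e. just above the largest
noise window correlation, so that by construction no window lying entirely in
the noise region forms a cluster.  The surviving fraction of signal-region
windows is reported as a sensitivity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .io import RegionMask, SpectraSet
from .jba import window_correlations

__all__ = ["CtSelection", "region_window_corrs", "select_ct"]


@dataclass
class CtSelection:
    """Outcome of threshold selection.

    ``ct`` is the smallest double strictly above the selected noise quantile
    (default quantile 1.0, i.e. the noise maximum), so that no noise window
    attains it under the >= acceptance rule used by seed detection and
    expansion.  ``signal_survival`` is the fraction of signal windows with
    average correlation >= ct.
    """

    ct: float
    noise_corrs: np.ndarray
    signal_corrs: np.ndarray
    noise_region: Optional[RegionMask] = None
    signal_region: Optional[RegionMask] = None
    quantile: float = 1.0

    @property
    def signal_survival(self) -> float:
        return float(np.mean(self.signal_corrs >= self.ct))


def region_window_corrs(s: SpectraSet, region: RegionMask, st: int,
                        cm: str = "pearson") -> np.ndarray:
    """Window average correlations for all windows fully inside the region.

    The values are the full-spectrum window correlations restricted to the
    anchors whose entire window lies inside the mask (so a window never
    straddles an interval boundary, and the restriction agrees bitwise with
    :func:`jbabin.jba.window_correlations` — thresholds derived from these
    values are therefore exactly comparable with a full-spectrum scan).
    """
    if st > s.n_variables:
        raise ParameterError("region holds fewer than st contiguous variables")
    cs = window_correlations(s, st, cm)
    inside = region.contains(s.ppm).astype(int)
    full = (np.lib.stride_tricks.sliding_window_view(inside, st).sum(axis=1) == st)
    if not full.any():
        raise ParameterError("region holds fewer than st contiguous variables")
    return cs.r_bar[np.flatnonzero(full)]


def select_ct(noise: np.ndarray, signal: np.ndarray,
              quantile: float = 1.0,
              noise_region: Optional[RegionMask] = None,
              signal_region: Optional[RegionMask] = None) -> CtSelection:
    """Place ``ct`` at the point where the noise correlation CDF reaches 1.

    With the default ``quantile`` of 1.0 that point is the noise maximum;
    lower quantiles give robustified variants.  The returned threshold is
    nudged to the next representable double above the quantile so that no
    noise window at or below it passes a >= comparison.
    """
    noise = np.asarray(noise, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if noise.size == 0 or signal.size == 0:
        raise ParameterError("noise and signal samples must be nonempty")
    if not 0.0 < quantile <= 1.0:
        raise ParameterError("quantile must lie in (0, 1]")
    base = float(np.quantile(noise, quantile))
    ct = float(np.nextafter(base, np.inf))
    return CtSelection(ct=ct, noise_corrs=noise, signal_corrs=signal,
                       noise_region=noise_region, signal_region=signal_region,
                       quantile=quantile)
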