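import numpy as np
import pytest

from jbabin import (JbaParams, RegionMask, generate, plasma_like_scenario,
                    region_window_corrs, run_jba, select_ct)


@pytest.fixture(scope="session")
def plasma():
    """The canned plasma-like scenario at its default seed: (spec, spectra, truth)."""
    spec = plasma_like_scenario()
    s, truth = generate(spec)
    return spec, s, truth


@pytest.fixture(scope="session")
def plasma_ct(plasma):
    """Threshold selection on the scenario's designated regions."""
    spec, s, _ = plasma
    noise = RegionMask([spec.noise_region])
    signal = RegionMask([spec.signal_region])
    return select_ct(region_window_corrs(s, noise, 4, "pearson"),
                     region_window_corrs(s, signal, 4, "pearson"),
                     noise_region=noise, signal_region=signal)


@pytest.fixture(scope="session")
def plasma_jba(plasma, plasma_ct):
    """JBA binning of the scenario (2-grid-point merge gap for split peaks)."""
    _, s, _ = plasma
    p = JbaParams(ct=plasma_ct.ct, st=4, cm="pearson", agg="sum",
                  merge_gap_ppm=0.004)
    return p, run_jba(s, p)


def small_peak_set(seed=0, n_samples=40, n_vars=60, peak=(30, 6, 50.0)):
    """A tiny one-peak spectra set used by several unit tests."""
    from jbabin.synthetic import Peak, SyntheticSpec, generate as gen

    center_idx, hwhm_pts, amp = peak
    step = 0.002
    spec = SyntheticSpec(
        n_samples=n_samples, ppm_lo=1.0, ppm_hi=1.0 + step * (n_vars - 1),
        step=step, peaks=[Peak(1.0 + step * center_idx, step * hwhm_pts, amp, 0)],
        n_factors=1, factor_log_sd=0.4, noise_sd=0.3, noise_rho=0.5,
        shift_sd=0.0, seed=seed)
    return gen(spec)
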