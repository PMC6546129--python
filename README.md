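# jbabin

Correlation-based binning of pJRES ¹H NMR spectra.

¹H NMR metabolic profiling of biofluids yields spectra with thousands of
variables but only a few hundred underlying metabolites, and in projected
J-resolved (pJRES) spectra the electronic noise is locally correlated rather
than random — so naive binning happily turns noise into features.  `jbabin`
implements **JBA**, a binning method that forms features only where adjacent
variables are *statistically* coupled across samples, together with the two
standard comparators and the evaluation machinery to judge all three.

Given a samples × variables matrix `X` with chemical-shift axis δ:

* a sliding window of `st` adjacent variables yields the average pairwise
  correlation
  `r̄(i) = mean{ corr(x_a, x_b) : i ≤ a < b ≤ i + st − 1 }`,
  a "pseudo-spectrum" whose peaks mark metabolic signals;
* local maxima with `r̄ ≥ ct` seed clusters, grown downfield/upfield while
  the cluster average stays ≥ `ct` and each candidate correlates more with
  its neighbour toward the cluster than away from it;
* cluster intensities are aggregated (sum/mean/median/max) and adjacent
  near-collinear clusters (r > 0.90) are fused, repairing peaks split by
  misalignment.

The threshold `ct` is not guessed: it is placed where the empirical CDF of
window correlations from a designated pure-noise region (e.g. δ 9.72–9.99)
reaches 1, so that by construction no noise window forms a cluster.

Also included: **SRV** (statistical recoupling of variables — segmentation
at local minima of the covariance/correlation landscape, superclustering at
Pearson r > 0.90), fixed-width **standard binning**, Spearman
cross-correlation of features against external (e.g. GC-MS) metabolite
concentrations with paired Wilcoxon method comparison, PCA diagnostics with
Hotelling's ellipse, and a synthetic pJRES generator with exact ground truth
(Lorentzian lines on latent log-normal concentrations, AR(1)-correlated
noise, per-sample misalignment).

## Worked example

```python
import numpy as np
from jbabin import (plasma_like_scenario, generate, RegionMask, region_window_corrs,
                    select_ct, JbaParams, run_jba, run_srv, SrvParams,
                    pca_diagnostics, region_recovery)

spec = plasma_like_scenario(seed=7)          # 617 samples, delta 0.40-10.00
spectra, truth = generate(spec)

noise = RegionMask([spec.noise_region])      # delta 9.70-10.00, pure noise
signal = RegionMask([spec.signal_region])    # delta 3.50-3.97, signal-rich
sel = select_ct(region_window_corrs(spectra, noise, st=4),
                region_window_corrs(spectra, signal, st=4))
print(f"selected ct: {sel.ct:.3f} (signal windows surviving: {sel.signal_survival:.0%})")

params = JbaParams(ct=sel.ct, st=4, cm="pearson", agg="sum", merge_gap_ppm=0.004)
bins = run_jba(spectra, params)
recovered = region_recovery(truth, bins, tol=2)
print(f"JBA: {bins.n_clusters} clusters, "
      f"{sum(recovered)}/{len(recovered)} planted regions recovered")

k = spec.n_factors
pca_fr = pca_diagnostics(spectra, "unit_variance", n_pc=k + 1)
pca_jba = pca_diagnostics(bins, "unit_variance", n_pc=min(k + 1, bins.n_clusters))
print(f"UV-scaled cumulative variance at PC {k}: "
      f"JBA {pca_jba.cumulative_variance[min(k, len(pca_jba.cumulative_variance)) - 1]:.0%} "
      f"vs full resolution {pca_fr.cumulative_variance[k - 1]:.0%}")
```

prints

```
selected ct: 0.411 (signal windows surviving: 31%)
JBA: 36 clusters, 23/25 planted regions recovered
UV-scaled cumulative variance at PC 27: JBA 86% vs full resolution 15%
```

Reading this: the data-driven threshold (0.411, the smallest value excluding
every noise window) keeps 31% of the signal-region windows as seed
candidates; JBA condenses 4 801 variables into 36 features, recovering 23 of
the 25 planted signal regions to within two grid points per boundary (the
two misses are weak peaks riding on strong lines' tails, whose merged
regions cannot be one cluster); and after unit-variance scaling — which
inflates every noise variable — 27 principal components explain 86% of the
variance of the JBA features versus 15% of the raw matrix, because the raw
matrix is still mostly noise columns.

## Command line

```
jba simulate --scenario plasma --seed 7 --out spectra.csv --truth truth.json
jba select-ct --input spectra.csv --noise-region 9.70:10.00 --signal-region 3.50:3.97
jba bin --method jba --input spectra.csv --st 4 --ct 0.411 --agg sum --out jba_bins.csv
jba bin --method srv --input spectra.csv --minsize 10 --out srv_bins.csv
jba evaluate --bins jba_bins.csv --bins srv_bins.csv --metabolites met.csv
```

Every artifact gets a JSON manifest (parameters, input checksums, version);
re-running a manifest's command reproduces the output byte-for-byte.

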