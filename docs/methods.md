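# Methods

## Problem setting

A projected J-resolved (pJRES) ¹H NMR spectrum of plasma is, for statistical
purposes, a vector of ~10⁴ intensities on a chemical-shift (ppm) axis.
Across a cohort of samples, the handful of variables that sample the same
metabolite resonance rise and fall together with that metabolite's
concentration, while variables in signal-free regions carry only electronic
noise — which, after apodization and zero-filling, is locally correlated
rather than i.i.d.  Binning methods collapse adjacent variables into
features; the question any binning method must answer is *where a feature
begins and ends*, and whether noise regions are allowed to become features.

This package implements three answers and the machinery to compare them:

* **JBA** — the correlation-threshold method this package is named for.
* **SRV** (statistical recoupling of variables) — an intensity-driven
  comparator.
* **SB** — fixed-width (standard) binning.

## The JBA procedure

Let `st` be the window size (default 4) and `cm` the correlation method
(Pearson or Spearman).

1. **Window correlation spectrum.** For every anchor `i`, the average of all
   `st(st−1)/2` pairwise correlations among variables `i … i+st−1` is
   computed, producing a pseudo-spectrum aligned to the ppm axis.  "Average
   correlation of the st variables" is read as the all-pairs mean (the
   consecutive-pairs mean is a strictly weaker statistic and is not used; the
   all-pairs definition is reused verbatim for cluster averages during
   expansion).  A zero-variance variable has all its correlations defined as
   0: a flat channel carries no covariance and must neither seed nor extend
   clusters.
2. **Seeds.** Local maxima of the pseudo-spectrum at or above the threshold
   `ct` become seeds.  A plateau (run of equal values strictly above its
   flanks) yields one seed at its lowest-ppm anchor; edge runs are compared
   only against their existing neighbour.
3. **Expansion.** Each seed window grows one variable at a time, alternating
   downfield (higher ppm) and upfield, each side closing permanently at the
   spectrum edge, at a variable claimed by a stronger cluster, or when its
   rule first fails.  A candidate is admitted only if (i) the cluster's
   all-pairs average correlation stays ≥ `ct`, and (ii) the candidate
   correlates at least as strongly with its neighbour toward the cluster as
   with its neighbour away from it.  Rule (ii) is what stops growth at the
   saddle between two distinct resonances and at the onset of noise —
   correlated noise actually sharpens this stop, because a noise candidate
   clings to the noise continuation rather than to the signal edge.
   Comparisons in rule (ii) carry a 1e−12 slack: mathematically equal
   correlations (exact rank-1 regions) differ by ~1 ulp in floating point
   and equality must mean "continue", not a coin flip.
   Seeds are processed in decreasing order of window correlation (ties:
   lower ppm first); a seed whose window is already partly claimed is
   dropped.  The output is therefore independent of storage order.
4. **Aggregation and merging.** Cluster intensity is the sum (or mean,
   median, max) of its member variables per sample.  Misalignment or overlap
   can split one resonance into fragments whose intensity profiles remain
   near-collinear; adjacent clusters whose aggregated intensities correlate
   above `merge_r` (default 0.90) are fused, iterating left to right until a
   pass makes no merge.  `merge_gap_ppm` widens "adjacent" to clusters whose
   facing edges are at most that far apart (default 0 = index-adjacent; two
   grid steps is the practical choice when split fragments leave one or two
   unclustered points at a decorrelated apex).  A fused cluster aggregates
   the union of the member variables — gap variables stay out — so sum
   aggregation is exactly conserved by merging.

### Choosing `ct`

`ct` separates metabolic from electronic-noise windows.  The selection rule
computes the window correlations inside a region known to be pure noise
(for plasma pJRES, δ 9.72–9.99 is the conventional choice) and inside a
signal-rich region (δ 3.50–3.97), and places `ct` where the empirical CDF of
the noise sample reaches 1 — implemented as the smallest double strictly
above the chosen noise quantile (default: the maximum), so that *no* noise
window attains the threshold under the ≥ rule.  The surviving fraction of
signal windows is reported as a sensitivity diagnostic.  Region window
correlations are computed as the restriction of the full-spectrum scan to
anchors whose whole window lies inside the region; this keeps the threshold
bitwise-comparable with the scan it will gate.

The guarantee is exact only for the sampled region: windows elsewhere in
noise territory can (and occasionally do) exceed the max of a 150-point
sample, which is why a handful of small spurious clusters can appear in
unsampled noise stretches — consistent with how the method behaves on real
cohorts, where the threshold generalizes well but not perfectly.

## SRV comparator

SRV scans the "dependency landscape": for each adjacent pair, the ratio of
covariance to Pearson correlation, which for non-degenerate pairs equals the
product of the two standard deviations (n−1 denominators throughout).
Pairs with a zero-variance member or exactly zero correlation are assigned
0, forcing edges at dead regions.  Strict local minima of the landscape are
cluster edges (plateau minima: edge at the lowest-ppm position of the run;
the boundary falls between the minimum pair's two variables; the axis ends
are implicit edges).  Segments with ≥ `minsize` variables (default 10) are
retained, smaller ones neglected.  Finally consecutive retained clusters
with Pearson correlation of aggregated intensities > 0.90 are fused into
superclusters; no gap limit applies, since discarded small segments may
separate fragments of one signal.

Because the landscape is intensity-driven, locally correlated noise also
produces retained segments — the central selectivity difference from JBA,
and the reason SRV carries a large share of noise features at permissive
`minsize`.

## Standard binning

Half-open intervals `[lo, lo + width)` anchored at the lowest ppm, default
width 0.005 ppm; every non-empty interval is a feature, so the bins
partition the variable set exactly.  Grid points that fall on an interval
boundary only through floating-point rounding are snapped up (tolerance
1e−9 of a width).

## Evaluation battery

* **Cross-correlation**: Spearman correlation of every feature with every
  externally quantified metabolite over the shared samples (≥ 3 required,
  matched by sample id).  Per metabolite the best feature is the *maximum*
  coefficient — concentrations and resonance intensities are positively
  related, so maximizing |r| would reward artifacts.  When a metabolite's
  resonance windows are known, candidates are restricted to features
  intersecting them; no candidate in range flags the metabolite ND (not
  detected).
* **Paired comparison**: two-sided Wilcoxon signed-rank on the paired
  per-metabolite coefficients of two methods, ND pairs dropped (a paired
  test needs both coefficients).  The exact null distribution is used for
  n ≤ 25 without zeros or tied magnitudes, otherwise the tie-corrected
  normal approximation (scipy's implementation in both cases).
* **PCA diagnostics**: SVD of the column-centred (optionally unit-variance
  scaled) matrix; explained-variance fractions from squared singular values;
  95% Hotelling T² ellipse for the first two scores with semi-axes
  `sqrt(var_PC · 2(n−1)/(n−2) · F₀.₉₅(2, n−2))`.  Zero-variance columns are
  dropped (with a warning) before unit-variance scaling.  Unit-variance
  scaling is the discriminating setting: it inflates every noise variable to
  unit weight, so a matrix still carrying noise variables needs many more
  components for the same cumulative variance.

## Synthetic data model

The generator produces the features of pJRES plasma spectra that matter to
correlation-based binning, with exact ground truth:

* **Lines**: Lorentzian shapes `h²/(h² + x²)` with per-peak half-width and
  amplitude, each driven by a latent "metabolite concentration" factor.
  The shape is truncated at 1% of apex — the same cutoff at which the
  ground-truth support is reported — so a support boundary means exactly
  "beyond this point the variable is pure noise".  This models the
  visibility limit of a real baseline: tails below ~1% of apex are sunk in
  noise.  (Untruncated tails of strong lines would remain detectably
  correlated far beyond any fixed cutoff at cohort sample sizes, making
  "the" support boundary ill-defined.)
* **Concentrations**: log-normal (median 1, log-sd 0.4 — right-skewed and
  non-negative like plasma metabolites), mildly equicorrelated between
  factors (r = 0.2) through a Gaussian copula.
* **Noise**: stationary AR(1) along the axis (ρ = 0.5, sd 0.4), emulating
  apodization-induced local correlation; "not truly random" noise is the
  reason a correlation threshold has to be *selected* rather than assumed 0.
* **Misalignment**: integer grid shifts per sample (sd 0.1 points), keeping
  truth bookkeeping exact.
* **Ground truth**: per-peak supports, their connected unions ("signal
  regions" — the unit a binning method can actually be asked to recover,
  since overlapping peaks are not separable at boundary resolution), the
  concentration matrix and the shifts.

### The canned plasma-like scenario

`plasma_like_scenario()` (617 samples — a typical large-cohort size — on a
δ 0.40–10.00 grid at 0.002 ppm/point):

* 20 isolated singlets at δ 0.8–5.3, amplitudes 60–140, half-width one grid
  point; four of them inside the δ 3.50–3.97 signal window used for
  threshold selection.
* three two-line multiplet groups sharing one factor per group, lines
  0.016 ppm apart so their supports overlap: each line seeds separately,
  expansion stops at the saddle, and the merge step reunites the fragments.
* two strong lines (amplitude 280) each carrying a weak narrow peak
  (amplitude 20) on its visible tail — the classic low-abundance-metabolite
  motif: the weak peak's footprint falls below SRV's default `minsize` and
  its landscape bump sits on the host's slope, so SRV merges or misses it,
  while JBA's correlation spectrum shows a local maximum there.
* δ 9.70–10.00 designated as the pure-noise window.

Amplitudes versus the noise floor are set so the 1%-of-apex level of a
typical line sits at or below the noise sd — the regime in which the support
cutoff is the natural detection boundary.  The two host+tail regions are not
recoverable as single clusters (their supports overlap but their factors
differ), which bounds ground-truth region recovery at 23/25 = 92% by
construction; the other 23 regions are recovered within ±2 variables across
every seed tried during development.

### What the generator does not emulate

J-coupling fine structure, tilting/symmetrization artifacts, baseline
distortion, chemical-shift drift with pH/ionic strength (beyond integer
shifts), peak-shape asymmetry, and ridge noise concentrated under strong
peaks.  Consequently, passing tests demonstrate that the algorithms behave
as specified under a faithful correlation structure — not that boundary
accuracy on real spectra will match the synthetic figures.  The real-data
headline numbers reported for this method (12 273 variables, ct = 0.834,
287 JBA vs 411 SRV clusters on the deposited cohort matrix) require the
deposited data and are outside this repository's test surface.

## Numerical choices

* Correlations via standardized column scores (z-scores of values for
  Pearson, of midranks for Spearman), so `corr(i,j) = zᵢ·zⱼ/(n−1)`;
  degenerate columns get all-zero scores.  Minimum 3 samples.
* Window averages computed lag-wise with exact sliding-window sums; the
  cluster average during expansion is maintained incrementally through the
  score-sum vector (O(n) per candidate) and matches the brute-force
  all-pairs mean to 1e−12.
* Text round-trips use `repr`/`%.17g` on write and round-trip float parsing
  on read, so written matrices and cluster tables reload bitwise-identical.
* Problem sizes in the test battery: the scenario matrix is 617 × 4801; the
  oracle batteries use 50 random matrices up to 30 × 25.  The full pipeline
  on the scenario runs in a few seconds.

## Known limitations

* The ct guarantee is by construction only within the sampled noise region.
* Heavily overlapped same-factor lines closer than ~4 grid points form a
  unimodal correlation ridge: the algorithm's own rules then yield a single
  seed whose expansion stops at the saddle, leaving the second line's flank
  unclustered.  This mirrors the method's documented weakness in extensively
  overlapped regions and is why the scenario's multiplets are placed at
  tail-overlap rather than apex-overlap separation.
* `merge_gap_ppm > 0` can bridge genuinely distinct but collinear
  resonances; it should stay at a small multiple of the grid step.
* SRV plateau/edge conventions follow this package's documented tie-breaks,
  not any specific historical implementation.
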