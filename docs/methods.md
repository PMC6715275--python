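# Methods

## Model

`peakqc` frames multi-caller (or multi-experiment) ChIP-Seq peak sets as a
capture–recapture problem. The unknown population is the set of genuine
binding regions of the assayed factor; each of the k datasets is a capture
occasion. After pooling and merging all regions, the support count of a
merged region — how many distinct datasets contain a peak in it — is the
number of times that region was "captured". Regions captured zero times
are unobservable, so the observed counts follow a zero-truncated
distribution; the package's metrics rest on the working assumption that
this distribution is (approximately) zero-truncated Poisson, and that
false-positive peaks are almost always *orphans* (support 1), since two
callers rarely invent the same artifact at the same locus.

Two consequences of the Poisson assumption are used:

1. The expected orphan count among genuine regions is
   f₁ᵉ = 2f₂²/(3f₃) (from p₁ = λe^{−λ}, p₂ = λ²e^{−λ}/2, p₃ = λ³e^{−λ}/6:
   eliminate λ via λ = 2p₂/p₁ and p₁ = 6p₃/λ²). FPCM = f₁/f₁ᵉ then
   measures the orphan excess and p_false = 1 − 1/FPCM the implied
   false-orphan proportion (clamped at 0 when FPCM < 1, where the formula
   would go negative).
2. The number of genuine regions N can be estimated from the truncated
   count frequencies: Chao's and Lanumteang–Böhning's moment estimators,
   Zelterman's estimator, and the zero-truncated Poisson MLE
   N̂ = n/(1 − e^{−λ*}).

When FPCM exceeds the threshold FPCM₀ the frequency-based estimators are
abandoned (removing orphans forces f₁ = 0 and breaks them) in favour of
pairwise two-sample Chapman estimates, screened for outliers and averaged.

## Merging and counting

Merged regions are single-linkage connected components of the pooled
intervals: two intervals connect iff they share at least `min_overlap_bp`
bases (default 1) on the same chromosome, under 0-based half-open BED
coordinates — bookended intervals do not merge. The implementation is a
sorted sweep, which for interval graphs yields exactly the connected
components; the test suite checks it against an independent O(m²)
union-find oracle on random fixtures.

Composition counts **distinct datasets**, not peaks: two peaks of one
caller inside one merged region contribute 1. This keeps composition in
1..k, which every frequency formula requires. The pairwise recapture count
|Dᵢ∩Dⱼ| used by Chapman is defined symmetrically as the number of
pair-only merged regions supported by both datasets, not the asymmetric
count of Dᵢ peaks touching Dⱼ.

## Numerical choices

* **ZTP MLE.** The log-likelihood L(λ) = log λ · Σᵢ i·fᵢ − n·log(e^λ − 1)
  has the stationarity condition λ/(1 − e^{−λ}) = (Σᵢ i·fᵢ)/n, whose left
  side is strictly increasing from 1; λ* is found by Brent bracketing on
  [10⁻⁸, 700] (the cap keeps e^λ finite) with absolute tolerance 10⁻¹⁰.
  A sample mean ≤ 1 has no interior maximum and raises. A test asserts
  both the stationarity equation (to 10⁻⁸) and agreement with a
  grid-search maximization of L.
* **Degenerate frequencies.** Chao and Lanumteang–Böhning return n
  (flagged) when their correction term vanishes identically (f₁ = 0, or
  f₃ = 0 for LB) even if f₂ = 0; the undefined-estimator error is raised
  only when the term is genuinely indeterminate (f₁ > 0 with f₂ = 0).
  Zelterman at f₁ = 0 returns its limit n, flagged. FPCM with f₂ = 0 or
  f₃ = 0 (and orphans present) is undefined and raises rather than
  guessing.
* **ZTP-ML at saturation.** When every region is supported by all k
  datasets (f = (0,…,0,m)) the three closed-form estimators return m
  exactly, but the MLE still allows for unseen zero-count regions:
  λ* solves λ/(1 − e^{−λ}) = k, giving N̂ = m/(1 − e^{−λ*}) ≈ 1.02 m at
  k = 4. FNCM of a perfect dataset is therefore a constant just below 1
  (≈ 0.995), not exactly 1.
* **Outlier screen.** Each Chapman estimate is tested once against the
  mean and *sample* (n−1) standard deviation of the other five-or-more
  original estimates; all elements breaching 3σ are removed in one
  simultaneous pass. The pass is deliberately not iterated: on the
  published six-estimate sample a single pass removes exactly the one
  low estimate (43591) and keeps the high one (47198), matching the
  published five-estimate average of 46119; iteration would remove both.
  σ = 0 with zero deviation keeps the element (0 > 0 is false).
* **Branch bookkeeping.** In the orphans-removed branch |Dᵢ| in the FNCM
  numerator is the original dataset size (the formula's literal reading);
  orphan-removed sizes are reported alongside. Pairwise overlaps are
  unaffected by orphan removal, since an orphan by definition overlaps
  nothing from another dataset.
* **Ranking.** Datasets are ranked by descending FNCM; ties break by
  input order. FNCM > 1 (dataset larger than the estimated population —
  estimator noise or uncorrected false positives) is reported with a
  warning, never clamped.
* **Default FPCM₀ = 2.0** (half the orphans false); configurable.

## Synthetic data

The generator places `n_true` genuine regions non-overlapping and
uniformly on a linear genome (sorted-uniform gap sampling, no rejection
loop), samples peak widths from a clipped normal (mean 200 bp, sd 40,
min 50 — the usual ChIP-Seq peak scale), and has each of k datasets
detect each region independently with probability `detection_prob[i]`
(defaults 0.85/0.80/0.75/0.80, a realistic spread of caller
sensitivities). Detected copies are jittered by up to ±20 bp per
boundary; jitter is capped below the minimum width and regions are spaced
more than twice the jitter apart, so jittered copies always stay in their
own region's component and the composition bookkeeping is exact (a test
compares frequencies with the ground-truth detection matrix). Spurious
peaks (`fp_count`, default 0) are rejection-sampled to overlap nothing —
orphans by construction. Everything derives from one integer seed via
`numpy.random.default_rng`; identical configs give bit-identical BED
output.

**What the generator does and does not emulate.** Composition is
independent-Bernoulli per dataset (binomial across datasets), matching
the biological story of k independent callers with a hard cap of k
captures. It is *not* Poisson, and for homogeneous binomial composition
the orphan expectation 2f₂²/(3f₃) evaluates to f₁·(k−1)/(k−2) — i.e.
FP-free FPCM concentrates at (k−2)/(k−1) = 2/3 for k = 4, for any
detection probability, rather than at 1. The Poisson value 1 is recovered
only as k grows. The calibration test asserts this analytic value; real
data, with heterogeneous per-region detectability, evidently sits closer
to the Poisson regime (published FP-free examples show FPCM ≈ 1). Passing
tests on the generator therefore validate the estimators and the
workflow's branch logic, not the accuracy of the Poisson orphan model on
any particular real dataset. Similarly, the four N estimators carry a
small model bias under binomial capture (≈ +2% for the ZTP-ML term at
p = 0.8, k = 4, ≈ +1% for their average); recovery tests allow 3 Monte-
Carlo standard errors with a 2% floor, while pure-Poisson simulated
samples are held to 3 standard errors with no floor. The generator also
does not model reads, fragment lengths, mappability, or tethered
(indirect) binding.

## Problem sizes

Monte-Carlo tests use n_true = 300–2000 regions, 10–100 replicates, and
≤ 100-interval oracle fixtures — sizes at which every statistical
tolerance above is already stable and the whole suite runs in well under
a minute.

## Limitations

* FPCM needs k ≥ 3 (f₂ and f₃) and is undefined when f₂ or f₃ is 0.
* The Poisson assumption is a working approximation; FPCM's absolute
  scale depends on it (see the binomial analysis above), which is why the
  decision rule uses a generous threshold (2–3) rather than a test at 1.
* No confidence intervals are provided for the N estimators; the
  outlier-screened Chapman average is a point estimate.
* Chromosome names are compared verbatim; a warning (not an error) is
  emitted when two datasets share no chromosome names.
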