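# peakqc

Quality control for ChIP-Seq peak datasets by capture–recapture: how many
of a peak caller's regions are false positives, and how many genuine
binding regions did it miss?

## The problem

A ChIP-Seq experiment for one transcription factor is typically processed
by several peak callers (e.g. GEM, MACS, PICS, SISSRs), each producing its
own set of transcription-factor binding regions (TFBRs). The callers
disagree, and the classical quality metrics (FRiP, NSC/RSC, ...) say
nothing about the false-positive or false-negative rate of any individual
dataset. `peakqc` treats the k datasets of a *meta-set*
D = {D₁, …, Dₖ} (k ≥ 3; one dataset per caller, or per experiment for the
same TF) as k independent "capture occasions" of an unknown population of
genuine binding regions and applies population-size estimation.

## The method

All TFBRs are pooled and merged into single-linkage connected components
(≥ 1 bp overlap, half-open BED coordinates). For each merged region the
number of distinct datasets supporting it is counted, giving the *pivotal
frequencies* f₁, …, fₖ with f₁ + … + fₖ = n merged regions. A region
supported by a single dataset is an *orphan* — and nearly all false
positives are orphans.

**False Positive Control Metric.** If the support count of a genuine
region is approximately Poisson(λ), then p₁ = 2p₂²/(3p₃), so the expected
orphan count is f₁ᵉ = 2f₂²/(3f₃) and

    FPCM = f₁ / f₁ᵉ,   p_false = 1 − 1/FPCM.

FPCM ≈ 1 means orphans occur at the expected rate (few false positives);
FPCM > a threshold FPCM₀ (default 2.0, i.e. at least half the orphans
false) recommends removing orphans.

**False Negative Control Metric.** FNCM(Dᵢ) = |Dᵢ| / N̂, where N̂
estimates the number of genuine regions N:

* *No-modification branch* (FPCM ≤ FPCM₀): N₁ᵉ is the mean of four
  frequency-based estimators — Chao (n + f₁²/2f₂), Lanumteang–Böhning
  (n + 3f₁³f₃/4f₂³), Zelterman (n / (1 − e^(−2f₂/f₁))) and the
  zero-truncated Poisson MLE (n / (1 − e^(−λ*)), λ* from the ZTP
  likelihood).
* *Orphans-removed branch* (FPCM > FPCM₀): f₁ vanishes and those
  estimators degenerate, so N₂ᵉ is the mean of the k(k−1)/2 pairwise
  Chapman estimates Eᵢⱼ = (|Dᵢ|+1)(|Dⱼ|+1)/(|Dᵢ∩Dⱼ|+1) − 1 after a
  single-pass leave-one-out 3σ outlier screen.

FNCM near 1 means few missed regions; datasets are ranked by descending
FNCM to pick the most complete caller.

## Worked example

A published four-caller CTCF meta-set has pivotal frequencies
f = (5534, 4542, 2482, 32141) over n = 44699 merged regions, with dataset
sizes 41827 (GEM), 45318 (MACS), 78011 (PICS), 43215 (SISSRs):

```bash
peakqc assess-freq --f 5534 4542 2482 32141 \
    --sizes 41827,45318,78011,43215 --labels GEM,MACS,PICS,SISSRs
```

prints (abridged):

```json
{
  "fpcm": {"fpcm": 0.9987, "f1_expected": 5541.17, "p_false": 0.0,
           "exceeds_threshold": false},
  "fncm": {
    "n_estimate": 49524.63,
    "estimator_values": {"chao": 48070.33, "lanumteang_bohning": 48065.97,
                         "zelterman": 55436.59, "ztp_ml": 46525.64},
    "per_dataset": {"GEM": 0.845, "MACS": 0.915, "PICS": 1.575,
                    "SISSRs": 0.873}
  },
  "recommendation": "keep_all"
}
```

FPCM ≈ 1: the 5534 observed orphans match the Poisson expectation, so no
orphan removal is needed, and N₁ᵉ ≈ 49525 genuine regions are estimated.
MACS misses the fewest (FNCM 0.915); PICS exceeding 1 flags
over-generation of peaks rather than completeness. A second meta-set with
f = (46452, 5797, 12012, 28175) gives FPCM ≈ 24.9 — the vast majority of
its 46452 orphans are false, and the tool recommends `filter-orphans` and
switches FNCM to the Chapman branch.

Other subcommands: `assess` (from BED files), `estimate` (just the four
estimators), `merge` (merged regions + frequency table), `filter-orphans`
(write orphan-removed BEDs), `simulate` (synthetic meta-sets with known
ground truth). Everything is also available as a library
(`import peakqc`).

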