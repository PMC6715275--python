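"""FPCM / FNCM quality-control workflow for ChIP-Seq peak meta-sets.

The false-positive control metric (FPCM) compares the observed orphan
count f_1 with the count expected under a Poisson model of how many
datasets capture a genuine region:

    FPCM = f_1 / f_1^e,    f_1^e = 2 f_2^2 / (3 f_3).

FPCM near 1 means orphans occur at roughly the Poisson-expected rate —
few false positives. FPCM >> 1 means orphans are in excess; the implied
proportion of false-positive orphans is p_false = 1 - 1/FPCM.

The false-negative control metric (FNCM) of each dataset is its size
divided by an estimate of the number of genuine binding regions N^gen:

* FPCM <= threshold (default 2.0): no modification; N_1^e is the mean of
  the Chao, Lanumteang-Bohning, Zelterman and zero-truncated-Poisson-ML
  estimators computed from the pivotal frequencies.
* FPCM > threshold: orphans are removed; with f_1 gone the four
  frequency-based estimators degenerate, so N_2^e is the mean of the
  k(k-1)/2 pairwise Chapman estimates after a single-pass leave-one-out
  3-sigma outlier screen.

FNCM close to 1 indicates few missed regions; estimator noise can push it
above 1, in which case it is reported with a warning, never clamped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DegenerateInputError, UndefinedMetricError
from .peak_io import MetaSet, PeakDataset
from .popsize_estimators import (
    PopulationEstimate,
    chao,
    chapman,
    lanumteang_bohning,
    leave_one_out_outliers,
    zelterman,
    ztp_mle,
)
from .region_merge import (
    MergedRegion,
    PivotalFrequencies,
    merge_meta_set,
    orphan_regions,
    pairwise_intersection,
    pivotal_frequencies,
)

logger = logging.getLogger(__name__)

DEFAULT_FPCM_THRESHOLD = 2.0

BRANCH_UNMODIFIED = "no_modification"
BRANCH_ORPHANS_REMOVED = "orphans_removed"


@dataclass
class FpcmResult:
    """FPCM together with the quantities it is built from."""

    fpcm: float
    f1_expected: float
    p_false: float
    threshold: float
    exceeds_threshold: bool
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "fpcm": self.fpcm,
            "f1_expected": self.f1_expected,
            "p_false": self.p_false,
            "threshold": self.threshold,
            "exceeds_threshold": self.exceeds_threshold,
            "note": self.note,
        }


@dataclass
class FncmResult:
    """Per-dataset FNCM values plus the N estimate behind them."""

    per_dataset: dict[str, float]
    n_estimate: float
    branch: str
    estimator_values: dict[str, float]
    discarded_outliers: list[float] = field(default_factory=list)
    sizes_after_orphan_removal: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return {
            "per_dataset": self.per_dataset,
            "n_estimate": self.n_estimate,
            "branch": self.branch,
            "estimator_values": self.estimator_values,
            "discarded_outliers": self.discarded_outliers,
            "sizes_after_orphan_removal": self.sizes_after_orphan_removal,
        }


@dataclass
class QcReport:
    """Complete QC assessment of one meta-set."""

    labels: list[str]
    sizes: list[int]
    frequencies: PivotalFrequencies
    fpcm: FpcmResult
    fncm: FncmResult | None
    recommendation: str
    ranking: list[str]

    def to_dict(self) -> dict:
        return {
            "k": len(self.labels),
            "labels": self.labels,
            "sizes": self.sizes,
            "frequencies": {"f": list(self.frequencies.f),
                            "n": self.frequencies.n},
            "fpcm": self.fpcm.to_dict(),
            "fncm": self.fncm.to_dict() if self.fncm is not None else None,
            "recommendation": self.recommendation,
            "ranking": self.ranking,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QcReport":
        fncm = None
        if d.get("fncm") is not None:
            fb = dict(d["fncm"])
            fncm = FncmResult(**fb)
        return cls(
            labels=list(d["labels"]),
            sizes=list(d["sizes"]),
            frequencies=PivotalFrequencies(
                f=list(d["frequencies"]["f"]), n=d["frequencies"]["n"]
            ),
            fpcm=FpcmResult(**d["fpcm"]),
            fncm=fncm,
            recommendation=d["recommendation"],
            ranking=list(d["ranking"]),
        )


def expected_orphans(f2: int, f3: int) -> float:
    """Poisson-expected orphan count f_1^e = 2 f_2^2 / (3 f_3).

    Derived from the ratios of the Poisson probabilities of composition
    1, 2 and 3; f_3 = 0 leaves the expectation (and hence FPCM) undefined.
    """
    if f3 <= 0:
        if f2 == 0:
            return 0.0
        raise UndefinedMetricError(
            "expected orphan count undefined: f3 = 0 with f2 > 0; "
            "inspect the merged regions directly"
        )
    return 2.0 * f2 ** 2 / (3.0 * f3)


def fpcm(freqs: PivotalFrequencies,
         threshold: float = DEFAULT_FPCM_THRESHOLD) -> FpcmResult:
    """Compute FPCM = f_1 / f_1^e and the implied false-orphan proportion.

    p_false = 1 - 1/FPCM, clamped at 0 when FPCM < 1 (fewer orphans than
    expected implies no estimable false-positive excess).
    """
    if freqs.k < 3:
        raise UndefinedMetricError(
            f"FPCM needs k >= 3 datasets (f2 and f3), got k = {freqs.k}"
        )
    f1, f2, f3 = freqs.f1, freqs.f2, freqs.f3
    if f1 == 0:
        return FpcmResult(
            fpcm=0.0, f1_expected=expected_orphans(f2, f3) if f3 > 0 else 0.0,
            p_false=0.0, threshold=threshold, exceeds_threshold=False,
            note="no orphans observed (f1 = 0)",
        )
    if f2 == 0 or f3 == 0:
        raise UndefinedMetricError(
            f"FPCM undefined for f2 = {f2}, f3 = {f3}; "
            "inspect the merged regions directly"
        )
    f1e = expected_orphans(f2, f3)
    value = f1 / f1e
    note = None
    if value >= 1.0:
        p_false = 1.0 - 1.0 / value
    else:
        p_false = 0.0
        note = "FPCM < 1: fewer orphans than expected; p_false clamped at 0"
    return FpcmResult(
        fpcm=value, f1_expected=f1e, p_false=p_false, threshold=threshold,
        exceeds_threshold=value > threshold, note=note,
    )


def fpcm_from_p_false(p_false: float) -> float:
    """Invert p_false = 1 - 1/FPCM: FPCM = 1 / (1 - p_false)."""
    if not 0.0 <= p_false < 1.0:
        raise ValueError("p_false must lie in [0, 1)")
    return 1.0 / (1.0 - p_false)


def _four_estimates(freqs: PivotalFrequencies) -> dict[str, PopulationEstimate]:
    _, e_ml = ztp_mle(freqs)
    return {
        "chao": chao(freqs.f1, freqs.f2, freqs.n),
        "lanumteang_bohning": lanumteang_bohning(
            freqs.f1, freqs.f2, freqs.f3, freqs.n),
        "zelterman": zelterman(freqs.f1, freqs.f2, freqs.n),
        "ztp_ml": e_ml,
    }


def _fncm_values(sizes: dict[str, int], n_estimate: float) -> dict[str, float]:
    out = {}
    for label, size in sizes.items():
        val = size / n_estimate
        if val > 1.0:
            warnings.warn(
                f"FNCM({label}) = {val:.3f} > 1: dataset larger than the "
                "estimated genuine-region count (estimator noise or false "
                "positives); reported unclamped",
                stacklevel=3,
            )
        out[label] = val
    return out


def fncm_unmodified(meta: MetaSet | None,
                    freqs: PivotalFrequencies,
                    sizes: dict[str, int] | None = None) -> FncmResult:
    """FNCM via N_1^e = mean(E_C, E_LB, E_Z, E_ML) — no-modification branch.

    ``sizes`` may be given instead of ``meta`` for the frequencies-only
    entry path (published frequency vectors plus dataset sizes).
    """
    if sizes is None:
        if meta is None:
            raise ValueError("either meta or sizes must be provided")
        sizes = dict(zip(meta.labels, meta.sizes))
    estimates = _four_estimates(freqs)
    n1e = float(np.mean([e.value for e in estimates.values()]))
    return FncmResult(
        per_dataset=_fncm_values(sizes, n1e),
        n_estimate=n1e,
        branch=BRANCH_UNMODIFIED,
        estimator_values={name: e.value for name, e in estimates.items()},
    )


def chapman_sample(meta: MetaSet,
                   min_overlap_bp: int = 1) -> dict[str, float]:
    """Chapman estimate E_ij for every unordered dataset pair (i < j)."""
    out: dict[str, float] = {}
    for i, j in combinations(range(meta.k), 2):
        overlap = pairwise_intersection(meta, i, j,
                                        min_overlap_bp=min_overlap_bp)
        size_i, size_j = meta.datasets[i].size, meta.datasets[j].size
        # the symmetric recapture count can exceed neither pair-merged
        # dataset region count, but a dataset with internally-overlapping
        # peaks may have fewer merged regions than peaks; cap defensively
        est = chapman(size_i, size_j, min(overlap, size_i, size_j))
        out[f"{meta.labels[i]}|{meta.labels[j]}"] = est.value
    return out


def fncm_modified(meta: MetaSet,
                  sizes: dict[str, int] | None = None,
                  min_overlap_bp: int = 1) -> FncmResult:
    """FNCM via outlier-screened pairwise Chapman estimates (orphans-removed
    branch).

    Pairwise overlaps are computed on ``meta`` as given (orphans never
    contribute to any pairwise overlap, so removing them beforehand does
    not change the recapture counts). |D_i| in the FNCM numerator uses
    the ORIGINAL dataset size unless ``sizes`` overrides it; the
    orphan-removed sizes are reported alongside.
    """
    if meta.k < 3:
        raise DegenerateInputError(
            f"modified branch needs k >= 3 (>= 3 Chapman estimates for the "
            f"outlier screen), got k = {meta.k}"
        )
    if sizes is None:
        sizes = dict(zip(meta.labels, meta.sizes))
    overlaps = {
        (i, j): pairwise_intersection(meta, i, j,
                                      min_overlap_bp=min_overlap_bp)
        for i, j in combinations(range(meta.k), 2)
    }
    if all(v == 0 for v in overlaps.values()):
        raise DegenerateInputError(
            "all pairwise dataset overlaps are zero; Chapman estimation is "
            "degenerate"
        )
    pair_estimates: dict[str, float] = {}
    for (i, j), overlap in overlaps.items():
        size_i, size_j = meta.datasets[i].size, meta.datasets[j].size
        est = chapman(size_i, size_j, min(overlap, size_i, size_j))
        pair_estimates[f"{meta.labels[i]}|{meta.labels[j]}"] = est.value
    values = list(pair_estimates.values())
    kept, removed = leave_one_out_outliers(values)
    n2e = float(np.mean(kept))
    removed_meta = remove_orphans(meta, min_overlap_bp=min_overlap_bp)
    return FncmResult(
        per_dataset=_fncm_values(sizes, n2e),
        n_estimate=n2e,
        branch=BRANCH_ORPHANS_REMOVED,
        estimator_values=pair_estimates,
        discarded_outliers=removed,
        sizes_after_orphan_removal=dict(
            zip(removed_meta.labels, removed_meta.sizes)),
    )


def remove_orphans(meta: MetaSet, min_overlap_bp: int = 1) -> MetaSet:
    """Drop every interval that forms a composition-1 merged region.

    Re-merging the result yields f_1 = 0: removing whole single-dataset
    components cannot split or create any other component.
    """
    regions = merge_meta_set(meta, min_overlap_bp=min_overlap_bp)
    orphan_ivs: list[set] = [set() for _ in range(meta.k)]
    for region in orphan_regions(regions):
        for d_idx, ivs in region.members.items():
            orphan_ivs[d_idx].update(ivs)
    new_datasets = []
    for d_idx, dataset in enumerate(meta.datasets):
        keep = [iv for iv in dataset.intervals if iv not in orphan_ivs[d_idx]]
        new_datasets.append(PeakDataset(label=dataset.label, intervals=keep))
    return MetaSet(new_datasets)


def rank_callers(fncm: FncmResult | dict[str, float]) -> list[str]:
    """Dataset labels in descending FNCM order (higher = fewer misses).

    Ties are broken by input order, making the ranking deterministic.
    """
    per = fncm.per_dataset if isinstance(fncm, FncmResult) else fncm
    if len(per) < 2:
        raise ValueError("ranking needs at least two datasets")
    order = list(per)
    return sorted(order, key=lambda lbl: (-per[lbl], order.index(lbl)))


def assess(meta: MetaSet,
           threshold: float = DEFAULT_FPCM_THRESHOLD,
           min_overlap_bp: int = 1) -> QcReport:
    """Run the full QC workflow on a meta-set of BED-derived datasets.

    Merge -> pivotal frequencies -> FPCM -> branch:
    FPCM <= threshold keeps all peaks and averages the four
    frequency-based estimators (N_1^e); FPCM > threshold recommends
    removing orphans and switches to the outlier-screened Chapman mean
    (N_2^e). The report carries the ranking of datasets by descending
    FNCM.
    """
    if meta.k < 3:
        raise DegenerateInputError(
            f"assessment needs k >= 3 datasets, got k = {meta.k}"
        )
    regions = merge_meta_set(meta, min_overlap_bp=min_overlap_bp)
    freqs = pivotal_frequencies(regions, meta.k)
    logger.info("k=%d sizes=%s n=%d f=%s", meta.k, meta.sizes, freqs.n, freqs.f)
    fp = fpcm(freqs, threshold=threshold)
    logger.info("FPCM=%.4g exceeds_threshold=%s", fp.fpcm, fp.exceeds_threshold)
    if fp.exceeds_threshold:
        fn = fncm_modified(meta, min_overlap_bp=min_overlap_bp)
        recommendation = "remove_orphans"
    else:
        fn = fncm_unmodified(meta, freqs)
        recommendation = "keep_all"
    logger.info("branch=%s N=%.6g fncm=%s", fn.branch, fn.n_estimate,
                {k: round(v, 4) for k, v in fn.per_dataset.items()})
    return QcReport(
        labels=meta.labels,
        sizes=meta.sizes,
        frequencies=freqs,
        fpcm=fp,
        fncm=fn,
        recommendation=recommendation,
        ranking=rank_callers(fn),
    )


def assess_frequencies(f: list[int],
                       sizes: list[int] | None = None,
                       labels: list[str] | None = None,
                       threshold: float = DEFAULT_FPCM_THRESHOLD) -> QcReport:
    """Frequencies-only entry path: assess a published frequency vector.

    Without BED files the orphan-removal branch cannot recompute pairwise
    overlaps, so when FPCM exceeds the threshold the report records the
    recommendation but carries FNCM only if the no-modification
    estimators are computable AND dataset sizes are supplied; FNCM is
    otherwise skipped (``fncm = None``).
    """
    freqs = PivotalFrequencies(f=list(f), n=int(sum(f)))
    if labels is None:
        labels = [f"D{i + 1}" for i in range(freqs.k)]
    if sizes is not None and len(sizes) != freqs.k:
        raise ValueError("sizes must have one entry per dataset")
    fp = fpcm(freqs, threshold=threshold)
    fn: FncmResult | None = None
    if sizes is not None and not fp.exceeds_threshold:
        fn = fncm_unmodified(None, freqs, sizes=dict(zip(labels, sizes)))
    recommendation = "remove_orphans" if fp.exceeds_threshold else "keep_all"
    return QcReport(
        labels=labels,
        sizes=list(sizes) if sizes is not None else [0] * freqs.k,
        frequencies=freqs,
        fpcm=fp,
        fncm=fn,
        recommendation=recommendation,
        ranking=rank_callers(fn) if fn is not None else [],
    )
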