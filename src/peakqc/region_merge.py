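"""Merging TFBRs across a meta-set and counting pivotal frequencies.

A *merged TFBR* is a connected component of the overlap graph over all
intervals pooled across the k datasets: two intervals are connected iff
they share at least ``min_overlap_bp`` base pairs on the same chromosome
(single linkage). Under the half-open convention, bookended intervals
(one ends exactly where the next starts) do not merge.

The *composition* of a merged region counts the number of DISTINCT source
datasets represented in it, not the number of member peaks, so composition
always lies in 1..k and the pivotal frequency vector f_1..f_k is well
defined. Two peaks from the same dataset inside one merged region count
once. A region of composition 1 is an *orphan*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peak_io import GenomicInterval, MetaSet, PeakDataset


@dataclass
class MergedRegion:
    """One connected component of overlapping intervals.

    ``members[d]`` lists the intervals contributed by dataset index ``d``;
    datasets contributing nothing are absent from the mapping.
    """

    interval: GenomicInterval
    members: dict[int, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def composition(self) -> int:
        """Number of distinct source datasets represented (1..k)."""
        return len(self.members)

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class PivotalFrequencies:
    """The counts f_1..f_k of merged regions by composition, plus n = sum f_i.

    ``f[i-1]`` is the number of merged regions composed of intervals from
    exactly i distinct datasets; f_1 counts the orphans.
    """

    f: list[int]
    n: int

    def __post_init__(self):
        if any(x < 0 for x in self.f):
            raise ValueError("pivotal frequencies must be non-negative")
        if sum(self.f) != self.n:
            raise ValueError(
                f"sum of frequencies {sum(self.f)} != n = {self.n}"
            )

    @property
    def k(self) -> int:
        return len(self.f)

    @property
    def f1(self) -> int:
        return self.f[0]

    @property
    def f2(self) -> int:
        return self.f[1] if self.k >= 2 else 0

    @property
    def f3(self) -> int:
        return self.f[2] if self.k >= 3 else 0

    @property
    def total_captures(self) -> int:
        """Sum of i * f_i — total dataset-memberships over merged regions."""
        return sum((i + 1) * fi for i, fi in enumerate(self.f))

    @property
    def mean_count(self) -> float:
        """Mean composition of a merged region (sample mean of the
        zero-truncated capture counts)."""
        return self.total_captures / self.n


def merge_meta_set(meta: MetaSet,
                   min_overlap_bp: int = 1) -> list[MergedRegion]:
    """Merge all intervals of a meta-set into merged regions.

    Pools every interval from every dataset, sorts by (chrom, start), and
    sweeps: an interval joins the current component when it overlaps the
    component span by at least ``min_overlap_bp`` bases. For interval
    graphs this sweep yields exactly the single-linkage connected
    components. Empty datasets contribute nothing; an empty meta-set
    yields an empty list. Regions are returned in genomic order.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pooled: list[tuple[str, int, int, int, GenomicInterval]] = []
    for d_idx, dataset in enumerate(meta.datasets):
        for iv in dataset.intervals:
            pooled.append((iv.chrom, iv.start, iv.end, d_idx, iv))
    pooled.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    regions: list[MergedRegion] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_members: dict[int, list[GenomicInterval]] = {}

    def flush():
        if cur_chrom is not None:
            regions.append(MergedRegion(
                interval=GenomicInterval(cur_chrom, cur_start, cur_end),
                members=cur_members,
            ))

    for chrom, start, end, d_idx, iv in pooled:
        # overlap of [start, end) with the running span [cur_start, cur_end)
        if (chrom == cur_chrom
                and min(end, cur_end) - start >= min_overlap_bp):
            cur_end = max(cur_end, end)
            cur_members.setdefault(d_idx, []).append(iv)
        else:
            flush()
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_members = {d_idx: [iv]}
    flush()
    return regions


def pivotal_frequencies(regions: list[MergedRegion],
                        k: int) -> PivotalFrequencies:
    """Count f_i = number of merged regions with composition exactly i."""
    f = [0] * k
    for region in regions:
        c = region.composition
        if not 1 <= c <= k:
            raise RuntimeError(
                f"merged region composition {c} outside 1..{k}"
            )
        f[c - 1] += 1
    return PivotalFrequencies(f=f, n=len(regions))


def orphan_regions(regions: list[MergedRegion]) -> list[MergedRegion]:
    """The merged regions supported by exactly one dataset (composition 1).

    Their count equals f_1 by definition.
    """
    return [r for r in regions if r.composition == 1]


def pairwise_intersection(meta: MetaSet, i: int, j: int,
                          min_overlap_bp: int = 1) -> int:
    """Symmetric recapture count |D_i ∩ D_j| for the Chapman estimator.

    Defined as the number of merged regions of the PAIR-ONLY merge of D_i
    and D_j supported by both datasets (composition 2). Symmetric in
    (i, j) by construction, unlike a raw "peaks of D_i overlapping D_j"
    count.
    """
    if i == j:
        raise ValueError("pairwise_intersection requires i != j")
    k = meta.k
    if not (0 <= i < k and 0 <= j < k):
        raise IndexError(f"dataset index out of range for k={k}: ({i}, {j})")
    pair = MetaSet([
        PeakDataset("a", meta.datasets[i].intervals),
        PeakDataset("b", meta.datasets[j].intervals),
    ])
    regions = merge_meta_set(pair, min_overlap_bp=min_overlap_bp)
    return sum(1 for r in regions if r.composition == 2)


def frequencies_table(freqs: PivotalFrequencies):
    """Pivotal frequencies as a small pandas DataFrame (for CLI output)."""
    import pandas as pd

    return pd.DataFrame({
        "composition": np.arange(1, freqs.k + 1),
        "count": freqs.f,
    })
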