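"""Shared fixtures and the brute-force merging oracle.

The oracle builds the full O(m^2) overlap graph over all pooled intervals
and takes its connected components with a union-find — independent of the
sweep-line implementation it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from peakqc.peak_io import GenomicInterval, MetaSet, PeakDataset


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def brute_force_components(meta: MetaSet) -> list[dict]:
    """All-pairs union-find merge; returns per-component summaries."""
    pooled = [
        (iv, d_idx)
        for d_idx, ds in enumerate(meta.datasets)
        for iv in ds.intervals
    ]
    uf = UnionFind(len(pooled))
    for a in range(len(pooled)):
        for b in range(a + 1, len(pooled)):
            if pooled[a][0].overlaps(pooled[b][0]):
                uf.union(a, b)
    comps: dict[int, list[int]] = {}
    for idx in range(len(pooled)):
        comps.setdefault(uf.find(idx), []).append(idx)
    out = []
    for members in comps.values():
        ivs = [pooled[m][0] for m in members]
        datasets = {pooled[m][1] for m in members}
        out.append({
            "chrom": ivs[0].chrom,
            "start": min(iv.start for iv in ivs),
            "end": max(iv.end for iv in ivs),
            "composition": len(datasets),
            "n_members": len(members),
            "datasets": datasets,
        })
    return out


def brute_force_frequencies(meta: MetaSet) -> list[int]:
    comps = brute_force_components(meta)
    f = [0] * meta.k
    for c in comps:
        f[c["composition"] - 1] += 1
    return f


def random_meta_set(rng: np.random.Generator, k: int = 3,
                    n_per_dataset: int = 30,
                    genome: int = 3000,
                    n_chroms: int = 2) -> MetaSet:
    """Small dense random meta-set; plenty of overlap at these settings."""
    datasets = []
    for d in range(k):
        ivs = []
        for _ in range(n_per_dataset):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            start = int(rng.integers(0, genome - 60))
            width = int(rng.integers(10, 60))
            ivs.append(GenomicInterval(chrom, start, start + width))
        datasets.append(PeakDataset(f"D{d + 1}", ivs))
    return MetaSet(datasets)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def simple_meta():
    """Three datasets: one shared region, one pair region, one orphan."""
    return MetaSet([
        PeakDataset("A", [GenomicInterval("chr1", 100, 200),
                          GenomicInterval("chr1", 1000, 1100)]),
        PeakDataset("B", [GenomicInterval("chr1", 150, 250),
                          GenomicInterval("chr1", 1050, 1150)]),
        PeakDataset("C", [GenomicInterval("chr1", 180, 260),
                          GenomicInterval("chr2", 500, 600)]),
    ])
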