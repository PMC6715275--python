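"""Reading peak datasets (BED) and serializing QC reports.

A transcription-factor binding region (TFBR) is a plain genomic interval:
strand, score and any further BED columns are ignored. Coordinates follow
the standard BED convention — 0-based, half-open ``[start, end)`` — and all
interval arithmetic in this package uses that convention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import BedParseError

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair.

        Bookended intervals (end == other.start) do NOT overlap under the
        half-open convention.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_bed_line(self) -> str:
        return f"{self.chrom}\t{self.start}\t{self.end}"


@dataclass
class PeakDataset:
    """One peak caller's (or one experiment's) TFBRs, with a label."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.intervals)

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


@dataclass
class MetaSet:
    """The ordered collection D = {D_1, ..., D_k} of peak datasets for one
    experiment (one dataset per peak caller) or one TF (one per experiment).
    """

    datasets: list[PeakDataset]

    def __post_init__(self):
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"dataset labels must be unique, got {labels}")
        self._warn_disjoint_chromosomes()

    def _warn_disjoint_chromosomes(self) -> None:
        # Mismatched chromosome naming ("chr1" vs "1") silently kills every
        # overlap; emit a warning when two non-empty datasets share nothing.
        named = [
            (d.label, d.chromosomes()) for d in self.datasets if d.size > 0
        ]
        for i in range(len(named)):
            for j in range(i + 1, len(named)):
                if not (named[i][1] & named[j][1]):
                    warnings.warn(
                        f"datasets {named[i][0]!r} and {named[j][0]!r} share "
                        "no chromosome names; check naming conventions",
                        stacklevel=3,
                    )

    @property
    def k(self) -> int:
        return len(self.datasets)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.datasets]

    @property
    def sizes(self) -> list[int]:
        return [d.size for d in self.datasets]

    def __len__(self) -> int:
        return self.k

    def __iter__(self) -> Iterator[PeakDataset]:
        return iter(self.datasets)


def read_bed(path: str | Path, label: str | None = None) -> PeakDataset:
    """Read a 3+ column BED file into a :class:`PeakDataset`.

    ``track``, ``browser`` and ``#`` comment lines and blank lines are
    skipped; columns beyond the third are ignored. A record with
    ``end <= start`` or a malformed coordinate raises
    :class:`~peakqc.errors.BedParseError` naming the line number.
    An empty file yields an empty dataset with a warning.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    intervals: list[GenomicInterval] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            stripped = line.strip()
            if not stripped or stripped.lower().startswith(_SKIP_PREFIXES):
                n_skipped += 1
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                # tolerate space-separated files
                fields = stripped.split()
            if len(fields) < 3:
                raise BedParseError(
                    path, lineno, f"expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    path, lineno, f"non-integer coordinates: {exc}"
                ) from None
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc)) from None
    if not intervals:
        warnings.warn(f"BED file {path} contains no records", stacklevel=2)
    logger.debug(
        "read %d intervals (%d lines skipped) from %s",
        len(intervals), n_skipped, path,
    )
    return PeakDataset(label=label, intervals=intervals)


def write_bed(dataset: PeakDataset | Iterable[GenomicInterval],
              path: str | Path) -> None:
    """Write intervals as a 3-column BED file (atomically: temp + rename)."""
    path = Path(path)
    intervals = dataset.intervals if isinstance(dataset, PeakDataset) else dataset
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        for iv in intervals:
            fh.write(iv.to_bed_line() + "\n")
    tmp.replace(path)


def read_meta_set(paths: Sequence[str | Path],
                  labels: Sequence[str] | None = None) -> MetaSet:
    """Read several BED files into one :class:`MetaSet`."""
    if labels is None:
        labels = [Path(p).stem for p in paths]
    if len(labels) != len(paths):
        raise ValueError("number of labels must match number of paths")
    return MetaSet([read_bed(p, lbl) for p, lbl in zip(paths, labels)])


def report_to_dict(report) -> dict:
    """Flatten a QcReport into plain JSON-serializable types."""
    return report.to_dict()


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`~peakqc.qc_metrics.QcReport` to JSON or TSV.

    JSON is a faithful round-trippable dump of every field, including the
    raw frequencies and all intermediate estimator values so published
    numbers can be audited. TSV is one row per dataset (label, size, fncm)
    with the meta-set-level numbers in ``#``-prefixed header lines.
    """
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    d = report.to_dict()
    if format == "json":
        with open(tmp, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        fncm_block = d.get("fncm") or {}
        header = {
            "k": d["k"],
            "n": d["frequencies"]["n"],
            "f": ",".join(str(x) for x in d["frequencies"]["f"]),
            "fpcm": d["fpcm"]["fpcm"],
            "p_false": d["fpcm"]["p_false"],
            "branch": fncm_block.get("branch", "NA"),
            "n_estimate": fncm_block.get("n_estimate", "NA"),
            "recommendation": d["recommendation"],
        }
        with open(tmp, "w") as fh:
            for key, val in header.items():
                fh.write(f"# {key}\t{val}\n")
            fh.write("label\tsize\tfncm\n")
            fncm = fncm_block.get("per_dataset", {})
            sizes = dict(zip(d["labels"], d["sizes"]))
            for label in d["labels"]:
                fh.write(f"{label}\t{sizes[label]}\t{fncm.get(label, 'NA')}\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")
    tmp.replace(path)


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
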