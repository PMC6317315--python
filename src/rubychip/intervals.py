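"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)`` on a named
chromosome, the convention of BED and bedGraph.  Overlap everywhere in
this package means sharing at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on ``chrom``, optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def clamped(self, chrom_length: int) -> "GenomicInterval":
        return replace(
            self,
            start=max(0, self.start),
            end=min(chrom_length, max(0, self.end)),
        )


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Transitively merge intervals.

    With ``gap=0`` only overlapping or book-ended intervals merge; with
    ``gap=g`` pairs separated by *strictly fewer* than ``g`` bases merge
    as well (a gap of exactly ``g`` keeps them apart).
    """
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if (
            out
            and out[-1].chrom == iv.chrom
            and (iv.start <= out[-1].end or iv.start - out[-1].end < gap)
        ):
            prev = out.pop()
            out.append(GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)))
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_sorted(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersections of two per-chromosome-sorted, internally
    non-overlapping interval lists (linear sweep)."""
    by_chrom: dict[str, tuple[list[GenomicInterval], list[GenomicInterval]]] = {}
    for iv in a:
        by_chrom.setdefault(iv.chrom, ([], []))[0].append(iv)
    for iv in b:
        by_chrom.setdefault(iv.chrom, ([], []))[1].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        xs, ys = by_chrom[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            inter = xs[i].intersection(ys[j])
            if inter is not None:
                out.append(inter)
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


@dataclass(frozen=True)
class AnnotatedGene:
    """Gene interval with biotype and strand-aware TSS.

    TSS is ``interval.start`` on the plus strand and ``interval.end - 1``
    on the minus strand.
    """

    interval: GenomicInterval
    biotype: str
    name: str = ""
    attributes: dict = field(default_factory=dict, compare=False)

    BIOTYPES = (
        "snRNA",
        "snoRNA",
        "tRNA",
        "miRNA",
        "lincRNA",
        "ncRNA",
        "protein_coding",
        "piRNA_typeI",
        "piRNA_typeII",
    )

    def __post_init__(self) -> None:
        if self.biotype not in self.BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("genes require an explicit strand")

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1
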