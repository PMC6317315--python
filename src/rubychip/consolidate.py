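"""Replicate consolidation into sharp uniform peaks.

Raw peak calls are reduced to summit-centered 300-bp regions, the two
replicates are intersected, each non-empty intersection is re-centered
on its midpoint at the final width, and regions overlapping blacklist
or low-mappability territory are discarded.  The result is a uniform
peak set suitable for quantitative overlap analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, intersect_sorted, merge_intervals
from .peaks import BlacklistRegion, PeakCall
from .tracks import CoverageTrack


@dataclass(frozen=True)
class ConsolidatedPeak:
    """Fixed-width (default 300 bp) replicate-supported peak region."""

    interval: GenomicInterval
    center: int
    source_ids: tuple = ()


@dataclass
class FilterReport:
    """Drop accounting from :func:`filter_regions`."""

    n_input: int = 0
    n_blacklisted: int = 0
    n_low_mappability: int = 0
    n_kept: int = 0


def extend_summits(
    peaks: list[PeakCall],
    flank: int = 150,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Summit s -> [s - flank, s + flank), clamped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for pk in peaks:
        length = None if chrom_lengths is None else chrom_lengths[pk.interval.chrom]
        if pk.summit < 0 or (length is not None and pk.summit >= length):
            raise ValueError(f"summit {pk.summit} outside chromosome {pk.interval.chrom}")
        start = max(0, pk.summit - flank)
        end = pk.summit + flank if flank > 0 else pk.summit + 1
        if length is not None:
            end = min(end, length)
        out.append(GenomicInterval(pk.interval.chrom, start, end))
    return out


def intersect_replicates(
    rep_a: list[GenomicInterval],
    rep_b: list[GenomicInterval],
    final_width: int = 300,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ConsolidatedPeak]:
    """Intersect two replicate region sets; re-center at final width.

    Each non-empty pairwise intersection yields a region of
    ``final_width`` centered on the intersection midpoint (rounded
    down), clamped at chromosome edges; duplicates are collapsed and
    output is coordinate-sorted.  Symmetric in its two arguments.
    """
    a = merge_intervals(rep_a)
    b = merge_intervals(rep_b)
    seen = set()
    out: list[ConsolidatedPeak] = []
    half = final_width // 2
    for inter in intersect_sorted(a, b):
        mid = (inter.start + inter.end) // 2
        start = max(0, mid - half)
        end = mid + (final_width - half)
        length = None if chrom_lengths is None else chrom_lengths[inter.chrom]
        if length is not None:
            end = min(end, length)
        key = (inter.chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            ConsolidatedPeak(GenomicInterval(inter.chrom, start, end), center=mid)
        )
    return sorted(out, key=lambda p: (p.interval.chrom, p.interval.start))


def filter_regions(
    regions: list[ConsolidatedPeak],
    blacklist: list[BlacklistRegion] | None = None,
    mappability: CoverageTrack | None = None,
    map_min: float = 0.25,
    criterion: str = "mean",
) -> tuple[list[ConsolidatedPeak], FilterReport]:
    """Drop regions touching the blacklist or with poor mappability.

    A single shared base with any blacklist region is disqualifying.
    The mappability rule applies ``criterion`` ("mean", the default, or
    "min") over the region and drops it when below ``map_min``.
    """
    if criterion not in ("mean", "min"):
        raise ValueError("criterion must be 'mean' or 'min'")
    report = FilterReport(n_input=len(regions))
    black = [b.interval for b in blacklist] if blacklist else []
    kept: list[ConsolidatedPeak] = []
    for region in regions:
        iv = region.interval
        if any(iv.overlaps(b) for b in black):
            report.n_blacklisted += 1
            continue
        if mappability is not None:
            vals = mappability.bin_slice(iv.chrom, iv.start, iv.end)
            stat = np.nanmean(vals) if criterion == "mean" else np.nanmin(vals)
            if stat < map_min:
                report.n_low_mappability += 1
                continue
        kept.append(region)
    report.n_kept = len(kept)
    return kept, report
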