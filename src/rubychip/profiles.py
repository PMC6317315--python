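"""Anchor-centered metaprofiles and binned cluster-vs-genome signal.

Profiles are anchored on single-bp positions (piRNA first-U bases or
Ruby motif starts), binned over a symmetric flank, and strand-flipped so
upstream is always on the left.  Cluster-vs-genome quantification tiles
piRNA clusters and whole somatic chromosomes into fixed bins (default
1 kb), summarizes each group as a notched Tukey box (notch half-width
1.58*IQR/sqrt(n)), and reports a two-sided Mann-Whitney test of the
cluster bins against each somatic chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .tracks import CoverageTrack


@dataclass
class ProfileMatrix:
    """anchors x position-bins matrix of signal around anchors."""

    values: np.ndarray  # shape (n_anchors, 2*flank/bin); NaN = missing
    anchors: list[tuple[str, int, str]]
    flank: int
    bin_size: int

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin center offsets relative to the anchor (upstream < 0)."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0


@dataclass
class GroupSummary:
    """Tukey box summary of one bin group."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float


@dataclass
class BinQuant:
    """Per-bin values and summaries for cluster-vs-chromosome groups."""

    bins: pd.DataFrame  # columns: group, chrom, start, end, value
    summaries: dict[str, GroupSummary]
    tests: pd.DataFrame  # cluster vs each somatic group: U, p
    bin_size: int


def anchored_profile(
    track: CoverageTrack,
    anchors: list[tuple[str, int, str]],
    flank: int = 500,
    bin_size: int = 10,
) -> ProfileMatrix:
    """Signal matrix around single-bp anchors.

    One row per (chrom, position, strand) anchor; each cell is the mean
    of unmasked track positions in that bin.  Rows of minus-strand
    anchors are reversed so upstream is on the left; bins beyond the
    chromosome edge, and all-masked bins, are NaN.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    if track.resolution != 1:
        raise ValueError("anchored profiles require 1-bp track resolution")
    n_bins = 2 * flank // bin_size
    mat = np.full((len(anchors), n_bins), np.nan)
    for row, (chrom, pos, strand) in enumerate(anchors):
        vec = track.data[chrom]
        lo, hi = pos - flank, pos + flank
        window = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(0, lo), min(len(vec), hi)
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
        w = window.reshape(n_bins, bin_size)
        finite = np.isfinite(w)
        cnt = finite.sum(axis=1)
        binned = np.where(
            cnt > 0,
            np.where(finite, w, 0.0).sum(axis=1) / np.maximum(cnt, 1),
            np.nan,
        )
        if strand == "-":
            binned = binned[::-1]
        mat[row] = binned
    return ProfileMatrix(mat, list(anchors), flank, bin_size)


def aggregate_profile(matrix: ProfileMatrix, trim: float = 0.0) -> pd.DataFrame:
    """Column-wise mean curve over anchors, ignoring missing cells.

    Returns a table with bin center offsets, mean (optionally trimmed),
    per-column n and standard error; all-missing columns stay NaN.
    """
    if matrix.values.size == 0:
        return pd.DataFrame(columns=["offset", "mean", "n", "se"])
    vals = matrix.values
    finite = np.isfinite(vals)
    n = finite.sum(axis=0)
    filled = np.where(finite, vals, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    if trim > 0:
        mean = np.array(
            [
                stats.trim_mean(col[np.isfinite(col)], trim)
                if np.isfinite(col).any()
                else np.nan
                for col in vals.T
            ]
        )
    # sample SD over finite cells per column
    sq = np.where(finite, (vals - np.where(np.isfinite(mean), mean, 0.0)) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.where(n > 1, np.sqrt(sq.sum(axis=0) / np.maximum(n - 1, 1)), np.nan)
        se = sd / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame(
        {"offset": matrix.bin_centers, "mean": mean, "n": n, "se": se}
    )


def _tukey_summary(values: np.ndarray) -> GroupSummary:
    values = values[np.isfinite(values)]
    n = len(values)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    notch = 1.58 * iqr / np.sqrt(n)
    return GroupSummary(
        n=n,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()) if len(inside) else float(med),
        whisker_hi=float(inside.max()) if len(inside) else float(med),
        notch_lo=float(med - notch),
        notch_hi=float(med + notch),
    )


def _tile(region: GenomicInterval, bin_size: int):
    starts = np.arange(region.start, region.end, bin_size)
    ends = np.minimum(starts + bin_size, region.end)
    return starts, ends


def quantify_bins(
    track: CoverageTrack,
    cluster_regions: list[GenomicInterval],
    somatic_chromosomes: list[str] = ("chrI", "chrII", "chrIII", "chrV"),
    bin_size: int = 1000,
) -> BinQuant:
    """Binned signal: piRNA clusters vs whole somatic chromosomes.

    Each group's territory is tiled into ``bin_size`` bins; the value of
    a bin is the mean of its unmasked positions.  The cluster group is
    compared against every somatic chromosome with a two-sided
    Mann-Whitney U test on bin values, complementing the notch overlap
    readout.
    """
    res = track.resolution
    rows = []

    def add_group(group: str, regions: list[GenomicInterval]) -> None:
        for region in regions:
            starts, ends = _tile(region, bin_size)
            for s, e in zip(starts, ends):
                vals = track.bin_slice(region.chrom, int(s), int(e))
                finite = np.isfinite(vals)
                value = float(np.mean(vals[finite])) if finite.any() else np.nan
                rows.append(
                    {
                        "group": group,
                        "chrom": region.chrom,
                        "start": int(s),
                        "end": int(e),
                        "value": value,
                    }
                )

    add_group("piRNA_cluster", cluster_regions)
    for chrom in somatic_chromosomes:
        length = track.chrom_length(chrom) * res
        add_group(chrom, [GenomicInterval(chrom, 0, length)])

    bins = pd.DataFrame(rows, columns=["group", "chrom", "start", "end", "value"])
    summaries: dict[str, GroupSummary] = {}
    for group, sub in bins.groupby("group"):
        vals = sub["value"].to_numpy()
        if np.isfinite(vals).any():
            summaries[group] = _tukey_summary(vals)
        else:
            import warnings

            warnings.warn(f"group {group!r} has no unmasked bins", stacklevel=2)

    cluster_vals = bins.loc[
        bins["group"] == "piRNA_cluster", "value"
    ].dropna().to_numpy()
    test_rows = []
    for chrom in somatic_chromosomes:
        other = bins.loc[bins["group"] == chrom, "value"].dropna().to_numpy()
        if len(cluster_vals) and len(other):
            u, p = stats.mannwhitneyu(cluster_vals, other, alternative="two-sided")
        else:
            u, p = np.nan, np.nan
        test_rows.append({"somatic_group": chrom, "U": u, "p": p})
    tests = pd.DataFrame(test_rows, columns=["somatic_group", "U", "p"])
    return BinQuant(bins=bins, summaries=summaries, tests=tests, bin_size=bin_size)
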