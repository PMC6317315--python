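"""Local-lambda Poisson peak calling and input-blacklist construction.

A deliberately small stand-in for a full model-based caller: fixed-width
sliding windows are scored against the most conservative of several
Poisson background rates (genome-wide, depth-scaled local control, and —
when run without a control, as for blacklist construction — local ChIP
background over 5-kb and 10-kb flanks), with Benjamini-Hochberg q-values
and transitive merging of significant windows.  Scores follow the
narrowPeak column-5 convention, -10*log10(q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals, sort_intervals
from .tracks import CoverageTrack, SummedInput

P_FLOOR = 1e-300


@dataclass(frozen=True)
class PeakCall:
    """A called peak: interval, summit, -10*log10(q) score, p and q."""

    interval: GenomicInterval
    summit: int
    score: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit must lie inside the peak interval")
        if not (0.0 < self.p_value <= 1.0 and 0.0 < self.q_value <= 1.0):
            raise ValueError("p and q must be in (0, 1]")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass(frozen=True)
class BlacklistRegion:
    """High-artifact-signal region assembled from input-library peaks."""

    interval: GenomicInterval
    provenance: str = "input-derived"
    n_peaks: int = 1

    def __post_init__(self) -> None:
        if self.provenance not in ("input-derived", "user-supplied"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.n_peaks < 1:
            raise ValueError("a blacklist region needs >= 1 contributing peak")


def _window_stats(
    chip: CoverageTrack,
    control: SummedInput | None,
    fragment_len: int,
    step: int,
    flank_sizes: tuple[int, ...],
):
    """Per-window read counts and Poisson lambdas across all chromosomes.

    Window read count = coverage mass in the window / fragment_len (each
    fragment contributes fragment_len bases of coverage).
    """
    chip_mass = chip.total_mass()
    genome_len = sum(len(v) for v in chip.data.values()) * chip.resolution
    genome_rate = chip_mass / genome_len  # mean per-base coverage
    ctrl_scale = None
    if control is not None:
        ctrl_mass = control.track.total_mass()
        if ctrl_mass > 0:
            ctrl_scale = chip_mass / ctrl_mass

    rows = []  # (chrom, win_start_bp, count, lam)
    res = chip.resolution
    w_bins = max(1, fragment_len // res)
    step_bins = max(1, step // res)
    for chrom in chip.chromosomes:
        vec = np.nan_to_num(chip.data[chrom])
        n_bins = len(vec)
        if n_bins < w_bins:
            continue
        csum = np.r_[0.0, np.cumsum(vec)]
        starts = np.arange(0, n_bins - w_bins + 1, step_bins)
        # reads in a window = coverage mass / fragment_len; with window
        # width == fragment_len the expected reads equal the mean
        # per-base coverage of the window's source region
        counts = (csum[starts + w_bins] - csum[starts]) * res / fragment_len
        lam = np.full(len(starts), genome_rate)
        if control is not None and ctrl_scale is not None:
            cvec = np.nan_to_num(control.track.data[chrom])
            ccsum = np.r_[0.0, np.cumsum(cvec)]
            local = (ccsum[starts + w_bins] - ccsum[starts]) * res / fragment_len
            lam = np.maximum(lam, local * ctrl_scale)
        else:
            # no-input mode: local ChIP background over large flanks
            for flank in flank_sizes:
                f_bins = max(w_bins, flank // res)
                lo = np.maximum(0, starts + w_bins // 2 - f_bins // 2)
                hi = np.minimum(n_bins, starts + w_bins // 2 + f_bins // 2)
                rate = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
                lam = np.maximum(lam, rate)
        rows.append((chrom, starts * res, counts, lam))
    return rows


def call_peaks(
    chip: CoverageTrack,
    control: SummedInput | None = None,
    q_cutoff: float = 0.05,
    fragment_len: int = 150,
    step: int | None = None,
    flank_sizes: tuple[int, ...] = (5_000, 10_000),
) -> list[PeakCall]:
    """Call enriched peaks on a raw-count coverage track.

    Windows of ``fragment_len`` bp (stepped by ``fragment_len // 2``)
    are tested against a Poisson upper tail with a local lambda; windows
    with BH q <= ``q_cutoff`` are merged when overlapping or adjacent.
    Summit = leftmost position of maximum coverage in the merged region;
    score and p/q of a peak come from its best window.
    """
    if not (0.0 < q_cutoff < 1.0):
        raise ValueError("q_cutoff must be in (0, 1)")
    if fragment_len <= 0:
        raise ValueError("fragment_len must be positive")
    if chip.total_mass() <= 0:
        return []
    step = step if step is not None else max(1, fragment_len // 2)

    rows = _window_stats(chip, control, fragment_len, step, flank_sizes)
    if not rows:
        return []
    all_counts = np.concatenate([r[2] for r in rows])
    all_lam = np.concatenate([r[3] for r in rows])
    # Poisson upper tail P(X >= k) on integerized counts
    k = np.ceil(all_counts - 1e-9)
    pvals = np.clip(stats.poisson.sf(k - 1, np.maximum(all_lam, 1e-12)), P_FLOOR, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    qvals = np.clip(qvals, P_FLOOR, 1.0)

    peaks: list[PeakCall] = []
    offset = 0
    for chrom, starts_bp, counts, _ in rows:
        n = len(starts_bp)
        q = qvals[offset : offset + n]
        p = pvals[offset : offset + n]
        offset += n
        sig = q <= q_cutoff
        if not sig.any():
            continue
        # merge significant windows into regions, track best window stats
        vec = np.nan_to_num(chip.data[chrom])
        res = chip.resolution
        idxs = np.nonzero(sig)[0]
        region_start = region_end = None
        best_p = best_q = 1.0
        def flush():
            nonlocal region_start, region_end, best_p, best_q
            if region_start is None:
                return
            lo, hi = region_start // res, -(-region_end // res)
            local = vec[lo:hi]
            summit = (lo + int(np.argmax(local))) * res
            peaks.append(
                PeakCall(
                    GenomicInterval(chrom, region_start, region_end),
                    summit=summit,
                    score=-10.0 * np.log10(best_q),
                    p_value=best_p,
                    q_value=best_q,
                )
            )
            region_start = region_end = None
            best_p = best_q = 1.0
        for i in idxs:
            s, e = int(starts_bp[i]), int(starts_bp[i]) + fragment_len
            if region_start is not None and s <= region_end:
                region_end = max(region_end, e)
            else:
                flush()
                region_start, region_end = s, e
            best_p = min(best_p, p[i])
            best_q = min(best_q, q[i])
        flush()
    return sorted(peaks, key=lambda pk: (pk.interval.chrom, pk.interval.start))


def build_blacklist(
    inputs: list[CoverageTrack],
    score_min: float = 100.0,
    cluster_within: int = 500,
    fragment_len: int = 150,
    q_cutoff: float = 0.05,
    extra_regions: list[GenomicInterval] | None = None,
) -> list[BlacklistRegion]:
    """Assemble an in-house blacklist from input-library pile-ups.

    Each input track is peak-called in no-control mode; peaks with score
    below ``score_min`` are discarded and surviving peaks closer than
    ``cluster_within`` bp (strict) are merged into single regions.  A
    user-supplied external blacklist can be unioned in via
    ``extra_regions``.  Returns sorted, disjoint regions.
    """
    kept: list[GenomicInterval] = []
    for track in inputs:
        for pk in call_peaks(track, control=None, q_cutoff=q_cutoff, fragment_len=fragment_len):
            if pk.score >= score_min:
                kept.append(pk.interval)
    merged = merge_intervals(kept, gap=cluster_within)
    out = [
        BlacklistRegion(
            region,
            provenance="input-derived",
            n_peaks=sum(1 for iv in kept if iv.overlaps(region)),
        )
        for region in merged
    ]
    if extra_regions:
        user = [
            BlacklistRegion(iv, provenance="user-supplied", n_peaks=1)
            for iv in merge_intervals(extra_regions, gap=cluster_within)
        ]
        combined = merge_intervals(
            [r.interval for r in out + user], gap=cluster_within
        )
        all_regions = out + user
        out = [
            BlacklistRegion(
                region,
                provenance=(
                    "input-derived"
                    if any(
                        r.provenance == "input-derived"
                        and r.interval.overlaps(region)
                        for r in all_regions
                    )
                    else "user-supplied"
                ),
                n_peaks=sum(
                    r.n_peaks for r in all_regions if r.interval.overlaps(region)
                ),
            )
            for region in combined
        ]
    return out
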