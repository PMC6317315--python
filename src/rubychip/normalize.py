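"""Bias-corrected, log2-scaled coverage normalization.

The contract mirrors the bias-elimination step used for ChIP-seq
browser tracks: ChIP and pooled-input coverage are library-size scaled
to equal genome-wide mass, the input is kernel-smoothed, the ratio is
log2-transformed, and positions of low mappability are masked.  The
published algorithm's read-level GC and mappability weighting is
deliberately replaced by this documented simplification; an optional
GC-stratified median correction is available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np

from .tracks import CoverageTrack, SummedInput

logger = logging.getLogger(__name__)

MAPPABILITY_MASK_THRESHOLD = 0.25  # GEM mappability < 25% is non-mappable


def sum_inputs(inputs: list[CoverageTrack]) -> SummedInput:
    """Position-wise sum of input libraries (pooled control).

    All tracks must share chromosome names, vector lengths and
    resolution.
    """
    if not inputs:
        raise ValueError("need at least one input track")
    first = inputs[0]
    total = first.copy()
    for other in inputs[1:]:
        if not first.compatible_with(other):
            raise ValueError("input tracks differ in chromosomes or resolution")
        for chrom in total.data:
            total.data[chrom] += other.data[chrom]
    return SummedInput(track=total, n_inputs=len(inputs))


def _smooth(vec: np.ndarray, bw_bins: int) -> np.ndarray:
    """Flat-kernel moving average, NaN-aware, edge-renormalized."""
    if bw_bins <= 1:
        return vec.copy()
    kernel = np.ones(bw_bins)
    finite = np.isfinite(vec)
    num = np.convolve(np.where(finite, vec, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _gc_median_correction(
    ratio: np.ndarray, gc: np.ndarray, n_strata: int = 10
) -> np.ndarray:
    """Divide linear ratios by their GC-stratum median (optional step)."""
    out = ratio.copy()
    strata = np.clip((gc * n_strata).astype(int), 0, n_strata - 1)
    for s in range(n_strata):
        sel = (strata == s) & np.isfinite(ratio)
        if sel.sum() >= 10:
            med = np.median(ratio[sel])
            if med > 0:
                out[sel] = ratio[sel] / med
    return out


def normalize(
    chip: CoverageTrack,
    control: SummedInput,
    mappability: CoverageTrack | None = None,
    smoothing_bw: int = 500,
    pseudocount: float = 1.0,
    mask_below: float = MAPPABILITY_MASK_THRESHOLD,
    gc_track: CoverageTrack | None = None,
) -> CoverageTrack:
    """log2 ChIP/input ratio track.

    Both tracks are scaled to the same genome-wide mass (so absolute
    library size cancels), the input is smoothed with a flat kernel of
    ``smoothing_bw`` bp, and the output is
    ``log2((chip + pc) / (input_smoothed + pc))``.  Positions whose
    mappability falls below ``mask_below`` are NaN.  Positions where the
    smoothed input is zero (and the pseudocount is zero) are set missing
    and counted in a log message.
    """
    inp = control.track
    if not chip.compatible_with(inp):
        raise ValueError("chip and input tracks differ in chromosomes or resolution")
    if mappability is not None and not chip.compatible_with(mappability):
        raise ValueError("mappability track incompatible with coverage tracks")
    if smoothing_bw < chip.resolution:
        raise ValueError("smoothing bandwidth must be >= track resolution")

    chip_mass = chip.total_mass()
    input_mass = inp.total_mass()
    if chip_mass <= 0 or input_mass <= 0:
        raise ValueError("cannot normalize an all-zero track")
    # scale both to the mean of the two masses; any c>0 rescaling of
    # either library cancels here
    target = 0.5 * (chip_mass + input_mass)
    chip_scale = target / chip_mass
    input_scale = target / input_mass

    bw_bins = max(1, int(round(smoothing_bw / chip.resolution)))
    out: dict[str, np.ndarray] = {}
    n_zero = 0
    for chrom in chip.chromosomes:
        c = chip.data[chrom] * chip_scale
        i = _smooth(inp.data[chrom], bw_bins) * input_scale
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (c + pseudocount) / (i + pseudocount)
            if gc_track is not None:
                ratio = _gc_median_correction(ratio, gc_track.data[chrom])
            vals = np.log2(ratio)
        bad = ~np.isfinite(vals)
        n_zero += int(np.sum(bad & np.isfinite(c)))
        vals[bad] = np.nan
        if mappability is not None:
            vals[mappability.data[chrom] < mask_below] = np.nan
        out[chrom] = vals
    if n_zero:
        logger.info("normalize: %d positions with empty smoothed input set missing", n_zero)
    return CoverageTrack(out, scale="log2", resolution=chip.resolution)
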