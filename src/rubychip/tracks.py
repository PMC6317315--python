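"""Per-base (or fixed-bin) coverage containers.

A :class:`CoverageTrack` holds one numeric vector per chromosome at a
fixed resolution with an explicit scale tag; masked positions carry NaN,
never 0, so missingness survives arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

SCALES = ("raw_counts", "linear_ratio", "log2", "fraction")


@dataclass
class CoverageTrack:
    """chromosome -> numeric vector at fixed ``resolution`` (bp)."""

    data: dict[str, np.ndarray]
    scale: str = "raw_counts"
    resolution: int = 1

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; use one of {SCALES}")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1 bp")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        if self.scale == "raw_counts":
            for chrom, vec in self.data.items():
                if np.nanmin(vec, initial=0.0) < 0:
                    raise ValueError(f"negative raw counts on {chrom}")

    @classmethod
    def zeros(
        cls,
        chrom_lengths: dict[str, int],
        scale: str = "raw_counts",
        resolution: int = 1,
    ) -> "CoverageTrack":
        data = {
            c: np.zeros(ceil(L / resolution), dtype=float)
            for c, L in chrom_lengths.items()
        }
        return cls(data, scale=scale, resolution=resolution)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    def chrom_length(self, chrom: str) -> int:
        """Length in bins (vector length), not bp."""
        return len(self.data[chrom])

    def compatible_with(self, other: "CoverageTrack") -> bool:
        return (
            self.resolution == other.resolution
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )

    def total_mass(self) -> float:
        return float(sum(np.nansum(v) for v in self.data.values()))

    def bin_slice(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Vector slice covering genomic ``[start_bp, end_bp)``, clamped."""
        lo = max(0, start_bp // self.resolution)
        hi = min(len(self.data[chrom]), ceil(end_bp / self.resolution))
        return self.data[chrom][lo:hi]

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            scale=self.scale,
            resolution=self.resolution,
        )


@dataclass
class SummedInput:
    """Position-wise sum of input (control) coverage tracks."""

    track: CoverageTrack
    n_inputs: int = 1

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("a summed input needs >= 1 constituent")
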