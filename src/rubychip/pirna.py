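"""Ruby/YRNT motif scanning and piRNA type handling.

Type I piRNA genes carry the 8-nt Ruby motif CTGTTTCA on the coding
strand upstream of the first-U base; type II genes lack it.  Anchors
throughout are the single genomic base of the mature piRNA's 5' U.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

from .synthetic import RUBY_MOTIF, revcomp

# IUPAC nucleotide classes; genome Ns never match (no class contains N)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

Anchor = tuple[str, int, str]  # (chrom, first-U position, strand)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``word`` is in motif sense (reverse
    complement of the genomic substring for minus-strand hits)."""

    chrom: str
    start: int
    strand: str
    word: str


@dataclass(frozen=True)
class PirnaGene:
    """Single-bp first-U anchor with type and cluster membership."""

    chrom: str
    first_u: int
    strand: str
    pirna_type: str  # "I" or "II"
    in_cluster: bool = False

    def __post_init__(self) -> None:
        if self.pirna_type not in ("I", "II"):
            raise ValueError("pirna_type must be 'I' or 'II'")

    @property
    def anchor(self) -> Anchor:
        return (self.chrom, self.first_u, self.strand)


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(_IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in motif") from None
    return re.compile(f"(?=({body}))")  # lookahead: overlapping hits too


def scan_motif(
    sequence: str,
    motif: str = RUBY_MOTIF,
    chrom: str = "chr",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All occurrences of an IUPAC motif in a sequence.

    Minus-strand hits are found by scanning for the motif's reverse
    complement on the given (plus) sequence and reported at the genomic
    start of the matching substring with strand "-".  Overlapping hits
    are all reported; matching is case-insensitive.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    hits = [
        MotifHit(chrom, m.start(), "+", m.group(1))
        for m in _iupac_regex(motif).finditer(seq)
    ]
    if both_strands:
        rc_pattern = _iupac_regex(revcomp(motif.upper().replace("U", "T")))
        hits += [
            MotifHit(chrom, m.start(), "-", revcomp(m.group(1)))
            for m in rc_pattern.finditer(seq)
        ]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def classify_pirna_types(
    all_pirnas: list[Anchor],
    type2_list: list[Anchor],
    cluster_regions=None,
) -> list[PirnaGene]:
    """Split a full piRNA anchor set into type I / type II.

    Type II membership is exact anchor+strand identity with
    ``type2_list``; type I is the set difference (the filtering
    convention for building type I lists from a full annotation).
    Anchors in the type II list missing from the full set trigger a
    warning with their count.
    """
    full = list(dict.fromkeys(all_pirnas))
    type2 = set(type2_list)
    orphans = type2 - set(full)
    if orphans:
        warnings.warn(
            f"{len(orphans)} type II anchors absent from the full piRNA list",
            stacklevel=2,
        )

    def in_cluster(anchor: Anchor) -> bool:
        if not cluster_regions:
            return False
        chrom, pos, _ = anchor
        return any(
            r.chrom == chrom and r.start <= pos < r.end for r in cluster_regions
        )

    return [
        PirnaGene(
            chrom,
            pos,
            strand,
            "II" if (chrom, pos, strand) in type2 else "I",
            in_cluster=in_cluster((chrom, pos, strand)),
        )
        for chrom, pos, strand in full
    ]


def validate_ruby_upstream(
    pirnas: list[PirnaGene],
    sequences: dict[str, str],
    search_window: int = 500,
) -> pd.DataFrame:
    """Distance from each piRNA first-U to its nearest upstream
    coding-strand Ruby motif within ``search_window`` bp.

    Distance is the gap in bp between the motif 3' end and the first-U
    base (a planted spacer of 40 reports 40); NaN where no hit exists in
    the window.  Returns one row per piRNA plus the summary is easily
    derived (fraction of finite distances).
    """
    m = len(RUBY_MOTIF)
    rows = []
    for gene in pirnas:
        seq = sequences[gene.chrom]
        distance = float("nan")
        if gene.strand == "+":
            lo = max(0, gene.first_u - search_window)
            window = seq[lo : gene.first_u]
            idx = window.rfind(RUBY_MOTIF)  # nearest upstream = rightmost
            if idx >= 0:
                distance = gene.first_u - (lo + idx + m)
        else:
            hi = min(len(seq), gene.first_u + 1 + search_window)
            window = seq[gene.first_u + 1 : hi]
            idx = window.find(revcomp(RUBY_MOTIF))  # nearest = leftmost
            if idx >= 0:
                distance = idx  # gap between first-U and motif 3' end
        rows.append(
            {
                "chrom": gene.chrom,
                "first_u": gene.first_u,
                "strand": gene.strand,
                "pirna_type": gene.pirna_type,
                "ruby_distance": distance,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "first_u", "strand", "pirna_type", "ruby_distance"]
    )
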