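"""Exclusive peak classification and hypergeometric overrepresentation.

Peaks are assigned to exactly one annotation class by a fixed priority
order (snRNA, snoRNA, tRNA, miRNA, lincRNA, ncRNA, promoter, gene body;
piRNA classes, when supplied, take precedence over snRNA).  Class
overrepresentation is tested with the hypergeometric upper tail over a
locus universe consisting of all annotated loci plus a fixed-width
tiling of the unannotated genome into pseudo-loci — the universe choice
materially changes p-values and is therefore explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consolidate import ConsolidatedPeak
from .intervals import AnnotatedGene, GenomicInterval, merge_intervals

DEFAULT_PRIORITY = (
    "snRNA",
    "snoRNA",
    "tRNA",
    "miRNA",
    "lincRNA",
    "ncRNA",
    "promoter",
    "gene_body",
)
PIRNA_PRIORITY = ("piRNA_typeI", "piRNA_typeII")
UNASSIGNED = "unassigned"


def build_promoters(
    genes: list[AnnotatedGene],
    upstream: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Promoter = ``upstream`` bp 5' of the TSS, strand-aware, clamped.

    A plus-strand gene [g0, g1) gets [g0 - upstream, g0); a minus-strand
    gene gets [g1, g1 + upstream).
    """
    out = []
    for gene in genes:
        iv = gene.interval
        if iv.strand == "+":
            prom = GenomicInterval(iv.chrom, max(0, iv.start - upstream), iv.start, "+")
        else:
            end = iv.end + upstream
            if chrom_lengths is not None:
                end = min(end, chrom_lengths[iv.chrom])
            prom = GenomicInterval(iv.chrom, iv.end, end, "-")
        out.append(prom)
    return out


@dataclass
class AnnotationUniverse:
    """Class -> loci mapping used for classification and for the
    hypergeometric universe.

    The universe is size-aware: a locus contributes
    ``max(1, round(len / tile_width))`` tiles to its class count K and
    to the universe size N (plus the pseudo-loci tiling of unannotated
    space).  Compact ncRNA loci therefore count one each, while a long
    gene body counts in proportion to the territory a randomly placed
    peak could hit — without this, size-heterogeneous classes are
    anti-conservative under a permutation control.
    """

    class_loci: dict[str, list[GenomicInterval]]
    priority: tuple[str, ...]
    pseudo_loci: int = 0
    tile_width: int = 300

    @property
    def n_loci(self) -> int:
        return (
            sum(self.loci_count(c) for c in self.class_loci) + self.pseudo_loci
        )

    def loci_count(self, cls: str) -> int:
        return sum(
            max(1, round(len(iv) / self.tile_width))
            for iv in self.class_loci.get(cls, [])
        )


def build_universe(
    genes: list[AnnotatedGene],
    chrom_lengths: dict[str, int],
    promoter_upstream: int = 500,
    pseudo_locus_width: int = 300,
    include_pirna: bool = True,
) -> AnnotationUniverse:
    """Assemble the exclusive-classification universe from gene models.

    Gene bodies feed their own biotype class (snRNA, ..., protein-coding
    bodies become "gene_body"); promoters of protein-coding genes form
    the "promoter" class.  Unannotated space is tiled into
    ``pseudo_locus_width`` pseudo-loci that enter the universe size only.
    """
    class_loci: dict[str, list[GenomicInterval]] = {}

    def add(cls: str, iv: GenomicInterval) -> None:
        class_loci.setdefault(cls, []).append(iv)

    for gene in genes:
        bt = gene.biotype
        if bt in ("piRNA_typeI", "piRNA_typeII"):
            if include_pirna:
                add(bt, gene.interval)
        elif bt == "protein_coding":
            add("gene_body", gene.interval)
        else:
            add(bt, gene.interval)
    for prom in build_promoters(
        [g for g in genes if g.biotype == "protein_coding"],
        upstream=promoter_upstream,
        chrom_lengths=chrom_lengths,
    ):
        add("promoter", prom)

    priority = (
        PIRNA_PRIORITY + DEFAULT_PRIORITY if include_pirna else DEFAULT_PRIORITY
    )
    tile_width = pseudo_locus_width
    # pseudo-loci: tile the genome not covered by any annotated locus
    annotated = merge_intervals(
        [iv for lst in class_loci.values() for iv in lst]
    )
    pseudo = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in annotated:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in chrom_lengths.items():
        pos = 0
        for iv in by_chrom.get(chrom, []) + [GenomicInterval(chrom, length, length)]:
            gap = iv.start - pos
            if gap > 0:
                pseudo += gap // pseudo_locus_width
            pos = max(pos, iv.end)
    return AnnotationUniverse(
        class_loci, priority, pseudo_loci=pseudo, tile_width=tile_width
    )


def classify_peaks(
    peaks: list[ConsolidatedPeak],
    universe: AnnotationUniverse,
    priority: tuple[str, ...] | None = None,
    exclude_regions: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Assign each peak to the highest-priority class it overlaps.

    Overlap means >= 1 shared base; a peak overlapping nothing is
    "unassigned".  ``exclude_regions`` (e.g. piRNA cluster spans) drops
    peaks before classification, reproducing outside-the-cluster
    analyses.  Returns a table with one row per retained peak.
    """
    priority = tuple(priority) if priority is not None else universe.priority
    unknown = [c for c in priority if c not in universe.class_loci and c not in
               PIRNA_PRIORITY + DEFAULT_PRIORITY]
    if unknown:
        raise ValueError(f"unknown classes in priority: {unknown}")

    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls, loci in universe.class_loci.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv in loci:
            if len(iv) > 0:
                per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        trees[cls] = per_chrom

    excl: dict[str, IntervalTree] = {}
    for iv in exclude_regions or []:
        excl.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    rows = []
    for i, peak in enumerate(peaks):
        iv = peak.interval
        if iv.chrom in excl and excl[iv.chrom].overlap(iv.start, iv.end):
            continue
        assigned = UNASSIGNED
        for cls in priority:
            per_chrom = trees.get(cls, {})
            if iv.chrom in per_chrom and per_chrom[iv.chrom].overlap(iv.start, iv.end):
                assigned = cls
                break
        rows.append(
            {
                "peak_id": i,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "assigned_class": assigned,
            }
        )
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "assigned_class"]
    )


def circular_shift_peaks(
    peaks: list[ConsolidatedPeak],
    chrom_lengths: dict[str, int],
    offset: int,
) -> list[ConsolidatedPeak]:
    """Shift every peak by ``offset`` bp along its chromosome, wrapping
    at the end — the permutation control for enrichment p-values (real
    annotation structure, randomized peak placement)."""
    out = []
    for peak in peaks:
        iv = peak.interval
        length = chrom_lengths[iv.chrom]
        width = len(iv)
        span = max(1, length - width)
        start = (iv.start + offset) % span
        out.append(
            ConsolidatedPeak(
                GenomicInterval(iv.chrom, start, start + width, iv.strand),
                center=start + width // 2,
            )
        )
    return out


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K marked,
    n drawn) — the probability of at least ``k`` class overlaps among
    ``n`` peaks when ``K`` of ``N`` loci belong to the class.  Evaluated
    through the survival function's log form for stability in deep
    tails.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K <= N and n <= N (K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


@dataclass
class EnrichmentMatrix:
    """Factor x class overlap counts with hypergeometric significance."""

    table: pd.DataFrame  # columns: factor, class, k, K, n, N, p, neg_log10_p, q

    def counts(self) -> pd.DataFrame:
        return self.table.pivot(index="factor", columns="class", values="k")

    def neg_log10_p(self) -> pd.DataFrame:
        return self.table.pivot(index="factor", columns="class", values="neg_log10_p")


def enrichment_matrix(
    assignments: dict[str, pd.DataFrame],
    universe: AnnotationUniverse,
    classes: tuple[str, ...] | None = None,
) -> EnrichmentMatrix:
    """Hypergeometric overrepresentation per factor x class.

    ``assignments`` maps factor name -> classify_peaks table.  For each
    factor, n = retained peaks, k = peaks assigned to the class,
    K = annotated loci of the class, N = all loci in the universe
    (annotated + pseudo-loci).  Raw p is reported as -log10 p alongside
    a BH-adjusted q over the whole grid.
    """
    classes = tuple(classes) if classes is not None else tuple(
        c for c in universe.priority if universe.loci_count(c) > 0
    )
    N = universe.n_loci
    rows = []
    for factor, table in assignments.items():
        n = len(table)
        counts = table["assigned_class"].value_counts()
        for cls in classes:
            K = universe.loci_count(cls)
            k = int(counts.get(cls, 0))
            p = 1.0 if n == 0 else hypergeom_overrep(min(k, min(n, K)), K, n, N)
            rows.append(
                {
                    "factor": factor,
                    "class": cls,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                    "neg_log10_p": -np.log10(max(p, 1e-300)),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        _, q, _, _ = multipletests(table["p"], method="fdr_bh")
        table["q"] = q
    return EnrichmentMatrix(table)
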