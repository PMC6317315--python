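"""Synthetic genome, annotation and ChIP/input coverage generator.

Emulates the signal structure of a piRNA-promoter ChIP-seq study in
*C. elegans*: type I piRNA genes sit inside two broad clusters on a
single chromosome-IV-like chromosome and carry the 8-nt Ruby motif
(CTGTTTCA) upstream of the first-U base plus a degenerate YRNT word
whose T is the first U; type II piRNA genes live on other chromosomes
with YRNT only.  Factors are simulated as fold-enrichments over a
negative-binomial background at class-specific promoter anchors, with
two replicates per factor and a pooled input; decoy artifact regions are
jointly inflated in ChIP and input to exercise blacklisting, and
low-mappability decoys exercise masking.

Coverage is represented per-base (piecewise constant over simulation
windows) rather than as reads; a fragment-interval BED writer is
provided for interval-based consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import AnnotatedGene, GenomicInterval
from .tracks import CoverageTrack

RUBY_MOTIF = "CTGTTTCA"
RUBY_RC = "TGAAACAG"
PIRNA_LEN = 21

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# footprint lengths used when planting non-piRNA genes
_BIOTYPE_LENGTHS = {
    "snRNA": 150,
    "snoRNA": 100,
    "tRNA": 72,
    "miRNA": 60,
    "lincRNA": 800,
    "ncRNA": 300,
    "protein_coding": 2000,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic genome.

    ``cluster_regions`` must all lie on ``cluster_chrom`` (the
    chromosome-IV analogue); type I piRNA genes are planted inside them,
    type II piRNAs and all other biotypes outside that chromosome.
    ``motif_to_tss_spacer`` is the gap in bp between the Ruby motif 3'
    end and the piRNA first-U base on the coding strand.
    """

    chromosomes: list[tuple[str, int]]
    cluster_chrom: str
    cluster_regions: list[GenomicInterval]
    n_typeI: int = 40
    n_typeII: int = 12
    biotype_counts: dict[str, int] = field(
        default_factory=lambda: {
            "snRNA": 10,
            "snoRNA": 8,
            "tRNA": 6,
            "miRNA": 6,
            "lincRNA": 4,
            "protein_coding": 20,
        }
    )
    motif_to_tss_spacer: int = 40
    seed: int = 0
    low_mappability_regions: list[GenomicInterval] = field(default_factory=list)
    artifact_regions: list[GenomicInterval] = field(default_factory=list)
    artifact_fold: float = 50.0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if self.cluster_chrom not in lengths:
            raise ValueError(f"cluster chromosome {self.cluster_chrom!r} not declared")
        for region in self.cluster_regions:
            if region.chrom != self.cluster_chrom:
                raise ValueError("cluster regions must lie on the cluster chromosome")
            if region.end > lengths[region.chrom]:
                raise ValueError(f"cluster region {region} exceeds chromosome bounds")
        for iv in self.low_mappability_regions + self.artifact_regions:
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise ValueError(f"region {iv} outside declared chromosomes")
        for biotype in self.biotype_counts:
            if biotype not in _BIOTYPE_LENGTHS:
                raise ValueError(f"unsupported biotype {biotype!r}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class FactorProfile:
    """Enrichment structure of one simulated ChIP factor.

    Folds are multiplicative enrichments over background coverage in a
    +/- ``fragment_len`` window around the class anchor (Ruby motif for
    type I, TSS otherwise).  ``depth`` is the mean background coverage;
    ``dispersion`` is the negative-binomial alpha (var = m + alpha m^2).
    """

    name: str
    fold_typeI: float = 1.0
    fold_typeII: float = 1.0
    fold_snRNA: float = 1.0
    n_replicates: int = 2
    depth: float = 30.0
    dispersion: float = 0.1
    fragment_len: int = 150

    def __post_init__(self) -> None:
        for fold in (self.fold_typeI, self.fold_typeII, self.fold_snRNA):
            if fold < 1.0:
                raise ValueError("enrichment folds must be >= 1")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SyntheticGenome:
    """make_genome output bundle: sequence, genes, mappability."""

    sequences: dict[str, str]
    genes: list[AnnotatedGene]
    mappability: CoverageTrack
    spec: GenomeSpec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def pirna_genes(self, pirna_type: str | None = None) -> list[AnnotatedGene]:
        wanted = (
            ("piRNA_typeI", "piRNA_typeII")
            if pirna_type is None
            else (f"piRNA_type{pirna_type}",)
        )
        return [g for g in self.genes if g.biotype in wanted]

    def first_u_anchors(self, pirna_type: str = "I") -> list[tuple[str, int, str]]:
        """(chrom, first-U position, strand) per piRNA gene of a type."""
        return [
            (g.interval.chrom, int(g.attributes["first_u"]), g.interval.strand)
            for g in self.pirna_genes(pirna_type)
        ]

    def ruby_positions(self) -> list[tuple[str, int, str]]:
        """(chrom, motif start, strand) of each planted Ruby motif."""
        out = []
        for g in self.pirna_genes("I"):
            u = int(g.attributes["first_u"])
            spacer = self.spec.motif_to_tss_spacer
            if g.interval.strand == "+":
                out.append((g.interval.chrom, u - spacer - len(RUBY_MOTIF), "+"))
            else:
                out.append((g.interval.chrom, u + spacer + 1, "-"))
        return out


def _plant(seq: list[str], start: int, word: str, gene_name: str, length: int) -> None:
    if start < 0 or start + len(word) > length:
        raise ValueError(f"planted element for {gene_name} exceeds chromosome bounds")
    seq[start : start + len(word)] = list(word)


class _Placer:
    """Rejection-samples non-colliding placements inside allowed spans."""

    def __init__(self, rng: np.random.Generator, max_tries: int = 200) -> None:
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {}
        self.max_tries = max_tries

    def _collides(self, chrom: str, start: int, end: int) -> bool:
        return any(
            start < e and s < end for s, e in self.occupied.get(chrom, [])
        )

    def reserve(self, chrom: str, start: int, end: int, name: str) -> None:
        if self._collides(chrom, start, end):
            raise ValueError(f"planted element for {name} collides with another")
        self.occupied.setdefault(chrom, []).append((start, end))

    def place(
        self, spans: list[GenomicInterval], footprint: int, name: str
    ) -> tuple[str, int]:
        """Return (chrom, start) of a free footprint inside one of ``spans``."""
        weights = np.array([max(len(s) - footprint, 0) for s in spans], dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"no span large enough for {name}")
        for _ in range(self.max_tries):
            idx = self.rng.choice(len(spans), p=weights / weights.sum())
            span = spans[idx]
            start = int(self.rng.integers(span.start, span.end - footprint))
            if not self._collides(span.chrom, start, start + footprint):
                self.reserve(span.chrom, start, start + footprint, name)
                return span.chrom, start
        raise ValueError(f"could not place {name} without collision")


def make_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate sequence, annotated genes and mappability from a spec.

    Deterministic in ``spec.seed``: identical specs give byte-identical
    FASTA/GFF3 output.  Type I piRNA genes carry CTGTTTCA on the coding
    strand ending ``motif_to_tss_spacer`` bp upstream of the first-U
    base and a YRNT word whose T is the first U; type II genes carry
    YRNT only.  Minus-strand genes plant reverse complements on the
    reference.  Mappability is 1.0 except in declared decoy regions
    (0.1).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = spec.chrom_lengths
    seqs = {
        chrom: list(rng.choice(list("ACGT"), size=length))
        for chrom, length in lengths.items()
    }
    placer = _Placer(rng)
    genes: list[AnnotatedGene] = []
    spacer = spec.motif_to_tss_spacer
    m = len(RUBY_MOTIF)

    somatic_spans = [
        GenomicInterval(chrom, 0, length)
        for chrom, length in spec.chromosomes
        if chrom != spec.cluster_chrom
    ]

    def plant_pirna(
        i: int,
        pirna_type: str,
        spans: list[GenomicInterval],
        fixed: tuple[str, int] | None = None,
    ) -> None:
        name = f"piRNA_type{pirna_type}_{i:03d}"
        with_ruby = pirna_type == "I"
        # footprint covers motif..gene on either strand plus a 10-bp margin
        upstream = (spacer + m if with_ruby else 4) + 10
        footprint = upstream + PIRNA_LEN + 10
        if fixed is not None:
            chrom, start = fixed
            placer.reserve(chrom, start, start + footprint, name)
        else:
            chrom, start = placer.place(spans, footprint, name)
        strand = "+" if rng.random() < 0.5 else "-"
        seq, L = seqs[chrom], lengths[chrom]
        y = "CT"[rng.integers(2)]
        r = "AG"[rng.integers(2)]
        n = "ACGT"[rng.integers(4)]
        yrnt = y + r + n + "T"
        if strand == "+":
            u = start + upstream
            if with_ruby:
                _plant(seq, u - spacer - m, RUBY_MOTIF, name, L)
            _plant(seq, u - 3, yrnt, name, L)
            interval = GenomicInterval(chrom, u, u + PIRNA_LEN, "+")
        else:
            u = start + footprint - upstream - 1
            if with_ruby:
                _plant(seq, u + spacer + 1, RUBY_RC, name, L)
            _plant(seq, u, revcomp(yrnt), name, L)
            interval = GenomicInterval(chrom, u - PIRNA_LEN + 1, u + 1, "-")
        genes.append(
            AnnotatedGene(
                interval,
                biotype=f"piRNA_type{pirna_type}",
                name=name,
                attributes={"first_u": u},
            )
        )

    # Type I genes are planted on a jittered regular grid across the
    # cluster territory, emulating the dense, fairly even piRNA spacing
    # of the natural clusters; the grid also keeps neighbouring promoter
    # signals resolvable.  Slots are apportioned to regions by length.
    cluster_spans = list(spec.cluster_regions)
    total_cluster = sum(len(r) for r in cluster_spans)
    if spec.n_typeI > 0 and total_cluster == 0:
        raise ValueError("type I piRNAs requested but no cluster territory")
    slots: list[tuple[str, int, int]] = []  # (chrom, slot_start, slot_width)
    remaining = spec.n_typeI
    for j, region in enumerate(cluster_spans):
        n_r = (
            remaining
            if j == len(cluster_spans) - 1
            else round(spec.n_typeI * len(region) / total_cluster)
        )
        n_r = min(n_r, remaining)
        remaining -= n_r
        if n_r == 0:
            continue
        width = len(region) // n_r
        for s in range(n_r):
            slots.append((region.chrom, region.start + s * width, width))
    upstream_I = spacer + m + 10
    footprint_I = upstream_I + PIRNA_LEN + 10
    for i, (chrom, slot_start, width) in enumerate(slots):
        margin = width - footprint_I
        if margin < 0:
            raise ValueError(
                f"cluster slot too narrow for piRNA_typeI_{i:03d}; "
                "enlarge cluster regions or reduce n_typeI"
            )
        jitter = int(rng.integers(0, min(margin, 50) + 1))
        plant_pirna(i, "I", cluster_spans, fixed=(chrom, slot_start + jitter))
    for i in range(spec.n_typeII):
        plant_pirna(i, "II", somatic_spans)

    for biotype in sorted(spec.biotype_counts):
        length = _BIOTYPE_LENGTHS[biotype]
        for i in range(spec.biotype_counts[biotype]):
            name = f"{biotype}_{i:03d}"
            chrom, start = placer.place(somatic_spans, length + 20, name)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                AnnotatedGene(
                    GenomicInterval(chrom, start + 10, start + 10 + length, strand),
                    biotype=biotype,
                    name=name,
                )
            )

    mappability = CoverageTrack.zeros(lengths, scale="fraction")
    for vec in mappability.data.values():
        vec[:] = 1.0
    for iv in spec.low_mappability_regions:
        mappability.data[iv.chrom][iv.start : iv.end] = 0.1

    sequences = {c: "".join(s) for c, s in seqs.items()}
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.name))
    return SyntheticGenome(sequences, genes, mappability, spec)


def _fold_mask(
    genome: SyntheticGenome, profile: FactorProfile
) -> dict[str, np.ndarray]:
    """Per-base multiplicative enrichment per chromosome for one factor.

    Enrichment follows fragment pile-up around a bound element: the full
    fold over the element core (Ruby motif through first-U for type I
    promoters, the TSS base otherwise) with linear tapers to 1 over one
    fragment length on each side.  Overlapping elements take the
    position-wise maximum.
    """
    folds = {c: np.ones(L) for c, L in genome.chrom_lengths.items()}
    # taper over 1.5 fragment lengths: sonicated fragments are a size
    # distribution, so pile-up spreads beyond the nominal fragment size
    taper = int(1.5 * profile.fragment_len)

    def boost(chrom: str, core_lo: int, core_hi: int, fold: float) -> None:
        # core [core_lo, core_hi) at full fold; linear taper outside
        if fold <= 1.0:
            return
        vec = folds[chrom]
        lo = max(0, core_lo - taper)
        hi = min(len(vec), core_hi + taper)
        pos = np.arange(lo, hi)
        dist = np.maximum(0, np.maximum(core_lo - pos, pos - (core_hi - 1)))
        shape = 1.0 + (fold - 1.0) * np.maximum(0.0, 1.0 - dist / taper)
        np.maximum(vec[lo:hi], shape, out=vec[lo:hi])

    spacer = genome.spec.motif_to_tss_spacer
    m = len(RUBY_MOTIF)
    for chrom, u, strand in genome.first_u_anchors("I"):
        if strand == "+":
            boost(chrom, u - spacer - m, u + 1, profile.fold_typeI)
        else:
            boost(chrom, u, u + spacer + m + 1, profile.fold_typeI)
    for chrom, u, strand in genome.first_u_anchors("II"):
        boost(chrom, u, u + 1, profile.fold_typeII)
    for gene in genome.genes:
        if gene.biotype in ("snRNA", "snoRNA"):
            boost(gene.interval.chrom, gene.tss, gene.tss + 1, profile.fold_snRNA)
    return folds


def _background(
    rng: np.random.Generator,
    lengths: dict[str, int],
    depth: float,
    dispersion: float,
    window: int,
) -> dict[str, np.ndarray]:
    """Piecewise-constant NB(mean=depth, var=m+alpha m^2) coverage."""
    out = {}
    for chrom in sorted(lengths):
        L = lengths[chrom]
        n_win = -(-L // window)
        if dispersion > 0:
            size = 1.0 / dispersion
            p = size / (size + depth)
            draws = rng.negative_binomial(size, p, n_win).astype(float)
        else:
            draws = rng.poisson(depth, n_win).astype(float)
        out[chrom] = np.repeat(draws, window)[:L]
    return out


def simulate_coverage(
    genome: SyntheticGenome,
    profile: FactorProfile,
    replicate_seed: int,
    window: int = 50,
) -> tuple[list[CoverageTrack], CoverageTrack]:
    """Simulate ChIP replicates and one matched input for a factor.

    Returns ``([chip_rep_1, ... chip_rep_k], input_track)``.  Replicates
    differ only by sub-seed.  The input has fold 1 everywhere; declared
    artifact regions are jointly inflated in both ChIP and input by
    ``spec.artifact_fold`` to emulate pile-up artifacts.
    """
    lengths = genome.chrom_lengths
    folds = _fold_mask(genome, profile)
    spec = genome.spec

    def apply_artifacts(cov: dict[str, np.ndarray]) -> None:
        for iv in spec.artifact_regions:
            cov[iv.chrom][iv.start : iv.end] *= spec.artifact_fold

    chip_reps = []
    for rep in range(profile.n_replicates):
        rng = np.random.default_rng([replicate_seed, rep])
        cov = _background(rng, lengths, profile.depth, profile.dispersion, window)
        for chrom in cov:
            cov[chrom] *= folds[chrom]
        apply_artifacts(cov)
        chip_reps.append(CoverageTrack(cov, scale="raw_counts"))

    rng = np.random.default_rng([replicate_seed, 10007])
    cov = _background(rng, lengths, profile.depth, profile.dispersion, window)
    apply_artifacts(cov)
    input_track = CoverageTrack(cov, scale="raw_counts")
    return chip_reps, input_track


def coverage_to_fragments_bed(
    track: CoverageTrack,
    path,
    fragment_len: int = 150,
    seed: int = 0,
) -> int:
    """Write BED intervals whose pile-up approximates ``track``.

    Samples ``total_mass / fragment_len`` fragment start positions per
    chromosome with probability proportional to local coverage; for
    consumers that want interval input rather than bedGraph.  Returns
    the number of fragments written.
    """
    rng = np.random.default_rng(seed)
    n_total = 0
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            vec = np.nan_to_num(track.data[chrom])
            mass = vec.sum()
            if mass <= 0:
                continue
            n_frag = int(round(mass / fragment_len))
            starts = rng.choice(len(vec), size=n_frag, p=vec / mass)
            for s in np.sort(starts):
                end = min(len(vec), s + fragment_len)
                fh.write(f"{chrom}\t{s}\t{end}\tfrag\t0\t+\n")
                n_total += 1
    return n_total


def demo_genome_spec(seed: int = 0) -> GenomeSpec:
    """The bundled study layout: a 200-kb cluster chromosome carrying two
    piRNA clusters plus four 100-kb somatic chromosomes, 40 type I and 12
    type II piRNA genes, snRNA/snoRNA/tRNA/miRNA/lincRNA/protein-coding
    genes, one low-mappability decoy and two input artifact regions."""
    return GenomeSpec(
        chromosomes=[
            ("chrIV", 200_000),
            ("chrI", 100_000),
            ("chrII", 100_000),
            ("chrIII", 100_000),
            ("chrV", 100_000),
        ],
        cluster_chrom="chrIV",
        cluster_regions=[
            GenomicInterval("chrIV", 30_000, 44_000),
            GenomicInterval("chrIV", 120_000, 134_000),
        ],
        low_mappability_regions=[GenomicInterval("chrI", 70_000, 72_000)],
        artifact_regions=[
            GenomicInterval("chrII", 40_000, 40_400),
            GenomicInterval("chrV", 60_000, 60_300),
        ],
        seed=seed,
    )


def demo_factor_profiles() -> list[FactorProfile]:
    """Four-factor study contrast: one piRNA-exclusive factor, one with
    reduced type II binding, and two additionally enriched at snRNA and
    snoRNA genes."""
    return [
        FactorProfile("PRDE-1-like", fold_typeI=8.0),
        FactorProfile("TOFU-4-like", fold_typeI=8.0, fold_typeII=1.5),
        FactorProfile("SNPC-4-like", fold_typeI=8.0, fold_typeII=6.0, fold_snRNA=8.0),
        FactorProfile("TOFU-5-like", fold_typeI=8.0, fold_typeII=6.0, fold_snRNA=8.0),
    ]
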