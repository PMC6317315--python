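"""Promoter construction, exclusive classification, hypergeometric test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from rubychip.annotate import (
    AnnotationUniverse,
    build_promoters,
    build_universe,
    circular_shift_peaks,
    classify_peaks,
    enrichment_matrix,
    hypergeom_overrep,
)
from rubychip.consolidate import ConsolidatedPeak
from rubychip.intervals import AnnotatedGene, GenomicInterval


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Independent oracle: exact P(X >= k) by summing the support."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


def gene(start, end, strand="+", biotype="snRNA", chrom="c"):
    return AnnotatedGene(GenomicInterval(chrom, start, end, strand), biotype)


def peak(start, end, chrom="c"):
    return ConsolidatedPeak(GenomicInterval(chrom, start, end), center=(start + end) // 2)


class TestBuildPromoters:
    def test_plus_strand(self):
        (prom,) = build_promoters([gene(1_000, 1_500, "+")])
        assert (prom.start, prom.end) == (500, 1_000)

    def test_minus_strand_mirror(self):
        (prom,) = build_promoters([gene(1_000, 1_500, "-")])
        assert (prom.start, prom.end) == (1_500, 2_000)

    def test_clamped_at_zero(self):
        (prom,) = build_promoters([gene(200, 800, "+")])
        assert (prom.start, prom.end) == (0, 200)

    def test_clamped_at_chromosome_end(self):
        (prom,) = build_promoters(
            [gene(200, 800, "-")], chrom_lengths={"c": 1_000}
        )
        assert (prom.start, prom.end) == (800, 1_000)


class TestClassifyPeaks:
    def universe(self):
        return AnnotationUniverse(
            class_loci={
                "snRNA": [GenomicInterval("c", 1_000, 1_150)],
                "promoter": [GenomicInterval("c", 900, 1_400)],
                "tRNA": [GenomicInterval("c", 5_000, 5_072)],
            },
            priority=("snRNA", "snoRNA", "tRNA", "miRNA", "lincRNA", "ncRNA",
                      "promoter", "gene_body"),
        )

    def test_priority_snRNA_over_promoter(self):
        table = classify_peaks([peak(1_050, 1_350)], self.universe())
        assert table["assigned_class"].tolist() == ["snRNA"]

    def test_unassigned_when_no_overlap(self):
        table = classify_peaks([peak(8_000, 8_300)], self.universe())
        assert table["assigned_class"].tolist() == ["unassigned"]

    def test_peaks_counted_not_genes(self):
        """Two peaks over one tRNA gene both count: k = 2."""
        table = classify_peaks(
            [peak(4_900, 5_010), peak(5_050, 5_200)], self.universe()
        )
        assert table["assigned_class"].tolist() == ["tRNA", "tRNA"]

    def test_unknown_priority_class_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_peaks([peak(0, 10)], self.universe(), priority=("enhancer",))

    def test_exclude_regions_drop_peaks_first(self):
        table = classify_peaks(
            [peak(1_050, 1_350), peak(8_000, 8_300)],
            self.universe(),
            exclude_regions=[GenomicInterval("c", 1_000, 2_000)],
        )
        assert len(table) == 1
        assert table["assigned_class"].tolist() == ["unassigned"]

    def test_priority_monotonicity(self):
        """Moving a class earlier never decreases its count."""
        peaks = [peak(1_050, 1_350), peak(950, 1_010), peak(1_200, 1_390)]
        uni = self.universe()
        base = classify_peaks(peaks, uni)
        promoted = classify_peaks(
            peaks, uni,
            priority=("promoter", "snRNA", "snoRNA", "tRNA", "miRNA", "lincRNA",
                      "ncRNA", "gene_body"),
        )
        n_base = (base["assigned_class"] == "promoter").sum()
        n_promoted = (promoted["assigned_class"] == "promoter").sum()
        assert n_promoted >= n_base

    def test_exclusivity(self, demo_result):
        for name, bundle in demo_result.factors.items():
            table = bundle["classified"]
            assert len(table) == len(table["peak_id"].unique())


class TestHypergeomOverrep:
    def test_k_zero_is_one(self):
        assert hypergeom_overrep(0, 5, 4, 10) == 1.0

    def test_exact_small_case(self):
        """N=10, K=5, n=4, k=4 -> C(5,4)/C(10,4) = 5/210."""
        expected = float(exact_upper_tail(4, 5, 4, 10))
        assert expected == pytest.approx(5 / 210)
        assert hypergeom_overrep(4, 5, 4, 10) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_product(self):
        """N=1000, K=10, n=10, k=10 -> prod (10-i)/(1000-i)."""
        expected = 1.0
        for i in range(10):
            expected *= (10 - i) / (1000 - i)
        assert hypergeom_overrep(10, 10, 10, 1000) == pytest.approx(
            expected, rel=1e-10
        )

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_overrep(5, 4, 4, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeom_overrep(1, 4, 11, 10)  # n > N


class TestEnrichmentMatrix:
    def universe(self):
        return AnnotationUniverse(
            class_loci={
                "snRNA": [GenomicInterval("c", i * 1_000, i * 1_000 + 150) for i in range(5)],
            },
            priority=("snRNA",),
            pseudo_loci=95,
        )

    def test_forced_full_overlap_p_one(self):
        """All N loci in one class: any draw gives k = n, p = 1."""
        uni = AnnotationUniverse(
            class_loci={"snRNA": [GenomicInterval("c", i, i + 1) for i in range(4)]},
            priority=("snRNA",),
            pseudo_loci=0,
        )
        peaks = [peak(0, 1), peak(1, 2), peak(2, 3), peak(3, 4)]
        table = enrichment_matrix(
            {"f": classify_peaks(peaks, uni)}, uni
        ).table
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_factor_row_is_null(self):
        uni = self.universe()
        table = enrichment_matrix({"empty": classify_peaks([], uni)}, uni).table
        assert (table["k"] == 0).all()
        assert (table["p"] == 1.0).all()

    def test_enriched_factor_smaller_p(self):
        uni = self.universe()
        hits = [peak(i * 1_000 + 50, i * 1_000 + 120) for i in range(5)]
        misses = [peak(50_000 + i * 1_000, 50_300 + i * 1_000) for i in range(5)]
        mat = enrichment_matrix(
            {
                "bound": classify_peaks(hits, uni),
                "unbound": classify_peaks(misses, uni),
            },
            uni,
        ).table.set_index("factor")
        assert mat.loc["bound", "p"] < mat.loc["unbound", "p"]

    def test_exclusive_row_sums(self, demo_result):
        table = demo_result.enrichment.table
        for factor, sub in table.groupby("factor"):
            n = sub["n"].iloc[0]
            assert sub["k"].sum() <= n


class TestBuildUniverse:
    def test_pseudo_loci_tile_unannotated_space(self):
        genes = [gene(10_000, 10_150, "+", "snRNA")]
        uni = build_universe(genes, {"c": 40_000}, pseudo_locus_width=300)
        assert uni.loci_count("snRNA") == 1
        # ~ (40_000 - 150) / 300 pseudo-loci, minus rounding at the gap edges
        assert uni.pseudo_loci == (10_000 // 300) + ((40_000 - 10_150) // 300)

    def test_pirna_priority_precedes_snRNA(self, demo_result):
        prio = demo_result.universe.priority
        assert prio.index("piRNA_typeI") < prio.index("snRNA")
        assert prio.index("piRNA_typeII") < prio.index("snRNA")


class TestCircularShift:
    def test_widths_preserved_and_wrapped(self):
        peaks = [peak(900, 1_200)]
        (shifted,) = circular_shift_peaks(peaks, {"c": 2_000}, offset=1_500)
        assert len(shifted.interval) == 300
        assert 0 <= shifted.interval.start < 2_000
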