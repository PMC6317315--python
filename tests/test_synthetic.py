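"""Generator contracts: motif planting, determinism, coverage statistics."""

import numpy as np
import pytest
from scipy import stats

from rubychip.intervals import GenomicInterval
from rubychip.synthetic import (
    PIRNA_LEN,
    RUBY_MOTIF,
    RUBY_RC,
    FactorProfile,
    GenomeSpec,
    demo_genome_spec,
    make_genome,
    revcomp,
    simulate_coverage,
)


def small_spec(seed=0, n_typeI=10, **kw):
    defaults = dict(
        chromosomes=[("chrIV", 100_000), ("chrI", 50_000)],
        cluster_chrom="chrIV",
        cluster_regions=[GenomicInterval("chrIV", 20_000, 30_000)],
        n_typeI=n_typeI,
        n_typeII=5,
        biotype_counts={"snRNA": 3},
        seed=seed,
    )
    defaults.update(kw)
    return GenomeSpec(**defaults)


class TestMakeGenome:
    def test_ruby_planted_in_upstream_window(self):
        """Every type I first-U has CTGTTTCA in [u-48, u-40) coding-strand."""
        spec = small_spec(motif_to_tss_spacer=40)
        genome = make_genome(spec)
        genes = genome.pirna_genes("I")
        assert len(genes) == 10
        for g in genes:
            u = int(g.attributes["first_u"])
            seq = genome.sequences[g.interval.chrom]
            if g.interval.strand == "+":
                assert seq[u - 48 : u - 40] == RUBY_MOTIF
                assert seq[u] == "T"  # first U
            else:
                assert seq[u + 41 : u + 49] == RUBY_RC
                assert seq[u] == "A"  # complement of coding-strand T

    def test_yrnt_at_first_u(self):
        genome = make_genome(small_spec())
        for g in genome.pirna_genes():
            u = int(g.attributes["first_u"])
            seq = genome.sequences[g.interval.chrom]
            word = (
                seq[u - 3 : u + 1]
                if g.interval.strand == "+"
                else revcomp(seq[u : u + 4])
            )
            assert word[0] in "CT" and word[1] in "AG" and word[3] == "T"

    def test_type_membership_of_clusters(self):
        genome = make_genome(small_spec())
        for g in genome.pirna_genes("I"):
            assert g.interval.chrom == "chrIV"
            assert any(
                r.start <= int(g.attributes["first_u"]) < r.end
                for r in genome.spec.cluster_regions
            )
        for g in genome.pirna_genes("II"):
            assert g.interval.chrom != "chrIV"

    def test_type_ii_lacks_upstream_ruby(self):
        genome = make_genome(small_spec())
        for g in genome.pirna_genes("II"):
            u = int(g.attributes["first_u"])
            seq = genome.sequences[g.interval.chrom]
            window = (
                seq[max(0, u - 60) : u]
                if g.interval.strand == "+"
                else revcomp(seq[u + 1 : u + 61])
            )
            assert RUBY_MOTIF not in window

    def test_empty_spec_has_only_chance_hits(self):
        spec = small_spec(n_typeI=0, n_typeII=0, biotype_counts={})
        genome = make_genome(spec)
        n_hits = sum(
            seq.count(RUBY_MOTIF) + seq.count(RUBY_RC)
            for seq in genome.sequences.values()
        )
        # chance rate 2 * 4^-8 per bp; within 5 SD of Poisson expectation
        genome_len = sum(len(s) for s in genome.sequences.values())
        expected = genome_len * 2 * 4**-8
        assert abs(n_hits - expected) <= 5 * np.sqrt(expected)

    def test_planted_motif_count(self, genome):
        n_typeI = genome.spec.n_typeI
        n_hits = sum(
            seq.count(RUBY_MOTIF) + seq.count(RUBY_RC)
            for seq in genome.sequences.values()
        )
        genome_len = sum(len(s) for s in genome.sequences.values())
        expected_chance = genome_len * 2 * 4**-8
        assert abs(n_hits - n_typeI - expected_chance) <= 5 * np.sqrt(expected_chance)

    def test_determinism_bit_exact(self):
        a, b = make_genome(small_spec(seed=7)), make_genome(small_spec(seed=7))
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        assert all(
            np.array_equal(a.mappability.data[c], b.mappability.data[c])
            for c in a.sequences
        )

    def test_different_seed_changes_sequence(self):
        a, b = make_genome(small_spec(seed=1)), make_genome(small_spec(seed=2))
        assert a.sequences != b.sequences

    def test_low_mappability_decoys(self):
        spec = small_spec(
            low_mappability_regions=[GenomicInterval("chrI", 1000, 2000)]
        )
        genome = make_genome(spec)
        assert np.all(genome.mappability.data["chrI"][1000:2000] < 0.25)
        assert np.all(genome.mappability.data["chrI"][:1000] == 1.0)

    def test_overfull_cluster_errors_with_gene_name(self):
        spec = small_spec(
            n_typeI=200,
            cluster_regions=[GenomicInterval("chrIV", 20_000, 22_000)],
        )
        with pytest.raises(ValueError, match="piRNA_typeI"):
            make_genome(spec)

    def test_both_strands_exercised(self, genome):
        strands = {g.interval.strand for g in genome.pirna_genes("I")}
        assert strands == {"+", "-"}


class TestSimulateCoverage:
    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            FactorProfile("f", depth=0.0)

    def test_folds_below_one_rejected(self):
        with pytest.raises(ValueError):
            FactorProfile("f", fold_typeI=0.5)

    def test_coverage_mass_fold1(self):
        """Total mass ~= depth * genome length within 1% for fold-1."""
        genome = make_genome(small_spec())
        profile = FactorProfile("flat", depth=30.0, n_replicates=1)
        reps, inp = simulate_coverage(genome, profile, replicate_seed=3)
        genome_len = sum(len(s) for s in genome.sequences.values())
        for track in (reps[0], inp):
            assert track.total_mass() == pytest.approx(
                30.0 * genome_len, rel=0.01
            )

    def test_fold1_chip_and_input_exchangeable(self):
        """Null factor: window means pass a two-sample location test."""
        genome = make_genome(small_spec(n_typeI=0, n_typeII=0, biotype_counts={}))
        profile = FactorProfile("flat", depth=30.0, n_replicates=1)
        reps, inp = simulate_coverage(genome, profile, replicate_seed=5)
        w = 200
        chip_means = reps[0].data["chrIV"][: 200 * w].reshape(200, w).mean(axis=1)
        input_means = inp.data["chrIV"][: 200 * w].reshape(200, w).mean(axis=1)
        _, p = stats.mannwhitneyu(chip_means, input_means, alternative="two-sided")
        assert p > 0.01

    def test_planted_windows_exceed_background_ratio(self, rng):
        genome = make_genome(small_spec(n_typeI=20))
        profile = FactorProfile("hot", fold_typeI=8.0, depth=30.0, dispersion=0.1)
        reps, inp = simulate_coverage(genome, profile, replicate_seed=9)
        chip, ctrl = reps[0], inp

        def window_ratio(chrom, center, half=150):
            c = chip.data[chrom][center - half : center + half].mean()
            i = ctrl.data[chrom][center - half : center + half].mean()
            return c / max(i, 1e-9)

        planted = [
            window_ratio(c, s + 4) for c, s, _ in genome.ruby_positions()
        ]
        length = len(chip.data["chrIV"])
        background = [
            window_ratio("chrIV", int(p))
            for p in rng.integers(200, length - 200, 1000)
        ]
        assert np.mean(planted) > np.mean(background)

    def test_artifact_region_exceeds_background_percentile(self):
        spec = small_spec(
            artifact_regions=[GenomicInterval("chrI", 10_000, 10_400)]
        )
        genome = make_genome(spec)
        profile = FactorProfile("flat", depth=30.0)
        _, inp = simulate_coverage(genome, profile, replicate_seed=2)
        artifact_cov = inp.data["chrI"][10_000:10_400]
        background = np.concatenate(
            [inp.data["chrI"][:10_000], inp.data["chrI"][10_400:]]
        )
        assert artifact_cov.min() > np.percentile(background, 99.9)

    def test_replicates_differ_but_seeds_reproduce(self):
        genome = make_genome(small_spec())
        profile = FactorProfile("f", n_replicates=2)
        reps_a, _ = simulate_coverage(genome, profile, replicate_seed=4)
        reps_b, _ = simulate_coverage(genome, profile, replicate_seed=4)
        assert not np.array_equal(reps_a[0].data["chrIV"], reps_a[1].data["chrIV"])
        for r_a, r_b in zip(reps_a, reps_b):
            assert np.array_equal(r_a.data["chrIV"], r_b.data["chrIV"])


def test_demo_spec_is_valid_and_deterministic():
    spec = demo_genome_spec(0)
    assert spec.cluster_chrom == "chrIV"
    g1, g2 = make_genome(spec), make_genome(demo_genome_spec(0))
    assert g1.sequences == g2.sequences
    assert len(g1.pirna_genes("I")) == spec.n_typeI


def test_pirna_gene_interval_covers_first_u(genome):
    for g in genome.pirna_genes():
        u = int(g.attributes["first_u"])
        assert g.interval.start <= u < g.interval.end
        assert len(g.interval) == PIRNA_LEN
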