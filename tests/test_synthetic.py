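"""Synthetic screen generator: determinism, composition, and read structure."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from luctrap import (
    CohortConfig,
    build_genome_index,
    extract_barcode_and_flank,
    generate_cohort,
    generate_genome,
    generate_wt_expression,
    map_flank,
    simulate_count_libraries,
    simulate_junction_library,
    simulate_junction_reads,
)
from luctrap.io import write_fasta, write_gff3


class TestGenome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            genome = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=20, seed=7)
            write_fasta(tmp_path / f"{run}.fa", genome.chromosomes)
            write_gff3(tmp_path / f"{run}.gff3", genome)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_zero_genes_still_valid(self):
        genome = generate_genome(n_chrom=1, chrom_len=20_000, n_genes=0, seed=1)
        assert genome.genes == []
        assert len(genome.chromosomes[0][1]) == 20_000

    def test_default_genic_fraction_near_half(self):
        genome = generate_genome(seed=3)
        genic = sum(g.end - g.start for g in genome.genes)
        total = sum(len(s) for _, s in genome.chromosomes)
        assert 0.45 <= genic / total <= 0.55

    def test_genes_within_bounds_and_non_overlapping(self, small_genome):
        sizes = {n: len(s) for n, s in small_genome.chromosomes}
        by_chrom = {}
        for g in small_genome.genes:
            assert 0 <= g.start < g.end <= sizes[g.chromosome]
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for intervals in by_chrom.values():
            intervals.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(intervals, intervals[1:]))

    def test_overdense_request_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(n_chrom=1, chrom_len=10_000, n_genes=40, seed=1)


class TestWtExpression:
    def test_fpkm_positive_and_mostly_genic(self, small_genome):
        wt = generate_wt_expression(small_genome, seed=9)
        assert all(r.fpkm > 0 for r in wt.regions)
        gene_keys = {(g.chromosome, g.start, g.end) for g in small_genome.genes}
        genic = sum((r.chromosome, r.start, r.end) in gene_keys for r in wt.regions)
        assert genic / len(wt.regions) > 0.9

    def test_transcribed_gene_fraction(self, small_genome):
        wt = generate_wt_expression(small_genome, transcribed_gene_fraction=0.704, seed=9)
        gene_keys = {(g.chromosome, g.start, g.end) for g in small_genome.genes}
        genic = sum((r.chromosome, r.start, r.end) in gene_keys for r in wt.regions)
        assert genic == round(0.704 * len(small_genome.genes))


class TestCohort:
    def test_all_probabilities_zero_means_silent(self, small_genome):
        config = CohortConfig(
            n_lines=40, p_activate_genic_sense=0, p_activate_genic_as=0,
            p_activate_intergenic=0, seed=4,
        )
        truth = generate_cohort(small_genome, config)
        assert (truth["true_level"] == 0).all()
        assert not truth["true_transcribed"].any()

    def test_transcribed_fraction_within_binomial_bound(self, small_genome):
        n = 10_000
        config = CohortConfig(
            n_lines=n, p_activate_genic_sense=1 / 3, p_activate_genic_as=1 / 3,
            p_activate_intergenic=1 / 3, seed=12,
        )
        truth = generate_cohort(small_genome, config)
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        assert abs(truth["true_transcribed"].sum() - n / 3) <= 3 * sd

    def test_cohort_of_76_with_27_expected_transcribed(self, small_genome):
        """A 76-line cohort configured at the screen's overall activation rate
        of 27/76 yields an expected transcribed count of 27."""
        p = 27 / 76
        config = CohortConfig(
            n_lines=76, p_activate_genic_sense=p, p_activate_genic_as=p,
            p_activate_intergenic=p, seed=13,
        )
        truth = generate_cohort(small_genome, config)
        assert 76 * p == pytest.approx(27)
        sd = np.sqrt(76 * p * (1 - p))
        assert abs(truth["true_transcribed"].sum() - 27) <= 3 * sd

    def test_active_levels_within_dynamic_range(self, small_genome):
        config = CohortConfig(n_lines=500, seed=21)
        truth = generate_cohort(small_genome, config)
        active = truth[truth["true_transcribed"]]
        assert ((active["true_level"] >= 1e1) & (active["true_level"] <= 1e7)).all()

    def test_placement_matches_interval_lengths(self, small_genome):
        """Genic vs intergenic placement frequencies follow the genome's
        interval-length fractions (chi-square GoF, p > 0.01 at n = 10,000)."""
        config = CohortConfig(n_lines=10_000, seed=30, margin=200)
        truth = generate_cohort(small_genome, config)
        genic_obs = (truth["insertion_type"] != "intergenic").sum()
        genic_bp = sum(g.end - g.start for g in small_genome.genes)
        total_bp = sum(len(s) for _, s in small_genome.chromosomes)
        p_genic = genic_bp / total_bp
        n = len(truth)
        _, p = stats.chisquare(
            [genic_obs, n - genic_obs], [n * p_genic, n * (1 - p_genic)]
        )
        assert p > 0.01

    def test_collisions_reuse_existing_barcodes(self, small_genome):
        config = CohortConfig(n_lines=200, collision_rate=0.3, seed=8)
        truth = generate_cohort(small_genome, config)
        primary = truth[~truth["secondary"]]
        assert primary["collided"].any()
        assert primary["barcode"].duplicated().any()

    def test_unique_barcodes_without_collisions(self, small_cohort):
        primary = small_cohort[~small_cohort["secondary"]]
        assert primary["barcode"].is_unique


class TestJunctionLibrary:
    def test_clean_reads_carry_true_barcode(self, small_genome, template):
        config = CohortConfig(n_lines=1, seed=40)
        truth = generate_cohort(small_genome, config)
        reads = simulate_junction_reads(truth, small_genome, template, depth_per_line=5, seed=41)
        assert len(reads) == 5
        for read_id, seq in reads:
            junc, reason = extract_barcode_and_flank(read_id, seq, template)
            assert reason == "ok"
            assert junc.barcode == truth.loc[0, "barcode"]

    def test_substitution_rate_one_destroys_every_barcode(self, small_genome, template):
        truth = generate_cohort(small_genome, CohortConfig(n_lines=5, seed=42))
        reads = simulate_junction_reads(
            truth, small_genome, template, depth_per_line=4,
            barcode_substitution_rate=1.0, seed=43,
        )
        true_barcodes = set(truth["barcode"])
        for read_id, seq in reads:
            junc, reason = extract_barcode_and_flank(read_id, seq, template)
            assert reason == "ok"
            assert junc.barcode not in true_barcodes

    def test_extract_then_map_recovers_every_line(self, small_genome, template):
        """End-to-end identity: extraction + mapping on clean reads returns
        the true (chromosome, junction, strand) for 100% of lines."""
        truth = generate_cohort(small_genome, CohortConfig(n_lines=40, seed=44))
        reads = simulate_junction_reads(truth, small_genome, template, depth_per_line=2, seed=45)
        index = build_genome_index(small_genome.chrom_dict(), k=10)
        expected = {
            r.barcode: (r.chromosome, r.rb_position, r.strand)
            for r in truth.itertuples(index=False)
        }
        for read_id, seq in reads:
            junc, reason = extract_barcode_and_flank(read_id, seq, template)
            assert reason == "ok"
            res = map_flank(junc.flank, index)
            assert res.reason == "unique"
            aln = res.alignment
            assert (aln.chromosome, aln.position, aln.strand) == expected[junc.barcode]

    def test_depth_zero_gives_empty_file(self, small_genome, template, tmp_path):
        truth = generate_cohort(small_genome, CohortConfig(n_lines=3, seed=46))
        n = simulate_junction_library(
            truth, small_genome, template, tmp_path / "j.fastq", depth_per_line=0
        )
        assert n == 0 and (tmp_path / "j.fastq").read_text() == ""

    def test_fixed_seed_reproduces_bytes(self, small_genome, template, tmp_path):
        truth = generate_cohort(small_genome, CohortConfig(n_lines=10, seed=47))
        for name in ("a", "b"):
            simulate_junction_library(
                truth, small_genome, template, tmp_path / f"{name}.fastq",
                depth_per_line=3, barcode_substitution_rate=0.2, seed=48,
            )
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


class TestCountLibraries:
    def test_silent_cohort_has_empty_rna_library(self, small_genome, template, tmp_path):
        config = CohortConfig(
            n_lines=10, p_activate_genic_sense=0, p_activate_genic_as=0,
            p_activate_intergenic=0, seed=50,
        )
        truth = generate_cohort(small_genome, config)
        dna, rna = simulate_count_libraries(
            truth, template, tmp_path / "d.fastq", tmp_path / "r.fastq",
            dna_depth=1000, rna_depth=1000, seed=51,
        )
        assert rna == {} and (tmp_path / "r.fastq").read_text() == ""
        assert sum(dna.values()) == 1000

    def test_rna_ratio_follows_levels(self, small_genome, template, tmp_path):
        """Two lines at levels L and 2L with equal DNA weights yield an RNA
        count ratio of 2 within multinomial sampling error."""
        truth = generate_cohort(small_genome, CohortConfig(n_lines=2, seed=52))
        truth["true_level"] = [1000.0, 2000.0]
        truth["true_transcribed"] = True
        depth = 300_000
        _, rna = simulate_count_libraries(
            truth, template, tmp_path / "d.fastq", tmp_path / "r.fastq",
            dna_depth=1000, rna_depth=depth, seed=53,
        )
        b1, b2 = truth["barcode"]
        p = 2 / 3
        sd = np.sqrt(depth * p * (1 - p))
        assert abs(rna[b2] - depth * p) <= 3 * sd
        assert rna[b1] + rna[b2] == depth

    def test_fixed_seed_reproduces_bytes(self, small_cohort, template, tmp_path):
        for name in ("a", "b"):
            simulate_count_libraries(
                small_cohort, template, tmp_path / f"d{name}.fastq", tmp_path / f"r{name}.fastq",
                dna_depth=5000, rna_depth=5000, dna_weight_jitter_sd=0.2, seed=54,
            )
        assert (tmp_path / "da.fastq").read_bytes() == (tmp_path / "db.fastq").read_bytes()
        assert (tmp_path / "ra.fastq").read_bytes() == (tmp_path / "rb.fastq").read_bytes()
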