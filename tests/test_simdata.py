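"""Synthetic genome/library generator: determinism, structure, truth labels."""

import filecmp
from collections import Counter

import numpy as np
import pytest

from capfilter.annotate import load_gene_models
from capfilter.invasion import upstream_window
from capfilter.simdata import (
    SimConfig,
    simulate_dataset,
    simulate_genome,
    simulate_library,
)


class TestGenome:
    def test_seed_determinism_is_byte_identical(self, tmp_path, default_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(default_config, 42, str(d1))
        simulate_dataset(default_config, 42, str(d2))
        for name in ("genome.fa", "annotation.gff3", "reads.fastq", "truth.sam", "truth.tsv", "rrna.bed"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_uniform_base_composition(self, default_config):
        sim = simulate_genome(default_config, 3)
        seq = "".join(sim.genome.sequence(c) for c in sim.genome.names)
        counts = Counter(seq)
        n = len(seq)
        sigma = (0.25 * 0.75 / n) ** 0.5
        for base in "ACGT":
            assert abs(counts[base] / n - 0.25) < 3.5 * sigma + 0.01

    def test_genes_do_not_overlap_and_parts_tile_the_span(self, default_config):
        sim = simulate_genome(default_config, 5)
        by_chrom = {}
        for g in sim.genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        for g in sim.genes:
            lo, hi = g.span
            covered = sorted(g.five_utr + g.cds + g.introns + g.three_utr)
            assert covered[0][0] == lo and covered[-1][1] == hi
            for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
                assert e1 == s2

    def test_gff3_roundtrip_matches_models(self, tmp_path, default_config):
        sim = simulate_genome(default_config, 8)
        path = tmp_path / "ann.gff3"
        sim.write_gff3(str(path))
        loaded = {g.gene_id: g for g in load_gene_models(str(path))}
        assert len(loaded) == len(sim.genes)
        for g in sim.genes:
            got = loaded[g.gene_id]
            assert (got.chrom, got.strand, got.tss, got.gene_end) == (
                g.chrom, g.strand, g.tss, g.gene_end,
            )
            assert got.five_utr == g.five_utr
            assert got.cds == g.cds
            assert got.three_utr == g.three_utr

    def test_zero_genes_gives_valid_empty_annotation(self, tmp_path):
        cfg = SimConfig(
            n_genes=0, n_capped=0, n_uncapped_body=0, n_strand_invasion=0, n_rrna=0
        )
        sim, lib = simulate_dataset(cfg, 1, str(tmp_path / "empty"))
        assert sim.genes == [] and lib.fastq == []
        text = (tmp_path / "empty" / "annotation.gff3").read_text()
        assert text.startswith("##gff-version 3")
        assert (tmp_path / "empty" / "genome.fa").stat().st_size > 0

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(chrom_lengths={"chr1": 12000}, n_genes=30)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(cfg, 1)

    def test_invasion_sites_have_exact_oligo_context(self, default_config):
        sim = simulate_genome(default_config, 13)
        tail9 = default_config.oligo_tail9(default_config.barcodes[0][1])
        for chrom, pos, strand in sim.invasion_sites:
            assert upstream_window(chrom, pos, strand, sim.genome) == tail9

    def test_yr_planting_marks_every_tss(self):
        cfg = SimConfig(plant_yr=True, n_invasion_sites=0)
        sim = simulate_genome(cfg, 2)
        for g in sim.genes:
            step = 1 if g.strand == "+" else -1
            assert sim.genome.base_at(g.chrom, g.tss - step, g.strand) == "C"
            assert sim.genome.base_at(g.chrom, g.tss, g.strand) == "A"


class TestLibrary:
    def test_truth_covers_all_reads_and_classes(self, sim_bundle):
        sim, lib, _ = sim_bundle
        cfg = sim.config
        assert len(lib.fastq) == len(lib.truth_records) == len(lib.truth_alignments)
        origins = Counter(t.origin for t in lib.truth_records)
        assert origins == Counter(
            {
                "capped": cfg.n_capped,
                "uncapped_body": cfg.n_uncapped_body,
                "strand_invasion": cfg.n_strand_invasion,
                "rRNA": cfg.n_rrna,
            }
        )

    def test_capped_only_when_other_rates_zero(self, capped_only_config):
        sim = simulate_genome(capped_only_config, 4)
        lib = simulate_library(sim, capped_only_config, 5)
        assert {t.origin for t in lib.truth_records} == {"capped"}

    def test_capped_five_prime_within_spread_of_tss(self, sim_bundle):
        sim, lib, _ = sim_bundle
        spread = sim.config.tss_spread
        for t in lib.truth_records:
            if t.origin != "capped":
                continue
            # un-prepended reads lose their first base to tagging: one extra step
            assert abs(t.five_prime - t.true_tss) <= spread + 1

    def test_prepend_probability_respected(self, sim_bundle):
        sim, lib, _ = sim_bundle
        capped = [t for t in lib.truth_records if t.origin == "capped"]
        frac = sum(t.prepended_unencoded for t in capped) / len(capped)
        assert frac == sim.config.unencoded_g_probability == 1.0
        others = [t for t in lib.truth_records if t.origin != "capped"]
        assert not any(t.prepended_unencoded for t in others)

    def test_raw_reads_carry_the_full_oligo_prefix(self, sim_bundle):
        sim, lib, _ = sim_bundle
        prefix = sim.config.oligo_prefix(sim.config.barcodes[0][1])
        assert all(seq.startswith(prefix) for _, seq, _ in lib.fastq)

    def test_extra_c_reads_get_soft_clipped_truth(self):
        cfg = SimConfig(
            n_capped=200, n_uncapped_body=0, n_strand_invasion=0, n_rrna=0,
            n_invasion_sites=0, extra_c_probability=1.0,
        )
        sim = simulate_genome(cfg, 6)
        lib = simulate_library(sim, cfg, 7)
        # prepend always, extra G always: one leftover unencoded base per read
        assert len(lib.clipped_prefixes) == len(lib.fastq)
        assert set(lib.clipped_prefixes.values()) == {"G"}

    def test_expression_weights_shared_by_replicates(self, default_config):
        sim = simulate_genome(default_config, 9)
        lib_a = simulate_library(sim, default_config, 10)
        lib_b = simulate_library(sim, default_config, 11)

        def gene_counts(lib):
            c = Counter(
                t.gene_id for t in lib.truth_records if t.origin == "capped"
            )
            return np.array([c.get(g.gene_id, 0) for g in sim.genes])

        a, b = gene_counts(lib_a), gene_counts(lib_b)
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.8
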