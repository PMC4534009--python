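"""Peak categorization, quartiles, filter sweep, FNR, mode context, metrics."""

import math

import pytest

from capfilter.alignments import Alignment
from capfilter.annotate import (
    CATEGORIES,
    GeneIndex,
    GeneModel,
    categorize_peak,
    categorize_peaks,
    category_distribution,
    false_negative_rate,
    filter_sweep,
    genes_with_peaks,
    library_metrics,
    mode_context_matrix,
    quartile_distribution,
)
from capfilter.genome import ReferenceGenome
from capfilter.gfilter import FilteredPeak, annotate_percent_capped, g_filter
from capfilter.peaks import Peak5p, call_peaks, five_prime_positions


def make_gene(strand="+", g0=5000, gene_id="g1", chrom="c"):
    """5'UTR(150) CDS(300) intron(120) CDS(300) 3'UTR(200), span 1070."""
    if strand == "+":
        return GeneModel(
            gene_id=gene_id, chrom=chrom, strand="+", tss=g0, gene_end=g0 + 1069,
            five_utr=[(g0, g0 + 150)],
            cds=[(g0 + 150, g0 + 450), (g0 + 570, g0 + 870)],
            three_utr=[(g0 + 870, g0 + 1070)],
        )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand="-", tss=g0 + 1069, gene_end=g0,
        five_utr=[(g0 + 920, g0 + 1070)],
        cds=[(g0 + 620, g0 + 920), (g0 + 200, g0 + 500)],
        three_utr=[(g0, g0 + 200)],
    )


def peak_at(start, end, strand="+", mode=None, chrom="c"):
    return Peak5p(
        chrom=chrom, strand=strand, start=start, end=end, count=20,
        mode=start if mode is None else mode, mode_count=10,
    )


class TestCategorizePeak:
    GENE = make_gene()
    INDEX = GeneIndex([GENE])

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (4995, 5005, "TSS"),  # interval spans the TSS coordinate
            (5010, 5030, "FiveUTR"),
            (5200, 5220, "CDS"),
            (5500, 5520, "Intron"),
            (5900, 5920, "ThreeUTR"),
            (6100, 6120, "ThreeUTR"),  # within 1000 bp past the gene end
            (2500, 2520, "Promoter"),  # 2500 bp upstream of the TSS
            (1400, 1420, "Intergenic"),  # 3600 bp upstream, >1 kb past ends
        ],
    )
    def test_plus_strand_categories(self, start, end, expected):
        assert categorize_peak(peak_at(start, end), self.INDEX).category == expected

    def test_minus_strand_mirror(self):
        gene = make_gene(strand="-")
        index = GeneIndex([gene])
        # TSS at 6069; promoter extends to higher coordinates
        assert categorize_peak(peak_at(6060, 6075, "-"), index).category == "TSS"
        assert categorize_peak(peak_at(8000, 8020, "-"), index).category == "Promoter"
        assert categorize_peak(peak_at(5950, 5970, "-"), index).category == "FiveUTR"
        assert categorize_peak(peak_at(4900, 4920, "-"), index).category == "ThreeUTR"

    def test_antisense_peak_falls_through_to_nongenic(self):
        peak = peak_at(5200, 5220, strand="-")  # over the + gene's CDS
        assert categorize_peak(peak, self.INDEX).category == "Intergenic"

    def test_tss_precedence_over_parts(self):
        # wide peak overlapping TSS and extending into the 5'UTR
        assert categorize_peak(peak_at(4990, 5100), self.INDEX).category == "TSS"

    def test_empty_annotation_warns_all_intergenic(self):
        with pytest.warns(UserWarning):
            cats = categorize_peaks([peak_at(10, 20)], [])
        assert cats[0].category == "Intergenic"

    def test_partition_exactly_one_category(self, sim_bundle):
        sim, lib, calls = sim_bundle
        peaks = call_peaks(five_prime_positions(lib.truth_alignments))
        cats = categorize_peaks(peaks, sim.genes)
        assert len(cats) == len(peaks)
        assert all(c.category in CATEGORIES for c in cats)


class TestDistributionAndSweep:
    def test_fractions_sum_to_one(self, sim_bundle):
        sim, lib, _ = sim_bundle
        peaks = call_peaks(five_prime_positions(lib.truth_alignments))
        dist = category_distribution(categorize_peaks(peaks, sim.genes))
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_input_gives_empty_table(self):
        assert category_distribution([]) == {}

    def test_sweep_row_zero_equals_unfiltered(self, sim_bundle):
        sim, lib, calls = sim_bundle
        peaks = annotate_percent_capped(
            call_peaks(five_prime_positions(lib.truth_alignments)), calls
        )
        sweep = filter_sweep(peaks, sim.genes, thresholds=(0, 50, 100))
        unfiltered = category_distribution(categorize_peaks(peaks, sim.genes))
        for cat, frac in unfiltered.items():
            assert sweep.loc[0, cat] == pytest.approx(frac)

    def test_tss_share_non_decreasing_up_to_75(self, sim_bundle):
        sim, lib, calls = sim_bundle
        peaks = annotate_percent_capped(
            call_peaks(five_prime_positions(lib.truth_alignments)), calls
        )
        sweep = filter_sweep(peaks, sim.genes, thresholds=tuple(range(0, 80, 5)))
        share = (sweep["TSS"].fillna(0) + sweep["FiveUTR"].fillna(0)).to_list()
        assert all(b >= a - 1e-9 for a, b in zip(share, share[1:]))

    def test_threshold_100_requires_every_read_unencoded_g(self, sim_bundle):
        sim, lib, calls = sim_bundle
        peaks = annotate_percent_capped(
            call_peaks(five_prime_positions(lib.truth_alignments)), calls
        )
        for p in g_filter(peaks, 100):
            assert p.percent_capped == pytest.approx(100.0)


class TestQuartiles:
    def _gene(self):
        # window = 100 upstream + span 700 = 800 nt, divisible by 4;
        # the TSS (offset 100) falls inside quartile 1 (first 200 nt)
        return GeneModel(
            gene_id="q1", chrom="c", strand="+", tss=1000, gene_end=1699,
            five_utr=[(1000, 1100)], cds=[(1100, 1500)], three_utr=[(1500, 1700)],
        )

    def _aln(self, pos, strand="+", name=None):
        return Alignment(name or f"a{pos}", "c", pos, strand, "ACGTACGT")

    def test_all_reads_at_tss_gives_quartile_one(self):
        dist, n, _ = quartile_distribution([self._aln(1000)] * 5, [self._gene()])
        assert n == 1 and dist[1] == pytest.approx(100.0)

    def test_reads_only_in_three_utr_gives_quartile_four(self):
        dist, n, _ = quartile_distribution([self._aln(1660)] * 3, [self._gene()])
        assert dist[4] == pytest.approx(100.0)

    def test_uniform_reads_tie_to_quartile_one(self):
        alns = [self._aln(p, name=f"u{p}") for p in range(900, 1700)]
        dist, n, _ = quartile_distribution(alns, [self._gene()])
        assert dist[1] == pytest.approx(100.0)

    def test_percentages_sum_to_100_and_strand_symmetric(self, sim_bundle):
        sim, lib, _ = sim_bundle
        dist, n, skipped = quartile_distribution(lib.truth_alignments, sim.genes)
        assert n > 0 and sum(dist.values()) == pytest.approx(100.0)
        # mirror every alignment and gene through a strand flip
        def flip_aln(a):
            strand = "-" if a.strand == "+" else "+"
            L = sim.genome.length(a.chrom)
            new_end = L - a.start
            return Alignment(a.qname, a.chrom, new_end - len(a.seq), strand, a.seq)

        def flip_gene(g):
            L = sim.genome.length(g.chrom)
            strand = "-" if g.strand == "+" else "+"
            flip = lambda iv: (L - iv[1], L - iv[0])
            return GeneModel(
                gene_id=g.gene_id, chrom=g.chrom, strand=strand,
                tss=L - 1 - g.tss, gene_end=L - 1 - g.gene_end,
                five_utr=sorted(map(flip, g.five_utr)),
                cds=sorted(map(flip, g.cds)),
                three_utr=sorted(map(flip, g.three_utr)),
            )

        flipped_dist, n2, _ = quartile_distribution(
            [flip_aln(a) for a in lib.truth_alignments],
            [flip_gene(g) for g in sim.genes],
        )
        assert n2 == n
        for q in (1, 2, 3, 4):
            assert flipped_dist[q] == pytest.approx(dist[q])

    def test_short_window_skipped(self):
        tiny = GeneModel(gene_id="t", chrom="c", strand="+", tss=10, gene_end=11)
        dist, n, skipped = quartile_distribution([], [tiny], upstream_bp=0)
        assert skipped == 1 and n == 0


class TestGeneCoverageAndFnr:
    def test_mean_peaks_per_gene(self):
        from capfilter.annotate import PeakCategory

        cats = [
            PeakCategory("TSS", "g1"),
            PeakCategory("TSS", "g2"),
            PeakCategory("CDS", "g3"),
            PeakCategory("FiveUTR", "g3"),
            PeakCategory("Intergenic", None),
        ]
        assert genes_with_peaks(cats) == (3, pytest.approx(4 / 3))

    def test_no_peaks(self):
        assert genes_with_peaks([]) == (0, None)

    def _fpeaks(self, genes):
        tss = genes[0].tss
        peaks = []
        for i in range(10):
            pct = 20.0 if i == 0 else 90.0
            peaks.append(
                FilteredPeak(
                    chrom="c", strand="+", start=tss - 5 + 40 * i, end=tss + 5 + 40 * i,
                    count=20, mode=tss + 40 * i, mode_count=10,
                    percent_capped=pct, n_informative=20,
                )
            )
        return peaks

    def test_one_of_ten_true_peaks_rejected_is_ten_percent(self):
        gene = make_gene()
        pre = self._fpeaks([gene])
        post = g_filter(pre, 50)
        assert false_negative_rate(pre, post, [gene]) == pytest.approx(10.0)

    def test_threshold_zero_has_zero_fnr(self):
        gene = make_gene()
        pre = self._fpeaks([gene])
        assert false_negative_rate(pre, g_filter(pre, 0), [gene]) == pytest.approx(0.0)

    def test_no_true_peaks_is_undefined(self):
        gene = make_gene()
        far = FilteredPeak(
            chrom="c", strand="+", start=20000, end=20010, count=20, mode=20005,
            mode_count=10, percent_capped=90.0, n_informative=20,
        )
        assert false_negative_rate([far], [far], [gene]) is None

    def test_fnr_non_decreasing_in_threshold(self, sim_bundle):
        sim, lib, calls = sim_bundle
        pre = annotate_percent_capped(
            call_peaks(five_prime_positions(lib.truth_alignments)), calls
        )
        rates = [
            false_negative_rate(pre, g_filter(pre, t), sim.genes)
            for t in (0, 25, 50, 75, 100)
        ]
        rates = [r for r in rates if r is not None]
        assert rates == sorted(rates)


class TestModeContext:
    def test_planted_ca_junction_gives_perfect_yr(self):
        seq = "T" * 30 + "CA" + "T" * 30
        genome = ReferenceGenome({"c": seq})
        peaks = [peak_at(31, 32, mode=31)]  # mode base = A, upstream = C
        matrix, yr, skipped = mode_context_matrix(peaks, genome, 5, 5)
        assert yr["pyrimidine_minus1"] == pytest.approx(1.0)
        assert yr["purine_plus1"] == pytest.approx(1.0)
        assert matrix.loc[1, "A"] == 1 and matrix.loc[-1, "C"] == 1

    def test_minus_strand_context_is_reverse_complemented(self):
        # plus strand reads TG at (mode-1, mode); minus strand reads CA
        seq = "A" * 30 + "TG" + "A" * 30
        genome = ReferenceGenome({"c": seq})
        peaks = [peak_at(30, 32, strand="-", mode=30)]  # mode base on '-' = A
        matrix, yr, _ = mode_context_matrix(peaks, genome, 3, 3)
        assert matrix.loc[1, "A"] == 1  # complement of T at 30
        assert matrix.loc[-1, "C"] == 1  # complement of G at 31
        assert yr["pyrimidine_minus1"] == pytest.approx(1.0)
        assert yr["purine_plus1"] == pytest.approx(1.0)

    def test_column_sums_equal_usable_peaks_and_edges_skipped(self):
        genome = ReferenceGenome({"c": "ACGT" * 20})
        peaks = [peak_at(40, 41, mode=40), peak_at(2, 3, mode=2)]  # second near edge
        matrix, _, skipped = mode_context_matrix(peaks, genome, 10, 10)
        assert skipped == 1
        assert (matrix.sum(axis=1) == 1).all()


class TestLibraryMetrics:
    def _alns(self, seqs):
        return [Alignment(f"r{i}", "c", 100 + i, "+", s) for i, s in enumerate(seqs)]

    def test_redundancy_formula(self):
        m = library_metrics(10, self._alns(["AAAA", "AAAA", "CCCC", "GGGG"]))
        assert m["redundancy"] == pytest.approx(4 / 3)

    def test_all_identical_reads(self):
        m = library_metrics(6, self._alns(["AAAA"] * 6))
        assert m["redundancy"] == pytest.approx(6.0)

    def test_rrna_percentage_and_absence(self):
        alns = self._alns(["AAAA", "CCCC", "GGGG", "TTTT"])
        m = library_metrics(4, alns, rrna_intervals=[("c", 100, 102)])
        assert m["pct_rrna"] == pytest.approx(50.0)
        assert library_metrics(4, alns)["pct_rrna"] is None
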