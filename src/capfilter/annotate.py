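"""Peak annotation against gene models and summary analytics.

Peaks are categorized by where they fall relative to annotated genes
(TSS, 5'UTR, CDS, Intron, 3'UTR, Promoter, Intergenic), read 5' ends are
summarized per gene quartile, the G'-filter threshold sweep and estimated
false-negative rate are computed, and base-count matrices around peak modes
quantify the pyrimidine(-1)/purine(+1) initiator preference (the YR rule).

Categorization rules (precedence top to bottom; genic tests require a
same-strand gene):
  * TSS       — the peak interval contains the annotated TSS coordinate;
  * FiveUTR / CDS / Intron / ThreeUTR — the gene part containing the peak's
    5'-most coordinate; the 3'UTR zone extends ``three_prime_bp`` downstream
    of the gene end so that near-gene 3' peaks are not called intergenic;
  * Promoter  — within ``promoter_bp`` upstream of a TSS;
  * Intergenic otherwise.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignments import Alignment
from .dna import PURINES, PYRIMIDINES
from .genome import ReferenceGenome
from .gfilter import FilteredPeak, g_filter
from .peaks import Peak5p

CATEGORIES = ("TSS", "FiveUTR", "CDS", "Intron", "ThreeUTR", "Promoter", "Intergenic")

Interval = Tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """Strand-aware protein-coding gene with derived introns.

    ``tss`` and ``gene_end`` are 0-based single coordinates (tss > gene_end
    on the minus strand); interval lists are 0-based half-open on the
    reference.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_end: int
    five_utr: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    three_utr: List[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        lo = min(self.tss, self.gene_end)
        hi = max(self.tss, self.gene_end)
        return (lo, hi + 1)

    @property
    def introns(self) -> List[Interval]:
        exonic = sorted(self.five_utr + self.cds + self.three_utr)
        gaps = []
        for (s1, e1), (s2, e2) in zip(exonic, exonic[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        return gaps


def _contains(intervals: Sequence[Interval], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


def load_gene_models(gff3_path: str) -> List[GeneModel]:
    """Parse gene / five_prime_UTR / CDS / three_prime_UTR features from GFF3."""
    import gffutils

    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        start0, end0 = g.start - 1, g.end  # GFF3 is 1-based inclusive
        strand = g.strand
        tss = start0 if strand == "+" else end0 - 1
        gene_end = end0 - 1 if strand == "+" else start0
        model = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=strand, tss=tss, gene_end=gene_end
        )
        for child in db.children(g, featuretype=("five_prime_UTR", "CDS", "three_prime_UTR")):
            iv = (child.start - 1, child.end)
            if child.featuretype == "five_prime_UTR":
                model.five_utr.append(iv)
            elif child.featuretype == "CDS":
                model.cds.append(iv)
            else:
                model.three_utr.append(iv)
        for lst in (model.five_utr, model.cds, model.three_utr):
            lst.sort()
        genes.append(model)
    return genes


class GeneIndex:
    """Per-(chrom, strand) gene lookup for categorization."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_key: Dict[Tuple[str, str], List[GeneModel]] = defaultdict(list)
        for g in genes:
            self._by_key[(g.chrom, g.strand)].append(g)
        for lst in self._by_key.values():
            lst.sort(key=lambda g: g.span)
        self.genes = list(genes)

    def same_strand(self, chrom: str, strand: str) -> List[GeneModel]:
        return self._by_key.get((chrom, strand), [])


@dataclass(frozen=True)
class PeakCategory:
    category: str
    gene_id: Optional[str] = None


def categorize_peak(
    peak: Peak5p,
    index: GeneIndex,
    promoter_bp: int = 3000,
    three_prime_bp: int = 1000,
) -> PeakCategory:
    """Assign exactly one category to a peak (precedence in module docstring)."""
    genes = index.same_strand(peak.chrom, peak.strand)
    # TSS: half-open peak interval contains an annotated TSS coordinate
    for g in genes:
        if peak.start <= g.tss < peak.end:
            return PeakCategory("TSS", g.gene_id)
    p5 = peak.five_prime_most
    best: Optional[PeakCategory] = None
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    for g in genes:
        cat = None
        lo, hi = g.span
        if lo <= p5 < hi:
            if _contains(g.five_utr, p5):
                cat = "FiveUTR"
            elif _contains(g.cds, p5):
                cat = "CDS"
            elif _contains(g.introns, p5):
                cat = "Intron"
            elif _contains(g.three_utr, p5):
                cat = "ThreeUTR"
            else:
                # inside the gene span but no annotated part (UTR-less models)
                cat = "Intron"
        else:
            # near-gene 3' zone counts with the gene's 3' portion
            d3 = (p5 - g.gene_end) if g.strand == "+" else (g.gene_end - p5)
            if 0 < d3 <= three_prime_bp:
                cat = "ThreeUTR"
        if cat and (best is None or rank[cat] < rank[best.category]):
            best = PeakCategory(cat, g.gene_id)
    if best:
        return best
    for g in genes:
        upstream = (g.tss - p5) if g.strand == "+" else (p5 - g.tss)
        if 0 < upstream <= promoter_bp:
            return PeakCategory("Promoter", g.gene_id)
    return PeakCategory("Intergenic")


def categorize_peaks(
    peaks: Sequence[Peak5p],
    genes: Sequence[GeneModel],
    promoter_bp: int = 3000,
    three_prime_bp: int = 1000,
) -> List[PeakCategory]:
    if not genes:
        import warnings

        warnings.warn("empty gene annotation: all peaks categorized Intergenic")
    index = GeneIndex(genes)
    return [categorize_peak(p, index, promoter_bp, three_prime_bp) for p in peaks]


def category_distribution(categories: Iterable[PeakCategory]) -> Dict[str, float]:
    """Fraction of peaks per category; empty input gives an empty table."""
    counts = Counter(c.category for c in categories)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {cat: counts.get(cat, 0) / total for cat in CATEGORIES}


def filter_sweep(
    peaks: Sequence[FilteredPeak],
    genes: Sequence[GeneModel],
    thresholds: Sequence[float] = tuple(range(0, 101, 5)),
    promoter_bp: int = 3000,
    three_prime_bp: int = 1000,
) -> pd.DataFrame:
    """Category distribution of surviving peaks at each G'-filter threshold."""
    index = GeneIndex(genes)
    cats = {p.key(): categorize_peak(p, index, promoter_bp, three_prime_bp) for p in peaks}
    rows = []
    for t in thresholds:
        surviving = g_filter(peaks, t)
        dist = category_distribution([cats[p.key()] for p in surviving])
        row = {"threshold": t, "n_peaks": len(surviving)}
        row.update({c: dist.get(c, np.nan) for c in CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


def quartile_distribution(
    alignments: Iterable[Alignment],
    genes: Sequence[GeneModel],
    upstream_bp: int = 100,
) -> Tuple[Dict[int, float], int, int]:
    """Percent of genes whose majority of read 5' ends fall in each quartile.

    Each gene's window runs from ``upstream_bp`` upstream of its TSS to its
    annotated end, split into four equal parts ordered 5'->3' (remainder
    bases going to the 3'-most quartiles); only same-strand reads inside the
    window count. Majority ties break to the lower quartile index. Returns
    (percent per quartile, genes counted, genes skipped for short windows).
    """
    per_gene: Dict[str, Counter] = defaultdict(Counter)
    windows = {}
    skipped = 0
    for g in genes:
        if g.strand == "+":
            w_start, w_end = g.tss - upstream_bp, g.gene_end + 1
        else:
            w_start, w_end = g.gene_end, g.tss + upstream_bp + 1
        length = w_end - w_start
        if length < 4:
            skipped += 1
            continue
        windows[g.gene_id] = (g, w_start, w_end)

    bounds = {}
    for gid, (g, w_start, w_end) in windows.items():
        length = w_end - w_start
        base, rem = divmod(length, 4)
        # remainder goes to the 3'-most quartiles
        sizes5to3 = [base + (1 if i >= 4 - rem else 0) for i in range(4)]
        bounds[gid] = (g, w_start, w_end, sizes5to3)

    for aln in alignments:
        p5 = aln.five_prime
        for gid, (g, w_start, w_end, sizes) in bounds.items():
            if g.chrom != aln.chrom or g.strand != aln.strand:
                continue
            if not (w_start <= p5 < w_end):
                continue
            off5 = (p5 - w_start) if g.strand == "+" else (w_end - 1 - p5)
            acc = 0
            for q, size in enumerate(sizes, start=1):
                acc += size
                if off5 < acc:
                    per_gene[gid][q] += 1
                    break
    counted = {gid: cnt for gid, cnt in per_gene.items() if sum(cnt.values()) > 0}
    n = len(counted)
    result = {q: 0.0 for q in (1, 2, 3, 4)}
    if n:
        for cnt in counted.values():
            best = max(cnt.values())
            majority_q = min(q for q in (1, 2, 3, 4) if cnt.get(q, 0) == best)
            result[majority_q] += 1
        result = {q: 100.0 * v / n for q, v in result.items()}
    return result, n, skipped


def genes_with_peaks(
    categories: Iterable[PeakCategory],
) -> Tuple[int, Optional[float]]:
    """(number of genes with >= 1 assigned peak, mean peaks per such gene)."""
    per_gene = Counter(c.gene_id for c in categories if c.gene_id is not None)
    if not per_gene:
        return 0, None
    return len(per_gene), sum(per_gene.values()) / len(per_gene)


def _is_true_five_prime(
    peak: Peak5p, category: PeakCategory, genes: Sequence[GeneModel], tss_window: int
) -> bool:
    if category.category in ("TSS", "FiveUTR"):
        return True
    return any(
        g.chrom == peak.chrom
        and g.strand == peak.strand
        and abs(peak.mode - g.tss) <= tss_window
        for g in genes
    )


def false_negative_rate(
    pre_filter: Sequence[FilteredPeak],
    post_filter: Sequence[FilteredPeak],
    genes: Sequence[GeneModel],
    tss_window: int = 500,
    promoter_bp: int = 3000,
    three_prime_bp: int = 1000,
) -> Optional[float]:
    """Percent of true-5' peaks (TSS/5'UTR category or mode within
    ``tss_window`` of an annotated TSS) rejected by the filter; None when no
    true-5' peak exists pre-filter."""
    index = GeneIndex(genes)
    surviving = {p.key() for p in post_filter}
    true5 = [
        p
        for p in pre_filter
        if _is_true_five_prime(
            p, categorize_peak(p, index, promoter_bp, three_prime_bp), genes, tss_window
        )
    ]
    if not true5:
        return None
    rejected = sum(1 for p in true5 if p.key() not in surviving)
    return 100.0 * rejected / len(true5)


def mode_context_matrix(
    peaks: Sequence[Peak5p],
    genome: ReferenceGenome,
    flank_5: int = 10,
    flank_3: int = 10,
) -> Tuple[pd.DataFrame, Dict[str, float], int]:
    """Base counts around peak modes, on the peak strand.

    Rows are positions -flank_5..-1, +1..+flank_3 (+1 = the mode base, -1 =
    immediately upstream, no position 0); columns A/C/G/T. Also returns the
    YR summary (pyrimidine fraction at -1, purine fraction at +1) and the
    number of peaks skipped because the flanked window left the contig.
    """
    positions = list(range(-flank_5, 0)) + list(range(1, flank_3 + 1))
    counts = {pos: Counter() for pos in positions}
    used = 0
    skipped = 0
    for p in peaks:
        step = 1 if p.strand == "+" else -1
        ok = True
        window = {}
        for pos in positions:
            # +1 sits at the mode itself; -1 one read-strand step upstream
            rel = pos - 1 if pos > 0 else pos
            base = genome.base_at(p.chrom, p.mode + step * rel, p.strand)
            if base is None or base not in "ACGT":
                ok = False
                break
            window[pos] = base
        if not ok:
            skipped += 1
            continue
        used += 1
        for pos, base in window.items():
            counts[pos][base] += 1
    matrix = pd.DataFrame(
        [{"position": pos, **{b: counts[pos].get(b, 0) for b in "ACGT"}} for pos in positions]
    ).set_index("position")
    yr = {"pyrimidine_minus1": float("nan"), "purine_plus1": float("nan")}
    if used:
        m1 = counts[-1]
        p1 = counts[1]
        yr["pyrimidine_minus1"] = sum(m1[b] for b in PYRIMIDINES) / used
        yr["purine_plus1"] = sum(p1[b] for b in PURINES) / used
    return matrix, yr, skipped


def library_metrics(
    raw_read_count: int,
    alignments: Sequence[Alignment],
    categories: Iterable[PeakCategory] = (),
    rrna_intervals: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Dict[str, object]:
    """Per-library summary row: mapping, rRNA, redundancy and gene coverage.

    Redundancy = uniquely mapped reads / distinct mapped read sequences.
    %-rRNA = mapped reads whose 5' end falls in an rRNA interval (BED-style
    0-based half-open), or None when no intervals are supplied.
    """
    mapped = len(alignments)
    distinct = len({a.seq for a in alignments})
    redundancy = (mapped / distinct) if distinct else None
    pct_rrna = None
    if rrna_intervals is not None:
        by_chrom = defaultdict(list)
        for chrom, s, e in rrna_intervals:
            by_chrom[chrom].append((s, e))
        n_rrna = sum(
            1
            for a in alignments
            if any(s <= a.five_prime < e for s, e in by_chrom.get(a.chrom, []))
        )
        pct_rrna = 100.0 * n_rrna / mapped if mapped else None
    n_genes, mean_peaks = genes_with_peaks(categories)
    return {
        "raw_reads": raw_read_count,
        "uniquely_mapped": mapped,
        "pct_rrna": pct_rrna,
        "redundancy": redundancy,
        "genes_with_peaks": n_genes,
        "mean_peaks_per_gene": mean_peaks,
    }


def read_rrna_bed(path: str) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
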