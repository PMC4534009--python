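"""Cross-library reproducibility analytics.

Two libraries' peak sets are paired by coordinate overlap (same chrom and
strand, >= 1 shared base, half-open intervals); only *uniquely* paired peaks
— each overlapping exactly one peak of the other set — are compared. Peak
counts are normalized to reads per million (RPM) and related by Spearman's
rank correlation; agreement of preferred start positions is summarized by
the median, mean and 95th percentile of |mode_a - mode_b|. A saturation
curve reruns peak calling and G'-filtering on random read subsamples to show
how gene discovery grows with depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .alignments import Alignment
from .annotate import GeneModel, categorize_peaks, genes_with_peaks
from .cap_tag import classify_alignments
from .genome import ReferenceGenome
from .gfilter import FilteredPeak, annotate_percent_capped, g_filter
from .peaks import Peak5p, call_peaks, five_prime_positions


@dataclass(frozen=True)
class PeakPair:
    peak_a: Peak5p
    peak_b: Peak5p

    @property
    def mode_distance(self) -> int:
        return abs(self.peak_a.mode - self.peak_b.mode)


def _overlaps(a: Peak5p, b: Peak5p) -> bool:
    return (
        a.chrom == b.chrom
        and a.strand == b.strand
        and a.start < b.end
        and b.start < a.end
    )


def pair_peaks(peaks_a: Sequence[Peak5p], peaks_b: Sequence[Peak5p]) -> List[PeakPair]:
    """Unique overlap pairing; peaks with zero or multiple partners drop out."""
    by_key_b = defaultdict(list)
    for b in peaks_b:
        by_key_b[(b.chrom, b.strand)].append(b)
    partners_a: Dict[int, List[Peak5p]] = {}
    partners_b_count: Dict[Tuple, int] = defaultdict(int)
    for a in peaks_a:
        hits = [b for b in by_key_b.get((a.chrom, a.strand), []) if _overlaps(a, b)]
        partners_a[id(a)] = hits
        for b in hits:
            partners_b_count[b.key()] += 1
    pairs = []
    for a in peaks_a:
        hits = partners_a[id(a)]
        if len(hits) == 1 and partners_b_count[hits[0].key()] == 1:
            pairs.append(PeakPair(peak_a=a, peak_b=hits[0]))
    return pairs


def rpm_normalize(counts: Sequence[float], library_total: int) -> np.ndarray:
    """Reads-per-million scaling of peak counts by the library's mapped total."""
    if library_total < 1:
        raise ValueError("library_total must be >= 1")
    return np.asarray(counts, dtype=float) * 1e6 / library_total


def spearman_rho(values_a: Sequence[float], values_b: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation (average ranks on ties); None when fewer
    than 3 pairs or either vector has zero variance."""
    if len(values_a) != len(values_b):
        raise ValueError("paired vectors must have equal length")
    if len(values_a) < 3:
        import warnings

        warnings.warn("fewer than 3 pairs: Spearman correlation undefined")
        return None
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def mode_distance_stats(
    pairs: Sequence[PeakPair],
) -> Tuple[Optional[int], Optional[float], Optional[int]]:
    """(median, mean, 95th percentile) of paired peak-mode distances.

    Median takes the lower middle element on even n; the 95th percentile is
    the smallest distance d such that at least 95% of pairs lie within d.
    """
    if not pairs:
        return None, None, None
    d = sorted(p.mode_distance for p in pairs)
    n = len(d)
    median = d[(n - 1) // 2]
    mean = sum(d) / n
    k = int(np.ceil(0.95 * n)) - 1
    p95 = d[max(k, 0)]
    return median, mean, p95


def peat_compatible_subset(
    peaks: Sequence[Peak5p],
    genes: Sequence[GeneModel],
    tss_window: int = 500,
    promoter_bp: int = 3000,
    three_prime_bp: int = 1000,
) -> List[Peak5p]:
    """Peaks at TSS/5'UTR or with mode within ``tss_window`` of an annotated
    TSS — the subset comparable to linker-ligation (PEAT-style) peak sets."""
    cats = categorize_peaks(peaks, genes, promoter_bp, three_prime_bp)
    out = []
    for p, c in zip(peaks, cats):
        if c.category in ("TSS", "FiveUTR"):
            out.append(p)
            continue
        if any(
            g.chrom == p.chrom and g.strand == p.strand and abs(p.mode - g.tss) <= tss_window
            for g in genes
        ):
            out.append(p)
    return out


def saturation_curve(
    alignments: Sequence[Alignment],
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    fractions: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 8)),
    seed: int = 0,
    min_reads: int = 10,
    max_gap: int = 20,
    min_capped_pct: float = 50.0,
) -> List[Tuple[float, int, int]]:
    """Genes with >= 1 high-confidence peak per read subsample fraction.

    Subsampling is without replacement, seeded. Each subsample is pushed
    through classification, peak calling and G'-filtering. Returns
    (fraction, reads used, genes with a filtered peak) per fraction.
    """
    rng = np.random.default_rng(seed)
    alns = list(alignments)
    out = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n = int(round(frac * len(alns)))
        idx = rng.choice(len(alns), size=n, replace=False) if n < len(alns) else np.arange(len(alns))
        subset = [alns[i] for i in sorted(idx)]
        calls = classify_alignments(subset, genome)
        raw_peaks = call_peaks(five_prime_positions(subset), min_reads, max_gap)
        filtered = g_filter(annotate_percent_capped(raw_peaks, calls), min_capped_pct)
        cats = categorize_peaks(filtered, genes)
        n_genes, _ = genes_with_peaks(cats)
        out.append((frac, n, n_genes))
    return out


def pairs_summary(
    peaks_a: Sequence[FilteredPeak],
    peaks_b: Sequence[FilteredPeak],
    total_a: int,
    total_b: int,
) -> Dict[str, object]:
    """Pair two libraries and report correlation plus mode-distance stats."""
    pairs = pair_peaks(peaks_a, peaks_b)
    rpm_a = rpm_normalize([p.peak_a.count for p in pairs], total_a)
    rpm_b = rpm_normalize([p.peak_b.count for p in pairs], total_b)
    rho = spearman_rho(rpm_a, rpm_b) if len(pairs) >= 3 else None
    median, mean, p95 = mode_distance_stats(pairs)
    return {
        "n_pairs": len(pairs),
        "spearman_rho": rho,
        "median_mode_distance": median,
        "mean_mode_distance": mean,
        "p95_mode_distance": p95,
    }
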