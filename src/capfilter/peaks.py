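"""Strand-specific clustering of read 5' ends into TSS peaks.

Transcription initiation is dispersed: reads from one promoter start over a
small run of neighbouring positions, so TSSs are called as *peaks* (read
clusters), not single bases. Positions on one (chrom, strand) are grouped by
single-linkage — neighbouring occupied positions at most ``max_gap`` nt
apart join one cluster — and clusters with at least ``min_reads`` member
reads (default 10) become peaks. Each peak records its *mode*, the most
frequently observed start position, with ties broken toward the 5'-most
position on the read strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .alignments import Alignment

PositionCounts = Dict[Tuple[str, str], Counter]


@dataclass(frozen=True)
class Peak5p:
    chrom: str
    strand: str
    start: int  # 0-based half-open interval over member 5' positions
    end: int
    count: int
    mode: int
    mode_count: int

    @property
    def five_prime_most(self) -> int:
        """The peak's 5'-most coordinate on its own strand."""
        return self.start if self.strand == "+" else self.end - 1

    def key(self) -> Tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


def five_prime_positions(alignments: Iterable[Alignment]) -> PositionCounts:
    """Count read 5' ends per (chrom, strand) position."""
    counts: PositionCounts = defaultdict(Counter)
    for aln in alignments:
        counts[(aln.chrom, aln.strand)][aln.five_prime] += 1
    return dict(counts)


def call_peaks(
    position_counts: PositionCounts,
    min_reads: int = 10,
    max_gap: int = 20,
) -> List[Peak5p]:
    """Single-linkage peak calling with a minimum-read cutoff.

    Deterministic given the counts; output sorted by (chrom, strand, start).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    peaks: List[Peak5p] = []
    for (chrom, strand), counter in sorted(position_counts.items()):
        positions = sorted(counter)
        cluster: List[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > max_gap:
                peak = _finalize(chrom, strand, cluster, counter, min_reads)
                if peak:
                    peaks.append(peak)
                cluster = []
            cluster.append(pos)
        if cluster:
            peak = _finalize(chrom, strand, cluster, counter, min_reads)
            if peak:
                peaks.append(peak)
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.start))
    return peaks


def _finalize(chrom, strand, cluster, counter, min_reads):
    total = sum(counter[p] for p in cluster)
    if total < min_reads:
        return None
    best = max(counter[p] for p in cluster)
    candidates = [p for p in cluster if counter[p] == best]
    # 5'-most tie-break on the read strand
    mode = min(candidates) if strand == "+" else max(candidates)
    return Peak5p(
        chrom=chrom,
        strand=strand,
        start=cluster[0],
        end=cluster[-1] + 1,
        count=total,
        mode=mode,
        mode_count=best,
    )


def peaks_to_frame(peaks: Iterable[Peak5p]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "name": f"peak_{i + 1}",
            "count": p.count,
            "strand": p.strand,
            "mode": p.mode,
            "mode_count": p.mode_count,
        }
        for i, p in enumerate(peaks)
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "count", "strand", "mode", "mode_count"],
    )


def frame_to_peaks(df: pd.DataFrame) -> List[Peak5p]:
    return [
        Peak5p(
            chrom=r.chrom,
            strand=r.strand,
            start=int(r.start),
            end=int(r.end),
            count=int(r.count),
            mode=int(r.mode),
            mode_count=int(r.mode_count),
        )
        for r in df.itertuples()
    ]
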