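"""G'-filtering: select peaks by their fraction of cap-signature reads.

For each peak, %-Capped is the percentage of member reads (those whose
aligned 5' end falls inside the peak interval on the peak's strand) whose
removed first base was an unencoded G. Peaks from capped mRNA carry a high
%-Capped; clusters of uncapped or artifactual reads do not, so thresholding
on %-Capped (default: at least 50%) enriches strongly for genuine TSS peaks
without discarding any reads.

Unencoded first bases other than G never count toward the numerator, and
indeterminate calls (contig-edge upstream base, or an N) are excluded from
numerator and denominator alike unless ``indeterminate_as_encoded`` is set.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .cap_tag import ENCODED, INDETERMINATE, UNENCODED, StartBaseCall
from .peaks import Peak5p


@dataclass(frozen=True)
class FilteredPeak(Peak5p):
    percent_capped: Optional[float] = None  # None when no informative member
    n_informative: int = 0


class _CallIndex:
    """Per-(chrom, strand) sorted positions with per-position tallies."""

    def __init__(self, calls: Iterable[StartBaseCall], indeterminate_as_encoded: bool):
        tallies: dict = defaultdict(lambda: defaultdict(lambda: [0, 0]))
        for c in calls:
            status = c.status
            if status == INDETERMINATE:
                if not indeterminate_as_encoded:
                    continue
                status = ENCODED
            cell = tallies[(c.chrom, c.strand)][c.position]
            cell[0] += 1  # informative
            if status == UNENCODED and c.removed_base == "G":
                cell[1] += 1  # unencoded G
        self._index = {}
        for key, by_pos in tallies.items():
            positions = sorted(by_pos)
            self._index[key] = (
                positions,
                [by_pos[p][0] for p in positions],
                [by_pos[p][1] for p in positions],
            )

    def tally(self, chrom: str, strand: str, start: int, end: int):
        """(informative members, unencoded-G members) with 5' end in [start, end)."""
        entry = self._index.get((chrom, strand))
        if entry is None:
            return 0, 0
        positions, informative, unenc_g = entry
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end - 1)
        return sum(informative[lo:hi]), sum(unenc_g[lo:hi])


def percent_capped(
    peak: Peak5p,
    calls: Sequence[StartBaseCall],
    indeterminate_as_encoded: bool = False,
) -> Optional[float]:
    """%-Capped of one peak, or None when no member call is informative."""
    idx = _CallIndex(calls, indeterminate_as_encoded)
    n, g = idx.tally(peak.chrom, peak.strand, peak.start, peak.end)
    return None if n == 0 else 100.0 * g / n


def annotate_percent_capped(
    peaks: Iterable[Peak5p],
    calls: Sequence[StartBaseCall],
    indeterminate_as_encoded: bool = False,
) -> List[FilteredPeak]:
    """Attach %-Capped and informative-member counts to every peak."""
    idx = _CallIndex(calls, indeterminate_as_encoded)
    out: List[FilteredPeak] = []
    for p in peaks:
        n, g = idx.tally(p.chrom, p.strand, p.start, p.end)
        out.append(
            FilteredPeak(
                chrom=p.chrom,
                strand=p.strand,
                start=p.start,
                end=p.end,
                count=p.count,
                mode=p.mode,
                mode_count=p.mode_count,
                percent_capped=(100.0 * g / n) if n else None,
                n_informative=n,
            )
        )
    return out


def g_filter(peaks: Iterable[FilteredPeak], min_percent: float = 50.0) -> List[FilteredPeak]:
    """Keep peaks whose %-Capped is at least ``min_percent`` (inclusive).

    Peaks without an informative member (percent_capped None) are kept only
    by the vacuous threshold 0, mirroring that a threshold of 0 rejects
    nothing.
    """
    if not 0 <= min_percent <= 100:
        raise ValueError("min_percent must lie in [0, 100]")
    out = []
    for p in peaks:
        if p.percent_capped is None:
            if min_percent == 0:
                out.append(p)
        elif p.percent_capped >= min_percent:
            out.append(p)
    return out


def filtered_peaks_to_frame(peaks: Iterable[FilteredPeak]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "name": f"peak_{i + 1}",
                "count": p.count,
                "strand": p.strand,
                "mode": p.mode,
                "mode_count": p.mode_count,
                # one decimal place keeps files diff-stable
                "pct_capped": "NA" if p.percent_capped is None else f"{p.percent_capped:.1f}",
                "n_informative": p.n_informative,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "count", "strand",
            "mode", "mode_count", "pct_capped", "n_informative",
        ],
    )


def frame_to_filtered_peaks(df: pd.DataFrame) -> List[FilteredPeak]:
    out = []
    for r in df.itertuples():
        pct = getattr(r, "pct_capped", "NA")
        out.append(
            FilteredPeak(
                chrom=r.chrom,
                strand=r.strand,
                start=int(r.start),
                end=int(r.end),
                count=int(r.count),
                mode=int(r.mode),
                mode_count=int(r.mode_count),
                percent_capped=None if str(pct) == "NA" else float(pct),
                n_informative=int(getattr(r, "n_informative", 0)),
            )
        )
    return out
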