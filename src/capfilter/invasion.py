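"""Strand-invasion artifact detection.

Template-switching oligos can anneal to complementary sequence inside an
RNA/cDNA molecule instead of the cap-adjacent cytosines, producing reads
whose 5' ends mark an internal site rather than a TSS. Such reads betray
themselves by genomic complementarity: the nine reference bases directly
upstream of the mapped 5' end resemble the last nine bases of the TS oligo.

A window matches when (a) its last three bases match at least
``min_g_matches`` of the oligo's three terminal Gs and (b) it has at most
``max_mismatch`` mismatches over all nine positions. The test is repeated
for windows shifted one to three steps up- and downstream of the 5' end
(seven windows in all); any match flags the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .alignments import Alignment
from .genome import ReferenceGenome

DEFAULT_OFFSETS: Tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)


@dataclass(frozen=True)
class InvasionCall:
    read_id: str
    flagged: bool
    triggering_offset: Optional[int] = None
    mismatches_at_offset: Optional[int] = None


def upstream_window(
    chrom: str,
    five_prime: int,
    strand: str,
    genome: ReferenceGenome,
    length: int = 9,
    offset: int = 0,
) -> Optional[str]:
    """Read-strand reference sequence ending just before the (shifted) 5' end.

    ``offset`` moves the notional 5' end along the read strand (negative =
    further upstream, i.e. further 5'). Returns None when the window runs
    off the contig.
    """
    if strand == "+":
        p = five_prime + offset
        return genome.fetch(chrom, p - length, p, "+")
    p = five_prime - offset
    return genome.fetch(chrom, p + 1, p + 1 + length, "-")


def window_matches_oligo(
    window9: str,
    oligo_tail9: str,
    max_mismatch: int = 2,
    min_g_matches: int = 2,
) -> bool:
    """Position-wise comparison of a 9-mer window to the oligo's last 9 nt."""
    if len(window9) != 9 or len(oligo_tail9) != 9:
        raise ValueError("window and oligo tail must both be 9 nt")
    if not oligo_tail9.upper().endswith("GGG"):
        raise ValueError("oligo tail must end in GGG")
    w = window9.upper()
    o = oligo_tail9.upper()
    g_matches = sum(1 for i in (6, 7, 8) if w[i] == o[i])
    mismatches = sum(1 for a, b in zip(w, o) if a != b)
    return g_matches >= min_g_matches and mismatches <= max_mismatch


def flag_strand_invasion(
    aln: Alignment,
    genome: ReferenceGenome,
    oligo_tail9: str,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    max_mismatch: int = 2,
    min_g_matches: int = 2,
) -> InvasionCall:
    """Flag one alignment if any offset window matches the oligo tail.

    The reported offset is the matching one of smallest magnitude, negative
    (upstream) first on ties. Windows falling off the contig count as
    non-matches.
    """
    matches = []
    for off in offsets:
        win = upstream_window(aln.chrom, aln.five_prime, aln.strand, genome, 9, off)
        if win is None or len(win) != 9:
            continue
        if window_matches_oligo(win, oligo_tail9, max_mismatch, min_g_matches):
            mm = sum(1 for a, b in zip(win.upper(), oligo_tail9.upper()) if a != b)
            matches.append((abs(off), off, mm))
    if not matches:
        return InvasionCall(read_id=aln.qname, flagged=False)
    matches.sort(key=lambda t: (t[0], t[1]))
    _, off, mm = matches[0]
    return InvasionCall(
        read_id=aln.qname, flagged=True, triggering_offset=off, mismatches_at_offset=mm
    )


def filter_invasion(
    alignments: Iterable[Alignment],
    genome: ReferenceGenome,
    oligo_tail9: str,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    max_mismatch: int = 2,
    min_g_matches: int = 2,
) -> Tuple[List[Alignment], List[InvasionCall]]:
    """Split alignments into (kept, all calls); flagged reads are dropped."""
    kept: List[Alignment] = []
    calls: List[InvasionCall] = []
    for aln in alignments:
        call = flag_strand_invasion(
            aln, genome, oligo_tail9, offsets, max_mismatch, min_g_matches
        )
        calls.append(call)
        if not call.flagged:
            kept.append(aln)
    return kept, calls


def flagged_ids(calls: Iterable[InvasionCall]) -> Set[str]:
    return {c.read_id for c in calls if c.flagged}
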