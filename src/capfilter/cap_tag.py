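"""Cap-signature tagging and start-base classification.

Reads derived from capped mRNA frequently begin with a guanosine that the
reverse transcriptase added opposite the cap — a base that is absent from
("unencoded in") the genome and can therefore prevent the most informative
reads from aligning. The remedy: remove each read's first base before
alignment while recording it in the read identifier, then, after alignment,
compare the removed base to the reference base immediately upstream of the
mapped 5' end. A removed base equal to that upstream base is *encoded*; a
removed G that differs is the cap signature (G').

Positions are 0-based internally; the mapped 5' end of a minus-strand read
is its highest aligned reference coordinate, and "upstream" always means one
step further 5' on the read strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from .alignments import Alignment
from .demux import FastqRecord
from .genome import ReferenceGenome

TAG_MARKER = "|CF="

ENCODED = "encoded"
UNENCODED = "unencoded"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TaggedRead:
    id: str  # original id + |CF=<base>:<qual>
    sequence: str
    quality: str


def tag_first_base(read: FastqRecord) -> Optional[TaggedRead]:
    """Move a read's first base (and its quality) into the identifier.

    Returns None for reads shorter than 2 nt, which cannot be tagged and
    still align. The tag contains no whitespace, so it survives the SAM
    qname field.
    """
    rid, seq, qual = read
    if len(seq) < 2:
        return None
    return TaggedRead(
        id=f"{rid}{TAG_MARKER}{seq[0]}:{qual[0]}",
        sequence=seq[1:],
        quality=qual[1:],
    )


def untag(tagged: TaggedRead) -> FastqRecord:
    """Exact inverse of tag_first_base."""
    rid, base, qual0 = parse_tag(tagged.id)
    return (rid, base + tagged.sequence, qual0 + tagged.quality)


def parse_tag(tagged_id: str) -> Tuple[str, str, str]:
    """Split a tagged identifier into (original id, removed base, quality char).

    Parsed from the right so original identifiers containing the marker
    earlier in the name are unaffected.
    """
    idx = tagged_id.rfind(TAG_MARKER)
    if idx < 0:
        raise ValueError(f"identifier carries no first-base tag: {tagged_id!r}")
    payload = tagged_id[idx + len(TAG_MARKER):]
    if len(payload) != 3 or payload[1] != ":":
        raise ValueError(f"malformed first-base tag in {tagged_id!r}")
    return tagged_id[:idx], payload[0], payload[2]


def tag_reads(reads: Iterable[FastqRecord]):
    """Tag a read stream; returns (tagged reads, number rejected as too short)."""
    tagged: List[TaggedRead] = []
    rejected = 0
    for read in reads:
        t = tag_first_base(read)
        if t is None:
            rejected += 1
        else:
            tagged.append(t)
    return tagged, rejected


@dataclass(frozen=True)
class StartBaseCall:
    read_id: str  # tagged qname as aligned
    removed_base: str
    status: str  # encoded | unencoded | indeterminate
    chrom: str
    position: int  # 0-based 5' end of the aligned (tagged) read
    strand: str

    @property
    def is_unencoded_g(self) -> bool:
        return self.status == UNENCODED and self.removed_base == "G"


def classify_start_base(aln: Alignment, genome: ReferenceGenome) -> StartBaseCall:
    """Classify the removed first base of one aligned, tagged read.

    The upstream reference base is taken one step in the 5' direction on the
    read strand (position - 1 on plus, position + 1 complemented on minus).
    The call is indeterminate when that base is unavailable (contig edge) or
    the removed base is N.
    """
    _, removed, _ = parse_tag(aln.qname)
    removed = removed.upper()
    p5 = aln.five_prime
    if aln.strand == "+":
        upstream = genome.base_at(aln.chrom, p5 - 1, "+")
    else:
        upstream = genome.base_at(aln.chrom, p5 + 1, "-")
    if upstream is None or removed == "N" or upstream == "N":
        status = INDETERMINATE
    elif removed == upstream:
        status = ENCODED
    else:
        status = UNENCODED
    return StartBaseCall(
        read_id=aln.qname,
        removed_base=removed,
        status=status,
        chrom=aln.chrom,
        position=p5,
        strand=aln.strand,
    )


def classify_alignments(
    alignments: Iterable[Alignment], genome: ReferenceGenome
) -> List[StartBaseCall]:
    return [classify_start_base(a, genome) for a in alignments]


def position_mismatch_profile(
    alignments: Iterable[Alignment],
    genome: ReferenceGenome,
    k: int = 2,
) -> pd.DataFrame:
    """Per-position, per-base fraction of reads mismatching the reference.

    Positions are numbered on the untrimmed read: position 1 is the removed
    first base (judged by its start-base call), positions >= 2 are aligned
    read bases compared directly to the reference. Returns a DataFrame
    indexed by position with columns A/C/G/T of mismatch fractions (NaN
    where no read shows that base at that position) plus an ``n_<base>``
    count column for each base.
    """
    mism: dict = defaultdict(lambda: defaultdict(int))
    totals: dict = defaultdict(lambda: defaultdict(int))
    warned_short = False
    for aln in alignments:
        call = classify_start_base(aln, genome)
        if call.status != INDETERMINATE and call.removed_base in "ACGT":
            totals[1][call.removed_base] += 1
            if call.status == UNENCODED:
                mism[1][call.removed_base] += 1
        step = 1 if aln.strand == "+" else -1
        upto = min(k, len(aln.seq) + 1)
        if upto < k:
            warned_short = True
        for pos in range(2, upto + 1):
            read_base = aln.seq[pos - 2].upper()
            if read_base not in "ACGT":
                continue
            gpos = aln.five_prime + step * (pos - 2)
            ref_base = genome.base_at(aln.chrom, gpos, aln.strand)
            if ref_base is None or ref_base == "N":
                continue
            totals[pos][read_base] += 1
            if read_base != ref_base:
                mism[pos][read_base] += 1
    if warned_short:
        import warnings

        warnings.warn("k exceeds some read lengths; profile truncated there")
    rows = []
    for pos in range(1, k + 1):
        row = {"position": pos}
        for base in "ACGT":
            n = totals[pos][base]
            row[base] = (mism[pos][base] / n) if n else float("nan")
            row[f"n_{base}"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def calls_to_frame(calls: Iterable[StartBaseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "removed_base": c.removed_base,
                "status": c.status,
                "chrom": c.chrom,
                "position": c.position,
                "strand": c.strand,
            }
            for c in calls
        ],
        columns=["read_id", "removed_base", "status", "chrom", "position", "strand"],
    )


def frame_to_calls(df: pd.DataFrame) -> List[StartBaseCall]:
    return [
        StartBaseCall(
            read_id=r.read_id,
            removed_base=r.removed_base,
            status=r.status,
            chrom=r.chrom,
            position=int(r.position),
            strand=r.strand,
        )
        for r in df.itertuples()
    ]
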