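"""A minimal alignment record plus SAM round-tripping via pysam.

The pipeline only needs each uniquely mapped read's 5' end, strand and
(read-strand) aligned sequence, so alignments are held as lightweight frozen
records rather than pysam objects. SAM input is restricted to primary,
mapped records; when an NH tag is present it must equal 1 ("uniquely mapped
reads" semantics). Soft-clipped prefix/suffix bases are dropped on read so
that ``seq`` always covers exactly the aligned reference span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping

import pysam

from .dna import revcomp


@dataclass(frozen=True)
class Alignment:
    """One uniquely mapped read.

    ``start`` is the 0-based leftmost reference coordinate; ``seq`` is the
    aligned portion of the read on the *read* strand (reverse-complemented
    relative to SAM storage for minus-strand reads).
    """

    qname: str
    chrom: str
    start: int
    strand: str  # "+" or "-"
    seq: str

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + len(self.seq)

    @property
    def five_prime(self) -> int:
        """0-based reference position of the read's 5'-most aligned base."""
        return self.start if self.strand == "+" else self.end - 1


def read_sam(path: str) -> List[Alignment]:
    """Load primary, uniquely mapped records from a SAM/BAM file."""
    out: List[Alignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                continue
            seq = rec.query_alignment_sequence
            if not seq:
                continue
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)
            out.append(
                Alignment(
                    qname=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand=strand,
                    seq=seq.upper(),
                )
            )
    return out


def write_sam(
    path: str,
    alignments: Iterable[Alignment],
    contig_lengths: Mapping[str, int],
    clipped_prefixes: Mapping[str, str] | None = None,
) -> None:
    """Write headered, coordinate-sorted SAM.

    ``clipped_prefixes`` optionally maps qname to extra 5' read-strand bases
    that do not derive from the reference; they are emitted as soft-clipped
    bases so the record faithfully reproduces what an aligner would report
    for a read carrying template-free additions.
    """
    clipped_prefixes = clipped_prefixes or {}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    order = {name: i for i, name in enumerate(contig_lengths)}
    recs = sorted(alignments, key=lambda a: (order[a.chrom], a.start))
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for aln in recs:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.qname
            clip = clipped_prefixes.get(aln.qname, "")
            read_seq = clip + aln.seq  # read-strand, 5'->3'
            cigar = []
            if clip:
                cigar.append((4, len(clip)))  # soft clip at read 5' end
            cigar.append((0, len(aln.seq)))
            if aln.strand == "-":
                rec.flag = 16
                rec.query_sequence = revcomp(read_seq)
                rec.cigartuples = list(reversed(cigar))
            else:
                rec.flag = 0
                rec.query_sequence = read_seq
                rec.cigartuples = cigar
            rec.reference_id = fh.header.get_tid(aln.chrom)
            rec.reference_start = aln.start
            rec.mapping_quality = 50
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(read_seq))
            rec.set_tag("NH", 1)
            fh.write(rec)
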