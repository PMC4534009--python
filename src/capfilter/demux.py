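"""Inline-barcode demultiplexing and template-switching oligo removal.

Reads from a 5'-end library begin with the TS oligo: an optional inline
barcode, an optional constant linker, and a G-tail (typically "GGG") that
annealed to template-free cytosines during reverse transcription. This
module assigns each read to a barcode by Hamming distance over the
barcode-length prefix, strips the full oligo prefix, and truncates reads to
a common length so libraries sequenced at different read lengths are
comparable.

Assignment rules: a read is assigned to the barcode with strictly fewest
mismatches, provided that count does not exceed ``max_mismatch`` (default 3).
Ties are unresolvable and reported as ambiguous. In single (non-barcoded)
mode the read must begin with the literal tail and only the tail is removed.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

from .dna import hamming

FastqRecord = Tuple[str, str, str]  # (id, sequence, quality)


@dataclass(frozen=True)
class BarcodeSpec:
    """One inline barcode: a label plus its fixed-length A/C/G/T sequence."""

    id: str
    sequence: str


def validate_barcode_set(specs: Sequence[BarcodeSpec]) -> int:
    """Check shared length and uniqueness; return the barcode length."""
    if not specs:
        raise ValueError("barcode set is empty")
    lengths = {len(s.sequence) for s in specs}
    if len(lengths) != 1:
        raise ValueError("all barcodes in a set must share one length")
    seqs = [s.sequence for s in specs]
    if len(set(seqs)) != len(seqs):
        raise ValueError("barcode sequences must be unique within a set")
    bad = [s.sequence for s in specs if set(s.sequence) - set("ACGT")]
    if bad:
        raise ValueError(f"barcodes must be A/C/G/T only: {bad}")
    return lengths.pop()


@dataclass(frozen=True)
class OligoLayout:
    """Structure of the TS-oligo prefix carried at read 5' ends.

    ``oligo_tail9`` (the last nine nucleotides of the full oligo) is what the
    strand-invasion filter compares genomic context against; it is derived
    from barcode + linker + tail when not given explicitly.
    """

    mode: str = "single"  # "single" or "barcoded"
    barcode_length: int = 0
    linker: Optional[str] = None
    tail: str = "GGG"

    def __post_init__(self):
        if self.mode not in ("single", "barcoded"):
            raise ValueError(f"unknown layout mode: {self.mode!r}")
        if not self.tail:
            raise ValueError("tail must be non-empty")
        if self.mode == "single" and self.barcode_length != 0:
            raise ValueError("single mode implies barcode_length = 0")
        if self.mode == "barcoded" and self.barcode_length < 1:
            raise ValueError("barcoded mode requires a positive barcode_length")

    @property
    def prefix_length(self) -> int:
        return self.barcode_length + len(self.linker or "") + len(self.tail)

    def oligo_tail9(self, barcode: str = "") -> str:
        """Last nine nucleotides of barcode + linker + tail (or fewer if short)."""
        full = barcode + (self.linker or "") + self.tail
        return full[-9:]


class Assignment(Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "unassigned_ambiguous"
    TOO_DISTANT = "unassigned_too_distant"
    NO_TAIL = "rejected_no_tail"


@dataclass(frozen=True)
class DemuxResult:
    assignment: Assignment
    barcode_id: Optional[str] = None
    mismatches: Optional[int] = None
    trimmed_sequence: Optional[str] = None
    trimmed_quality: Optional[str] = None


def assign_barcode(
    prefix: str, specs: Sequence[BarcodeSpec], max_mismatch: int = 3
) -> DemuxResult:
    """Assign a read prefix to the barcode with strictly fewest mismatches.

    Mismatches are Hamming distance over the barcode-length prefix (no
    indels); N counts as a mismatch. A tie at the fewest mismatches is
    ambiguous; a best distance above ``max_mismatch`` is too distant.
    """
    bc_len = validate_barcode_set(specs)
    if len(prefix) < bc_len:
        raise ValueError("prefix shorter than barcode length")
    head = prefix[:bc_len].upper()
    dists = [(hamming(head, s.sequence), s) for s in specs]
    best, best_spec = min(dists, key=lambda d: d[0])
    if best > max_mismatch:
        return DemuxResult(Assignment.TOO_DISTANT, mismatches=best)
    if sum(1 for d, _ in dists if d == best) > 1:
        return DemuxResult(Assignment.AMBIGUOUS, mismatches=best)
    return DemuxResult(Assignment.ASSIGNED, barcode_id=best_spec.id, mismatches=best)


def trim_oligo(
    read: FastqRecord, layout: OligoLayout, assignment: Optional[DemuxResult] = None
) -> DemuxResult:
    """Strip the TS-oligo prefix from an accepted read.

    Single mode demands a literal tail at the read start (the tail is the
    whole oligo there); barcoded mode removes barcode + linker + tail at
    fixed offsets, tolerating mismatches in the tail because acceptance was
    already decided by the barcode. Quality is trimmed in lockstep.
    """
    _, seq, qual = read
    if layout.mode == "single":
        if not seq.upper().startswith(layout.tail.upper()):
            return DemuxResult(Assignment.NO_TAIL)
        n = len(layout.tail)
        return DemuxResult(
            Assignment.ASSIGNED,
            mismatches=0,
            trimmed_sequence=seq[n:],
            trimmed_quality=qual[n:],
        )
    if assignment is None or assignment.assignment is not Assignment.ASSIGNED:
        raise ValueError("barcoded-mode trim requires an assigned barcode")
    n = layout.prefix_length
    if len(seq) < n:
        return DemuxResult(Assignment.NO_TAIL)
    return DemuxResult(
        Assignment.ASSIGNED,
        barcode_id=assignment.barcode_id,
        mismatches=assignment.mismatches,
        trimmed_sequence=seq[n:],
        trimmed_quality=qual[n:],
    )


def harmonize_length(read: FastqRecord, target_length: int) -> FastqRecord:
    """Truncate a read at the 3' end to ``target_length`` if longer."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    rid, seq, qual = read
    return (rid, seq[:target_length], qual[:target_length])


# ---------------------------------------------------------------------------
# FASTQ-level driver


@dataclass
class DemuxStats:
    per_class: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.per_class.values())


def demux_reads(
    reads: Iterable[FastqRecord],
    layout: OligoLayout,
    specs: Sequence[BarcodeSpec] = (),
    max_mismatch: int = 3,
    trim_to: Optional[int] = None,
) -> Tuple[dict, List[FastqRecord], DemuxStats]:
    """Partition reads into per-barcode bins plus one unassigned bin.

    Every input read lands in exactly one class. Returns
    ``(per-barcode reads, unassigned reads, stats)``; in single mode the
    accepted bin is keyed ``"single"``.
    """
    if layout.mode == "barcoded":
        bc_len = validate_barcode_set(specs)
        if bc_len != layout.barcode_length:
            raise ValueError("barcode length does not match layout")
        bins: dict = {s.id: [] for s in specs}
    else:
        bins = {"single": []}
    unassigned: List[FastqRecord] = []
    stats = DemuxStats()

    for read in reads:
        rid, seq, qual = read
        if layout.mode == "barcoded":
            if len(seq) < layout.barcode_length:
                stats.per_class[Assignment.TOO_DISTANT.value] += 1
                unassigned.append(read)
                continue
            assign = assign_barcode(seq, specs, max_mismatch=max_mismatch)
            if assign.assignment is not Assignment.ASSIGNED:
                stats.per_class[assign.assignment.value] += 1
                unassigned.append(read)
                continue
            trimmed = trim_oligo(read, layout, assign)
            key = assign.barcode_id
        else:
            trimmed = trim_oligo(read, layout)
            key = "single"
        if trimmed.assignment is not Assignment.ASSIGNED:
            stats.per_class[trimmed.assignment.value] += 1
            unassigned.append(read)
            continue
        out = (rid, trimmed.trimmed_sequence, trimmed.trimmed_quality)
        if trim_to is not None:
            out = harmonize_length(out, trim_to)
        bins[key].append(out)
        stats.per_class[key] += 1
    return bins, unassigned, stats


def read_fastq(handle: TextIO) -> List[FastqRecord]:
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(handle, "fastq")
    ]


def write_fastq(handle: TextIO, reads: Iterable[FastqRecord]) -> None:
    for rid, seq, qual in reads:
        handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def load_barcode_tsv(path: str) -> List[BarcodeSpec]:
    """Two-column TSV (id, sequence), no header."""
    specs = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            specs.append(BarcodeSpec(id=row[0], sequence=row[1].upper()))
    validate_barcode_set(specs)
    return specs


def write_demux_report(path: str, stats: DemuxStats) -> None:
    with open(path, "w") as fh:
        fh.write("class\treads\n")
        for name, n in sorted(stats.per_class.items()):
            fh.write(f"{name}\t{n}\n")
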