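"""Reference genome access with strand-aware base lookup.

Coordinates are 0-based half-open throughout. Lookups that fall outside a
contig return ``None`` rather than wrapping or raising, because downstream
callers (start-base classification, invasion windows) must treat a missing
upstream context as "indeterminate"/"no match", never as an error.
"""

from __future__ import annotations

from typing import Mapping, Optional

from pyfaidx import Fasta

from .dna import revcomp


class ReferenceGenome:
    """In-memory reference with read-strand base access.

    Parameters
    ----------
    sequences
        Mapping of contig name to uppercase nucleotide string.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def names(self):
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def lengths(self) -> dict:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> Optional[str]:
        """Read-strand sequence of [start, end), or None if out of bounds.

        On the minus strand the returned string is the reverse complement,
        i.e. it reads 5'->3' along the minus strand.
        """
        if chrom not in self._seqs:
            return None
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            return None
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub

    def base_at(self, chrom: str, pos: int, strand: str = "+") -> Optional[str]:
        """Single read-strand base at 0-based ``pos`` (complemented on minus)."""
        got = self.fetch(chrom, pos, pos + 1, strand)
        return got if got else None
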