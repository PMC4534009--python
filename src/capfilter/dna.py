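"""Small nucleotide-string helpers shared across the pipeline."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Position-wise mismatch count over two equal-length strings.

    N is treated as a mismatch against anything (including N), because an
    uncalled base gives no evidence of a match.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")
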