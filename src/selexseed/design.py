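"""Library design: the constant flanks around the random region.

An in-vivo SELEX library is a single-stranded DNA of fixed total length in
which a random region is bracketed by two constant primer-binding flanks.
Sequencing reads the sense strand, so the 3' constant region appears as the
reverse complement of the reverse primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class LibraryDesign:
    """Constant-flank layout of a selection library.

    Attributes
    ----------
    fw_flank
        5' constant region on the sense strand (the forward primer site).
    rv_flank_sense
        3' constant region on the sense strand, i.e. the reverse complement
        of the reverse primer.
    random_len
        Length of the variable region in nucleotides.
    """

    fw_flank: str
    rv_flank_sense: str
    random_len: int

    def __post_init__(self) -> None:
        for name, flank in (("fw_flank", self.fw_flank), ("rv_flank_sense", self.rv_flank_sense)):
            if not flank or not set(flank) <= DNA_ALPHABET:
                raise ValueError(f"{name} must be non-empty over A/C/G/T, got {flank!r}")
        if self.random_len < 1:
            raise ValueError("random_len must be >= 1")

    @property
    def total_len(self) -> int:
        return len(self.fw_flank) + self.random_len + len(self.rv_flank_sense)


FORWARD_PRIMER = "GCTGTGTGACTCCTGCAA"
REVERSE_PRIMER = "GGAGACAAGATACAGCTGC"

#: The D3/D3P library layout: 18-nt forward flank, 43-nt random region and a
#: 19-nt reverse flank (sense strand), 80 nt in total.
DEFAULT_DESIGN = LibraryDesign(
    fw_flank=FORWARD_PRIMER,
    rv_flank_sense=reverse_complement(REVERSE_PRIMER),
    random_len=43,
)
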