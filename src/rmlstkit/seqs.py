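"""Low-level nucleotide/codon utilities shared across the package.

All coordinates in this package are 0-based, half-open, on the forward
strand of the sequence they refer to unless stated otherwise.  The genetic
code is the bacterial/archaeal code (translation table 11); stop codons
translate to ``'*'``.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Translation table 11 (identical sense-codon assignments to the standard
# code; differs only in permitted start codons, which we track separately).
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*W"
          "LLLLPPPPHHQQRRRR"
          "IIIMTTTTNNKKSSRR"
          "VVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]

SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*"))

#: start codons permitted under table 11 (common bacterial starts)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codon dropped.

    Codons containing characters outside ACGT translate to ``'X'``.
    """
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


def six_frame_translate(seq: str) -> list[str]:
    """Peptides for frames +0,+1,+2,-0,-1,-2 (reverse frames on the
    reverse complement), stops rendered as ``'*'``."""
    seq = seq.upper()
    rc = reverse_complement(seq)
    return [translate(seq[f:]) for f in range(3)] + [translate(rc[f:]) for f in range(3)]


def has_internal_stop(seq: str) -> bool:
    """True if any codon before the final one is a stop codon."""
    seq = seq.upper()
    n = len(seq) - len(seq) % 3
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, n - 3, 3))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
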