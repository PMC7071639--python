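"""IUPAC nucleotide ambiguity codes and small sequence helpers."""

from __future__ import annotations

BASES = "ACGT"

# frozenset of plain bases -> single ambiguity letter
_SET_TO_CODE = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_CODE_TO_SET = {code: s for s, code in _SET_TO_CODE.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)


def iupac_code(bases) -> str:
    """Single-letter code for a non-empty set of plain bases A/C/G/T."""
    s = frozenset(bases)
    if not s or not s <= frozenset(BASES):
        raise ValueError(f"not a set of plain bases: {bases!r}")
    return _SET_TO_CODE[s]


def expand_iupac(code: str) -> frozenset:
    """Set of plain bases encoded by a single IUPAC letter ('N' -> all four)."""
    try:
        return _CODE_TO_SET[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def is_iupac(code: str) -> bool:
    return code.upper() in _CODE_TO_SET


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
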