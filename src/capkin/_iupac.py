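"""IUPAC nucleotide ambiguity codes and strand operations."""

from __future__ import annotations

IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
IUPAC_COMPLEMENT: dict[str, str] = {
    code: BASES_TO_IUPAC[frozenset(_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_TO_BASES.items()
}

GAP_SYMBOLS = frozenset("-.")


def ambiguity_code(bases: set[str] | frozenset[str]) -> str:
    """Single-letter IUPAC code for a non-empty set of A/C/G/T bases."""
    key = frozenset(bases)
    if key not in BASES_TO_IUPAC:
        raise ValueError(f"not a valid base set: {sorted(bases)}")
    return BASES_TO_IUPAC[key]


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot reverse-complement symbol {exc.args[0]!r}") from None
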