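"""IUPAC nucleotide ambiguity codes.

Sanger consensus sequences from pooled or heterozygous templates encode a
heterozygous base call as the single IUPAC letter for the observed allele
set (e.g. ``S`` = {G, C}).  Every module in this package that touches
nucleotide data shares the expansion tables defined here.
"""

from __future__ import annotations

#: IUPAC code -> set of concrete bases.
EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: allele set -> IUPAC code.
CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in EXPANSION.items()}

#: Complement map covering every ambiguity code.
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

#: Missing-data code used in allele matrices; distinct from N.
MISSING = "."

IUPAC_DNA_CHARS = frozenset(EXPANSION) | {"-"}
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX-*")


def expand(code: str) -> frozenset[str]:
    """Return the set of concrete bases a single IUPAC code stands for.

    The missing-data code ``.`` expands to the empty set.
    """
    if code == MISSING:
        return frozenset()
    try:
        return EXPANSION[code]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(alleles: frozenset[str] | set[str]) -> str:
    """Return the IUPAC code for a non-empty set of concrete bases."""
    key = frozenset(alleles)
    try:
        return CODE_FOR[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for allele set {sorted(key)}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement honoring ambiguity codes."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None


def pattern_matches(pattern_char: str, base: str) -> bool:
    """True if a consensus symbol admits the observed base.

    Match semantics are subset containment: the pattern symbol's allele set
    must cover every base the sequence character could be.
    """
    return expand(base) <= expand(pattern_char)
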