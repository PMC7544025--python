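"""Protein-level comparisons: translation, global alignment, residue checks.

The methyltransferase (SAMT) and methylesterase (SABP2) families carry
well-characterized functional residues -- the Ser/Asp/His catalytic triad of
the esterase and the cofactor-binding motif of the methyltransferase.
``check_residues`` verifies such annotations across an aligned family by
mapping reference residue indices through the reference row's gaps.

The pairwise aligner is a Needleman-Wunsch / Gotoh dynamic program with
affine gap penalties, reporting identity and query-relative coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .core_io import Alignment


@dataclass
class ResidueAnnotation:
    """Expected residues at 1-based positions of a reference sequence."""

    name: str
    reference_id: str
    positions: list[int]
    expected_residues: list[str]
    kind: str = "binding_residue"  # catalytic_triad | binding_residue | motif_span

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.expected_residues):
            raise ValueError("positions and expected residues differ in length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("annotation positions must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "ResidueAnnotation":
        raw = yaml.safe_load(open(path))
        sites = raw["sites"]
        return cls(
            name=raw["name"],
            reference_id=raw["reference"],
            positions=[s["pos"] for s in sites],
            expected_residues=[s["aa"] for s in sites],
            kind=raw.get("kind", "binding_residue"),
        )


@dataclass
class PairwiseResult:
    identity_pct: float
    coverage_pct: float
    aligned_length: int
    score: float
    aligned_a: str = ""
    aligned_b: str = ""


def translate(cds: str, frame: int = 0, allow_internal_stop: bool = False) -> str:
    """Translate a coding sequence with the standard genetic code.

    The trailing stop codon is dropped; an internal stop raises unless
    ``allow_internal_stop``, in which case it becomes ``X``.  Any trailing
    partial codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = cds.upper()[frame:]
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-DNA characters in CDS: {sorted(bad)}")
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    aa: list[str] = []
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    for k, codon in enumerate(codons):
        if codon in stops:
            if k == len(codons) - 1:
                break
            if not allow_internal_stop:
                raise ValueError(f"internal stop codon at codon {k + 1}")
            aa.append("X")
        else:
            aa.append(table[codon])
    return "".join(aa)


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {name!r}") from None


def global_align(
    a: str,
    b: str,
    substitution: str | dict = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseResult:
    """Affine-gap global alignment (Gotoh) of two protein sequences.

    ``gap_open`` is the cost of the first residue of a gap; each further
    residue costs ``gap_extend``.  Traceback ties prefer the diagonal, then
    the vertical (gap in ``b``) move, making the reported alignment
    deterministic.  Identity is matches over columns excluding terminal
    gaps; coverage is the fraction of query (``a``) residues inside the
    non-terminal-gap region, BLAST-style.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    if isinstance(substitution, str):
        matrix = _load_matrix(substitution)
        score_of = lambda x, y: float(matrix[x, y])  # noqa: E731
    else:
        score_of = lambda x, y: float(substitution[(x, y)] if (x, y) in substitution
                                      else substitution[(y, x)])  # noqa: E731
    n, m = len(a), len(b)
    neg = -np.inf
    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a (consumes b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_of(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    score = max(M[n, m], X[n, m], Y[n, m])

    # Traceback; tie preference diagonal (M) > up (X) > left (Y).
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = "M" if M[i, j] == score else ("X" if X[i, j] == score else "Y")
    while i > 0 or j > 0:
        if state == "M":
            s = score_of(a[i - 1], b[j - 1])
            prev = M[i, j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = "M" if M[i, j] == prev else ("X" if X[i, j] == prev else "Y")
        elif state == "X":
            val = X[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            if i - 1 == 0 and j == 0:
                i -= 1
                break
            if M[i - 1, j] + gap_open == val:
                state = "M"
            elif X[i - 1, j] + gap_extend == val:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            val = Y[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            if j - 1 == 0 and i == 0:
                j -= 1
                break
            if M[i, j - 1] + gap_open == val:
                state = "M"
            elif Y[i, j - 1] + gap_extend == val:
                state = "Y"
            else:
                state = "X"
            j -= 1
    aln_a = "".join(reversed(out_a))
    aln_b = "".join(reversed(out_b))

    cols = len(aln_a)
    first = 0
    while first < cols and (aln_a[first] == "-" or aln_b[first] == "-"):
        first += 1
    last = cols - 1
    while last >= 0 and (aln_a[last] == "-" or aln_b[last] == "-"):
        last -= 1
    core = range(first, last + 1)
    matches = sum(aln_a[k] == aln_b[k] for k in core)
    n_core = max(len(core), 0)
    identity = 100.0 * matches / n_core if n_core else 0.0
    covered_query = sum(aln_a[k] != "-" for k in core)
    coverage = 100.0 * covered_query / len(a)
    return PairwiseResult(
        identity_pct=identity, coverage_pct=coverage, aligned_length=cols,
        score=float(score), aligned_a=aln_a, aligned_b=aln_b,
    )


def map_reference_positions(reference_row: str, positions: list[int]) -> list[int]:
    """Map 1-based residue indices of an ungapped reference to 1-based
    alignment columns of its gapped row."""
    cols: list[int] = []
    residue = 0
    want = iter(sorted(positions))
    target = next(want, None)
    for col, ch in enumerate(reference_row, start=1):
        if ch == "-":
            continue
        residue += 1
        while target is not None and residue == target:
            cols.append(col)
            target = next(want, None)
    if target is not None:
        raise ValueError(f"annotation position {target} beyond reference length {residue}")
    return cols


def check_residues(alignment: Alignment, annotation: ResidueAnnotation):
    """Verify expected residues across an aligned protein family.

    Returns a pandas DataFrame indexed by sequence id with one boolean
    column per annotated reference position plus ``n_conserved``.
    """
    import pandas as pd

    ref = alignment[annotation.reference_id]
    cols = map_reference_positions(ref.residues, annotation.positions)
    rows = {}
    for rec in alignment.records:
        passes = [
            rec.residues[c - 1] == exp
            for c, exp in zip(cols, annotation.expected_residues)
        ]
        rows[rec.id] = passes + [sum(passes)]
    colnames = [f"pos{p}{aa}" for p, aa in zip(annotation.positions, annotation.expected_residues)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=colnames + ["n_conserved"])
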