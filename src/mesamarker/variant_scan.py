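"""Group-diagnostic SNP discovery from IUPAC consensus calls.

The central question: at which positions does one group of individuals
carry an allele that no individual of the other group carries?  Because the
input is Sanger consensus data, a heterozygous individual is a single IUPAC
code, and "carries allele a" means a is in the code's expansion -- so a
high-producer called ``S`` carries the diagnostic ``C`` even though the low
group is fixed for ``G``.

A marker's *penetrance* is the fraction of target-group individuals that
carry the diagnostic allele; the threshold theta formalizes how prominent a
group-specific substitution must be before it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from . import iupac
from .core_io import AlleleMatrix, Alignment, Individual

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AlleleCall:
    """One decoded IUPAC call."""

    code: str
    alleles: frozenset[str]
    zygosity: str  # homozygous | heterozygous | missing
    uninformative: bool = False  # N (all four bases) or missing

    def carries(self, base: str) -> bool:
        return base in self.alleles


def expand_iupac(code: str) -> AlleleCall:
    """Decode a single IUPAC character (or ``.``) into an allele call.

    ``N`` is formally heterozygous (all four bases) but flagged
    uninformative: it can neither support nor defeat a diagnostic allele.
    """
    alleles = iupac.expand(code)  # raises on non-IUPAC input
    if not alleles:
        return AlleleCall(code=code, alleles=alleles, zygosity="missing", uninformative=True)
    zygosity = "homozygous" if len(alleles) == 1 else "heterozygous"
    return AlleleCall(code=code, alleles=alleles, zygosity=zygosity,
                      uninformative=(code == "N"))


@dataclass
class DiagnosticMarker:
    """A position whose allele separates the target group from the contrast."""

    position: int
    diagnostic_allele: str
    target_group: str
    carrier_count_target: int
    n_target: int
    carrier_count_contrast: int
    n_contrast: int
    penetrance: float
    contrast_fixed_allele: str | None = None
    n_uninformative: int = 0

    def __post_init__(self) -> None:
        if self.carrier_count_contrast != 0:
            raise ValueError("a diagnostic allele must be absent from the contrast group")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance outside [0, 1]")


@dataclass
class ClassificationResult:
    individual_id: str
    votes_for_target: int
    panel_size: int
    covered: int
    verdict: str  # target | contrast | ambiguous

    def __post_init__(self) -> None:
        if not 0 <= self.votes_for_target <= self.panel_size:
            raise ValueError("vote count outside [0, panel size]")


def alignment_to_matrix(
    alignment: Alignment,
    positions: list[int] | None = None,
) -> AlleleMatrix:
    """Collapse a nucleotide alignment into an allele matrix.

    Without an explicit position list, only polymorphic columns are kept: a
    column is polymorphic when the union of expanded alleles across
    non-missing calls contains more than one base.  Gaps are recorded as
    missing calls.
    """
    if alignment.moltype != "dna":
        raise ValueError("allele matrices are defined for nucleotide alignments only")
    individuals = [
        Individual(id=r.id, species_code=r.species_code, group=r.group)
        for r in alignment.records
    ]
    if positions is None:
        positions = []
        for pos in range(1, alignment.length + 1):
            alleles: set[str] = set()
            for ch in alignment.column(pos):
                if ch not in ("-", iupac.MISSING):
                    alleles |= iupac.expand(ch)
            if len(alleles) > 1:
                positions.append(pos)
    calls = []
    for pos in positions:
        row = [ch if ch != "-" else iupac.MISSING for ch in alignment.column(pos)]
        calls.append(row)
    return AlleleMatrix(positions=list(positions), individuals=individuals, calls=calls)


def heterozygosity_profile(
    matrix: AlleleMatrix,
    group: str | None = None,
    species: str | None = None,
) -> dict:
    """Count heterozygous calls per position within a group or species subset.

    Returns per-position counts, the grand total, and the set of positions
    with at least one heterozygous call.  ``N`` calls are counted separately
    as uninformative, not as heterozygous evidence.
    """
    if group is not None and species is not None:
        raise ValueError("give either a group or a species subset, not both")
    idx = matrix.individual_indices(group=group, species=species)
    if not idx:
        label = group if group is not None else species
        raise ValueError(f"no individuals match subset {label!r}")
    per_position: dict[int, int] = {}
    uninformative = 0
    for pos, row in zip(matrix.positions, matrix.calls):
        count = 0
        for j in idx:
            call = expand_iupac(row[j])
            if call.uninformative:
                uninformative += call.zygosity != "missing"
            elif call.zygosity == "heterozygous":
                count += 1
        per_position[pos] = count
    return {
        "per_position": per_position,
        "total": sum(per_position.values()),
        "het_positions": {p for p, c in per_position.items() if c > 0},
        "n_uninformative_calls": uninformative,
        "n_individuals": len(idx),
    }


def find_diagnostic_snps(
    matrix: AlleleMatrix,
    target_group: str = "high",
    theta: float = 0.9,
    require_contrast_fixed: bool = True,
    contrast_group: str | None = None,
) -> list[DiagnosticMarker]:
    """Scan every (position, allele) pair for group-diagnostic SNPs.

    An allele a is diagnostic for the target group at a position iff

    1. no contrast individual carries a (N and missing calls excluded as
       uninformative),
    2. the fraction of informative target individuals carrying a is >= theta,
    3. optionally, all informative contrast calls are one homozygous base.

    At most one marker per position is returned (highest penetrance, ties
    broken alphabetically), sorted by position.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    groups = matrix.groups()
    if target_group not in groups:
        raise ValueError(f"no individuals in target group {target_group!r}")
    if contrast_group is None:
        candidates = sorted(groups - {target_group, "unassigned"})
        if len(candidates) != 1:
            raise ValueError(
                f"contrast group is ambiguous ({candidates}); pass contrast_group explicitly"
            )
        contrast_group = candidates[0]
    t_idx = matrix.individual_indices(group=target_group)
    c_idx = matrix.individual_indices(group=contrast_group)
    if not c_idx:
        raise ValueError(f"no individuals in contrast group {contrast_group!r}")

    markers: list[DiagnosticMarker] = []
    for pos, row in zip(matrix.positions, matrix.calls):
        t_calls = [expand_iupac(row[j]) for j in t_idx]
        c_calls = [expand_iupac(row[j]) for j in c_idx]
        t_inf = [c for c in t_calls if not c.uninformative]
        c_inf = [c for c in c_calls if not c.uninformative]
        n_uninf = (len(t_calls) - len(t_inf)) + (len(c_calls) - len(c_inf))
        if not t_inf or not c_inf:
            continue
        contrast_fixed: str | None = None
        c_allele_union = frozenset().union(*(c.alleles for c in c_inf))
        if len(c_allele_union) == 1:
            contrast_fixed = next(iter(c_allele_union))
        if require_contrast_fixed and contrast_fixed is None:
            continue
        best: DiagnosticMarker | None = None
        for allele in BASES:  # alphabetical order = deterministic tie-break
            if any(c.carries(allele) for c in c_inf):
                continue
            carriers = sum(c.carries(allele) for c in t_inf)
            penetrance = carriers / len(t_inf)
            if penetrance < theta:
                continue
            if best is None or penetrance > best.penetrance:
                best = DiagnosticMarker(
                    position=pos,
                    diagnostic_allele=allele,
                    target_group=target_group,
                    carrier_count_target=carriers,
                    n_target=len(t_inf),
                    carrier_count_contrast=0,
                    n_contrast=len(c_inf),
                    penetrance=penetrance,
                    contrast_fixed_allele=contrast_fixed,
                    n_uninformative=n_uninf,
                )
        if best is not None:
            markers.append(best)
    return markers


def classify_individual(
    panel: list[DiagnosticMarker],
    calls: Mapping[int, str],
    individual_id: str = "query",
    min_covered: int = 3,
) -> ClassificationResult:
    """Vote a new individual against a marker panel.

    Each covered panel position contributes one vote iff the individual's
    call carries the diagnostic allele.  Majority of covered positions
    decides; an exact tie or fewer than ``min_covered`` covered positions is
    ambiguous.
    """
    if not panel:
        raise ValueError("empty marker panel")
    votes = 0
    covered = 0
    for marker in panel:
        code = calls.get(marker.position)
        if code is None:
            continue
        call = expand_iupac(code)
        if call.zygosity == "missing":
            continue
        covered += 1
        if call.carries(marker.diagnostic_allele):
            votes += 1
    if covered == 0:
        raise ValueError("calls cover no panel position")
    if covered < min_covered or votes * 2 == covered:
        verdict = "ambiguous"
    elif votes * 2 > covered:
        verdict = "target"
    else:
        verdict = "contrast"
    return ClassificationResult(
        individual_id=individual_id, votes_for_target=votes,
        panel_size=len(panel), covered=covered, verdict=verdict,
    )
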