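"""Readers and writers for the formats the pipeline touches.

Covers multi-record FASTA (via Biopython), the tab-separated allele matrix
of per-individual IUPAC consensus calls, newick trees, run configuration
and simple TSV/JSON result reports.  Positions and alignment columns are
1-based in every user-facing structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import iupac
from .tree import Tree, read_newick, write_newick  # noqa: F401  (re-exported)

GROUPS = ("high", "low", "unassigned")

#: Species -> MeSA-production group used throughout the study system:
#: yellow/cherry birches and relatives are constitutive (high) producers,
#: silver birch and relatives are low producers.
DEFAULT_SPECIES_GROUPS: dict[str, str] = {
    "ale": "high",  # B. alleghaniensis
    "len": "high",  # B. lenta
    "bg": "high",   # B. grossa
    "med": "high",  # B. medwediewii
    "pen": "low",   # B. pendula
    "uti": "low",   # B. utilis
    "nan": "low",   # B. nana
    "aln": "low",   # B. alnoides
}


@dataclass
class SequenceRecord:
    """A labeled nucleotide or protein sequence."""

    id: str
    residues: str
    species_code: str = ""
    group: str = "unassigned"
    moltype: str = "dna"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.group not in GROUPS:
            raise ValueError(f"record {self.id!r}: unknown group {self.group!r}")
        self.residues = self.residues.upper()
        alphabet = iupac.IUPAC_DNA_CHARS if self.moltype == "dna" else iupac.PROTEIN_CHARS
        for offset, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.moltype} character "
                    f"{ch!r} at offset {offset}"
                )

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """Equal-length sequence records; columns are addressed 1-based."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        if self.length < 1:
            raise ValueError("zero-length alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def moltype(self) -> str:
        return self.records[0].moltype

    def column(self, pos: int) -> str:
        """1-based column as a string, one character per record."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} out of range 1..{self.length}")
        return "".join(r.residues[pos - 1] for r in self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass(frozen=True)
class Individual:
    id: str
    species_code: str
    group: str


@dataclass
class AlleleMatrix:
    """Positions x individuals grid of single IUPAC consensus calls.

    ``.`` marks missing data and is distinct from ``N`` (an uninformative
    call covering all four bases).
    """

    positions: list[int]
    individuals: list[Individual]
    calls: list[list[str]]  # calls[i][j]: position i, individual j

    VALID_CALLS = frozenset(iupac.EXPANSION) | {iupac.MISSING}

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        if len(self.calls) != len(self.positions):
            raise ValueError("row count != number of positions")
        for pos, row in zip(self.positions, self.calls):
            if len(row) != len(self.individuals):
                raise ValueError(f"ragged row at position {pos}")
            for ind, call in zip(self.individuals, row):
                if call not in self.VALID_CALLS:
                    raise ValueError(
                        f"non-IUPAC call {call!r} at position {pos}, individual {ind.id}"
                    )

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def call(self, position: int, individual_id: str) -> str:
        i = self.positions.index(position)
        j = [ind.id for ind in self.individuals].index(individual_id)
        return self.calls[i][j]

    def individual_indices(self, *, group: str | None = None, species: str | None = None) -> list[int]:
        out = []
        for j, ind in enumerate(self.individuals):
            if group is not None and ind.group != group:
                continue
            if species is not None and ind.species_code != species:
                continue
            out.append(j)
        return out

    def column_calls(self, individual_id: str) -> dict[int, str]:
        """All calls of one individual, keyed by position."""
        j = [ind.id for ind in self.individuals].index(individual_id)
        return {pos: row[j] for pos, row in zip(self.positions, self.calls)}

    def groups(self) -> set[str]:
        return {ind.group for ind in self.individuals}


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``penetrance_threshold`` formalizes how prominent a group-specific
    substitution must be: the minimum fraction of target-group individuals
    that must carry the diagnostic allele.
    """

    penetrance_threshold: float = 0.9
    require_contrast_fixed: bool = True
    motif_dictionary_path: str | None = None
    reference_genes: list[str] = field(default_factory=lambda: ["actin", "ubiquitin"])
    rng_seed: int = 0
    species_groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SPECIES_GROUPS))

    def __post_init__(self) -> None:
        if not 0 < self.penetrance_threshold <= 1:
            raise ValueError("penetrance_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _species_and_group(name: str, species_map: Mapping[str, str] | None) -> tuple[str, str]:
    prefix = name.split("_")[0]
    if species_map and prefix in species_map:
        return prefix, species_map[prefix]
    return (prefix if species_map is not None else ""), "unassigned"


def read_fasta(
    path: str | Path,
    moltype: str = "dna",
    species_map: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    When ``species_map`` is given, each record's species code is taken from
    the header prefix (up to the first ``_``) and its group looked up in the
    map; headers without a mapped prefix stay unassigned.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        species, group = _species_and_group(rec.id, species_map)
        records.append(
            SequenceRecord(
                id=rec.id, residues=str(rec.seq), species_code=species,
                group=group, moltype=moltype,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_allele_matrix(
    path: str | Path,
    species_groups: Mapping[str, str] | None = None,
) -> AlleleMatrix:
    """Read a TSV allele matrix: header ``pos<TAB>id1<TAB>id2...``, one row
    per 1-based position, one IUPAC character (or ``.``) per cell.

    Individual ids are expected as ``<species>_<index>``; group membership
    comes from ``species_groups`` (default: the standard high/low birch
    assignment).
    """
    if species_groups is None:
        species_groups = DEFAULT_SPECIES_GROUPS
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"allele matrix {path} needs a header and >=1 position row")
    header = lines[0].split("\t")
    ids = header[1:]
    individuals = []
    for ind_id in ids:
        species = ind_id.split("_")[0]
        individuals.append(
            Individual(id=ind_id, species_code=species,
                       group=species_groups.get(species, "unassigned"))
        )
    positions: list[int] = []
    calls: list[list[str]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"ragged row in {path}: {ln[:40]!r}")
        positions.append(int(cells[0]))
        calls.append([c.strip().upper() for c in cells[1:]])
    return AlleleMatrix(positions=positions, individuals=individuals, calls=calls)


def write_allele_matrix(matrix: AlleleMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(ind.id for ind in matrix.individuals) + "\n")
        for pos, row in zip(matrix.positions, matrix.calls):
            fh.write(f"{pos}\t" + "\t".join(row) + "\n")


def load_table2_matrix() -> AlleleMatrix:
    """The packaged esterase-gene SNP validation matrix.

    The published table reports per-species genotype counts at six SNP
    positions over 38 individuals (20 high / 18 low producers); the fixture
    expands the count notation into one column per individual.
    """
    ref = resources.files("mesamarker.data").joinpath("table2_sabp2.tsv")
    with resources.as_file(ref) as p:
        return read_allele_matrix(p)


def default_motifs_path() -> Path:
    ref = resources.files("mesamarker.data").joinpath("motifs.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def write_report(results: Mapping[str, object], path: str | Path) -> None:
    """Write a JSON result report (lists of dicts also land as TSV siblings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_tsv(rows: Iterable[Mapping[str, object]], path: str | Path, columns: Sequence[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
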