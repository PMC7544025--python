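"""Synthetic data generators with known ground truth.

Every pipeline stage can be exercised without downloads: a gene-family
generator plants group-diagnostic substitutions (with heterozygous IUPAC
consensus codes) on a constant coding background, a promoter generator
plants cis-element instances into motif-free background, and a Ct-table
generator produces qPCR readings from chosen true expression levels.

Defaults emulate the study conditions: 38 individuals from eight birch
species (20 high / 18 low MeSA producers), a 792 bp esterase-like CDS with
six planted diagnostic positions, heterozygosity concentrated in the high
group, promoters of a few hundred bp, and expression assayed in leaf and
bark with three biological x three technical replicates.

Which individuals carry a planted allele (and which of those are
heterozygous) is assigned deterministically so that penetrance is hit
exactly; only background substitutions and Ct noise consume random draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import iupac
from .core_io import DEFAULT_SPECIES_GROUPS, SequenceRecord
from .promoter_scan import MotifPattern, scan

BASES = ("A", "C", "G", "T")

#: individuals per species, mirroring the validation panel.
DEFAULT_SPECIES_COUNTS: dict[str, int] = {
    "ale": 6, "len": 6, "bg": 4, "med": 4,
    "pen": 6, "uti": 4, "nan": 4, "aln": 4,
}

DEFAULT_PLANTED: list[tuple[int, str, str]] = [
    (160, "C", "G"),
    (189, "A", "G"),
    (262, "T", "A"),
    (298, "G", "A"),
    (304, "G", "T"),
    (336, "A", "G"),
]
DEFAULT_PENETRANCE: list[float] = [1.0, 0.95, 0.95, 0.9, 0.95, 1.0]


@dataclass
class GeneFamilyTruth:
    """Ground truth for one simulated candidate-gene family."""

    planted_positions: list[tuple[int, str, str]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED))
    planted_penetrance: list[float] = field(
        default_factory=lambda: list(DEFAULT_PENETRANCE))
    het_rate_high: float = 0.5
    het_rate_low: float = 0.0
    # Non-diagnostic polymorphism in these amplicons is scarce (the observed
    # validation matrix contains no SNPs beyond the diagnostic ones), so the
    # default background substitution rate is low: ~0.4 substitutions per
    # 792 bp consensus, i.e. ~15 segregating background sites across the
    # 38-individual panel -- still more variation than the validation data
    # shows in this region.
    background_mutation_rate: float = 0.0005
    cds_length: int = 792
    species_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS))
    species_groups: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_GROUPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.planted_positions) != len(self.planted_penetrance):
            raise ValueError("one penetrance per planted position")
        for pos, hi, lo in self.planted_positions:
            if not 1 <= pos <= self.cds_length:
                raise ValueError(f"planted position {pos} outside 1..{self.cds_length}")
            if hi == lo or hi not in BASES or lo not in BASES:
                raise ValueError(f"invalid allele pair at {pos}: {hi}/{lo}")
        if any(not 0 < p <= 1 for p in self.planted_penetrance):
            raise ValueError("penetrance must be in (0, 1]")
        for rate in (self.het_rate_high, self.het_rate_low):
            if not 0 <= rate < 1:
                raise ValueError("het rates must be in [0, 1)")
        if not 0 <= self.background_mutation_rate < 1:
            raise ValueError("background mutation rate must be in [0, 1)")

    @property
    def n_high(self) -> int:
        return sum(n for sp, n in self.species_counts.items()
                   if self.species_groups.get(sp) == "high")

    @property
    def n_low(self) -> int:
        return sum(n for sp, n in self.species_counts.items()
                   if self.species_groups.get(sp) == "low")

    def individuals(self) -> list[tuple[str, str, str]]:
        out = []
        for sp, n in self.species_counts.items():
            grp = self.species_groups.get(sp, "unassigned")
            out.extend((f"{sp}_{i}", sp, grp) for i in range(1, n + 1))
        return out


def gen_gene_family(truth: GeneFamilyTruth) -> list[SequenceRecord]:
    """One IUPAC consensus sequence per individual, from planted truth.

    At each planted position the first ``round(penetrance * n_high)`` high
    individuals carry the high allele; ``round(het_rate_high * carriers)``
    of the carriers are heterozygous (IUPAC code of {high, low}), with the
    heterozygous block rotated across positions so that -- as in real
    consensus data -- every individual mixes heterozygous and homozygous
    diagnostic calls rather than being heterozygous everywhere.  Low
    individuals are fixed for the low allele except for ``het_rate_low``
    leakage.  All other sites start from a shared random background with
    independent per-individual substitutions.
    """
    rng = np.random.default_rng(truth.seed)
    background = rng.choice(BASES, size=truth.cds_length)
    planted_sites = {pos for pos, _, _ in truth.planted_positions}
    individuals = truth.individuals()
    high_ids = [i for i, (_, _, g) in enumerate(individuals) if g == "high"]
    low_ids = [i for i, (_, _, g) in enumerate(individuals) if g == "low"]

    seqs = [background.copy().astype(object) for _ in individuals]

    # Background substitutions (stochastic), never at planted sites.
    for s in seqs:
        hits = np.nonzero(rng.random(truth.cds_length) < truth.background_mutation_rate)[0]
        for site in hits:
            if site + 1 in planted_sites:
                continue
            alt = [b for b in BASES if b != s[site]]
            s[site] = alt[rng.integers(len(alt))]

    for site_index, ((pos, hi, lo), pen) in enumerate(
        zip(truth.planted_positions, truth.planted_penetrance)
    ):
        het_code = iupac.code_for({hi, lo})
        n_high = len(high_ids)
        n_carriers = round(pen * n_high)
        if n_carriers < 1:
            raise ValueError(f"penetrance {pen} yields no carriers at position {pos}")
        # Rotate the non-carrier block across positions: real panels spread
        # non-carrying individuals over positions instead of stacking every
        # exception onto the same individual.
        nc_start = (site_index * max(n_high - n_carriers, 1)) % n_high
        non_carriers = {high_ids[(nc_start + k) % n_high]
                        for k in range(n_high - n_carriers)}
        carriers = [idx for idx in high_ids if idx not in non_carriers]
        n_het = round(truth.het_rate_high * n_carriers)
        offset = (site_index * n_het) % n_carriers
        het_set = {carriers[(offset + k) % n_carriers] for k in range(n_het)}
        for idx in carriers:
            seqs[idx][pos - 1] = het_code if idx in het_set else hi
        for idx in non_carriers:
            seqs[idx][pos - 1] = lo
        n_low_het = round(truth.het_rate_low * len(low_ids))
        for k, idx in enumerate(low_ids):
            seqs[idx][pos - 1] = het_code if k < n_low_het else lo

    return [
        SequenceRecord(id=ind_id, residues="".join(s), species_code=sp,
                       group=grp, moltype="dna")
        for (ind_id, sp, grp), s in zip(individuals, seqs)
    ]


@dataclass(frozen=True)
class PlantedMotif:
    species: str
    motif_name: str
    position: int  # forward-coordinate start of the instance
    strand: str


def _motif_free_background(length: int, patterns: Sequence[MotifPattern],
                           rng: np.random.Generator) -> str:
    """Random sequence rejected-and-patched until no pattern matches."""
    seq = list(rng.choice(BASES, size=length))
    for _ in range(200):
        hits = scan("".join(seq), patterns)
        if not hits:
            return "".join(seq)
        for h in hits:
            k = len(h.matched_substring)
            for off in range(k):
                seq[h.position - 1 + off] = BASES[rng.integers(4)]
    raise RuntimeError("could not generate motif-free background; sequence too short?")


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(sorted(iupac.expand(c))[rng.integers(len(iupac.expand(c)))]
                   for c in consensus)


def gen_promoters(
    planted_counts: Mapping[str, Mapping[str, int]],
    patterns: Sequence[MotifPattern],
    length: int = 700,
    seed: int = 0,
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Per-species promoter sequences with planted cis-element instances.

    ``planted_counts`` maps species -> {motif name -> instance count}.  The
    background is filtered so it contains no match to any pattern in the
    dictionary; planted instances are placed without overlap on a random
    strand each, and all are recorded in the returned truth list.  Each
    species' sequence is verified by rescanning (junction windows around an
    insertion can create incidental matches) and regenerated until its hit
    counts equal the planted counts exactly, so frequency tables reproduce
    the planted design.
    """
    rng = np.random.default_rng(seed)
    by_name = {p.name: p for p in patterns}
    promoters: dict[str, str] = {}
    truth: list[PlantedMotif] = []
    for species in planted_counts:
        wanted = {m: c for m, c in planted_counts[species].items() if c > 0}
        total_len = sum(len(by_name[m]) * c for m, c in wanted.items())
        if total_len > length // 2:
            raise ValueError(f"{species}: requested motif instances do not fit")
        for _regen in range(100):
            seq, placed = _plant_one_species(species, wanted, by_name, patterns,
                                             length, rng)
            observed: dict[str, int] = {}
            for hit in scan(seq, patterns):
                observed[hit.motif_name] = observed.get(hit.motif_name, 0) + 1
            if observed == wanted:
                break
        else:
            raise RuntimeError(f"{species}: could not plant motifs without "
                               "incidental extra matches")
        promoters[species] = seq
        truth.extend(placed)
    truth.sort(key=lambda t: (t.species, t.position, t.strand))
    return promoters, truth


def _plant_one_species(species, wanted, by_name, patterns, length, rng):
    seq = list(_motif_free_background(length, patterns, rng))
    max_k = max((len(p) for p in patterns), default=0)
    occupied: list[tuple[int, int]] = []  # 0-based [start, end)
    placed: list[PlantedMotif] = []
    for motif_name in sorted(wanted):
        pattern = by_name[motif_name]
        k = len(pattern)
        for _ in range(wanted[motif_name]):
            for _attempt in range(1000):
                start = int(rng.integers(0, length - k + 1))
                lo = max(start - max_k, 0)
                hi = start + k + max_k
                if all(e <= lo or s >= hi for s, e in occupied):
                    break
            else:
                raise ValueError(f"{species}: no room to plant {motif_name}")
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _instantiate(pattern.consensus, rng)
            insert = instance if strand == "+" else iupac.reverse_complement(instance)
            seq[start:start + k] = list(insert)
            occupied.append((start, start + k))
            placed.append(PlantedMotif(species=species, motif_name=motif_name,
                                       position=start + 1, strand=strand))
    return "".join(seq), placed


@dataclass
class ExpressionTruth:
    """True expression levels behind a simulated qPCR experiment.

    Levels are relative to the reference genes (level 1.0).  The default
    scenario mirrors the study design: the methyltransferase is strongly
    expressed in the bark of the two high producers, with an 8-fold
    bark/leaf contrast in one of them, and weakly expressed in the two low
    producers.
    """

    levels: dict[tuple[str, str, str], float] = field(default_factory=lambda: {
        ("ale", "bark", "SAMT"): 8.0,
        ("ale", "leaf", "SAMT"): 6.0,
        ("len", "bark", "SAMT"): 8.0,
        ("len", "leaf", "SAMT"): 1.0,
        ("pen", "bark", "SAMT"): 0.5,
        ("pen", "leaf", "SAMT"): 0.5,
        ("uti", "bark", "SAMT"): 0.5,
        ("uti", "leaf", "SAMT"): 0.5,
    })
    reference_genes: list[str] = field(default_factory=lambda: ["actin", "ubiquitin"])
    noise_sd: float = 0.3
    n_bio: int = 3
    n_tech: int = 3
    base_ref_ct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.levels.values()):
            raise ValueError("expression levels must be positive")
        if self.noise_sd < 0 or self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("invalid replicate/noise settings")


def gen_ct_table(truth: ExpressionTruth) -> pd.DataFrame:
    """Simulate a replicated Ct table from true expression levels.

    Each technical replicate reads Ct = base_ref_ct - log2(level) +
    Normal(0, noise_sd); reference genes sit at level 1.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    conditions = sorted({(sp, ti) for sp, ti, _ in truth.levels})
    genes_by_condition = {
        (sp, ti): sorted(g for s, t, g in truth.levels if (s, t) == (sp, ti))
        for sp, ti in conditions
    }
    for sp, ti in conditions:
        genes = genes_by_condition[(sp, ti)] + truth.reference_genes
        for bio in range(1, truth.n_bio + 1):
            sample = f"{sp}_{ti}_b{bio}"
            for gene in genes:
                level = truth.levels.get((sp, ti, gene), 1.0)
                true_ct = truth.base_ref_ct - float(np.log2(level))
                for tech in range(1, truth.n_tech + 1):
                    ct = true_ct + rng.normal(0.0, truth.noise_sd)
                    rows.append({"sample": sample, "species": sp, "tissue": ti,
                                 "gene": gene, "rep": tech, "ct": round(ct, 4)})
    return pd.DataFrame(rows)
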