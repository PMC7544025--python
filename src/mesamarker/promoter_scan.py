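"""Consensus-pattern scanning of promoter sequences.

Scans both strands of ungapped promoter sequences against a small editable
dictionary of cis-element consensus strings (TATA-box, CAAT-box, ABRE,
G-box, ...) written with IUPAC ambiguity codes, and tabulates per-species
hit counts for comparison between high and low producer groups.  Hits are
reported in the compact ``<position><strand>`` notation, e.g. ``74+``:
1-based start on the forward coordinate system plus the matched strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import iupac


@dataclass(frozen=True)
class MotifPattern:
    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = set(self.consensus.upper()) - set(iupac.EXPANSION)
        if bad:
            raise ValueError(f"motif {self.name!r}: non-IUPAC symbols {sorted(bad)}")
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int  # 1-based start of the match span in forward coordinates
    strand: str    # '+' or '-'
    matched_substring: str  # sequence content read 5'->3' on the hit strand

    @property
    def notation(self) -> str:
        return f"{self.position}{self.strand}"


@dataclass
class MotifFrequencyTable:
    counts: pd.DataFrame          # species x motif hit counts
    group_totals: pd.DataFrame    # group x motif summed counts
    differences: pd.DataFrame     # motifs whose group mean counts differ


def load_motifs(path: str | Path) -> list[MotifPattern]:
    raw = yaml.safe_load(Path(path).read_text())
    entries = raw["motifs"] if isinstance(raw, dict) else raw
    return [MotifPattern(name=e["name"], consensus=e["consensus"]) for e in entries]


def _forward_hits(seq: str, pattern: MotifPattern) -> list[int]:
    k = len(pattern)
    cons = pattern.consensus
    out = []
    for start in range(len(seq) - k + 1):
        window = seq[start:start + k]
        if all(iupac.pattern_matches(p, b) for p, b in zip(cons, window)):
            out.append(start + 1)
    return out


def scan(seq: str, patterns: Sequence[MotifPattern]) -> list[MotifHit]:
    """All consensus matches on both strands of an ungapped DNA sequence.

    Minus-strand hits are reported at the forward-coordinate start of the
    matched span; overlapping hits are all kept.  Sorted by position, then
    strand ('+' before '-'), then motif name.
    """
    seq = seq.upper()
    if "-" in seq or iupac.MISSING in seq:
        raise ValueError("promoter scanning requires an ungapped sequence")
    bad = set(seq) - set(iupac.EXPANSION)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    L = len(seq)
    rc = iupac.reverse_complement(seq)
    hits: list[MotifHit] = []
    for pat in patterns:
        k = len(pat)
        for p in _forward_hits(seq, pat):
            hits.append(MotifHit(pat.name, p, "+", seq[p - 1:p - 1 + k]))
        for q in _forward_hits(rc, pat):
            # start q on the reverse strand spans forward positions
            # [L - q - k + 2, L - q + 1]; report the span start.
            p = L - q - k + 2
            hits.append(MotifHit(pat.name, p, "-", rc[q - 1:q - 1 + k]))
    hits.sort(key=lambda h: (h.position, h.strand, h.motif_name))
    return hits


def frequency_table(
    promoters: Mapping[str, str],
    patterns: Sequence[MotifPattern],
    groups: Mapping[str, str],
) -> MotifFrequencyTable:
    """Per-species motif hit counts with group totals and group contrasts.

    ``promoters`` maps species code -> promoter sequence; ``groups`` maps
    species code -> group name.  The differences table lists, per motif, the
    mean count in each group and their difference, keeping motifs whose
    group means differ.
    """
    if not promoters:
        raise ValueError("no promoter sequences given")
    motif_names = [p.name for p in patterns]
    rows = {}
    for species in promoters:
        hit_counts = {name: 0 for name in motif_names}
        for hit in scan(promoters[species], patterns):
            hit_counts[hit.motif_name] += 1
        rows[species] = hit_counts
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=list(promoters), columns=motif_names, fill_value=0
    ).astype(int)
    counts.index.name = "species"

    group_of = pd.Series({sp: groups.get(sp, "unassigned") for sp in counts.index})
    group_totals = counts.groupby(group_of).sum()
    group_totals.index.name = "group"

    group_means = counts.groupby(group_of).mean()
    diffs = []
    if len(group_means) >= 2:
        gnames = sorted(group_means.index)
        g0, g1 = gnames[0], gnames[1]
        for motif in motif_names:
            m0, m1 = group_means.loc[g0, motif], group_means.loc[g1, motif]
            if m0 != m1:
                diffs.append({"motif": motif, f"mean_{g0}": m0, f"mean_{g1}": m1,
                              "difference": m0 - m1})
    differences = pd.DataFrame(diffs)
    return MotifFrequencyTable(counts=counts, group_totals=group_totals,
                               differences=differences)
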