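import numpy as np
import pytest

from mesamarker.core_io import AlleleMatrix, Individual, load_table2_matrix

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


@pytest.fixture(scope="session")
def table2():
    return load_table2_matrix()


def make_matrix(rows: dict[int, str], groups: str) -> AlleleMatrix:
    """Build a small allele matrix from {position: call-string}.

    ``groups`` is one character per individual: 'h' (high) or 'l' (low).
    """
    n = len(groups)
    individuals = [
        Individual(id=f"i{j}", species_code=f"sp{j}",
                   group={"h": "high", "l": "low"}[g])
        for j, g in enumerate(groups)
    ]
    positions = sorted(rows)
    calls = [list(rows[p]) for p in positions]
    assert all(len(row) == n for row in calls)
    return AlleleMatrix(positions=positions, individuals=individuals, calls=calls)


def brute_force_diagnostic(matrix, target_group, theta, require_contrast_fixed):
    """Independent oracle: enumerate every (position, allele) pair directly.

    Uses its own IUPAC table and straightforward counting; returns
    {position: best allele} with the same tie rule (max penetrance, then
    alphabetical) stated for the scanner.
    """
    target = [j for j, ind in enumerate(matrix.individuals) if ind.group == target_group]
    contrast = [j for j, ind in enumerate(matrix.individuals)
                if ind.group not in (target_group, "unassigned")]
    result = {}
    for i, pos in enumerate(matrix.positions):
        row = matrix.calls[i]
        t_calls = [row[j] for j in target if row[j] != "." and row[j] != "N"]
        c_calls = [row[j] for j in contrast if row[j] != "." and row[j] != "N"]
        if not t_calls or not c_calls:
            continue
        if require_contrast_fixed:
            union = set()
            for c in c_calls:
                union |= IUPAC_SETS[c]
            if len(union) != 1:
                continue
        best = None
        for allele in "ACGT":
            if any(allele in IUPAC_SETS[c] for c in c_calls):
                continue
            pen = sum(allele in IUPAC_SETS[c] for c in t_calls) / len(t_calls)
            if pen >= theta and (best is None or pen > best[1]):
                best = (allele, pen)
        if best:
            result[pos] = best[0]
    return result


def random_matrix(rng: np.random.Generator, max_positions=10, n_individuals=12) -> AlleleMatrix:
    codes = list(IUPAC_SETS) + ["."]
    n_pos = int(rng.integers(1, max_positions + 1))
    groups = "".join(rng.choice(["h", "l"], size=n_individuals - 2).tolist()) + "hl"
    rows = {}
    pos = 0
    for _ in range(n_pos):
        pos += int(rng.integers(1, 50))
        rows[pos] = "".join(rng.choice(codes, size=n_individuals).tolist())
    return make_matrix(rows, groups)
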