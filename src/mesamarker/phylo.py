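"""Distance-based phylogeny: p-distance, neighbor joining, bootstrap.

The group-level question in this study system is topological -- do the high
and low MeSA producers fall into two clades? -- so the module computes
uncorrected p-distances, builds a neighbor-joining tree (exact on additive
matrices), attaches column-resampling bootstrap supports, and tests group
monophyly in the unrooted sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import iupac
from .core_io import Alignment
from .tree import Tree, TreeNode

GAPLIKE = {"-", iupac.MISSING}


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("non-zero diagonal")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")


#: 4-bit allele masks (A=1, C=2, G=4, T=8) per IUPAC code; 0 = gap/missing.
_CODE_MASK = {"-": 0, iupac.MISSING: 0}
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
for _code, _alleles in iupac.EXPANSION.items():
    _CODE_MASK[_code] = sum(_BASE_BIT[b] for b in _alleles)
#: distinct ordinal per code so strict mode can compare literally.
_CODE_ORD = {c: k for k, c in enumerate(sorted(_CODE_MASK))}


def _encode(alignment: Alignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Alignment -> (allele bitmask matrix, literal-code matrix, labels)."""
    if alignment.moltype != "dna":
        raise ValueError("p-distance is defined on nucleotide alignments here")
    masks = np.array([[_CODE_MASK[c] for c in r.residues] for r in alignment.records],
                     dtype=np.uint8)
    ords = np.array([[_CODE_ORD[c] for c in r.residues] for r in alignment.records],
                    dtype=np.uint8)
    return masks, ords, [r.id for r in alignment.records]


def _distances_from_encoding(masks: np.ndarray, ords: np.ndarray,
                             labels: list[str], strict: bool) -> DistanceMatrix:
    n = masks.shape[0]
    d = np.zeros((n, n))
    valid = masks != 0
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        if strict:
            differ = (ords[i] != ords[i + 1:]) & both
        else:
            differ = ((masks[i] & masks[i + 1:]) == 0) & both
        compared = both.sum(axis=1)
        zero = np.nonzero(compared == 0)[0]
        if zero.size:
            j = int(zero[0]) + i + 1
            raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
        d[i, i + 1:] = d[i + 1:, i] = differ.sum(axis=1) / compared
    return DistanceMatrix(labels=list(labels), d=d)


def p_distance(alignment: Alignment, strict: bool = False) -> DistanceMatrix:
    """Uncorrected pairwise distance: mismatches / compared sites.

    Columns where either sequence has a gap or missing call are deleted
    pairwise.  By default, ambiguity codes match whenever their expansions
    overlap (a heterozygous R is compatible with A); ``strict`` compares
    codes literally, so a heterozygous consensus call counts as differing
    from a homozygote.
    """
    masks, ords, labels = _encode(alignment)
    return _distances_from_encoding(masks, ords, labels, strict)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Deterministic: the minimal Q pair is chosen in (row, column) index order
    of the current label list, which itself follows input order; negative
    branch lengths are clamped to zero.  The returned tree is unrooted,
    represented with a degree-3 root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        q[np.tril_indices(m)] = np.inf
        # argmin scans row-major, so ties resolve to the first (i, j) pair
        # in current node order -- deterministic for a fixed input order.
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # Closed form for the final three branches around the central node.
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))
    return Tree(TreeNode(children=[a, b, c]))


def bootstrap_support(alignment: Alignment, n_reps: int = 100,
                      seed: int = 0, strict: bool = False) -> Tree:
    """Column-resampling bootstrap for the NJ tree.

    Builds the tree on the full alignment, then resamples columns with
    replacement ``n_reps`` times; each internal edge's support is the
    percentage of replicate trees containing the same bipartition.
    Zero-length internal edges in a replicate are unresolved splits and do
    not count as containment (so identical sequences support nothing).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if alignment.length < 2:
        raise ValueError("alignment too short to bootstrap")
    masks, ords, labels = _encode(alignment)
    main = neighbor_joining(_distances_from_encoding(masks, ords, labels, strict))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in main.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        try:
            rep_dm = _distances_from_encoding(masks[:, cols], ords[:, cols], labels, strict)
            rep_tree = neighbor_joining(rep_dm)
        except ValueError:
            continue  # degenerate replicate (e.g. a pair with no comparable sites)
        rep_bps = rep_tree.bipartitions(min_length=1e-12)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(main.leaf_names())
    for node in main.iter_nodes():
        if node is main.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        bp = frozenset({side, all_leaves - side})
        if bp in counts:
            node.support = 100.0 * counts[bp] / n_reps
    return main


def is_group_monophyletic(tree: Tree, group_labels) -> tuple[bool, frozenset | None]:
    """Test whether one edge separates exactly ``group_labels`` from the rest."""
    leaves = set(tree.leaf_names())
    group = set(group_labels)
    unknown = group - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    bp = tree.find_bipartition(group)
    return (bp is not None), bp
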