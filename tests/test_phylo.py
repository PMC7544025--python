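"""p-distance, neighbor joining (vs additive-tree oracle), bootstrap,
monophyly."""

import numpy as np
import pytest

from mesamarker.core_io import Alignment, SequenceRecord
from mesamarker.phylo import (
    DistanceMatrix,
    bootstrap_support,
    is_group_monophyletic,
    neighbor_joining,
    p_distance,
)
from mesamarker.tree import read_newick


def dna_alignment(seqs: dict[str, str], groups: dict[str, str] | None = None) -> Alignment:
    groups = groups or {}
    return Alignment([
        SequenceRecord(id=k, residues=v, group=groups.get(k, "unassigned"))
        for k, v in seqs.items()
    ])


# ---------------------------------------------------------------- oracle ---

def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree; returns (labels, distance matrix,
    bipartition set) computed by direct path summation, independent of the
    package's tree machinery."""
    labels = [f"t{k}" for k in range(n_leaves)]
    # adjacency with branch lengths; start from a 3-star, attach leaves to
    # random edges through new internal nodes
    next_node = n_leaves  # internal ids from n_leaves upward
    edges: dict[tuple[int, int], float] = {}

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    def del_edge(u, v):
        del edges[(min(u, v), max(u, v))]

    def blen():
        return float(rng.uniform(0.5, 3.0))

    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, blen())
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        w = edges[(u, v)]
        split = float(rng.uniform(0.25, 0.75)) * w
        mid = next_node
        next_node += 1
        del_edge(u, v)
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(leaf, mid, blen())

    # all-pairs leaf distances by BFS over the weighted tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]

    # true bipartitions: for every internal edge, leaves on one side
    bps = set()
    for (u, v) in edges:
        blocked = {(u, v), (v, u)}
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(labels[x])
            for y, _ in adj[x]:
                if (x, y) not in blocked and y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n_leaves - 2:
            other = frozenset(labels) - frozenset(side)
            bps.add(frozenset({frozenset(side), frozenset(other)}))
    return labels, d, bps


def tree_leaf_distances(tree, labels):
    """Path-length matrix of a Tree, via parent maps (test-local)."""
    parents = {}
    for node in tree.iter_nodes():
        for child in node.children:
            parents[id(child)] = node
    by_name = {n.name: n for n in tree.iter_nodes() if n.is_leaf}

    def path_to_root(node):
        out = []
        while id(node) in parents:
            out.append(node)
            node = parents[id(node)]
        return out

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(by_name[labels[i]])
            pj = path_to_root(by_name[labels[j]])
            seti = {id(x) for x in pi}
            setj = {id(x) for x in pj}
            total = sum(x.length for x in pi if id(x) not in setj)
            total += sum(x.length for x in pj if id(x) not in seti)
            d[i, j] = d[j, i] = total
    return d


# ----------------------------------------------------------------- tests ---

class TestPDistance:
    def test_identical_sequences(self):
        dm = p_distance(dna_alignment({"a": "ACGT", "b": "ACGT"}))
        assert dm.d[0, 1] == 0.0

    def test_single_mismatch(self):
        dm = p_distance(dna_alignment({"a": "AAAA", "b": "AAAT"}))
        assert dm.d[0, 1] == 0.25

    def test_ambiguity_overlap_vs_strict(self):
        aln = dna_alignment({"a": "ASAA", "b": "ACAA"})
        assert p_distance(aln, strict=False).d[0, 1] == 0.0
        assert p_distance(aln, strict=True).d[0, 1] == 0.25

    def test_pairwise_deletion_of_gaps(self):
        dm = p_distance(dna_alignment({"a": "A-GT", "b": "ACGA"}))
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="no comparable sites"):
            p_distance(dna_alignment({"a": "--AA", "b": "AA--"}))

    def test_symmetry_and_self_identity(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGTRYSWKM"), size=30))
                for i in range(5)}
        dm = p_distance(dna_alignment(seqs))
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(labels=["a", "b", "c"],
                            d=np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.]]))
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 4.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1.5,(c:3,d:4)) -> known path distances
        d = np.array([
            [0, 3, 5.5, 6.5],
            [3, 0, 6.5, 7.5],
            [5.5, 6.5, 0, 7],
            [6.5, 7.5, 7, 0.],
        ])
        tree = neighbor_joining(DistanceMatrix(labels=list("abcd"), d=d))
        assert tree.bipartitions() == {
            frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})
        }
        got = tree_leaf_distances(tree, list("abcd"))
        assert np.allclose(got, d)

    def test_random_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            labels, d, true_bps = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
            assert tree.bipartitions() == true_bps
            assert np.allclose(tree_leaf_distances(tree, labels), d, atol=1e-9)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(7)
        labels, d, _ = random_additive_tree(rng, 6)
        t1 = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        perm = rng.permutation(6)
        t2 = neighbor_joining(DistanceMatrix(
            labels=[labels[k] for k in perm], d=d[np.ix_(perm, perm)]))
        assert t1.bipartitions() == t2.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0, 1], [2, 0.]]))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))


class TestBootstrap:
    @staticmethod
    def separated_alignment(n_cols_diag=12, seed=0):
        """Two 4-taxon groups separated by many diagnostic columns."""
        rng = np.random.default_rng(seed)
        L = 60
        base = rng.choice(list("ACGT"), size=L)
        cols = rng.choice(L, size=n_cols_diag, replace=False)
        seqs = {}
        for k in range(4):
            s = base.copy()
            seqs[f"g1_{k}"] = "".join(s)
        for k in range(4):
            s = base.copy()
            for c in cols:
                s[c] = "T" if base[c] != "T" else "A"
            seqs[f"g2_{k}"] = "".join(s)
        # a private substitution per taxon so distances are not degenerate
        out = {}
        free = [c for c in range(L) if c not in set(cols)]
        for i, (k, s) in enumerate(seqs.items()):
            s = list(s)
            c = free[i]
            s[c] = "C" if s[c] != "C" else "G"
            out[k] = "".join(s)
        return dna_alignment(out)

    def test_clear_separation_gets_high_support(self):
        aln = self.separated_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        group = {f"g1_{k}" for k in range(4)}
        mono, bp = is_group_monophyletic(tree, group)
        assert mono
        supports = {}
        all_leaves = frozenset(tree.leaf_names())
        for node in tree.iter_nodes():
            if node is tree.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            supports[frozenset({side, all_leaves - side})] = node.support
        assert supports[bp] >= 95

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = self.separated_alignment()
        tree = bootstrap_support(aln, n_reps=1, seed=3)
        values = [n.support for n in tree.iter_nodes()
                  if n.support is not None]
        assert values and set(values) <= {0.0, 100.0}

    def test_identical_sequences_support_nothing(self):
        aln = dna_alignment({f"s{i}": "ACGTACGT" for i in range(5)})
        tree = bootstrap_support(aln, n_reps=20, seed=0)
        assert all((n.support or 0.0) == 0.0 for n in tree.iter_nodes()
                   if n.support is not None)

    def test_fixed_seed_reproducible(self):
        from mesamarker.tree import write_newick
        aln = self.separated_alignment()
        t1 = bootstrap_support(aln, n_reps=30, seed=11)
        t2 = bootstrap_support(aln, n_reps=30, seed=11)
        assert write_newick(t1) == write_newick(t2)


class TestMonophyly:
    TREE = read_newick("((a:1,b:1):1,(c:1,d:1):1);")

    def test_true_group(self):
        mono, bp = is_group_monophyletic(self.TREE, {"a", "b"})
        assert mono and frozenset({"a", "b"}) in bp

    def test_false_group(self):
        mono, bp = is_group_monophyletic(self.TREE, {"a", "c"})
        assert not mono and bp is None

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            is_group_monophyletic(self.TREE, {"zzz"})
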