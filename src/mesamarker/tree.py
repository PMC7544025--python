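"""Minimal phylogenetic tree container with newick I/O.

Trees produced by neighbor joining are unrooted; they are represented here
with an arbitrary root node of degree three (the last join).  Bipartitions
and monophyly are always evaluated in the unrooted sense, so the placement
of that root never affects results.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name] if self.name is not None else []
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class Tree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def bipartitions(self, min_length: float | None = None) -> set[frozenset[frozenset[str]]]:
        """All non-trivial bipartitions induced by internal edges.

        Each bipartition is the unordered pair {side, complement} as a
        frozenset of two frozensets, which makes comparison independent of
        rooting and leaf order.  With ``min_length``, edges at or below that
        length are treated as unresolved (collapsed) and contribute nothing.
        """
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.iter_nodes():
            if node is self.root or node.is_leaf:
                continue
            if min_length is not None and (node.length or 0.0) <= min_length:
                continue
            side = frozenset(node.leaf_names())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset({side, other}))
        return out

    def find_bipartition(self, group: set[str]):
        """Return the bipartition separating ``group`` from the rest, if any.

        Also checks trivial splits (single leaf / rest), so a one-member
        group is reported as separable.
        """
        all_leaves = frozenset(self.leaf_names())
        target = frozenset(group)
        if target == all_leaves - target or not target:
            return None
        if len(target) == 1 or len(all_leaves - target) == 1:
            return frozenset({target, all_leaves - target})
        for bp in self.bipartitions():
            if target in bp:
                return bp
        return None


def _format_length(x: float) -> str:
    return repr(float(x))


def _node_newick(node: TreeNode, *, with_support: bool) -> str:
    if node.is_leaf:
        label = node.name or ""
    else:
        inner = ",".join(_node_newick(c, with_support=with_support) for c in node.children)
        label = f"({inner})"
        if with_support and node.support is not None:
            label += f"{node.support:g}"
        elif node.name:
            label += node.name
    if node.length is not None:
        label += f":{_format_length(node.length)}"
    return label


def write_newick(tree: Tree, *, with_support: bool = True) -> str:
    """Serialize to a newick string with branch lengths.

    Internal-node support values, when present, are written as internal
    labels in the conventional ``(...)support:length`` position.
    """
    if tree is None or tree.root is None or (tree.root.is_leaf and tree.root.name is None):
        raise ValueError("cannot serialize an empty tree")
    if not tree.leaf_names():
        raise ValueError("cannot serialize an empty tree")
    return _node_newick(tree.root, with_support=with_support) + ";"


class _NewickParser:
    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def parse(self) -> Tree:
        if not self.text or self.text == ";":
            raise ValueError("empty newick string")
        root = self.parse_node()
        if self.peek() != ";":
            raise ValueError(f"expected ';' at offset {self.pos}")
        return Tree(root)

    def parse_node(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.take()
            node.children.append(self.parse_node())
            while self.peek() == ",":
                self.take()
                node.children.append(self.parse_node())
            if self.take() != ")":
                raise ValueError("unbalanced parentheses in newick string")
            label = self.parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            node.name = self.parse_label()
            if not node.name:
                raise ValueError(f"expected leaf label at offset {self.pos}")
        if self.peek() == ":":
            self.take()
            node.length = float(self.parse_label())
        return node

    def parse_label(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in "(),:;":
            self.take()
        return self.text[start:self.pos].strip()


def read_newick(text: str) -> Tree:
    """Parse a newick string (labels, branch lengths, numeric supports)."""
    return _NewickParser(text).parse()
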