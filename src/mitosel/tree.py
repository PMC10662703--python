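"""A light rooted-tree container shared by Fitch counting, PIC and the simulator.

DendroPy does the Newick parsing and Yule simulation; this module keeps only
the structure those algorithms traverse (parent links, branch lengths, tip
group labels), so the recursions stay free of library-specific node APIs.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy


class Node:
    __slots__ = ("name", "length", "children", "parent", "index", "group")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length  # branch length to parent (root: 0)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.index: int = -1  # postorder index, set by Tree
        self.group: Optional[int] = None  # tip group label (1 fg / 0 bg)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name or self.index}, len={self.length})"


class Tree:
    """Rooted tree with unique tip labels and nonnegative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    def _index(self) -> None:
        self.nodes: list[Node] = list(self._postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.index = i
        names = [n.name for n in self.nodes if n.is_leaf]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels in tree")

    @staticmethod
    def _postorder(node: Node) -> Iterator[Node]:
        for child in node.children:
            yield from Tree._postorder(child)
        yield node

    def postorder(self) -> list[Node]:
        return self.nodes

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.name for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def max_depth(self) -> float:
        """Maximum root-to-tip path length."""
        depth = {self.root: 0.0}
        best = 0.0
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
                if node.is_leaf:
                    best = max(best, depth[node])
        return best

    def scale(self, factor: float) -> None:
        for node in self.nodes:
            node.length *= factor

    def set_groups(self, labels: dict[str, int]) -> None:
        for tip in self.tips:
            if tip.name in labels:
                tip.group = int(labels[tip.name])

    def clade_tips(self, node: Node) -> list[Node]:
        return [n for n in self._postorder(node) if n.is_leaf]

    # ---- Newick round-trip via dendropy ---------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node.parent is None:
                return f"({inner})"
            return f"({inner}):{node.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Tree":
        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(name=label, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)
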