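"""Functional-annotation hierarchies.

A :class:`TaxonomyTree` is a rooted tree of annotation codes (for example the
four-level enzyme-code hierarchy under an artificial root) supporting level,
ancestor and lowest-common-ancestor queries.  Node names are opaque strings:
only the child→parent edge table defines the topology, never the dotted-code
convention.

Level numbering: the root has level 0 and each child is one level below its
parent, so enzyme-code leaves of a full four-level hierarchy sit at level 4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

DEFAULT_MAX_HEIGHT = 4


class TaxonomyError(ValueError):
    """Raised for malformed trees or unknown nodes."""


@dataclass(frozen=True)
class TaxNode:
    """One node of the annotation hierarchy."""

    node_id: int
    name: str
    parent_id: int | None
    level: int


class TaxonomyTree:
    """Rooted annotation tree with O(height) LCA via parent climbing.

    The tree is immutable after construction.  ``max_height`` bounds the depth
    below the root (default 4, matching enzyme-code hierarchies); pass ``None``
    to disable the check.
    """

    def __init__(self, nodes: Sequence[TaxNode], max_height: int | None = DEFAULT_MAX_HEIGHT):
        self._nodes: list[TaxNode] = list(nodes)
        self._name_index: dict[str, int] = {}
        roots = [n for n in self._nodes if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(f"tree must have exactly one root, found {len(roots)}")
        self._root_id = roots[0].node_id
        for n in self._nodes:
            if n.name in self._name_index:
                raise TaxonomyError(f"duplicate node name {n.name!r}")
            self._name_index[n.name] = n.node_id
        self._levels = np.array([n.level for n in self._nodes], dtype=np.int32)
        self._parents = [(-1 if n.parent_id is None else n.parent_id) for n in self._nodes]
        self._height = int(self._levels.max(initial=0))
        if max_height is not None and self._height > max_height:
            raise TaxonomyError(
                f"tree height {self._height} exceeds configured maximum {max_height}"
            )
        self._anc: np.ndarray | None = None  # lazily built level-ancestor matrix

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        max_height: int | None = DEFAULT_MAX_HEIGHT,
    ) -> "TaxonomyTree":
        """Build a tree from ``(child_name, parent_name)`` pairs.

        Exactly one name must appear only on the parent side (the root).
        Raises :class:`TaxonomyError` on cycles, conflicting duplicate edges
        or multiple roots.
        """
        parent_of: dict[str, str] = {}
        names: dict[str, None] = {}  # insertion-ordered set
        n_edges = 0
        for child, parent in edges:
            n_edges += 1
            if child in parent_of and parent_of[child] != parent:
                raise TaxonomyError(
                    f"node {child!r} has conflicting parents "
                    f"{parent_of[child]!r} and {parent!r}"
                )
            parent_of[child] = parent
            names.setdefault(parent)
            names.setdefault(child)
        if n_edges == 0:
            raise TaxonomyError("empty edge list")
        root_names = [n for n in names if n not in parent_of]
        if len(root_names) == 0:
            raise TaxonomyError("cycle detected: no root (every node has a parent)")
        if len(root_names) > 1:
            raise TaxonomyError(f"multiple roots: {sorted(root_names)}")
        root = root_names[0]

        children: dict[str, list[str]] = {n: [] for n in names}
        for child, parent in parent_of.items():
            children[parent].append(child)

        # BFS from the root assigns ids and levels; unreached nodes sit on a cycle.
        nodes: list[TaxNode] = []
        name_to_id: dict[str, int] = {}
        queue = [root]
        name_to_id[root] = 0
        nodes.append(TaxNode(0, root, None, 0))
        head = 0
        while head < len(queue):
            cur = queue[head]
            head += 1
            cur_id = name_to_id[cur]
            cur_level = nodes[cur_id].level
            for ch in children[cur]:
                ch_id = len(nodes)
                name_to_id[ch] = ch_id
                nodes.append(TaxNode(ch_id, ch, cur_id, cur_level + 1))
                queue.append(ch)
        if len(nodes) != len(names):
            missing = sorted(set(names) - set(name_to_id))
            raise TaxonomyError(f"cycle detected: unreachable nodes {missing}")
        return cls(nodes, max_height=max_height)

    @classmethod
    def from_tsv(cls, path, max_height: int | None = DEFAULT_MAX_HEIGHT) -> "TaxonomyTree":
        """Read a two-column ``child TAB parent`` table (header tolerated)."""
        edges = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2:
                    raise TaxonomyError(f"malformed tree row: {row!r}")
                if not edges and row[0].strip().lower() == "child":
                    continue
                edges.append((row[0].strip(), row[1].strip()))
        return cls.from_edges(edges, max_height=max_height)

    def to_edges(self) -> list[tuple[str, str]]:
        """Child→parent edge list (root omitted), in node-id order."""
        return [
            (n.name, self._nodes[n.parent_id].name)
            for n in self._nodes
            if n.parent_id is not None
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for child, parent in self.to_edges():
                fh.write(f"{child}\t{parent}\n")

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[TaxNode]:
        return iter(self._nodes)

    @property
    def root_id(self) -> int:
        return self._root_id

    @property
    def height(self) -> int:
        return self._height

    def node(self, node_id: int) -> TaxNode:
        if not 0 <= node_id < len(self._nodes):
            raise TaxonomyError(f"unknown node id {node_id}")
        return self._nodes[node_id]

    def id_of(self, name: str) -> int:
        try:
            return self._name_index[name]
        except KeyError:
            raise TaxonomyError(f"unknown node name {name!r}") from None

    def name_of(self, node_id: int) -> str:
        return self.node(node_id).name

    def level(self, node_id: int) -> int:
        return self.node(node_id).level

    def __contains__(self, name: str) -> bool:
        return name in self._name_index

    def children(self, node_id: int) -> list[int]:
        self.node(node_id)
        return [n.node_id for n in self._nodes if n.parent_id == node_id]

    def leaves(self) -> list[int]:
        has_child = [False] * len(self._nodes)
        for n in self._nodes:
            if n.parent_id is not None:
                has_child[n.parent_id] = True
        return [n.node_id for n in self._nodes if not has_child[n.node_id]]

    def subtree_leaves(self, node_id: int) -> list[int]:
        return [v for v in self.leaves() if self.is_ancestor(node_id, v)]

    # -- queries -----------------------------------------------------------

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor by depth-equalized parent climbing."""
        na, nb = self.node(a), self.node(b)
        ia, ib = na.node_id, nb.node_id
        la, lb = na.level, nb.level
        while la > lb:
            ia = self._parents[ia]
            la -= 1
        while lb > la:
            ib = self._parents[ib]
            lb -= 1
        while ia != ib:
            ia = self._parents[ia]
            ib = self._parents[ib]
        return ia

    def lca_many(self, node_ids: Iterable[int]) -> int:
        it = iter(node_ids)
        try:
            acc = next(it)
        except StopIteration:
            raise TaxonomyError("lca of empty node set") from None
        self.node(acc)
        for v in it:
            acc = self.lca(acc, v)
            if acc == self._root_id:
                break
        return acc

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` lies on the root-path of ``b`` (a == b counts)."""
        la = self.node(a).level
        cur = self.node(b).node_id
        lb = self._nodes[cur].level
        if la > lb:
            return False
        while lb > la:
            cur = self._parents[cur]
            lb -= 1
        return cur == a

    def level_ancestor(self, a: int, level: int) -> int | None:
        """Ancestor of ``a`` at exactly ``level``; None if ``a`` sits above it."""
        if not 0 <= level <= self._height:
            raise TaxonomyError(f"level {level} outside [0, {self._height}]")
        cur = self.node(a).node_id
        la = self._nodes[cur].level
        if la < level:
            return None
        while la > level:
            cur = self._parents[cur]
            la -= 1
        return cur

    # -- vectorized support for the labeled index -------------------------

    @property
    def ancestor_matrix(self) -> np.ndarray:
        """``anc[l, v]`` = ancestor of node v at level l, or -1 if level(v) < l."""
        if self._anc is None:
            h = self._height
            anc = np.full((h + 1, len(self._nodes)), -1, dtype=np.int32)
            for n in self._nodes:  # BFS order: parents precede children
                anc[: n.level + 1, n.node_id] = (
                    anc[: n.level, n.parent_id].tolist() + [n.node_id]
                    if n.parent_id is not None
                    else [n.node_id]
                )
            self._anc = anc
        return self._anc

    def lca_vector(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Elementwise LCA of two equal-length node-id arrays."""
        anc = self.ancestor_matrix
        res = np.full(a.shape, self._root_id, dtype=np.int32)
        for l in range(1, anc.shape[0]):
            aa = anc[l, a]
            eq = (aa == anc[l, b]) & (aa >= 0)
            res = np.where(eq, aa, res)
        return res
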