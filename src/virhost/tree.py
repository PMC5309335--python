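"""Rooted reference trees and patristic distances.

Phylogenetic read placement assigns environmental reads to nodes (leaves or
internal nodes) of a fixed reference tree; every diversity statistic in this
package reduces to patristic distances — the sum of branch lengths along the
unique path between two nodes — on that tree.  Newick parsing is delegated to
:mod:`dendropy`; this module wraps the result in a validated, immutable
structure with parent links, deterministic identifiers for unlabeled internal
nodes, and exact path-sum distances.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["ReferenceTree", "read_newick", "write_newick"]


class ReferenceTree:
    """A rooted tree with unique node identifiers and nonnegative branch lengths.

    Parameters
    ----------
    parent
        Map node id -> parent id; the single root maps to ``None``.
    branch_lengths
        Map node id -> length of the branch above it.  The root's entry is 0.
    children
        Map node id -> ordered child ids (defines traversal and Newick order).
    root
        Identifier of the root node.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        branch_lengths: Mapping[str, float],
        children: Mapping[str, Sequence[str]],
        root: str,
    ) -> None:
        self.parent = dict(parent)
        self.branch_lengths = {k: float(v) for k, v in branch_lengths.items()}
        self.children = {k: list(v) for k, v in children.items()}
        self.root = root
        self._validate()
        # depth = patristic distance to the root; level = edge count to the root
        self._depth: dict[str, float] = {}
        self._level: dict[str, int] = {}
        for node in self.preorder():
            p = self.parent[node]
            if p is None:
                self._depth[node] = 0.0
                self._level[node] = 0
            else:
                self._depth[node] = self._depth[p] + self.branch_lengths[node]
                self._level[node] = self._level[p] + 1

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "ReferenceTree":
        """Parse a Newick string into a validated tree.

        Unlabeled internal nodes receive deterministic identifiers ``N<i>``
        where ``<i>`` is the node's 0-based preorder index.
        """
        try:
            dtree = dendropy.Tree.get(
                data=source,
                schema="newick",
                suppress_internal_node_taxa=True,
                suppress_leaf_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several DataError subtypes
            offset = ""
            for attr in ("col_num", "column"):
                col = getattr(exc, attr, None)
                if col is not None:
                    offset = f" (character offset {col})"
                    break
            raise FormatError(f"Newick parse failure{offset}: {exc}") from exc

        parent: dict[str, str | None] = {}
        blen: dict[str, float] = {}
        children: dict[str, list[str]] = {}
        names: dict[int, str] = {}
        for idx, node in enumerate(dtree.preorder_node_iter()):
            if node.taxon is not None and node.taxon.label:
                name = str(node.taxon.label)
            elif node.label:
                name = str(node.label)
            else:
                name = f"N{idx}"
            if name in parent:
                raise ValidationError(f"duplicate node identifier {name!r}")
            names[id(node)] = name
            is_root = node.parent_node is None
            length = node.edge.length
            if length is None:
                if not is_root:
                    raise ValidationError(f"node {name!r} has no branch length")
                length = 0.0
            parent[name] = None if is_root else names[id(node.parent_node)]
            blen[name] = float(length)
            children[name] = []
            if not is_root:
                children[parent[name]].append(name)
        roots = [n for n, p in parent.items() if p is None]
        return cls(parent, blen, children, roots[0])

    def _validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1 or roots[0] != self.root:
            raise ValidationError(f"tree must have exactly one root, found {roots!r}")
        if set(self.parent) != set(self.branch_lengths) or set(self.parent) != set(self.children):
            raise ValidationError("inconsistent node sets in tree tables")
        for node, length in self.branch_lengths.items():
            if not np.isfinite(length) or length < 0:
                raise ValidationError(f"branch length of node {node!r} is {length!r}; must be finite and >= 0")
        for node, kids in self.children.items():
            for child in kids:
                if self.parent.get(child) != node:
                    raise ValidationError(f"child link {node!r}->{child!r} disagrees with parent map")

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.parent)

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children[node]))
        return out

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if not self.children[n]]

    def __contains__(self, node: str) -> bool:
        return node in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def _lca(self, a: str, b: str) -> str:
        la, lb = self._level[a], self._level[b]
        while la > lb:
            a = self.parent[a]  # type: ignore[assignment]
            la -= 1
        while lb > la:
            b = self.parent[b]  # type: ignore[assignment]
            lb -= 1
        while a != b:
            a = self.parent[a]  # type: ignore[assignment]
            b = self.parent[b]  # type: ignore[assignment]
        return a

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between ``a`` and ``b``."""
        for n in (a, b):
            if n not in self.parent:
                raise ValidationError(f"unknown node {n!r}")
        if a == b:
            return 0.0
        anc = self._lca(a, b)
        return self._depth[a] + self._depth[b] - 2.0 * self._depth[anc]

    def distance_matrix(self, node_ids: Sequence[str]) -> np.ndarray:
        """Symmetric patristic distance matrix over ``node_ids`` (given order)."""
        unknown = [n for n in node_ids if n not in self.parent]
        if unknown:
            raise ValidationError(f"unknown nodes: {unknown!r}")
        k = len(node_ids)
        mat = np.zeros((k, k), dtype=float)
        for i in range(k):
            for j in range(i + 1, k):
                d = self.patristic_distance(node_ids[i], node_ids[j])
                mat[i, j] = mat[j, i] = d
        return mat

    # -- output ----------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with internal-node labels so identifiers round-trip."""

        def render(node: str) -> str:
            kids = self.children[node]
            label = node
            inner = f"({','.join(render(k) for k in kids)})" if kids else ""
            return f"{inner}{label}:{self.branch_lengths[node]!r}"

        return render(self.root) + ";"

    def scaled(self, factor: float) -> "ReferenceTree":
        """A copy with every branch length multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be > 0")
        return ReferenceTree(
            self.parent,
            {n: length * factor for n, length in self.branch_lengths.items()},
            self.children,
            self.root,
        )


def read_newick(path: str | os.PathLike) -> ReferenceTree:
    """Read and validate a Newick tree file."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        return ReferenceTree.from_newick(fh.read())


def write_newick(tree: ReferenceTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
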