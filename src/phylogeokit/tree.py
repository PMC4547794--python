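"""Fixed tree topologies with uniquely named tips.

The tree is the *given* in every analysis here: dispersal parsimony and the
randomization test score population labelings over a fixed topology and never
re-estimate it.  Branch lengths are carried along when present (the dispersal
engine ignores them; the sequence simulator requires them).
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["LabeledTree", "TreeParseError", "read_newick"]


class TreeParseError(ValueError):
    """Raised for malformed Newick input or invalid tip labeling."""


class LabeledTree:
    """A rooted, binary-or-polytomous tree whose tips carry unique names.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the invariants
    needed by the dispersal engine (>= 2 tips, unique tip names) and exposes a
    flattened postorder structure for dynamic programming.
    """

    def __init__(self, dtree: dendropy.Tree):
        tips = [leaf.taxon.label if leaf.taxon is not None else None
                for leaf in dtree.leaf_node_iter()]
        if any(t is None or t == "" for t in tips):
            raise TreeParseError("every tip must carry a non-empty name")
        if len(tips) < 2:
            raise TreeParseError("a labeled tree needs at least 2 tips")
        seen: set[str] = set()
        for t in tips:
            if t in seen:
                raise TreeParseError(f"duplicate tip name: {t!r}")
            seen.add(t)
        self._dtree = dtree
        self._tips = tips

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_newick_file(cls, path: str) -> "LabeledTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic queries ------------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    def has_branch_lengths(self) -> bool:
        return all(
            n.edge.length is not None
            for n in self._dtree.preorder_node_iter()
            if n.parent_node is not None
        )

    def internal_node_labels(self) -> list[str | None]:
        return [
            (n.taxon.label if n.taxon is not None else n.label)
            for n in self._dtree.postorder_internal_node_iter()
        ]

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def to_newick_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structure for dynamic programming ----------------------------------

    def postorder_structure(self):
        """Flatten to postorder arrays.

        Returns ``(children, tip_index, edge_lengths)`` where ``children[i]``
        is the list of postorder indices of node i's children (empty for
        tips), ``tip_index`` maps tip name -> postorder index, and
        ``edge_lengths[i]`` is the length of the edge above node i (None when
        absent).  The root is the last node.
        """
        nodes = list(self._dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children = [
            [index[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        tip_index = {
            n.taxon.label: i for i, n in enumerate(nodes) if n.is_leaf()
        }
        edge_lengths = [n.edge.length for n in nodes]
        return children, tip_index, edge_lengths

    def preorder_edges(self) -> Iterator[tuple[int, int]]:
        """Yield (parent_index, child_index) pairs in postorder indexing."""
        nodes = list(self._dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        for n in self._dtree.preorder_node_iter():
            for c in n.child_nodes():
                yield index[id(n)], index[id(c)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LabeledTree(n_tips={self.n_tips})"


def read_newick(text: str) -> LabeledTree:
    """Parse a Newick string into a :class:`LabeledTree`."""
    return LabeledTree.from_newick(text)
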