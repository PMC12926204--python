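"""Lightweight rooted trees shared by the simulator and the phylogenetic code.

The package keeps its own minimal tree node (:class:`Clade`) because trees are
created in bulk by the coalescent simulator (thousands per scan) and a slim
structure keeps that cheap.  Conversion to :mod:`dendropy` is provided for
anything that needs richer tree operations (rerooting, bipartitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["Clade", "from_newick", "to_dendropy"]


@dataclass
class Clade:
    """A rooted tree node.

    ``length`` is the length of the branch above this node (``None`` for an
    unlengthed root).  Leaves have a non-empty ``name`` and no children.
    """

    name: str | None = None
    length: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out: list[Clade] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def depths(self) -> dict[int, float]:
        """Map ``id(node) -> distance from this (root) node``."""
        out = {id(self): 0.0}
        stack = [(self, 0.0)]
        while stack:
            node, d = stack.pop()
            for c in node.children:
                dc = d + (c.length or 0.0)
                out[id(c)] = dc
                stack.append((c, dc))
        return out

    def mrca(self, names) -> "Clade":
        """Most recent common ancestor of the named leaves."""
        want = set(names)
        missing = want - set(self.leaf_names())
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")

        def walk(node: Clade) -> Clade | None:
            found = set(node.leaf_names()) & want
            if found != want:
                return None
            for c in node.children:
                hit = walk(c)
                if hit is not None:
                    return hit
            return node

        return walk(self)

    def mrca_depth(self, names) -> float:
        return self.depths()[id(self.mrca(names))]

    def newick(self, precision: int = 10) -> str:
        return _newick(self, precision) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.newick()})"


def _newick(node: Clade, precision: int) -> str:
    if node.is_leaf:
        base = node.name or ""
    else:
        base = "(" + ",".join(_newick(c, precision) for c in node.children) + ")"
        if node.name:
            base += node.name
    if node.length is not None:
        base += f":{node.length:.{precision}g}"
    return base


def from_newick(text: str) -> Clade:
    """Parse a Newick string into a :class:`Clade` (via dendropy)."""
    tree = dendropy.Tree.get(data=text, schema="newick")
    return _convert(tree.seed_node)


def _convert(node) -> Clade:
    name = node.taxon.label if node.taxon is not None else (node.label or None)
    clade = Clade(name=name, length=node.edge.length)
    for child in node.child_nodes():
        clade.children.append(_convert(child))
    return clade


def to_dendropy(tree: Clade | str, taxon_namespace=None) -> dendropy.Tree:
    text = tree if isinstance(tree, str) else tree.newick()
    return dendropy.Tree.get(
        data=text, schema="newick", taxon_namespace=taxon_namespace
    )


def as_clade(tree) -> Clade:
    """Coerce a Clade, Newick string, or dendropy Tree to a Clade."""
    if isinstance(tree, Clade):
        return tree
    if isinstance(tree, str):
        return from_newick(tree)
    if isinstance(tree, dendropy.Tree):
        return _convert(tree.seed_node)
    raise TypeError(f"cannot interpret {type(tree).__name__} as a tree")
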