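"""Chronogram handling: Newick I/O, ultrametricity, and the shared-ancestry
covariance matrix C used throughout the comparative analyses.

Under Brownian motion along the tree, trait values at the tips are jointly
normal with covariance sigma^2 * C, where C[i, j] is the length of the
root-to-tip path shared by tips i and j (their MRCA's depth). All comparative
routines in :mod:`tempoevo.comparative` consume trees through this wrapper.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["Chronogram", "NotUltrametricError"]


class NotUltrametricError(ValueError):
    """Raised when a tree's root-to-tip depths are unequal beyond tolerance."""


class Chronogram:
    """A rooted, ultrametric, time-calibrated phylogeny.

    Thin wrapper around a :class:`dendropy.Tree` that validates branch
    lengths and tip labels and exposes the phylogenetic covariance matrix.
    """

    def __init__(self, tree: dendropy.Tree, require_ultrametric: bool = True,
                 rel_tol: float = 1e-6):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                if edge.length is None:
                    edge.length = 0.0
                continue
            if edge.length is None or edge.length < 0:
                raise ValueError("all branch lengths must be present and >= 0")
        self._labels = sorted(labels)
        if require_ultrametric and not self.is_ultrametric(rel_tol):
            raise NotUltrametricError(
                f"root-to-tip depths differ by more than rel_tol={rel_tol}"
            )

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path, **kwargs) -> "Chronogram":
        """Build from a Newick string or a path to a Newick file."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree, **kwargs)

    # -- basic properties ------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxa(self) -> list[str]:
        """Tip labels, sorted."""
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (tree age for an ultrametric tree)."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        h = depths.max()
        if h == 0:
            return True
        return bool(np.all(np.abs(depths - h) <= rel_tol * h))

    # -- covariance ------------------------------------------------------
    def vcv(self, order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Phylogenetic covariance matrix C and its tip ordering.

        ``C[i, j]`` is the depth of the MRCA of tips i and j; the diagonal
        holds the root-to-tip depths.
        """
        order = list(order) if order is not None else self.taxa
        idx = {label: i for i, label in enumerate(order)}
        missing = set(order) - {l for l in self._labels}
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        n = len(order)
        C = np.zeros((n, n))
        # each edge contributes its length to all tip pairs below it
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            below = [
                idx[leaf.taxon.label]
                for leaf in node.leaf_iter()
                if leaf.taxon.label in idx
            ]
            if not below:
                continue
            length = node.edge.length or 0.0
            ii = np.asarray(below)
            C[np.ix_(ii, ii)] += length
        return C, order

    # -- manipulation ----------------------------------------------------
    def prune_to(self, taxa: Sequence[str]) -> "Chronogram":
        """Return a copy restricted to the given tips."""
        keep = set(taxa)
        missing = keep - set(self._labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return Chronogram(clone)

    def scale(self, factor: float) -> "Chronogram":
        """Return a copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Chronogram(clone)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Chronogram(n_tips={self.n_tips}, height={self.height:.4g})"
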