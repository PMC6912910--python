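"""Phylogeny ingestion and phylogeny-derived quantities.

A :class:`Phylogeny` is a rooted tree with branch lengths (time units, e.g.
Myr).  From it we derive the three quantities the rest of the analysis is
built on:

* the cophenetic (patristic) distance matrix ``d_ij`` — substrate of the
  mean pairwise distance (MPD) and hence the net relatedness index;
* the Brownian-motion covariance matrix ``C_ij`` = depth of the most recent
  common ancestor of tips *i* and *j* — substrate of Pagel's lambda;
* Faith's phylogenetic diversity — total branch length of the minimal
  subtree spanning a species set *and the root* (root-inclusive convention,
  fixed here; see docs/methods.md).

Taxon names are matched exactly after trimming whitespace and treating
underscores as spaces; no fuzzy matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Phylogeny",
    "DistanceMatrix",
    "PhyloCovariance",
    "CladeFilter",
    "read_newick",
    "write_newick",
    "apply_clade_filter",
    "cophenetic_matrix",
    "phylo_covariance",
    "faith_pd",
]


class TreeError(ValueError):
    """Invalid tree input (parse failure, duplicate labels, missing lengths)."""


def normalize_label(label: str) -> str:
    """Canonical form used for taxon matching: trim, underscores as spaces,
    internal whitespace collapsed."""
    return " ".join(str(label).replace("_", " ").split())


@dataclass(frozen=True)
class _LabelledMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # square, aligned to ``labels``

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        object.__setattr__(self, "values", v)

    def loc(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "_LabelledMatrix":
        idx = [self.labels.index(l) for l in labels]
        return type(self)(tuple(labels), self.values[np.ix_(idx, idx)])


class DistanceMatrix(_LabelledMatrix):
    """Symmetric matrix of tip-to-tip patristic distances."""


class PhyloCovariance(_LabelledMatrix):
    """Brownian-motion trait covariance structure: C_ij = MRCA depth,
    C_ii = root-to-tip depth."""


@dataclass
class CladeFilter:
    """Taxa to exclude from the analysis (e.g. gymnosperms, which sit on a
    long branch and would otherwise dominate every pairwise distance)."""

    names: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "CladeFilter":
        """One taxon name per line; ``#`` starts a comment."""
        names = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
        return cls(names)


class Phylogeny:
    """Rooted, branch-lengthed tree wrapping a dendropy ``Tree``.

    Invariants checked at construction: one root, unique tip labels (after
    normalization), branch lengths present and non-negative on every
    non-root edge.  Polytomies and zero-length branches are accepted.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()
        self._index()

    # -- construction / validation ------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse failure: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        tree = self._tree
        seed = tree.seed_node
        if seed is None:
            raise TreeError("empty tree")
        labels = []
        for node in tree.preorder_node_iter():
            if node is not seed:
                if node.edge.length is None:
                    raise TreeError(
                        "missing branch length on edge above "
                        f"{node.taxon.label if node.taxon else 'an internal node'!r}"
                    )
                if node.edge.length < 0:
                    raise TreeError("negative branch length")
            if node.is_leaf():
                if node.taxon is None or node.taxon.label is None:
                    raise TreeError("tip without a label")
                labels.append(normalize_label(node.taxon.label))
        if not labels:
            raise TreeError("tree has no tips")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")

    def _index(self) -> None:
        # node depths from the root (seed edge, if any, is ignored)
        seed = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is seed:
                node._depth = 0.0
            else:
                node._depth = node.parent_node._depth + node.edge.length
        leaves = sorted(
            self._tree.leaf_node_iter(),
            key=lambda n: normalize_label(n.taxon.label),
        )
        self._leaves = leaves
        self._labels = tuple(n.taxon.label for n in leaves)
        self._norm_to_leaf = {
            normalize_label(n.taxon.label): n for n in leaves
        }

    # -- basic properties ----------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in canonical (sorted) order."""
        return self._labels

    def __len__(self) -> int:
        return len(self._labels)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root edge excluded)."""
        seed = self._tree.seed_node
        return float(
            sum(
                n.edge.length
                for n in self._tree.preorder_node_iter()
                if n is not seed
            )
        )

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = [leaf._depth for leaf in self._leaves]
        return max(depths) - min(depths) <= tol

    # -- Newick round trip ----------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return s.strip() + "\n"

    # -- derived matrices ------------------------------------------------

    def _tip_index(self) -> dict[int, int]:
        return {id(leaf): i for i, leaf in enumerate(self._leaves)}

    def covariance(self) -> PhyloCovariance:
        """C_ij = depth of MRCA(i, j); C_ii = root-to-tip depth.

        Single postorder sweep: at each internal node of depth *d*, tip
        pairs split across different children have their MRCA there.
        """
        n = len(self._leaves)
        idx = self._tip_index()
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[id(node)] = np.array([idx[id(node)]])
                continue
            blocks = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            for a in range(len(blocks)):
                for b in range(a + 1, len(blocks)):
                    C[np.ix_(blocks[a], blocks[b])] = node._depth
                    C[np.ix_(blocks[b], blocks[a])] = node._depth
            tipsets[id(node)] = np.concatenate(blocks)
        depths = np.array([leaf._depth for leaf in self._leaves])
        np.fill_diagonal(C, depths)
        return PhyloCovariance(self._labels, C)

    def distances(self) -> DistanceMatrix:
        """Patristic distances via d_ij = depth_i + depth_j - 2 * MRCA depth
        (holds on any rooted tree, ultrametric or not)."""
        C = self.covariance().values
        depths = np.diag(C)
        D = depths[:, None] + depths[None, :] - 2.0 * C
        np.fill_diagonal(D, 0.0)
        return DistanceMatrix(self._labels, D)

    # -- Faith's PD -------------------------------------------------------

    def faith_pd(self, taxa: Iterable[str]) -> float:
        """Root-inclusive Faith's PD: sum of branch lengths of the minimal
        subtree connecting ``taxa`` and the root."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("taxa set is empty")
        marked: set[int] = set()
        seed = self._tree.seed_node
        for name in taxa:
            leaf = self._norm_to_leaf.get(normalize_label(name))
            if leaf is None:
                raise KeyError(f"unknown taxon: {name!r}")
            node = leaf
            while node is not seed and id(node) not in marked:
                marked.add(id(node))
                node = node.parent_node
        return float(
            sum(
                n.edge.length
                for n in self._tree.preorder_node_iter()
                if id(n) in marked
            )
        )

    # -- pruning -----------------------------------------------------------

    def retain(self, taxa: Sequence[str]) -> "Phylogeny":
        """New tree restricted to ``taxa``; degree-2 nodes created by the
        pruning are suppressed with branch lengths summed, so patristic
        distances among survivors are preserved."""
        wanted = {normalize_label(t) for t in taxa}
        keep = [
            leaf.taxon.label
            for leaf in self._leaves
            if normalize_label(leaf.taxon.label) in wanted
        ]
        missing = wanted - {normalize_label(k) for k in keep}
        if missing:
            raise KeyError(f"unknown taxa: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("fewer than 2 tips would remain")
        sub = self._tree.extract_tree_with_taxa_labels(labels=set(keep))
        return Phylogeny(sub)

    def drop(self, filt: CladeFilter) -> "Phylogeny":
        """Remove the filter's taxa (unmatched names warn, not error)."""
        norm_names = {normalize_label(n) for n in filt.names}
        present = {normalize_label(l) for l in self._labels}
        unmatched = sorted(norm_names - present)
        if unmatched:
            warnings.warn(
                f"clade filter names not found in tree: {unmatched}",
                stacklevel=2,
            )
        if not norm_names & present:
            return self
        keep = [
            l for l in self._labels if normalize_label(l) not in norm_names
        ]
        if len(keep) < 2:
            raise TreeError("fewer than 2 tips would remain after filtering")
        return self.retain(keep)


# ---------------------------------------------------------------------------
# Functional surface


def read_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def apply_clade_filter(tree: Phylogeny, filt: CladeFilter) -> Phylogeny:
    return tree.drop(filt)


def cophenetic_matrix(tree: Phylogeny) -> DistanceMatrix:
    return tree.distances()


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    return tree.covariance()


def faith_pd(tree: Phylogeny, taxa: Iterable[str]) -> float:
    return tree.faith_pd(taxa)
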