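"""Phylogenies and the covariance structures the mixed model consumes.

A rooted, branch-length-annotated phylogeny over the study species induces
the Brownian-motion trait covariance C, where ``C[i, j]`` is the shared
root-to-MRCA path length of species *i* and *j*.  The mixed model uses the
diagonal-standardized form ``A = C / max(diag(C))`` so that the species-level
variance component keeps trait units and phylogenetic heritability is
scale-free.  On an ultrametric tree A has unit diagonal, i.e. it is the
correlation matrix implied by Brownian motion.

Parsing and tree surgery are delegated to :mod:`dendropy`; this module owns
validation, covariance construction and Grafen branch-length assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "TaxonLookupError",
    "DegenerateTreeError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "covariance_from_tree",
    "assign_branch_lengths",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the character position."""


class TreeValidationError(ValueError):
    """Tree violates a structural invariant (labels, branch lengths, size)."""


class TaxonLookupError(KeyError):
    """A requested taxon is not a tip of the tree."""


class DegenerateTreeError(ValueError):
    """Tree has zero total depth; no covariance can be formed."""


@dataclass
class Phylogeny:
    """A validated rooted phylogeny.

    Wraps a :class:`dendropy.Tree`.  Invariants enforced on construction:
    at least two leaves, every leaf labelled, labels unique, all branch
    lengths (where present) non-negative.  Unlabelled internal nodes and
    polytomies are permitted; polytomies are never randomly resolved.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        leaves = list(self.tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeValidationError("tree must have at least 2 leaves")
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeValidationError("every leaf must carry a non-empty label")
            labels.append(label)
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )

    @property
    def taxa(self) -> list[str]:
        """Tip labels in tree (Newick) order."""
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def has_branch_lengths(self) -> bool:
        """True if every non-root edge carries a length."""
        root = self.tree.seed_node
        return all(
            e.length is not None
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not root
        )

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per taxon (root edge excluded)."""
        depths: dict[dendropy.Node, float] = {self.tree.seed_node: 0.0}
        out: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
            if node.is_leaf():
                out[node.taxon.label] = depths[node]
        return out

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = np.asarray(list(self.tip_depths().values()))
        scale = max(d.max(), 1e-300)
        return bool(np.ptp(d) <= rel_tol * scale)


@dataclass
class PhyloCovariance:
    """Species-level Brownian covariance and its standardized form.

    ``C[i, j]`` = shared root-to-MRCA path length of ``species_order[i]``
    and ``species_order[j]``; ``A = C / max(diag(C))``.
    """

    species_order: list[str]
    C: np.ndarray
    A: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.species_order),) * 2:
            raise ValueError("C shape does not match species_order")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")
        self.C = C
        scale = float(np.max(np.diag(C)))
        if scale <= 0:
            raise DegenerateTreeError("tree has zero total depth")
        self.A = C / scale

    def submatrix(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.species_order.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.C[np.ix_(idx, idx)])


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree string into a validated :class:`Phylogeny`.

    Raises :class:`NewickParseError` (naming the character offset) on
    malformed input and :class:`TreeValidationError` on duplicate leaf
    labels or other invariant violations.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as err:
        col = getattr(err, "col_num", None)
        msg = getattr(err, "message", str(err))
        if "Duplicate taxon labels" in str(err) or "Multiple occurrences" in str(err):
            raise TreeValidationError(f"duplicate leaf labels in Newick input: {msg}")
        raise NewickParseError(
            f"malformed Newick at character {col}: {msg}"
        ) from err
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read the first tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(phy: Phylogeny, path=None) -> str:
    """Serialize to Newick with 6-significant-digit branch lengths."""
    text = phy.tree.as_string(
        schema="newick",
        real_value_format_specifier=".6g",
        suppress_rooting=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def assign_branch_lengths(phy: Phylogeny, method: str = "grafen") -> Phylogeny:
    """Assign branch lengths to a topology-only tree.

    Grafen's method: each node sits at height (number of descendant
    leaves - 1)/(n - 1), tips at height 0, so the result is ultrametric
    with unit root height.
    """
    if method != "grafen":
        raise ValueError(f"unknown branch-length method: {method!r}")
    out = phy.clone()
    n = out.n_tips
    heights: dict[dendropy.Node, float] = {}
    for node in out.tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            k = sum(1 for _ in node.leaf_iter())
            heights[node] = (k - 1) / (n - 1)
    for node in out.tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = heights[node.parent_node] - heights[node]
    return Phylogeny(out.tree)


def covariance_from_tree(
    phy: Phylogeny, taxa_subset: list[str] | None = None
) -> PhyloCovariance:
    """Brownian-motion covariance of tip values on the (pruned) tree.

    The tree is pruned to ``taxa_subset`` first (path lengths through
    suppressed degree-2 nodes are preserved), then ``C[i, j]`` is read off
    as the root depth of the MRCA of tips *i* and *j*.

    Raises :class:`TaxonLookupError` for unknown taxa,
    :class:`TreeValidationError` if branch lengths are missing (apply
    :func:`assign_branch_lengths` first), and
    :class:`DegenerateTreeError` for a zero-depth tree.
    """
    if not phy.has_branch_lengths:
        raise TreeValidationError(
            "tree lacks branch lengths; apply assign_branch_lengths(method='grafen') "
            "explicitly if a Grafen ultrametricization is acceptable"
        )
    tree = phy.tree
    if taxa_subset is not None:
        missing = set(taxa_subset) - set(phy.taxa)
        if missing:
            raise TaxonLookupError(f"taxa not in tree: {sorted(missing)}")
        if len(taxa_subset) < 2:
            raise TreeValidationError("need at least 2 taxa for a covariance")
        work = phy.clone()
        work.tree.retain_taxa_with_labels(list(taxa_subset))
        tree = work.tree

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[node] = [i]
            C[i, i] = depths[node]
        else:
            groups = [below[c] for c in node.child_nodes()]
            d = depths[node]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            C[i, j] = C[j, i] = d
            below[node] = [i for g in groups for i in g]

    if taxa_subset is not None:
        perm = [index[t] for t in taxa_subset]
        return PhyloCovariance(list(taxa_subset), C[np.ix_(perm, perm)])
    return PhyloCovariance(labels, C)
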