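"""Tree input/output and tree algorithms.

Provides the :class:`Phylogeny` wrapper around a rooted dendropy tree plus
the tree computations the analysis pipeline needs: cophenetic (patristic)
distance matrices, Felsenstein's phylogenetically independent contrasts
(PIC), and maximum clade credibility (MCC) tree selection with mean node
heights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("commstruct")


class PhylogenyError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Thin wrapper over ``dendropy.Tree`` exposing an ordered tip list and
    the algorithms used downstream. Tip labels must be unique; edge
    lengths are taken as 0 where missing on the root edge.
    """

    tree: dendropy.Tree
    tips: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhylogenyError(f"duplicate tip label(s): {', '.join(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise PhylogenyError(
                    f"negative branch length {edge.length} on edge above "
                    f"{_node_desc(edge.head_node)}"
                )
        self.tips = tuple(sorted(labels))
        if not self.is_ultrametric() and len(labels) > 2:
            logger.warning("tree is not ultrametric; distance metrics remain defined")

    # -- basic properties -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = []
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        if not depths:
            return True
        return max(depths) - min(depths) <= tol * max(max(depths), 1.0)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


def _node_desc(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths and polytomies are preserved exactly. Duplicate tip
    labels and syntax errors raise :class:`PhylogenyError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def read_tree_list(path_or_text: str, schema: str = "newick") -> list[Phylogeny]:
    """Read a multi-tree Newick or Nexus file (or string) as a list of trees."""
    try:
        tl = dendropy.TreeList.get(path=path_or_text, schema=schema,
                                   preserve_underscores=True)
    except (FileNotFoundError, OSError):
        tl = dendropy.TreeList.get(data=path_or_text, schema=schema,
                                   preserve_underscores=True)
    return [Phylogeny(t) for t in tl]


# -- cophenetic distances --------------------------------------------------

def cophenetic_matrix(phy: Phylogeny) -> pd.DataFrame:
    """Patristic distance matrix: entry (i, j) = branch-length path i -> j.

    Returns a symmetric zero-diagonal DataFrame indexed by tip label in
    sorted order.
    """
    if phy.n_tips < 2:
        raise PhylogenyError("cophenetic distances need at least 2 tips")
    labels = list(phy.tips)
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    dmat = np.zeros((n, n))
    # depth of every node from root, then d(i,j) = d_i + d_j - 2 * d_mrca
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phy.tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
            dmat[a, b] = dmat[b, a] = d
    return pd.DataFrame(dmat, index=labels, columns=labels)


# -- independent contrasts -------------------------------------------------

@dataclass
class ContrastSet:
    """Standardized independent contrasts, listed in postorder node visit order."""

    contrasts: np.ndarray          # (n_tips - 1,)
    node_heights: np.ndarray       # height of each internal node visited
    operator: np.ndarray           # (n_tips - 1, n_tips) linear map tips -> contrasts
    tip_order: tuple[str, ...]

    @property
    def variance(self) -> float:
        return float(np.var(self.contrasts, ddof=1))


def _resolved_bifurcating(phy: Phylogeny) -> dendropy.Tree:
    """Copy of the tree with polytomies resolved deterministically.

    Children of a polytomy are ordered by their smallest descendant tip
    label and folded pairwise with zero-length internal branches.
    """
    tree = phy.tree.clone(depth=1)
    for node in list(tree.postorder_node_iter()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        kids = sorted(kids, key=lambda c: min(lf.taxon.label for lf in c.leaf_iter()))
        for k in kids:
            node.remove_child(k)
        left = kids[0]
        for k in kids[1:-1]:
            join = dendropy.Node(edge_length=0.0)
            join.add_child(left)
            join.add_child(k)
            left = join
        node.add_child(left)
        node.add_child(kids[-1])
    return tree


def pic_operator(phy: Phylogeny) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Linear operator C with contrasts = C @ x for tip values x.

    Felsenstein's pruning recursion is linear in the trait vector, so the
    whole contrast computation can be captured once per tree and applied
    to many trait vectors (used heavily by the randomization test).
    Returns ``(C, node_heights, tip_order)`` with each internal node's
    height = distance to its furthest descendant tip.
    """
    tree = _resolved_bifurcating(phy)
    tip_order = phy.tips
    idx = {lab: k for k, lab in enumerate(tip_order)}
    n = len(tip_order)
    rows: list[np.ndarray] = []
    heights: list[float] = []
    # per-node: (weight row vector, adjusted branch length to parent, height)
    state: dict[int, tuple[np.ndarray, float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            w = np.zeros(n)
            w[idx[node.taxon.label]] = 1.0
            state[id(node)] = (w, float(node.edge.length or 0.0), 0.0)
            continue
        kids = node.child_nodes()
        (w1, v1, h1), (w2, v2, h2) = (state.pop(id(c)) for c in kids)
        height = max(h1 + (kids[0].edge.length or 0.0),
                     h2 + (kids[1].edge.length or 0.0))
        vsum = v1 + v2
        if vsum > 0:
            rows.append((w1 - w2) / np.sqrt(vsum))
            w = (w1 / v1 + w2 / v2) / (1.0 / v1 + 1.0 / v2) if min(v1, v2) > 0 \
                else (w1 if v1 == 0 else w2)
            adj = v1 * v2 / vsum
        else:
            # zero-length resolution of a polytomy: raw difference, plain mean
            rows.append(w1 - w2)
            w = 0.5 * (w1 + w2)
            adj = 0.0
        heights.append(height)
        state[id(node)] = (w, float(node.edge.length or 0.0) + adj, height)
    return np.vstack(rows), np.asarray(heights), tip_order


def independent_contrasts(phy: Phylogeny, trait) -> ContrastSet:
    """Felsenstein's standardized independent contrasts for one trait.

    ``trait`` is a mapping or Series of species -> value covering every
    tip. Polytomies are resolved to zero-length branches first, so a tree
    with n tips always yields n - 1 contrasts.
    """
    trait = pd.Series(trait)
    missing = sorted(set(phy.tips) - set(trait.index))
    if missing:
        raise PhylogenyError(f"missing trait value for: {', '.join(missing)}")
    C, heights, tip_order = pic_operator(phy)
    x = trait.reindex(list(tip_order)).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = [t for t, v in zip(tip_order, x) if not np.isfinite(v)]
        raise PhylogenyError(f"non-finite trait value for: {', '.join(bad)}")
    return ContrastSet(C @ x, heights, C, tip_order)


# -- maximum clade credibility tree ---------------------------------------

def _clade_heights(phy: Phylogeny) -> dict[frozenset, float]:
    """Clade -> height map, with tip 'height' = parent height - edge length.

    Height of an internal node is the distance to its furthest descendant
    tip (age-like on dated trees). Tips carry a derived height so that
    non-ultrametric trees round-trip through height-based reconstruction.
    """
    heights: dict[frozenset, float] = {}
    node_h: dict[int, float] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            node_h[id(node)] = 0.0
        else:
            h = max(node_h[id(c)] + (c.edge.length or 0.0)
                    for c in node.child_nodes())
            node_h[id(node)] = h
            heights[frozenset(lf.taxon.label for lf in node.leaf_iter())] = h
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            parent = node.parent_node
            ph = node_h[id(parent)] if parent is not None else 0.0
            heights[frozenset([node.taxon.label])] = ph - (node.edge.length or 0.0)
    return heights


def mcc_tree(trees: list[Phylogeny]) -> Phylogeny:
    """Maximum clade credibility tree with mean node heights.

    Clade credibility is the frequency of each clade across the input set;
    the tree maximizing the product of its clades' credibilities is
    selected (first in input order on ties) and every node height is
    replaced with the mean height of that clade over the trees containing
    it. Branch lengths are rebuilt from the averaged heights, so mixed
    topologies can produce slightly negative terminal branches (as
    TreeAnnotator's mean-heights trees can); these are clamped to 0.
    """
    if not trees:
        raise PhylogenyError("mcc_tree needs at least one tree")
    tipsets = {t.tips for t in trees}
    if len(tipsets) != 1:
        raise PhylogenyError("trees have mismatched tip sets")

    all_heights = [_clade_heights(t) for t in trees]
    counts: dict[frozenset, int] = {}
    height_sums: dict[frozenset, float] = {}
    for hmap in all_heights:
        for clade, h in hmap.items():
            counts[clade] = counts.get(clade, 0) + 1
            height_sums[clade] = height_sums.get(clade, 0.0) + h
    ntrees = len(trees)

    def log_score(hmap) -> float:
        return sum(np.log(counts[c] / ntrees) for c in hmap if len(c) > 1)

    scores = [log_score(h) for h in all_heights]
    best = int(np.argmax(scores))  # argmax takes the first maximum: tie rule

    out = trees[best].copy()
    mean_h = {c: height_sums[c] / counts[c] for c in counts}

    target: dict[int, float] = {}
    for node in out.tree.postorder_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        target[id(node)] = mean_h[clade]
    for node in out.tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max(0.0, target[id(node.parent_node)]
                                   - target[id(node)])
    return Phylogeny(out.tree)
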