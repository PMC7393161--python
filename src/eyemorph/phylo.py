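"""Continuous-trait ancestral state reconstruction on rooted trees.

Under a Brownian-motion (BM) model of trait evolution the maximum-
likelihood ancestral state of every internal node is a generalized-least-
squares weighted average of the tip values; for each node it equals the
GLS root estimate of the tree re-rooted at that node.  The same states
minimize the branch-length-weighted sum of squared changes over the tree
(weighted squared-change parsimony), which is how multivariate mean shapes
are mapped onto a phylogeny.

Trees are handled with dendropy; tip trait values are supplied as a
mapping from tip label to scalar (or vector for shapes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TraitTree",
    "prune_tips",
    "bm_ancestral_ml",
    "sqcp_ancestral_shapes",
    "patristic_distances",
    "internal_node_labels",
]


@dataclass
class TraitTree:
    """A rooted tree with branch lengths plus tip trait values."""

    tree: dendropy.Tree
    traits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                continue
            if not np.isfinite(edge.length):
                raise ValueError("branch lengths must be finite")
            if edge.length < 0:
                raise ValueError("negative branch lengths are not allowed")

    @classmethod
    def from_newick(cls, newick: str, traits: dict | None = None) -> "TraitTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # malformed newick, duplicate taxa, ...
            raise ValueError(f"invalid newick: {exc}") from exc
        return cls(tree=tree, traits=dict(traits or {}))

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "TraitTree":
        return TraitTree(tree=self.tree.clone(depth=1), traits=dict(self.traits))


def internal_node_labels(tree: dendropy.Tree) -> dict:
    """Deterministic preorder labels node0, node1, ... for internal nodes."""
    labels = {}
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            labels[id(node)] = f"node{i}"
            i += 1
    return labels


def prune_tips(tt: TraitTree, tips_to_remove) -> TraitTree:
    """Remove tips and re-account branch lengths.

    Degree-2 internal nodes left behind are collapsed by summing the two
    incident branch lengths, so patristic distances among the remaining
    tips are conserved exactly.
    """
    tips_to_remove = set(tips_to_remove)
    remaining = [t for t in tt.tip_labels if t not in tips_to_remove]
    if len(remaining) < 2:
        raise ValueError("at least 2 tips must remain")
    if not tips_to_remove:
        return tt.clone()
    out = tt.clone()
    taxa = [tax for tax in out.tree.taxon_namespace if tax.label in tips_to_remove]
    out.tree.prune_taxa(taxa, suppress_unifurcations=True)
    out.tree.purge_taxon_namespace()
    out.traits = {k: v for k, v in out.traits.items() if k not in tips_to_remove}
    return out


def patristic_distances(tt: TraitTree) -> dict:
    """Pairwise path-length distances between tips, keyed by frozenset of labels."""
    pdm = tt.tree.phylogenetic_distance_matrix()
    out = {}
    taxa = [lf.taxon for lf in tt.tree.leaf_node_iter()]
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[frozenset((a.label, b.label))] = pdm.patristic_distance(a, b)
    return out


def _effective_lengths(tree: dendropy.Tree) -> dict:
    """Edge lengths with zeros replaced by a tiny fraction of tree height."""
    height = max(
        (lf.distance_from_root() for lf in tree.leaf_node_iter()), default=1.0
    )
    floor = 1e-8 * (height if height > 0 else 1.0)
    lengths = {}
    replaced = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl <= 0:
            bl = floor
            replaced += 1
        lengths[id(node)] = bl
    if replaced:
        log.warning("replaced %d zero-length branches by %.3g", replaced, floor)
    return lengths


def bm_ancestral_ml(tt: TraitTree) -> tuple[dict, dict]:
    """Brownian-motion ML ancestral states for all internal nodes.

    Implemented as exact Gaussian message passing on the tree: an upward
    (pruning) pass aggregates tip information into (estimate, variance)
    messages, a downward pass adds the information flowing from the rest of
    the tree, and each node's state is the precision-weighted average of
    all incident messages - the re-rooted GLS estimator.  Returns
    ``(states, variances)`` keyed by preorder internal-node label; the
    variances are the GLS conditional variances up to the (unit) BM rate.
    """
    tree = tt.tree
    tips = tt.tip_labels
    missing = [t for t in tips if t not in tt.traits]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    lengths = _effective_lengths(tree)
    labels = internal_node_labels(tree)

    up_mean: dict = {}
    up_var: dict = {}   # variance of the up-message *above* the node's edge
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up_mean[id(node)] = float(np.asarray(tt.traits[node.taxon.label], dtype=float))
            up_var[id(node)] = 0.0
        else:
            weights = []
            means = []
            for ch in node.child_nodes():
                v = up_var[id(ch)] + lengths[id(ch)]
                weights.append(1.0 / v)
                means.append(up_mean[id(ch)])
            wsum = sum(weights)
            up_mean[id(node)] = sum(w * m for w, m in zip(weights, means)) / wsum
            up_var[id(node)] = 1.0 / wsum

    down_mean: dict = {}
    down_var: dict = {}  # message from the rest of the tree through the parent
    states: dict = {}
    variances: dict = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        msgs = []
        for ch in node.child_nodes():
            v = up_var[id(ch)] + lengths[id(ch)]
            msgs.append((up_mean[id(ch)], v))
        if node.parent_node is not None:
            msgs.append((down_mean[id(node)], down_var[id(node)]))
        wsum = sum(1.0 / v for _, v in msgs)
        est = sum(m / v for m, v in msgs) / wsum
        states[labels[id(node)]] = est
        variances[labels[id(node)]] = 1.0 / wsum
        # downward messages to children: everything incident on this node
        # except the child's own up-message (identified by position)
        child_msgs = [(up_mean[id(ch)], up_var[id(ch)] + lengths[id(ch)])
                      for ch in node.child_nodes()]
        parent_msg = ([(down_mean[id(node)], down_var[id(node)])]
                      if node.parent_node is not None else [])
        for i, ch in enumerate(node.child_nodes()):
            if ch.is_leaf():
                continue
            rest = child_msgs[:i] + child_msgs[i + 1:] + parent_msg
            wsum_r = sum(1.0 / v for _, v in rest)
            mean_r = sum(m / v for m, v in rest) / wsum_r
            down_mean[id(ch)] = mean_r
            down_var[id(ch)] = 1.0 / wsum_r + lengths[id(ch)]
    return states, variances


def sqcp_ancestral_shapes(tt: TraitTree, tip_shapes: dict | None = None,
                          weighted: bool = True) -> dict:
    """Squared-change parsimony ancestral states (scalar or shape vectors).

    Minimizes the sum over edges of (change)²/branch length (or the
    unweighted sum of squared changes with ``weighted=False``) with tip
    values fixed, by solving the tree's Laplacian linear system per
    coordinate.  With branch-length weights this equals the BM ML states
    applied coordinate-wise.
    """
    tree = tt.tree
    traits = tip_shapes if tip_shapes is not None else tt.traits
    tips = tt.tip_labels
    missing = [t for t in tips if t not in traits]
    if missing:
        raise ValueError(f"missing shapes for tips: {missing}")
    vals = {t: np.atleast_1d(np.asarray(traits[t], dtype=float)) for t in tips}
    dims = {v.shape for v in vals.values()}
    if len(dims) != 1:
        raise ValueError("tip shape dimensions differ")
    dim = vals[tips[0]].shape[0]

    lengths = _effective_lengths(tree)
    labels = internal_node_labels(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internal)}
    k = len(internal)
    a = np.zeros((k, k))
    b = np.zeros((k, dim))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = 1.0 / lengths[id(node)] if weighted else 1.0
        pi = index[id(node.parent_node)]
        if node.is_leaf():
            a[pi, pi] += w
            b[pi] += w * vals[node.taxon.label]
        else:
            ci = index[id(node)]
            a[pi, pi] += w
            a[ci, ci] += w
            a[pi, ci] -= w
            a[ci, pi] -= w
    sol = np.linalg.solve(a, b)
    out = {}
    for node in internal:
        v = sol[index[id(node)]]
        out[labels[id(node)]] = float(v[0]) if dim == 1 else v
    return out
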