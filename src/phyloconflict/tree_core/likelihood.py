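"""Felsenstein pruning on rooted trees with site-pattern compression.

The engine caches per-leaf partial likelihoods for the distinct site
patterns of an alignment and exposes both whole-tree evaluation and a
cheap single-edge profile used by coordinate-wise branch-length
optimization.
"""

from __future__ import annotations

import numpy as np

from .models import AMBIGUITY, SubstitutionModel
from .tree import RootedTree, TreeNode, TreeError


class AlignmentError(ValueError):
    pass


def compress_alignment(alignment: dict[str, str]):
    """Collapse an alignment to unique site patterns.

    Returns (taxa, pattern_matrix[char codes], weights, site_to_pattern).
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    n_sites = lengths.pop()
    if n_sites == 0:
        raise AlignmentError("zero-length alignment")
    mat = np.array([list(alignment[t].upper()) for t in taxa])
    patterns, site_to_pattern = np.unique(mat, axis=1, return_inverse=True)
    weights = np.bincount(site_to_pattern)
    return taxa, patterns, weights, site_to_pattern


def _leaf_partials(column: np.ndarray) -> np.ndarray:
    out = np.empty((len(column), 4))
    for i, ch in enumerate(column):
        try:
            out[i] = AMBIGUITY[ch]
        except KeyError:
            raise AlignmentError(f"unknown residue {ch!r}") from None
    return out


class LikelihoodEngine:
    """Per-site log-likelihoods of an alignment on a fixed topology.

    Branch lengths live on the tree nodes and may be modified between
    calls (the engine reads them afresh on every evaluation).
    """

    def __init__(self, tree: RootedTree, alignment: dict[str, str],
                 model: SubstitutionModel) -> None:
        leaf_names = set(tree.leaf_names())
        offenders = sorted(set(alignment) - leaf_names)
        if offenders:
            raise AlignmentError(
                f"alignment taxa missing from tree: {offenders}")
        self.tree = tree
        self.model = model
        taxa, patterns, weights, site_to_pattern = compress_alignment(
            alignment)
        self.weights = weights.astype(float)
        self.site_to_pattern = site_to_pattern
        self.n_patterns = patterns.shape[1]
        self.n_sites = len(site_to_pattern)
        self.rates = model.category_rates()

        self.nodes: list[TreeNode] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        row_of = {t: i for i, t in enumerate(taxa)}
        self.leaf_partial: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                if node.name not in row_of:
                    # leaf absent from the alignment: fully missing
                    self.leaf_partial[id(node)] = np.ones(
                        (self.n_patterns, 4))
                else:
                    self.leaf_partial[id(node)] = _leaf_partials(
                        patterns[row_of[node.name]])

    # ------------------------------------------------------------------
    def _edge_length(self, node: TreeNode) -> float:
        if node.length is None:
            raise TreeError(f"missing branch length above {node.name!r}")
        return node.length

    def _down_pass(self):
        """Conditional likelihoods below each node and child->parent
        messages, per rate category.  Shapes: (ncat, npat, 4)."""
        ncat = len(self.rates)
        down: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                lp = self.leaf_partial[id(node)]
                down[id(node)] = np.broadcast_to(
                    lp, (ncat, self.n_patterns, 4))
            else:
                acc = None
                for child in node.children:
                    m = msg[id(child)]
                    acc = m if acc is None else acc * m
                down[id(node)] = acc
            if node.parent is not None:
                t = self._edge_length(node)
                d = down[id(node)]
                out = np.empty_like(d, dtype=float)
                for c, r in enumerate(self.rates):
                    p = self.model.transition_matrix(t * r)
                    out[c] = d[c] @ p.T
                msg[id(node)] = out
        return down, msg

    def site_log_likelihoods(self) -> np.ndarray:
        """Vector of per-site log-likelihoods (original site order)."""
        down, _ = self._down_pass()
        root = down[id(self.tree.root)]
        per_pattern = np.einsum("cps,s->p", root, self.model.freqs)
        per_pattern /= len(self.rates)
        if np.any(per_pattern <= 0):
            per_pattern = np.clip(per_pattern, 1e-300, None)
        return np.log(per_pattern)[self.site_to_pattern]

    def log_likelihood(self) -> float:
        down, _ = self._down_pass()
        root = down[id(self.tree.root)]
        per_pattern = np.einsum("cps,s->p", root, self.model.freqs)
        per_pattern /= len(self.rates)
        per_pattern = np.clip(per_pattern, 1e-300, None)
        return float(self.weights @ np.log(per_pattern))

    # ------------------------------------------------------------------
    def edge_profile(self, node: TreeNode):
        """Closure f(t) -> total logL as a function of one branch length.

        ``node`` identifies the edge from its parent.  All other branch
        lengths are read at call time of :meth:`edge_profile` (not of the
        closure), so re-profile after changing other edges.
        """
        if node.parent is None:
            raise TreeError("the root has no subtending edge")
        down, msg = self._down_pass()
        ncat = len(self.rates)

        # upward partial at each node (likelihood of everything outside
        # the node's subtree, root prior included)
        up: dict[int, np.ndarray] = {
            id(self.tree.root): np.broadcast_to(
                self.model.freqs, (ncat, self.n_patterns, 4)).copy()}
        for parent in self.tree.preorder():
            if parent.is_leaf:
                continue
            for child in parent.children:
                acc = up[id(parent)].copy()
                for sib in parent.children:
                    if sib is not child:
                        acc *= msg[id(sib)]
                if child is node:
                    up_node = acc
                if not child.is_leaf:
                    t = self._edge_length(child)
                    out = np.empty_like(acc)
                    for c, r in enumerate(self.rates):
                        p = self.model.transition_matrix(t * r)
                        out[c] = acc[c] @ p
                    up[id(child)] = out
        d = down[id(node)]

        if self.model.family == "JC69" and ncat == 1:
            # P(t) = pd * J + (ps - pd) * I collapses the edge likelihood
            # to two per-pattern dot products
            su = up_node[0].sum(axis=1)
            sd = d[0].sum(axis=1)
            cross = (up_node[0] * d[0]).sum(axis=1)
            outer = su * sd

            def f(t: float) -> float:
                ps, pd = self.model.jc_probabilities(t)
                per_pattern = pd * outer + (ps - pd) * cross
                per_pattern = np.clip(per_pattern, 1e-300, None)
                return float(self.weights @ np.log(per_pattern))

            return f

        def f(t: float) -> float:
            per_pattern = np.zeros(self.n_patterns)
            for c, r in enumerate(self.rates):
                p = self.model.transition_matrix(t * r)
                per_pattern += np.einsum("ps,st,pt->p", up_node[c], p, d[c])
            per_pattern /= ncat
            per_pattern = np.clip(per_pattern, 1e-300, None)
            return float(self.weights @ np.log(per_pattern))

        return f


def site_log_likelihoods(tree: RootedTree, alignment: dict[str, str],
                         model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning."""
    return LikelihoodEngine(tree, alignment, model).site_log_likelihoods()


def log_likelihood(tree: RootedTree, alignment: dict[str, str],
                   model: SubstitutionModel) -> float:
    return LikelihoodEngine(tree, alignment, model).log_likelihood()
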