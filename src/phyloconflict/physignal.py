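"""Blomberg's K with a randomization test against the Brownian null.

K compares the observed ratio of the non-phylogenetic to the
phylogenetically corrected mean squared error with its expectation
under Brownian motion on the tree; K = 1 is the Brownian expectation,
K > 1 indicates stronger-than-Brownian conservatism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tree_core import RootedTree


@dataclass
class PhyloSignalResult:
    trait: str
    k: float
    p_value: float
    n_randomizations: int
    null_mode: str                 # "permutation" or "brownian"
    null_k: np.ndarray
    non_ultrametric: bool = False


def brownian_covariance(tree: RootedTree,
                        warn_non_ultrametric: bool = True
                        ) -> tuple[np.ndarray, list[str]]:
    """Tip covariance under Brownian motion: shared root-to-MRCA path.

    Returns (C, tip_labels) with C[i, j] the length of the common path
    from the root to the MRCA of tips i and j.
    """
    depths = tree.node_depths()
    leaves = tree.leaves()
    labels = [l.name for l in leaves]
    n = len(leaves)
    if max(depths[l] for l in leaves) <= 0:
        raise ValueError("tree depth must be positive")
    if warn_non_ultrametric and not tree.is_ultrametric(tol=1e-6):
        warnings.warn("tree is not ultrametric; K remains computable but "
                      "the Brownian null is approximate", RuntimeWarning)
    # ancestor sets per leaf for pairwise MRCA depth
    anc: dict[int, list] = {}
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent
        anc[id(leaf)] = chain
    c = np.zeros((n, n))
    for i in range(n):
        chain_i = anc[id(leaves[i])]
        set_i = {id(x) for x in chain_i}
        c[i, i] = depths[leaves[i]]
        for j in range(i + 1, n):
            node = leaves[j]
            while id(node) not in set_i:
                node = node.parent
            c[i, j] = c[j, i] = depths[node]
    return c, labels


def _k_statistic(x: np.ndarray, c: np.ndarray, c_inv: np.ndarray,
                 expected_ratio: float) -> float:
    n = len(x)
    ones = np.ones(n)
    denom = ones @ c_inv @ ones
    a_hat = (ones @ c_inv @ x) / denom
    resid = x - a_hat
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ c_inv @ resid) / (n - 1)
    if mse <= 0:
        raise ValueError("degenerate phylogenetic MSE")
    return float((mse0 / mse) / expected_ratio)


def _prepare(tree: RootedTree, trait: pd.Series):
    c, labels = brownian_covariance(tree, warn_non_ultrametric=False)
    missing = set(labels) - set(trait.index)
    extra = set(trait.index) - set(labels)
    if missing or extra:
        raise ValueError(f"trait/tip mismatch: missing={sorted(missing)}, "
                         f"extra={sorted(extra)}")
    x = trait[labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    if x.std() == 0:
        raise ValueError("constant trait: K undefined")
    n = len(x)
    try:
        c_inv = np.linalg.inv(c)
    except np.linalg.LinAlgError:
        raise ValueError("singular Brownian covariance matrix") from None
    ones = np.ones(n)
    expected = (np.trace(c) - n / (ones @ c_inv @ ones)) / (n - 1)
    return c, c_inv, x, expected


def blombergs_k(tree: RootedTree, trait: pd.Series) -> float:
    """Blomberg's K for one continuous trait on an ultrametric tree."""
    if tree.n_leaves() < 4:
        raise ValueError("need at least 4 tips")
    if tree.n_leaves() < 10:
        warnings.warn("K is unstable below 10 tips; interpret with care",
                      RuntimeWarning)
    c, c_inv, x, expected = _prepare(tree, trait)
    return _k_statistic(x, c, c_inv, expected)


def signal_randomization_test(tree: RootedTree, trait: pd.Series,
                              n_perm: int = 10000,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None,
                              null: str = "permutation",
                              trait_name: str = "trait"
                              ) -> PhyloSignalResult:
    """Randomization test of K.

    ``null='permutation'`` shuffles trait values across tips (default);
    ``null='brownian'`` simulates Brownian traits on the tree.  The
    p-value is (1 + #{null K >= observed K}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c, c_inv, x, expected = _prepare(tree, trait)
    k_obs = _k_statistic(x, c, c_inv, expected)
    null_k = np.empty(n_perm)
    if null == "permutation":
        for i in range(n_perm):
            null_k[i] = _k_statistic(rng.permutation(x), c, c_inv, expected)
    elif null == "brownian":
        chol = np.linalg.cholesky(c)
        sigma = float(np.std(x))
        for i in range(n_perm):
            sim = chol @ rng.standard_normal(len(x)) * sigma
            null_k[i] = _k_statistic(sim, c, c_inv, expected)
    else:
        raise ValueError("null must be 'permutation' or 'brownian'")
    p = (1.0 + np.sum(null_k >= k_obs)) / (1.0 + n_perm)
    return PhyloSignalResult(trait_name, k_obs, float(p), n_perm, null,
                             null_k,
                             non_ultrametric=not tree.is_ultrametric(1e-6))


def signal_table(tree: RootedTree, traits: pd.DataFrame,
                 n_perm: int = 10000, seed: Optional[int] = None,
                 null: str = "permutation") -> pd.DataFrame:
    """K and p for every trait column; mirrors a (trait, K, p) report."""
    rng = np.random.default_rng(seed)
    rows = []
    for col in traits.columns:
        res = signal_randomization_test(tree, traits[col], n_perm, rng=rng,
                                        null=null, trait_name=col)
        rows.append({"trait": col, "K": res.k, "p": res.p_value,
                     "null": null})
    return pd.DataFrame(rows)
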