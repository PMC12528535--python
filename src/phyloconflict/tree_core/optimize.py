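"""Branch-length optimization by coordinate-wise bounded search."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import LikelihoodEngine
from .models import SubstitutionModel
from .tree import RootedTree, TreeError

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0


def optimize_branch_lengths(
        topology: RootedTree,
        alignment: dict[str, str],
        model: SubstitutionModel,
        *,
        initial_length: float = 0.05,
        tol: float = 1e-6,
        max_sweeps: int = 40,
) -> tuple[RootedTree, float]:
    """Fit branch lengths of ``topology`` to ``alignment`` by ML.

    Each edge is optimized in turn with bounded Brent search on
    [1e-8, 10]; sweeps repeat until the relative log-likelihood change
    drops below ``tol``.  Returns a copy of the topology with fitted
    lengths and the total log-likelihood.
    """
    if not topology.is_binary():
        raise TreeError("branch-length optimization requires a binary tree")
    tree = topology.copy()
    for node in tree.postorder():
        if node.parent is not None and (node.length is None
                                        or not node.length > 0):
            node.length = initial_length
        node.length = None if node.parent is None else min(
            max(node.length, BRANCH_MIN), BRANCH_MAX)
    engine = LikelihoodEngine(tree, alignment, model)
    edges = [n for n in tree.postorder() if n.parent is not None]
    logl = engine.log_likelihood()
    start_logl = logl
    converged = False
    for _ in range(max_sweeps):
        prev = logl
        for edge in edges:
            f = engine.edge_profile(edge)
            res = minimize_scalar(
                lambda t: -f(t), bounds=(BRANCH_MIN, BRANCH_MAX),
                method="bounded", options={"xatol": 1e-8})
            if -res.fun >= f(edge.length):
                edge.length = float(res.x)
                logl = float(-res.fun)
        if abs(logl - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization hit the sweep cap; "
                      "returning best lengths found", RuntimeWarning)
    if logl < start_logl:  # bounded search can only improve; guard anyway
        logl = start_logl
    return tree, logl


def jc_distance(p_mismatch: float) -> float:
    """Analytic JC69 distance for an observed mismatch fraction."""
    if p_mismatch >= 0.75:
        return BRANCH_MAX
    return -0.75 * np.log(1.0 - 4.0 * p_mismatch / 3.0)


def select_model_bic(topology: RootedTree, alignment: dict[str, str],
                     families=("JC69", "K80", "HKY85", "GTR"),
                     **opt_kw) -> tuple[SubstitutionModel, dict[str, float]]:
    """Pick a substitution-model family for one alignment by BIC.

    Frequencies are empirical; K80/HKY85 kappa and GTR exchangeabilities
    are profiled with a small bounded optimization, alternating with
    branch-length fitting.  Returns the winning model and per-family BIC.
    """
    from scipy.optimize import minimize

    counts = np.zeros(4)
    for seq in alignment.values():
        for i, b in enumerate("ACGT"):
            counts[i] += seq.upper().count(b)
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    freqs = np.clip(freqs, 1e-3, None)
    freqs /= freqs.sum()
    n_sites = len(next(iter(alignment.values())))
    n_branches = sum(1 for n in topology.postorder() if n.parent is not None)

    scores: dict[str, float] = {}
    fitted: dict[str, SubstitutionModel] = {}
    for family in families:
        if family == "JC69":
            model = SubstitutionModel.jc69()
        elif family == "K80":
            model = SubstitutionModel.k80()
        elif family == "HKY85":
            model = SubstitutionModel.hky85(freqs)
        elif family == "GTR":
            model = SubstitutionModel.gtr(freqs, np.ones(6))
        else:
            raise ValueError(f"unknown family {family!r}")

        def refit(params, family=family):
            if family in ("K80", "HKY85"):
                kappa = float(np.exp(params[0]))
                fr = np.full(4, 0.25) if family == "K80" else freqs
                ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
            elif family == "GTR":
                ex = np.concatenate([np.exp(params), [1.0]])
                fr = freqs
            else:
                ex, fr = np.ones(6), np.full(4, 0.25)
            m = SubstitutionModel(family if family != "K80" else "K80",
                                  fr, ex)
            _, ll = optimize_branch_lengths(topology, alignment, m, **opt_kw)
            return m, ll

        if family == "JC69":
            model, logl = refit(np.zeros(0))
        elif family in ("K80", "HKY85"):
            res = minimize(lambda p: -refit(p)[1], x0=[np.log(2.0)],
                           method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-4,
                                    "maxiter": 40})
            model, logl = refit(res.x)
        else:
            res = minimize(lambda p: -refit(p)[1], x0=np.zeros(5),
                           method="Nelder-Mead",
                           options={"xatol": 1e-2, "fatol": 1e-3,
                                    "maxiter": 80})
            model, logl = refit(res.x)
        k = model.n_free_parameters() + n_branches
        scores[family] = k * np.log(n_sites) - 2.0 * logl
        fitted[family] = model
    best = min(scores, key=scores.get)
    return fitted[best], scores
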