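"""Classification of gene-tree discordance into ILS vs ILS+introgression.

For every taxon triplet and displayed rooted topology, internal branch
lengths across genes are modelled either as a single exponential
(ILS only) or as a two-component mixture of an exponential and a
delay-shifted exponential with shared rate (ILS + introgression).
Models are compared by BIC = k ln(n) - 2 logL; a topology is called
significant for introgression when BIC_mix - BIC_ils < -10.

This is a deliberate approximation of the QuIBL contrast: the ILS
component is an exponential rather than the full coalescent-derived
density, so decisions are about the mixture-vs-single contrast, not
numeric equality with QuIBL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .tree_core import RootedTree

DELTA_BIC_THRESHOLD = -10.0


@dataclass
class TripletObservation:
    gene_id: str
    triplet: tuple[str, str, str]
    outlier: str                  # the taxon outside the cherry
    internal_branch: float        # substitutions/site, >= 0

    @property
    def topology_label(self) -> str:
        pair = sorted(set(self.triplet) - {self.outlier})
        return f"(({pair[0]},{pair[1]}),{self.outlier})"


@dataclass
class MixtureFit:
    model: str                    # "ILS_only" or "ILS_plus_intro"
    pi_ils: float
    rate: float
    delay: float
    log_likelihood: float
    n_params: int
    n_obs: int
    degenerate: bool = False

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.log_likelihood


@dataclass
class TripletClassification:
    triplet: tuple[str, str, str]
    topology_label: str
    prop_ils: float
    prop_non_ils: float
    bic_mix: float
    bic_ils: float
    delta_bic: float
    n_genes: int
    n_ils_genes: int
    n_introgression_genes: int
    significant: bool
    posterior_prop_ils: float = float("nan")
    fits: tuple = field(default=(), repr=False)


# ----------------------------------------------------------------------
# extraction
# ----------------------------------------------------------------------
def triplet_categories(ingroup: Sequence[str]) -> list[tuple[tuple, str]]:
    """All (triplet, rooted-topology) categories for a set of ingroup taxa.

    Four ingroup taxa yield C(4,3) * 3 = 12 categories.
    """
    cats = []
    for trip in combinations(sorted(ingroup), 3):
        for outlier in trip:
            pair = sorted(set(trip) - {outlier})
            cats.append((trip, f"(({pair[0]},{pair[1]}),{outlier})"))
    return cats


def _collapse_to_species(tree: RootedTree,
                         species_of_sample: Optional[dict[str, str]]
                         ) -> RootedTree:
    """Keep one sample per species (first sample alphabetically)."""
    if not species_of_sample:
        return tree
    chosen: dict[str, str] = {}
    for sample in sorted(tree.leaf_names()):
        sp = species_of_sample.get(sample, sample)
        chosen.setdefault(sp, sample)
    restricted = tree.restrict(sorted(chosen.values()))
    sample_to_species = {v: k for k, v in chosen.items()}
    return restricted.map_leaf_names(lambda s: sample_to_species.get(s, s))


def extract_triplet_observations(
        gene_trees: Sequence[RootedTree],
        ingroup: Sequence[str],
        outgroup: str,
        species_of_sample: Optional[dict[str, str]] = None,
        gene_ids: Optional[Sequence[str]] = None,
        skipped: Optional[list] = None) -> list[TripletObservation]:
    """Per-gene, per-triplet displayed topologies and internal branches.

    Each gene tree is rooted by ``outgroup``, restricted to each
    3-subset of ``ingroup``, and the branch between the two coalescences
    recorded.  Genes missing the outgroup or an ingroup taxon are
    skipped (ids appended to ``skipped`` when given).
    """
    obs: list[TripletObservation] = []
    ingroup = sorted(ingroup)
    for gi, tree in enumerate(gene_trees):
        gene_id = gene_ids[gi] if gene_ids is not None else f"gene{gi + 1}"
        tree = _collapse_to_species(tree, species_of_sample)
        names = set(tree.leaf_names())
        if outgroup not in names or not set(ingroup) <= names:
            if skipped is not None:
                skipped.append(gene_id)
            continue
        rooted = tree.reroot_with_outgroup(outgroup)
        for trip in combinations(ingroup, 3):
            sub = rooted.restrict(list(trip) + [outgroup])
            sub = sub.reroot_with_outgroup(outgroup)
            ing = sub.mrca(trip)
            # displayed topology: the cherry under the triplet's MRCA
            cherry = None
            for child in ing.children:
                leaves_below = [l.name for l in RootedTree(child).leaves()
                                if l.name in trip]
                if len(leaves_below) == 2:
                    cherry = child
            if cherry is None:  # polytomy: unresolved triplet, skip
                continue
            pair = {l.name for l in RootedTree(cherry).leaves()}
            outlier = next(iter(set(trip) - pair))
            t_int = cherry.length or 0.0
            obs.append(TripletObservation(gene_id, trip, outlier,
                                          float(max(t_int, 0.0))))
    return obs


# ----------------------------------------------------------------------
# mixture fitting
# ----------------------------------------------------------------------
def _exp_loglik(t: np.ndarray, rate: float) -> float:
    return float(len(t) * np.log(rate) - rate * t.sum())


def _mixture_loglik(t: np.ndarray, pi: float, rate: float,
                    delay: float) -> float:
    comp1 = pi * rate * np.exp(-rate * t)
    shifted = t - delay
    comp2 = np.where(shifted >= 0,
                     (1.0 - pi) * rate * np.exp(-rate *
                                                np.maximum(shifted, 0.0)),
                     0.0)
    dens = comp1 + comp2
    if np.any(dens <= 0):
        return -np.inf
    return float(np.log(dens).sum())


def _responsibilities(t: np.ndarray, pi: float, rate: float,
                      delay: float) -> np.ndarray:
    comp1 = pi * rate * np.exp(-rate * t)
    shifted = t - delay
    comp2 = np.where(shifted >= 0,
                     (1.0 - pi) * rate * np.exp(-rate *
                                                np.maximum(shifted, 0.0)),
                     0.0)
    tot = comp1 + comp2
    tot = np.where(tot <= 0, 1e-300, tot)
    return comp2 / tot  # responsibility of the introgression component


def em_fit_mixture(t_values: Sequence[float], model: str = "ILS_plus_intro",
                   tol: float = 1e-10, max_iter: int = 2000,
                   n_starts: int = 10) -> MixtureFit:
    """Fit the ILS-only exponential or the shared-rate mixture by EM.

    The mixture is fitted from ``n_starts`` deterministic starts with
    the delay initialized at quantiles of the data; (pi, rate) are
    updated by EM steps and the delay by a bounded profile search each
    iteration, so the observed log-likelihood is non-decreasing.
    """
    t = np.asarray(list(t_values), dtype=float)
    if len(t) < 5:
        raise ValueError(f"need at least 5 observations, got {len(t)}")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("internal branch lengths must be finite and >= 0")
    degenerate = float(t.max() - t.min()) == 0.0 or t.mean() == 0.0
    mean = t.mean() if t.mean() > 0 else 1e-12
    rate0 = 1.0 / mean

    if model == "ILS_only":
        ll = _exp_loglik(t, rate0) if not degenerate else \
            _exp_loglik(np.maximum(t, 1e-12), min(rate0, 1e12))
        return MixtureFit("ILS_only", 1.0, min(rate0, 1e12), 0.0, ll, 1,
                          len(t), degenerate=degenerate)
    if model != "ILS_plus_intro":
        raise ValueError(f"unknown model {model!r}")
    if degenerate:
        ll = _exp_loglik(np.maximum(t, 1e-12), min(rate0, 1e12))
        return MixtureFit("ILS_plus_intro", 1.0, min(rate0, 1e12), 0.0, ll,
                          3, len(t), degenerate=True)

    best: Optional[tuple] = None
    quantiles = np.quantile(t, np.linspace(0.05, 0.95, n_starts))
    t_max = float(t.max())
    for delay0 in quantiles:
        pi, rate, delay = 0.7, rate0, float(delay0)
        ll = _mixture_loglik(t, pi, rate, delay)
        for _outer in range(60):
            # EM on (pi, rate) at fixed delay; monotone by construction
            for _ in range(max_iter):
                resp2 = _responsibilities(t, pi, rate, delay)
                new_pi = float(np.clip(1.0 - resp2.sum() / len(t),
                                       1e-6, 1.0 - 1e-6))
                denom = float(((1.0 - resp2) * t).sum()
                              + (resp2 * np.maximum(t - delay, 0.0)).sum())
                new_rate = len(t) / max(denom, 1e-300)
                cand_ll = _mixture_loglik(t, new_pi, new_rate, delay)
                assert cand_ll >= ll - 1e-9, "EM log-likelihood decreased"
                if cand_ll < ll:
                    break
                pi, rate = new_pi, new_rate
                if abs(cand_ll - ll) <= tol * (abs(ll) + 1.0):
                    ll = cand_ll
                    break
                ll = cand_ll
            # profile step on the delay (accepted only if it improves)
            res = minimize_scalar(
                lambda d: -_mixture_loglik(t, pi, rate, d),
                bounds=(0.0, t_max), method="bounded",
                options={"xatol": 1e-10})
            if -res.fun > ll + tol * (abs(ll) + 1.0):
                delay = float(res.x)
                ll = float(-res.fun)
            else:
                if -res.fun > ll:
                    delay = float(res.x)
                    ll = float(-res.fun)
                break
        if best is None or ll > best[0]:
            best = (ll, pi, rate, delay)
    ll, pi, rate, delay = best
    ll_ils = _exp_loglik(t, rate0)
    if ll < ll_ils - 1e-6:
        # mixture nests the single exponential; never report worse
        pi, rate, delay, ll = 1.0 - 1e-9, rate0, 0.0, ll_ils
    return MixtureFit("ILS_plus_intro", pi, rate, delay, ll, 3, len(t))


def classify_triplet_topology(
        observations: Sequence[TripletObservation],
        threshold: float = DELTA_BIC_THRESHOLD) -> TripletClassification:
    """BIC contrast and gene assignment for one (triplet, topology)."""
    if not observations:
        raise ValueError("no observations for this category")
    trip = observations[0].triplet
    label = observations[0].topology_label
    t = np.array([o.internal_branch for o in observations])
    fit_ils = em_fit_mixture(t, "ILS_only")
    fit_mix = em_fit_mixture(t, "ILS_plus_intro")
    delta = fit_mix.bic - fit_ils.bic
    n = len(t)
    if delta < threshold and not fit_mix.degenerate:
        resp2 = _responsibilities(t, fit_mix.pi_ils, fit_mix.rate,
                                  fit_mix.delay)
        n_intro = int((resp2 > 0.5).sum())
        prop_ils = fit_mix.pi_ils
        post_prop = 1.0 - float(resp2.mean())
        significant = True
    else:
        n_intro = 0
        prop_ils = 1.0
        post_prop = 1.0
        significant = False
    return TripletClassification(
        trip, label, prop_ils, 1.0 - prop_ils, fit_mix.bic, fit_ils.bic,
        delta, n, n - n_intro, n_intro, significant,
        posterior_prop_ils=post_prop, fits=(fit_ils, fit_mix))


def classify_all(observations: Sequence[TripletObservation],
                 min_genes: int = 5,
                 threshold: float = DELTA_BIC_THRESHOLD
                 ) -> list[TripletClassification]:
    """Classify every (triplet, topology) category with enough genes."""
    buckets: dict[tuple, list[TripletObservation]] = {}
    for o in observations:
        buckets.setdefault((o.triplet, o.topology_label), []).append(o)
    out = []
    for key in sorted(buckets):
        if len(buckets[key]) >= min_genes:
            out.append(classify_triplet_topology(buckets[key], threshold))
    return out


def classifications_to_frame(
        classifications: Sequence[TripletClassification]) -> pd.DataFrame:
    """Summary table shaped like the per-topology report."""
    return pd.DataFrame([{
        "topology": c.topology_label,
        "Prop_ILS": c.prop_ils,
        "Prop_non-ILS": c.prop_non_ils,
        "BIC_ILS+intro": c.bic_mix,
        "BIC_ILS_only": c.bic_ils,
        "dBIC": c.delta_bic,
        "n_genes": c.n_genes,
        "n_ILS": c.n_ils_genes,
        "n_introgression": c.n_introgression_genes,
        "significant": c.significant,
    } for c in classifications])
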