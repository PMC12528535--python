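"""Multispecies-coalescent simulation under declared demographic scenarios.

Simulates gene genealogies by the structured coalescent (divergence and
pulse-admixture events, diploid scaling: pairwise coalescence rate
1/(2N) per generation within a population of diploid size N), evolves
sequence alignments along gene trees, and generates microsatellite
panels under the strict stepwise mutation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree_core import RootedTree, TreeNode
from .tree_core.models import SubstitutionModel


class ScenarioError(ValueError):
    pass


@dataclass
class DivergenceEvent:
    """Backward in time: ``derived`` populations merge into ``ancestor``."""
    time: float
    derived: tuple[str, ...]
    ancestor: str

    def __post_init__(self) -> None:
        self.derived = tuple(self.derived)
        if self.time <= 0:
            raise ScenarioError("divergence time must be positive")


@dataclass
class AdmixtureEvent:
    """Backward in time: each lineage in ``recipient`` moves to ``donor``
    with probability ``proportion``."""
    time: float
    recipient: str
    donor: str
    proportion: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ScenarioError("admixture time must be positive")
        if not 0.0 <= self.proportion <= 1.0:
            raise ScenarioError("admixture proportion must be in [0, 1]")


@dataclass
class DemographicScenario:
    populations: list[str]
    sizes: dict[str, float]
    divergences: list[DivergenceEvent] = field(default_factory=list)
    admixtures: list[AdmixtureEvent] = field(default_factory=list)
    mu: float = 1e-8            # substitutions / site / generation
    mu_ssr: float = 1e-4        # SSR mutations / locus / generation
    generation_time: float = 1.0  # years / generation
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pop, n in self.sizes.items():
            if n <= 0:
                raise ScenarioError(f"population size of {pop!r} must be > 0")
        known = set(self.sizes)
        for pop in self.populations:
            if pop not in known:
                raise ScenarioError(f"no size declared for {pop!r}")
        alive = set(self.populations)
        for ev in self._events():
            if isinstance(ev, AdmixtureEvent):
                if ev.recipient not in alive:
                    raise ScenarioError(
                        f"admixture recipient {ev.recipient!r} not alive at "
                        f"time {ev.time}")
                if ev.donor not in alive:
                    raise ScenarioError(
                        f"admixture donor {ev.donor!r} not alive at time "
                        f"{ev.time}")
            else:
                for pop in ev.derived:
                    if pop not in alive:
                        raise ScenarioError(
                            f"population {pop!r} already absorbed before its "
                            f"divergence at time {ev.time}")
                    alive.discard(pop)
                if ev.ancestor not in self.sizes:
                    raise ScenarioError(
                        f"no size declared for ancestor {ev.ancestor!r}")
                alive.add(ev.ancestor)
        if len(alive) != 1:
            raise ScenarioError(
                f"{len(alive)} populations remain at the oldest time "
                f"({sorted(alive)}); exactly one must remain")

    def _events(self):
        """Events in forward order of (time, admixtures-before-divergences)."""
        evs: list = list(self.divergences) + list(self.admixtures)
        return sorted(evs, key=lambda e: (e.time,
                                          isinstance(e, DivergenceEvent)))


@dataclass
class SampleConfig:
    """Lineages (haploid) or individuals (diploid) sampled per population."""
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for pop, k in self.counts.items():
            if k < 0:
                raise ScenarioError(f"negative sample count for {pop!r}")
        if sum(self.counts.values()) < 1:
            raise ScenarioError("at least one sample required")


# ----------------------------------------------------------------------
# core structured coalescent on flat arrays
# ----------------------------------------------------------------------
def _simulate_coalescent_arrays(scenario: DemographicScenario,
                                lineage_pops: Sequence[str],
                                rng: np.random.Generator):
    """Structured coalescent for named lineages.

    Returns (parent, time) arrays over 2n-1 nodes; tips are nodes
    0..n-1 in input order, the root is the last created node.  Times are
    in generations.
    """
    n = len(lineage_pops)
    if n < 2:
        raise ScenarioError("need at least two lineages")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active: dict[str, list[int]] = {}
    for i, pop in enumerate(lineage_pops):
        if pop not in scenario.sizes:
            raise ScenarioError(f"sample population {pop!r} unknown")
        active.setdefault(pop, []).append(i)
    events = scenario._events()
    ev_idx = 0
    t = 0.0
    next_node = n
    sizes = scenario.sizes
    n_active = n
    while True:
        if n_active == 1 and ev_idx >= len(events):
            break
        pops = []
        rates = []
        total = 0.0
        for p, v in active.items():
            k = len(v)
            if k >= 2:
                rate = k * (k - 1) / (4.0 * sizes[p])
                pops.append(p)
                rates.append(rate)
                total += rate
        next_ev = events[ev_idx].time if ev_idx < len(events) else math.inf
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if t + wait < next_ev:
            t += wait
            if len(pops) == 1:
                pop = pops[0]
            else:
                u = rng.random() * total
                acc = 0.0
                for pop, rate in zip(pops, rates):
                    acc += rate
                    if u < acc:
                        break
            lin = active[pop]
            k = len(lin)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = lin[i], lin[j]
            hi, lo = (i, j) if i > j else (j, i)
            lin[hi] = lin[-1]     # remove both by swap-with-last
            lin.pop()
            lin[lo] = lin[-1]
            lin.pop()
            lin.append(next_node)
            parent[a] = parent[b] = next_node
            time[next_node] = t
            next_node += 1
            n_active -= 1
        else:
            if math.isinf(next_ev):
                raise ScenarioError(
                    "lineages remain in separate populations with no "
                    "ancestral population to merge them")
            t = next_ev
            ev = events[ev_idx]
            ev_idx += 1
            if isinstance(ev, AdmixtureEvent):
                recip = active.get(ev.recipient, [])
                if recip:
                    move = rng.random(len(recip)) < ev.proportion
                    stay = [x for x, mv in zip(recip, move) if not mv]
                    moved = [x for x, mv in zip(recip, move) if mv]
                    active[ev.recipient] = stay
                    active.setdefault(ev.donor, []).extend(moved)
            else:
                merged = active.setdefault(ev.ancestor, [])
                for pop in ev.derived:
                    merged.extend(active.pop(pop, []))
    # trim unused entries when early coalescences were impossible
    return parent[:next_node], time[:next_node]


def _arrays_to_tree(parent: np.ndarray, time: np.ndarray,
                    labels: list[str]) -> RootedTree:
    n_nodes = len(parent)
    nodes = [TreeNode() for _ in range(n_nodes)]
    for i, lbl in enumerate(labels):
        nodes[i].name = lbl
    root = None
    for i in range(n_nodes):
        nodes[i].annotations["time"] = float(time[i])
        if parent[i] >= 0:
            nodes[parent[i]].add_child(nodes[i])
            nodes[i].length = float(time[parent[i]] - time[i])
        else:
            root = nodes[i]
    return RootedTree(root)


def simulate_gene_tree(scenario: DemographicScenario,
                       samples: SampleConfig,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> RootedTree:
    """One gene genealogy; branch lengths in generations.

    Leaves are labelled ``pop_1 .. pop_k`` per population (plain ``pop``
    when a single lineage is sampled).  Node times (generations before
    present) are stored in ``annotations['time']``; coalescent-unit
    times relative to a reference size N are ``time / (2N)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels: list[str] = []
    pops: list[str] = []
    for pop, k in samples.counts.items():
        for i in range(k):
            labels.append(pop if k == 1 else f"{pop}_{i + 1}")
            pops.append(pop)
    parent, time = _simulate_coalescent_arrays(scenario, pops, rng)
    return _arrays_to_tree(parent, time, labels)


def to_substitution_units(gene_tree: RootedTree, mu: float) -> RootedTree:
    """Rescale branch lengths from generations to substitutions/site."""
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    return gene_tree.scale_lengths(mu)


def simulate_alignment(gene_tree: RootedTree, model: SubstitutionModel,
                       n_sites: int,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> dict[str, str]:
    """Evolve sequences along a tree with lengths in substitutions/site."""
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = model.category_rates()
    site_rate = rates[rng.integers(0, len(rates), size=n_sites)] \
        if len(rates) > 1 else None
    states: dict[int, np.ndarray] = {}
    root = gene_tree.root
    states[id(root)] = rng.choice(4, size=n_sites, p=model.freqs)
    out: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for node in gene_tree.preorder():
        if node is not root:
            t = node.length or 0.0
            parent_states = states[id(node.parent)]
            child = np.empty(n_sites, dtype=np.int64)
            if site_rate is None:
                p = model.transition_matrix(t)
                cum = np.cumsum(p, axis=1)
                u = rng.random(n_sites)
                for s in range(4):
                    mask = parent_states == s
                    child[mask] = np.searchsorted(cum[s], u[mask],
                                                  side="right")
            else:
                for r in np.unique(site_rate):
                    p = model.transition_matrix(t * r)
                    cum = np.cumsum(p, axis=1)
                    rmask = site_rate == r
                    u = rng.random(rmask.sum())
                    sub = np.empty(rmask.sum(), dtype=np.int64)
                    ps = parent_states[rmask]
                    for s in range(4):
                        mask = ps == s
                        sub[mask] = np.searchsorted(cum[s], u[mask],
                                                    side="right")
                    child[rmask] = sub
            np.clip(child, 0, 3, out=child)
            states[id(node)] = child
        if node.is_leaf:
            out[node.name] = "".join(bases[states[id(node)]])
    return out


# ----------------------------------------------------------------------
# microsatellites (strict stepwise mutation model)
# ----------------------------------------------------------------------
ROOT_REPEAT = 100


def simulate_ssr(scenario: DemographicScenario, samples: SampleConfig,
                 n_loci: int, mu_ssr: Optional[float] = None,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Diploid SSR genotype table under the strict +/-1 SMM.

    ``samples.counts`` gives diploid individuals per population.  The
    result has one row per individual with columns ``individual``,
    ``population`` and ``L{i}_1``/``L{i}_2`` integer repeat scores.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if mu_ssr is None:
        mu_ssr = scenario.mu_ssr
    if rng is None:
        rng = np.random.default_rng(seed)
    pops: list[str] = []
    inds: list[str] = []
    for pop, k in samples.counts.items():
        for i in range(k):
            inds.append(f"{pop}_{i + 1}")
            pops.append(pop)
    lineage_pops = np.repeat(pops, 2)
    n_lin = len(lineage_pops)
    geno = np.empty((len(inds), 2 * n_loci), dtype=np.int64)
    for locus in range(n_loci):
        parent, time = _simulate_coalescent_arrays(
            scenario, lineage_pops, rng)
        alleles = _smm_alleles(parent, time, mu_ssr, rng)
        geno[:, 2 * locus] = alleles[0::2][:len(inds)]
        geno[:, 2 * locus + 1] = alleles[1::2][:len(inds)]
    cols = {}
    for locus in range(n_loci):
        cols[f"L{locus + 1}_1"] = geno[:, 2 * locus]
        cols[f"L{locus + 1}_2"] = geno[:, 2 * locus + 1]
    df = pd.DataFrame({"individual": inds, "population": pops, **cols})
    return df


def _smm_alleles(parent: np.ndarray, time: np.ndarray, mu_ssr: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Allele sizes at the tips of a coalescent tree under the SMM."""
    n_nodes = len(parent)
    has_parent = parent >= 0
    blen = np.zeros(n_nodes)
    blen[has_parent] = time[parent[has_parent]] - time[has_parent]
    n_mut = rng.poisson(mu_ssr * blen)
    steps = np.zeros(n_nodes, dtype=np.int64)
    nz = n_mut > 0
    if nz.any():
        ups = rng.binomial(n_mut[nz], 0.5)
        steps[nz] = 2 * ups - n_mut[nz]
    value = np.full(n_nodes, ROOT_REPEAT, dtype=np.int64)
    order = np.argsort(time)[::-1]  # root first (oldest time)
    for i in order:
        if has_parent[i]:
            value[i] = value[parent[i]] + steps[i]
    n_tips = (n_nodes + 1) // 2
    return value[:n_tips]


def write_ssr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ssr_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
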