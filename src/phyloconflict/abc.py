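"""Rejection ABC over demographic scenarios on SSR summary statistics.

Summary statistics per population (mean allele count, unbiased expected
heterozygosity, allele-size SD), per population pair (Weir-Cockerham
FST, mean squared allele-size difference) and globally (total allele
count) are computed for observed and simulated panels.  Highly
correlated statistics are pruned greedily (|Pearson r| > threshold),
the remaining columns are standardized by median absolute deviation,
and plain rejection retains the nearest simulations for model choice
and log-scale parameter estimation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msc_sim import DemographicScenario, SampleConfig, simulate_ssr
from .scenarios import ScenarioTemplate


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------
def _locus_columns(df: pd.DataFrame) -> list[tuple[str, str]]:
    loci = []
    i = 1
    while f"L{i}_1" in df.columns:
        loci.append((f"L{i}_1", f"L{i}_2"))
        i += 1
    if not loci:
        raise ValueError("no locus columns (expected L1_1, L1_2, ...)")
    return loci


def compute_sumstats(ssr: pd.DataFrame,
                     populations: Optional[Sequence[str]] = None
                     ) -> pd.Series:
    """Named SSR summary statistics for one genotype table."""
    if populations is None:
        populations = sorted(ssr["population"].unique())
    loci = _locus_columns(ssr)
    stats: dict[str, float] = {}
    alleles_by_pop: dict[str, np.ndarray] = {}
    pop_col = ssr["population"].to_numpy()
    all_cols = ssr[[c for pair in loci for c in pair]].to_numpy()
    for pop in populations:
        mask = pop_col == pop
        if mask.sum() < 2:
            raise ValueError(f"need >= 2 individuals in population {pop!r}")
        block = all_cols[mask]  # (individuals, 2 * loci)
        mat = np.stack([np.concatenate([block[:, 2 * l], block[:, 2 * l + 1]])
                        for l in range(len(loci))])  # (loci, 2*individuals)
        alleles_by_pop[pop] = mat
        ks, hs, sds = [], [], []
        for row in mat:
            vals, cnt = np.unique(row, return_counts=True)
            n = len(row)
            p = cnt / n
            ks.append(len(vals))
            hs.append(n / (n - 1) * (1.0 - np.sum(p ** 2)))
            sds.append(row.std(ddof=1))
        stats[f"K_{pop}"] = float(np.mean(ks))
        stats[f"H_{pop}"] = float(np.mean(hs))
        stats[f"sd_{pop}"] = float(np.mean(sds))
    for p1, p2 in combinations(populations, 2):
        stats[f"fst_{p1}_{p2}"] = weir_cockerham_fst(
            alleles_by_pop[p1], alleles_by_pop[p2])
        d = alleles_by_pop[p1].mean(axis=1) - alleles_by_pop[p2].mean(axis=1)
        stats[f"dmu2_{p1}_{p2}"] = float(np.mean(d ** 2))
    total = 0
    for li in range(len(loci)):
        allp = np.concatenate([alleles_by_pop[p][li] for p in populations])
        total += len(np.unique(allp))
    stats["K_total"] = float(total)
    return pd.Series(stats)


def weir_cockerham_fst(alleles1: np.ndarray, alleles2: np.ndarray) -> float:
    """Multi-locus, multi-allele Weir-Cockerham theta for two populations.

    Inputs are (loci x 2*individuals) arrays of integer allele sizes;
    individuals are haploid-encoded (each column one allele copy), so
    the within-individual component is folded into the error term
    (heterozygosity-free estimator).  Returns 0 with a warning when the
    panel is monomorphic everywhere.
    """
    n1 = alleles1.shape[1]
    n2 = alleles2.shape[1]
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    num = 0.0
    den = 0.0
    for row1, row2 in zip(alleles1, alleles2):
        allv = np.unique(np.concatenate([row1, row2]))
        if len(allv) < 2:
            continue
        p1 = (row1[None, :] == allv[:, None]).mean(axis=1)
        p2 = (row2[None, :] == allv[:, None]).mean(axis=1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) \
            / ((r - 1) * nbar)
        het = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - het / (nbar - 1))
        b = (nbar / (nbar - 1)) * het
        num += float(a.sum())
        den += float((a + b).sum())
    if den == 0.0:
        warnings.warn("monomorphic panel: FST undefined, reporting 0",
                      RuntimeWarning)
        return 0.0
    return float(num / den)


# ----------------------------------------------------------------------
# statistic pruning
# ----------------------------------------------------------------------
def filter_correlated(stat_matrix: pd.DataFrame,
                      threshold: float = 0.8) -> list[str]:
    """Greedy correlation pruning in column-declaration order.

    A statistic is kept iff its |Pearson r| with every already-kept
    statistic is <= threshold.  Zero-variance columns are dropped with
    a warning.  Deterministic given the column order.
    """
    if stat_matrix.shape[1] < 2:
        raise ValueError("need at least 2 statistics")
    if stat_matrix.shape[0] < 10:
        raise ValueError("need at least 10 rows to estimate correlations")
    values = stat_matrix.to_numpy(dtype=float)
    names = list(stat_matrix.columns)
    stds = values.std(axis=0)
    kept: list[int] = []
    for j, name in enumerate(names):
        if stds[j] == 0.0:
            warnings.warn(f"dropping constant statistic {name!r}",
                          RuntimeWarning)
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(values[:, j], values[:, k])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return [names[j] for j in kept]


# ----------------------------------------------------------------------
# simulation bank
# ----------------------------------------------------------------------
@dataclass
class SimulationTable:
    """Banked simulations: per row a model id, drawn parameters, stats."""
    frame: pd.DataFrame           # columns: model, param:*, stat columns
    stat_names: list[str]
    param_names: list[str]
    provenance: dict = field(default_factory=dict)

    def stats(self) -> pd.DataFrame:
        return self.frame[self.stat_names]

    def to_tsv(self, path, sidecar: Optional[str] = None) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
        if sidecar:
            with open(sidecar, "w") as fh:
                json.dump({"stat_names": self.stat_names,
                           "param_names": self.param_names,
                           "provenance": self.provenance}, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, sidecar) -> "SimulationTable":
        frame = pd.read_csv(path, sep="\t")
        with open(sidecar) as fh:
            meta = json.load(fh)
        return cls(frame, meta["stat_names"], meta["param_names"],
                   meta.get("provenance", {}))


def simulate_bank(templates: Sequence[ScenarioTemplate],
                  samples: SampleConfig, n_loci: int, n_sims: int,
                  seed: int, mu_ssr: Optional[float] = None
                  ) -> SimulationTable:
    """Draw parameters from each template's priors and bank SSR stats.

    Per-replicate seeds are derived from ``seed`` by a counter scheme
    (replicate i of template j uses child stream j * n_sims + i) and
    recorded in the provenance block.
    """
    rows = []
    param_names: list[str] = []
    for tmpl in templates:
        for p in tmpl.parameters:
            if p not in param_names:
                param_names.append(p)
    stat_names: Optional[list[str]] = None
    for tj, tmpl in enumerate(templates):
        for i in range(n_sims):
            rng = np.random.default_rng([seed, tj, i])
            params = tmpl.sample_params(rng)
            if mu_ssr is not None:
                params["mu_ssr"] = mu_ssr
            scenario = tmpl.build(params)
            ssr = simulate_ssr(scenario, samples, n_loci, rng=rng)
            stats = compute_sumstats(ssr)
            if stat_names is None:
                stat_names = list(stats.index)
            row = {"model": tmpl.name}
            row.update({f"param:{k}": params.get(k, np.nan)
                        for k in param_names})
            row.update(stats.to_dict())
            rows.append(row)
    frame = pd.DataFrame(rows)
    return SimulationTable(
        frame, stat_names, param_names,
        provenance={"seed": seed, "n_sims": n_sims,
                    "templates": [t.name for t in templates],
                    "seed_scheme": "default_rng([seed, template_idx, i])"})


# ----------------------------------------------------------------------
# rejection ABC
# ----------------------------------------------------------------------
@dataclass
class ABCModelPosterior:
    posterior: dict[str, float]
    n_retained: int
    distance_quantile: float
    stat_names: list[str]

    @property
    def best_model(self) -> str:
        return max(self.posterior, key=self.posterior.get)


@dataclass
class ABCParameterPosterior:
    model: str
    samples: pd.DataFrame         # retained rows, original scale
    point: dict[str, float]       # medians
    interval: dict[str, tuple[float, float]]  # central 95%


def _standardize(table_stats: np.ndarray):
    med = np.median(table_stats, axis=0)
    mad = np.median(np.abs(table_stats - med), axis=0)
    mad = np.where(mad == 0.0, 1.0, mad)
    return med, mad


def _distances(observed: np.ndarray, table_stats: np.ndarray) -> np.ndarray:
    med, mad = _standardize(table_stats)
    z = (table_stats - med) / mad
    zo = (observed - med) / mad
    return np.sqrt(((z - zo) ** 2).sum(axis=1))


def abc_model_selection(observed: pd.Series, table: SimulationTable,
                        n_retain: int = 5000,
                        stat_names: Optional[Sequence[str]] = None
                        ) -> ABCModelPosterior:
    """Posterior model probabilities from the nearest retained rows."""
    if stat_names is None:
        stat_names = table.stat_names
    stat_names = list(stat_names)
    n_rows = len(table.frame)
    if n_retain > n_rows:
        raise ValueError(f"n_retain={n_retain} exceeds {n_rows} rows")
    obs = observed[stat_names].to_numpy(dtype=float)
    sims = table.frame[stat_names].to_numpy(dtype=float)
    dist = _distances(obs, sims)
    order = np.argsort(dist, kind="stable")[:n_retain]
    models = table.frame["model"].to_numpy()[order]
    uniq = sorted(table.frame["model"].unique())
    posterior = {m: float(np.mean(models == m)) for m in uniq}
    return ABCModelPosterior(posterior, n_retain,
                             float(n_retain / n_rows), stat_names)


def abc_parameter_estimate(observed: pd.Series, table: SimulationTable,
                           model: str, n_retain: int = 2000,
                           log_transform: bool = True,
                           stat_names: Optional[Sequence[str]] = None
                           ) -> ABCParameterPosterior:
    """Log-scale rejection posterior for one model's parameters."""
    if stat_names is None:
        stat_names = table.stat_names
    stat_names = list(stat_names)
    sub = table.frame[table.frame["model"] == model]
    if len(sub) < n_retain:
        raise ValueError(
            f"model {model!r} has {len(sub)} rows < n_retain={n_retain}")
    obs = observed[stat_names].to_numpy(dtype=float)
    sims = sub[stat_names].to_numpy(dtype=float)
    dist = _distances(obs, sims)
    order = np.argsort(dist, kind="stable")[:n_retain]
    param_cols = [c for c in sub.columns if c.startswith("param:")]
    retained = sub.iloc[order][param_cols].rename(
        columns=lambda c: c[len("param:"):])
    retained = retained.dropna(axis=1, how="all")
    point: dict[str, float] = {}
    interval: dict[str, tuple[float, float]] = {}
    for name in retained.columns:
        vals = retained[name].to_numpy(dtype=float)
        if log_transform:
            if np.any(vals <= 0):
                raise ValueError(
                    f"parameter {name!r} has non-positive values; cannot "
                    f"log-transform")
            logs = np.log(vals)
            point[name] = float(np.exp(np.median(logs)))
            lo, hi = np.percentile(logs, [2.5, 97.5])
            interval[name] = (float(np.exp(lo)), float(np.exp(hi)))
        else:
            point[name] = float(np.median(vals))
            lo, hi = np.percentile(vals, [2.5, 97.5])
            interval[name] = (float(lo), float(hi))
    return ABCParameterPosterior(model, retained, point, interval)
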