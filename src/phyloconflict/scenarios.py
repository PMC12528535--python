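"""Registry of the nine demographic scenario templates (a-i).

The templates cover four hypothesis classes over the taxa
``att``, ``dai``, ``lgk`` and ``mus``:

* H1 (``a``, ``b``): ``mus`` is of hybrid origin between ``att`` and
  ``dai`` (pulse admixture with proportion ``gamma``).
* H2 (``c``): the species-tree arrangement ``(((att,lgk),mus),dai)``.
* H3 (``d``, ``e``, ``f``): ``dai`` sister to ``mus``.
* H4 (``g``, ``h``, ``i``): ``dai`` and ``lgk`` form a clade.

The class-defining feature of each template is fixed; the within-class
variants enumerate the arrangements of the remaining taxa.  Free
parameters are the stacked divergence times ``t1 < t2 < t3`` (in
generations), a shared diploid effective size ``N`` and, for the hybrid
templates, the admixture proportion ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .msc_sim import (AdmixtureEvent, DemographicScenario, DivergenceEvent,
                      ScenarioError)

TAXA = ("att", "dai", "lgk", "mus")


@dataclass
class PriorSpec:
    """Sampling prior for one scenario parameter."""
    low: float
    high: float
    log: bool = True  # log-uniform by default

    def sample(self, rng: np.random.Generator, size=None):
        if self.log:
            return np.exp(rng.uniform(np.log(self.low), np.log(self.high),
                                      size=size))
        return rng.uniform(self.low, self.high, size=size)


DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "N": PriorSpec(1e2, 1e6),
    "t1": PriorSpec(1e2, 1e6),
    "t2": PriorSpec(1e2, 1e6),
    "t3": PriorSpec(1e2, 1e6),
    "gamma": PriorSpec(0.0, 1.0, log=False),
}


def _ladder(order: tuple[str, str, str, str], params) -> DemographicScenario:
    """Caterpillar (((o0,o1),o2),o3) with stacked times t1<t2<t3."""
    t1, t2, t3 = params["t1"], params["t2"], params["t3"]
    n = params["N"]
    anc = {"A12": n, "A123": n, "root": n}
    return DemographicScenario(
        populations=list(order),
        sizes={**{p: n for p in order}, **anc},
        divergences=[
            DivergenceEvent(t1, (order[0], order[1]), "A12"),
            DivergenceEvent(t2, ("A12", order[2]), "A123"),
            DivergenceEvent(t3, ("A123", order[3]), "root"),
        ],
        **_rates(params),
    )


def _balanced(pair1: tuple[str, str], pair2: tuple[str, str],
              params) -> DemographicScenario:
    """((p1a,p1b),(p2a,p2b)) with cherry times t1, t2 and root t3."""
    t1, t2, t3 = params["t1"], params["t2"], params["t3"]
    n = params["N"]
    pops = list(pair1) + list(pair2)
    return DemographicScenario(
        populations=pops,
        sizes={**{p: n for p in pops}, "A1": n, "A2": n, "root": n},
        divergences=[
            DivergenceEvent(t1, pair1, "A1"),
            DivergenceEvent(t2, pair2, "A2"),
            DivergenceEvent(t3, ("A1", "A2"), "root"),
        ],
        **_rates(params),
    )


def _hybrid(primary: str, params) -> DemographicScenario:
    """``mus`` founded at t1 by admixture between ``att`` and ``dai``.

    Backward in time a fraction ``gamma`` of ``mus`` lineages moves to
    the non-primary parent; the remainder merges into ``primary``.
    The backbone is ((att,lgk),dai) with times t2 < t3.
    """
    t1, t2, t3 = params["t1"], params["t2"], params["t3"]
    n, gamma = params["N"], params.get("gamma", 0.5)
    other = "dai" if primary == "att" else "att"
    return DemographicScenario(
        populations=["att", "dai", "lgk", "mus"],
        sizes={p: n for p in ("att", "dai", "lgk", "mus", "A12", "root")},
        admixtures=[AdmixtureEvent(t1, "mus", other, gamma)],
        divergences=[
            DivergenceEvent(t1, ("mus",), primary),
            DivergenceEvent(t2, ("att", "lgk"), "A12"),
            DivergenceEvent(t3, ("A12", "dai"), "root"),
        ],
        **_rates(params),
    )


def _rates(params) -> dict:
    return {
        "mu": params.get("mu", 1e-8),
        "mu_ssr": params.get("mu_ssr", 1e-4),
        "generation_time": params.get("generation_time", 1.0),
    }


@dataclass
class ScenarioTemplate:
    name: str
    hypothesis: str
    description: str
    builder: Callable[[dict], DemographicScenario]
    parameters: tuple[str, ...]
    priors: dict[str, PriorSpec] = field(default_factory=dict)

    def build(self, params: dict) -> DemographicScenario:
        missing = [p for p in self.parameters if p not in params]
        if missing:
            raise ScenarioError(
                f"template {self.name!r} missing parameters {missing}")
        ordered = self._order_times(params)
        scenario = self.builder(ordered)
        scenario.name = self.name
        return scenario

    def _order_times(self, params: dict) -> dict:
        out = dict(params)
        times = sorted(out[k] for k in ("t1", "t2", "t3"))
        out["t1"], out["t2"], out["t3"] = times
        if times[0] == times[1] or times[1] == times[2]:
            eps = max(1e-6, 1e-9 * times[2])
            out["t1"], out["t2"], out["t3"] = (
                times[0], times[1] + eps, times[2] + 2 * eps)
        return out

    def sample_params(self, rng: np.random.Generator) -> dict:
        priors = {**DEFAULT_PRIORS, **self.priors}
        return {p: float(priors[p].sample(rng)) for p in self.parameters}


_TIME_PARAMS = ("t1", "t2", "t3", "N")
_HYBRID_PARAMS = ("t1", "t2", "t3", "N", "gamma")

REGISTRY: dict[str, ScenarioTemplate] = {
    "a": ScenarioTemplate(
        "a", "H1", "mus hybrid of att x dai; remainder merges into att",
        lambda p: _hybrid("att", p), _HYBRID_PARAMS),
    "b": ScenarioTemplate(
        "b", "H1", "mus hybrid of att x dai; remainder merges into dai",
        lambda p: _hybrid("dai", p), _HYBRID_PARAMS),
    "c": ScenarioTemplate(
        "c", "H2", "species tree (((att,lgk),mus),dai)",
        lambda p: _ladder(("att", "lgk", "mus", "dai"), p), _TIME_PARAMS),
    "d": ScenarioTemplate(
        "d", "H3", "(((dai,mus),att),lgk)",
        lambda p: _ladder(("dai", "mus", "att", "lgk"), p), _TIME_PARAMS),
    "e": ScenarioTemplate(
        "e", "H3", "(((dai,mus),lgk),att)",
        lambda p: _ladder(("dai", "mus", "lgk", "att"), p), _TIME_PARAMS),
    "f": ScenarioTemplate(
        "f", "H3", "((dai,mus),(att,lgk))",
        lambda p: _balanced(("dai", "mus"), ("att", "lgk"), p), _TIME_PARAMS),
    "g": ScenarioTemplate(
        "g", "H4", "(((dai,lgk),att),mus)",
        lambda p: _ladder(("dai", "lgk", "att", "mus"), p), _TIME_PARAMS),
    "h": ScenarioTemplate(
        "h", "H4", "(((dai,lgk),mus),att)",
        lambda p: _ladder(("dai", "lgk", "mus", "att"), p), _TIME_PARAMS),
    "i": ScenarioTemplate(
        "i", "H4", "((dai,lgk),(att,mus))",
        lambda p: _balanced(("dai", "lgk"), ("att", "mus"), p), _TIME_PARAMS),
}

HYPOTHESIS_CLASSES: dict[str, tuple[str, ...]] = {
    "H1": ("a", "b"),
    "H2": ("c",),
    "H3": ("d", "e", "f"),
    "H4": ("g", "h", "i"),
}


def scenario_to_dict(scenario: DemographicScenario) -> dict:
    return {
        "name": scenario.name,
        "populations": list(scenario.populations),
        "sizes": dict(scenario.sizes),
        "divergences": [{"time": ev.time, "derived": list(ev.derived),
                         "ancestor": ev.ancestor}
                        for ev in scenario.divergences],
        "admixtures": [{"time": ev.time, "recipient": ev.recipient,
                        "donor": ev.donor, "proportion": ev.proportion}
                       for ev in scenario.admixtures],
        "mu": scenario.mu,
        "mu_ssr": scenario.mu_ssr,
        "generation_time": scenario.generation_time,
    }


def scenario_from_dict(data: dict) -> DemographicScenario:
    return DemographicScenario(
        populations=list(data["populations"]),
        sizes={k: float(v) for k, v in data["sizes"].items()},
        divergences=[DivergenceEvent(d["time"], tuple(d["derived"]),
                                     d["ancestor"])
                     for d in data.get("divergences", [])],
        admixtures=[AdmixtureEvent(a["time"], a["recipient"], a["donor"],
                                   a["proportion"])
                    for a in data.get("admixtures", [])],
        mu=float(data.get("mu", 1e-8)),
        mu_ssr=float(data.get("mu_ssr", 1e-4)),
        generation_time=float(data.get("generation_time", 1.0)),
        name=data.get("name", ""),
    )


def save_scenario(scenario: DemographicScenario, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(scenario_to_dict(scenario), fh, indent=1)


def load_scenario(path) -> DemographicScenario:
    import json

    with open(path) as fh:
        return scenario_from_dict(json.load(fh))


def get_template(name: str) -> ScenarioTemplate:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ScenarioError(
            f"unknown scenario template {name!r}; available: "
            f"{sorted(REGISTRY)}") from None


def with_outgroup(scenario: DemographicScenario, label: str = "ela",
                  time: float = 4.2e5,
                  size: float | None = None) -> DemographicScenario:
    """Attach an outgroup population diverging at the root at ``time``."""
    last = max(ev.time for ev in scenario.divergences)
    if time <= last:
        raise ScenarioError("outgroup divergence must predate the root")
    # find the single population alive after all existing events
    alive = set(scenario.populations)
    for ev in scenario._events():
        if isinstance(ev, DivergenceEvent):
            alive -= set(ev.derived)
            alive.add(ev.ancestor)
    final = alive.pop()
    n = size if size is not None else scenario.sizes[final]
    return DemographicScenario(
        populations=scenario.populations + [label],
        sizes={**scenario.sizes, label: n, "og_root": n},
        divergences=scenario.divergences + [
            DivergenceEvent(time, (final, label), "og_root")],
        admixtures=scenario.admixtures,
        mu=scenario.mu, mu_ssr=scenario.mu_ssr,
        generation_time=scenario.generation_time,
        name=scenario.name,
    )
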