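"""Ground-truth study fixtures: alignments, gene trees, SSRs, traits.

A fixture bundle is a directory with ``alignments/*.fasta``,
``genetrees.nwk``, ``ssr.tsv``, ``traits.tsv`` and ``manifest.json``;
the manifest records every seed and parameter so the bundle can be
regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .msc_sim import (DemographicScenario, SampleConfig, simulate_alignment,
                      simulate_gene_tree, simulate_ssr, to_substitution_units)
from .physignal import brownian_covariance
from .scenarios import TAXA, get_template, with_outgroup
from .tree_core import (RootedTree, SubstitutionModel, parse_newick,
                        write_fasta, write_newick, write_newick_file)

OUTGROUP = "ela"


@dataclass
class StudyFixture:
    path: Path
    scenario: DemographicScenario
    gene_trees: list[RootedTree]
    topology_tally: dict[str, int]
    manifest: dict

    @property
    def alignment_dir(self) -> Path:
        return self.path / "alignments"


def make_fixture(template: str = "c",
                 n_genes: int = 100,
                 sites_per_gene: int = 300,
                 ssr_loci: int = 8,
                 ssr_individuals: int = 10,
                 seed: int = 0,
                 out_dir=None,
                 params: Optional[dict] = None,
                 outgroup_time: float = 4.2e5,
                 n_traits: int = 21,
                 conserved_index: int = 0) -> StudyFixture:
    """Generate a complete miniature study bundle with known truth.

    Gene alignments (ingroup taxa + outgroup) are simulated under the
    named scenario template, SSR panels under the same scenario without
    the outgroup, and a trait table on the scenario's species tree with
    exactly one conserved trait.  Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    tmpl = get_template(template)
    if params is None:
        params = {"N": 20000.0, "t1": 8800.0, "t2": 18600.0, "t3": 93100.0,
                  "gamma": 0.5, "mu": 1e-8}
    scenario = tmpl.build(params)
    scenario_og = with_outgroup(scenario, OUTGROUP, time=outgroup_time)
    out_dir = Path(out_dir) if out_dir is not None else Path(
        f"fixture_{template}_{seed}")
    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)

    model = SubstitutionModel.jc69()
    gene_trees: list[RootedTree] = []
    tally: dict[str, int] = {}
    samples = SampleConfig({**{t: 1 for t in TAXA}, OUTGROUP: 1})
    for g in range(n_genes):
        rng = np.random.default_rng([seed, 0, g])
        gt = simulate_gene_tree(scenario_og, samples, rng=rng)
        sub = to_substitution_units(gt, scenario.mu)
        aln = simulate_alignment(sub, model, sites_per_gene, rng=rng)
        write_fasta(aln, aln_dir / f"gene{g + 1:04d}.fasta")
        gene_trees.append(sub)
        ingroup_id = sub.restrict(list(TAXA)).topology_id()
        tally[ingroup_id] = tally.get(ingroup_id, 0) + 1
    write_newick_file(gene_trees, out_dir / "genetrees.nwk")

    rng = np.random.default_rng([seed, 1])
    ssr = simulate_ssr(scenario, SampleConfig({t: ssr_individuals
                                               for t in TAXA}),
                       n_loci=ssr_loci, rng=rng)
    ssr.to_csv(out_dir / "ssr.tsv", sep="\t", index=False)

    species_tree = species_tree_of(scenario)
    traits = make_trait_table(species_tree, n_traits=n_traits,
                              conserved_index=conserved_index,
                              seed=[seed, 2])
    traits.to_csv(out_dir / "traits.tsv", sep="\t")
    write_newick_file([species_tree], out_dir / "speciestree.nwk")

    manifest = {
        "template": template,
        "params": params,
        "seed": seed,
        "n_genes": n_genes,
        "sites_per_gene": sites_per_gene,
        "ssr_loci": ssr_loci,
        "ssr_individuals": ssr_individuals,
        "outgroup": OUTGROUP,
        "outgroup_time": outgroup_time,
        "n_traits": n_traits,
        "conserved_index": conserved_index,
        "topology_tally": tally,
        "seed_scheme": ("alignments: default_rng([seed, 0, gene]); "
                        "ssr: default_rng([seed, 1]); "
                        "traits: default_rng([seed, 2])"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return StudyFixture(out_dir, scenario_og, gene_trees, tally, manifest)


def species_tree_of(scenario: DemographicScenario) -> RootedTree:
    """Ultrametric species tree implied by a scenario's divergence events.

    Admixture pulses are ignored (the tree follows the divergence
    backbone), which is the conventional reduction for signal testing.
    """
    from .tree_core import TreeNode

    nodes: dict[str, TreeNode] = {}
    height: dict[str, float] = {}
    for pop in scenario.populations:
        nodes[pop] = TreeNode(pop)
        height[pop] = 0.0
    for ev in sorted(scenario.divergences, key=lambda e: e.time):
        children = [c for c in ev.derived if c in nodes]
        if ev.ancestor in nodes and ev.ancestor not in children:
            children.append(ev.ancestor)
        if len(children) < 2:
            # pulse-founded population merging into an existing branch
            if children:
                nodes[ev.ancestor] = nodes[children[0]]
                height[ev.ancestor] = height[children[0]]
            continue
        parent = TreeNode()
        for c in children:
            node = nodes.pop(c)
            node.length = ev.time - height.pop(c)
            parent.add_child(node)
        nodes[ev.ancestor] = parent
        height[ev.ancestor] = ev.time
    remaining = list(nodes.values())
    if len(remaining) != 1:
        raise ValueError("scenario does not reduce to a single species tree")
    return RootedTree(remaining[0])


def make_trait_table(species_tree: RootedTree, n_traits: int = 21,
                     conserved_index: int = 0,
                     seed=0) -> pd.DataFrame:
    """Trait table with one phylogenetically conserved trait.

    The conserved trait is Brownian motion on an early-burst rescaling
    of the tree (variance concentrated on deep branches, so clades are
    internally homogeneous and K > 1) plus tiny independent tip noise.
    All other traits are tip-level shuffles of Brownian draws, which
    destroys the phylogenetic signal (K at or below the Brownian
    expectation).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if not 0 <= conserved_index < n_traits:
        raise ValueError("conserved_index out of range")
    rng = np.random.default_rng(seed)
    c, labels = brownian_covariance(species_tree,
                                    warn_non_ultrametric=False)
    depth = float(np.max(np.diag(c)))
    c_unit = c / depth
    chol = np.linalg.cholesky(c_unit + 1e-12 * np.eye(len(labels)))

    # early-burst: shrink shallow shared history, keep deep structure
    g = 4.0
    c_eb = (1.0 - np.exp(-g * c_unit)) / (1.0 - np.exp(-g))
    chol_eb = np.linalg.cholesky(c_eb + 1e-12 * np.eye(len(labels)))

    cols = {}
    for j in range(n_traits):
        if j == conserved_index:
            x = chol_eb @ rng.standard_normal(len(labels))
            x = x + 0.03 * rng.standard_normal(len(labels))
        else:
            x = chol @ rng.standard_normal(len(labels))
            x = rng.permutation(x)
        cols[f"trait{j + 1:02d}"] = x
    df = pd.DataFrame(cols, index=pd.Index(labels, name="tip"))
    df.attrs["conserved"] = f"trait{conserved_index + 1:02d}"
    return df


def load_fixture_manifest(path) -> dict:
    with open(Path(path) / "manifest.json") as fh:
        return json.load(fh)
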