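# phyloconflict

Toolkit for analysing gene-tree/species-tree conflict in small species
complexes:

* **tree_core** — rooted trees, strict Newick I/O, exhaustive constrained
  enumeration of rooted binary topologies, reversible substitution models
  (JC69/K80/HKY85/GTR, discrete-gamma), Felsenstein pruning with site-pattern
  compression, and coordinate-wise branch-length optimization.
* **msc_sim / scenarios** — structured-coalescent simulation of gene trees
  under demographic scenarios with divergence and pulse-admixture events,
  sequence evolution along gene trees, strict stepwise-mutation
  microsatellite (SSR) panels, and a registry of nine scenario templates
  (`a`–`i`) grouped into four hypothesis classes.
* **ggi** — gene genealogy interrogation: per-gene scoring of candidate
  topologies, RELL multiscale bootstrap, approximately-unbiased (AU)
  p-values from the signed-distance/curvature fit, best-fit selection by
  lowest ΔL, and per-topology summaries.
* **triplet_ils** — triplet extraction from gene trees and
  exponential vs shifted-exponential mixture classification of internal
  branch lengths (ILS-only vs ILS+introgression) with a ΔBIC < −10 rule.
* **abc** — SSR summary statistics (allele counts, unbiased expected
  heterozygosity, allele-size SD, Weir–Cockerham FST, (δμ)²), greedy
  |r| > 0.8 correlation pruning, and plain rejection ABC for model choice
  and log-scale parameter estimation.
* **physignal** — Blomberg's K with permutation or Brownian-simulation
  randomization tests.
* **synthetic_data** — deterministic miniature study bundles (alignments,
  gene trees, SSR panel, trait table, manifest) with known ground truth.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the full-size acceptance experiments
(AU-test calibration, ABC model recovery, …) and takes the bulk of the
runtime; the per-module files hold fast scaled-down versions of the same
checks.

## CLI

```sh
# generate a ground-truth bundle under scenario template c
phyloconflict fixture make --template c --n-genes 100 --seed 1 --out bundle/

# interrogate every gene against a candidate-topology file
phyloconflict ggi run --alignments bundle/alignments \
    --candidates candidates.nwk --alpha 0.05 --seed 1

# classify triplet discordance from gene trees
phyloconflict triplets --genetrees bundle/genetrees.nwk \
    --ingroup att,dai,lgk,mus --outgroup ela

# rejection ABC
phyloconflict abc simulate --scenario c,d,g --n 20000 --seed 1 --out-prefix bank
phyloconflict abc select --obs bundle/ssr.tsv --bank bank.tsv --retain 5000
phyloconflict abc estimate --obs bundle/ssr.tsv --bank bank.tsv --model c --retain 2000

# phylogenetic signal
phyloconflict signal --tree bundle/speciestree.nwk --traits bundle/traits.tsv
```

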