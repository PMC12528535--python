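"""Exhaustive enumeration of rooted binary leaf-labelled topologies.

Enumeration proceeds by recursive bipartition of the label set (the
smallest label is pinned to the left part, so every topology is produced
exactly once), optionally under monophyly constraints and with a fixed
outgroup attached at the root.  Results are returned in a deterministic
canonical order (sorted by canonical Newick).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .tree import RootedTree, TreeNode, TreeError


class ConstraintError(ValueError):
    pass


@dataclass
class TopologyConstraint:
    """Constraints applied during topology enumeration.

    ``species_of_sample`` maps sample labels to species labels;
    ``monophyly_groups`` lists species whose samples must form a clade;
    ``fixed_outgroup`` names a label (or species) placed as sister to
    everything else.
    """

    species_of_sample: dict[str, str] = field(default_factory=dict)
    monophyly_groups: list[list[str]] = field(default_factory=list)
    fixed_outgroup: Optional[str] = None

    def validate(self, labels: Sequence[str]) -> None:
        labelset = set(labels)
        for sample in self.species_of_sample:
            if sample not in labelset:
                raise ConstraintError(
                    f"sample {sample!r} in species map is not a leaf label")
        seen: set[str] = set()
        for group in self.monophyly_groups:
            g = set(group)
            if g & seen:
                raise ConstraintError(
                    f"overlapping monophyly groups at {sorted(g & seen)}")
            seen |= g

    def samples_of_species(self, species: str,
                           labels: Sequence[str]) -> list[str]:
        if self.species_of_sample:
            return sorted(s for s in labels
                          if self.species_of_sample.get(s, s) == species)
        return [species] if species in labels else []


def _join(left: TreeNode, right: TreeNode) -> TreeNode:
    root = TreeNode()
    root.add_child(left)
    root.add_child(right)
    return root


def _enum_subtrees(labels: tuple[str, ...]) -> list[TreeNode]:
    if len(labels) == 1:
        return [TreeNode(labels[0])]
    first, rest = labels[0], labels[1:]
    out: list[TreeNode] = []
    for k in range(len(rest) + 1):
        for chosen in combinations(rest, k):
            left = (first,) + chosen
            right = tuple(x for x in rest if x not in chosen)
            if not right:
                continue
            for lt in _enum_subtrees(left):
                for rt in _enum_subtrees(right):
                    out.append(_join(_copy(lt), _copy(rt)))
    return out


def _copy(node: TreeNode) -> TreeNode:
    new = TreeNode(node.name, node.length)
    for c in node.children:
        new.add_child(_copy(c))
    return new


def _graft(skeleton: TreeNode, placements: dict[str, TreeNode]) -> TreeNode:
    if skeleton.is_leaf:
        if skeleton.name in placements:
            return _copy(placements[skeleton.name])
        return TreeNode(skeleton.name)
    new = TreeNode()
    for c in skeleton.children:
        new.add_child(_graft(c, placements))
    return new


def enumerate_rooted_topologies(
        labels: Sequence[str],
        constraint: Optional[TopologyConstraint] = None,
) -> list[RootedTree]:
    """All distinct rooted binary topologies on ``labels``.

    With a constraint, samples of each species in a monophyly group are
    confined to a clade, and a ``fixed_outgroup`` is attached as sister
    to the remaining enumeration.  Count without constraints is
    (2n-3)!! for n labels.
    """
    labels = list(dict.fromkeys(labels))
    if len(labels) < 2:
        raise TreeError("need at least 2 labels to enumerate topologies")
    if constraint is None:
        constraint = TopologyConstraint()
    constraint.validate(labels)

    working = list(labels)
    outgroup_label = None
    if constraint.fixed_outgroup is not None:
        og = constraint.fixed_outgroup
        og_samples = [s for s in working
                      if s == og or constraint.species_of_sample.get(s) == og]
        if not og_samples:
            raise ConstraintError(f"fixed outgroup {og!r} matches no label")
        if len(og_samples) > 1:
            raise ConstraintError(
                "fixed outgroup must resolve to a single sample label")
        outgroup_label = og_samples[0]
        working.remove(outgroup_label)

    # collapse each monophyly group to a meta-leaf
    placements: dict[str, list[TreeNode]] = {}
    meta_labels: list[str] = []
    grouped: set[str] = set()
    for group in constraint.monophyly_groups:
        samples: list[str] = []
        for species in group:
            samples.extend(constraint.samples_of_species(species, working))
        samples = sorted(set(samples))
        if not samples:
            continue
        meta = "\x00group:" + ",".join(samples)
        grouped |= set(samples)
        meta_labels.append(meta)
        if len(samples) == 1:
            placements[meta] = [TreeNode(samples[0])]
        else:
            placements[meta] = _enum_subtrees(tuple(samples))
    free = [lbl for lbl in working if lbl not in grouped]
    skeleton_labels = tuple(free + meta_labels)

    if len(skeleton_labels) == 1:
        skeletons = [TreeNode(skeleton_labels[0])]
    else:
        skeletons = _enum_subtrees(skeleton_labels)

    trees: list[RootedTree] = []
    for skel in skeletons:
        stack = [({k: v[i] for k, (v, i) in zip(placements, pairs)})
                 for pairs in _assignments(placements)]
        for assign in stack:
            grafted = _graft(skel, assign)
            if outgroup_label is not None:
                grafted = _join(grafted, TreeNode(outgroup_label))
            trees.append(RootedTree(grafted))
    trees.sort(key=lambda t: t.topology_id())
    return trees


def _assignments(placements: dict[str, list[TreeNode]]):
    """Cartesian product over per-group subtree choices."""
    keys = list(placements)
    if not keys:
        yield []
        return

    def rec(i: int, acc):
        if i == len(keys):
            yield list(acc)
            return
        for j in range(len(placements[keys[i]])):
            acc.append((placements[keys[i]], j))
            yield from rec(i + 1, acc)
            acc.pop()

    yield from rec(0, [])


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! — the number of rooted binary topologies on n labels."""
    if n < 2:
        raise ValueError("n must be >= 2")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out
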