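import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloconflict.tree_core import (AlignmentError, ConstraintError,
                                     NewickError, SubstitutionModel,
                                     TopologyConstraint, TreeError,
                                     enumerate_rooted_topologies,
                                     jc_distance, log_likelihood,
                                     n_rooted_topologies,
                                     optimize_branch_lengths, parse_newick,
                                     site_log_likelihoods, write_newick)

from conftest import random_tree


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------
class TestNewick:
    def test_smallest_valid_input(self):
        tree = parse_newick("(A:1,B:1);")
        assert sorted(tree.leaf_names()) == ["A", "B"]
        assert [l.length for l in tree.leaves()] == [1.0, 1.0]

    def test_caterpillar_species_hypothesis(self):
        tree = parse_newick("(((att,lgk),mus),dai);")
        assert tree.topology_id() == "(((att,lgk),mus),dai);"
        assert tree.is_binary()

    def test_polytomy_preserved(self):
        tree = parse_newick("(A,B,C);")
        assert len(tree.root.children) == 3
        assert not tree.is_binary()

    def test_malformed_reports_offset(self):
        with pytest.raises(NewickError) as err:
            parse_newick("((A,B);")
        assert "character" in str(err.value)

    def test_missing_semicolon(self):
        with pytest.raises(NewickError):
            parse_newick("(A,B)")

    def test_duplicate_leaf_label(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("(A,A);")

    def test_quoted_labels(self):
        tree = parse_newick("('sp one':0.1,'it''s':0.2);")
        assert sorted(tree.leaf_names()) == ["it's", "sp one"]
        assert parse_newick(write_newick(tree)).topology_id() == \
            tree.topology_id()

    def test_roundtrip_random_trees(self, rng):
        labels = [f"t{i}" for i in range(16)]
        for rep in range(100):
            n = int(rng.integers(2, 17))
            tree = random_tree(labels[:n], rng)
            text = write_newick(tree)
            back = parse_newick(text)
            assert back.topology_id() == tree.topology_id()
            d1, d2 = tree.leaf_depths(), back.leaf_depths()
            assert all(abs(d1[k] - d2[k]) < 1e-12 for k in d1)
            assert write_newick(back) == text

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        tree = random_tree([f"x{i}" for i in range(n)], rng)
        assert parse_newick(write_newick(tree)).topology_id() == \
            tree.topology_id()


class TestReroot:
    def test_total_length_preserved(self, rng):
        tree = random_tree(list("ABCDEF"), rng)
        for og in "ABCDEF":
            out = tree.reroot_with_outgroup(og)
            assert out.is_binary()
            assert abs(out.total_length() - tree.total_length()) < 1e-12
            assert out.root.children[0].name == og or \
                out.root.children[1].name == og

    def test_missing_outgroup(self, rng):
        tree = random_tree(list("ABC"), rng)
        with pytest.raises(TreeError):
            tree.reroot_with_outgroup("Z")


# ----------------------------------------------------------------------
# enumeration
# ----------------------------------------------------------------------
def _insertion_enumeration(labels):
    """Independent oracle: stepwise leaf insertion on every edge + root."""
    from phyloconflict.tree_core import RootedTree, TreeNode

    def attach_all(tree, label):
        out = []
        edges = [n for n in tree.postorder() if n.parent is not None]
        for i in range(len(edges) + 1):
            t = tree.copy()
            new_leaf = TreeNode(label)
            if i == len(edges):
                new_root = TreeNode()
                new_root.add_child(t.root)
                new_root.add_child(new_leaf)
                out.append(RootedTree(new_root))
            else:
                edge = [n for n in t.postorder() if n.parent is not None][i]
                parent = edge.parent
                mid = TreeNode()
                parent.children[parent.children.index(edge)] = mid
                mid.parent = parent
                mid.add_child(edge)
                mid.add_child(new_leaf)
                out.append(t)
        return out

    trees = [parse_newick(f"({labels[0]},{labels[1]});")]
    for label in labels[2:]:
        trees = [t2 for t in trees for t2 in attach_all(t, label)]
    return {t.topology_id() for t in trees}


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105),
                                         (6, 945)])
    def test_counts_match_double_factorial(self, n, count):
        labels = [f"t{i}" for i in range(n)]
        tops = enumerate_rooted_topologies(labels)
        assert len(tops) == count == n_rooted_topologies(n)
        assert len({t.topology_id() for t in tops}) == count

    def test_matches_insertion_oracle_n5(self):
        labels = list("ABCDE")
        ours = {t.topology_id() for t in enumerate_rooted_topologies(labels)}
        assert ours == _insertion_enumeration(labels)

    def test_deterministic_canonical_order(self):
        a = [t.topology_id() for t in enumerate_rooted_topologies("ABCD")]
        b = [t.topology_id() for t in enumerate_rooted_topologies("ABCD")]
        assert a == b == sorted(a)

    @pytest.mark.parametrize("n,g", [(4, 2), (5, 3), (6, 3)])
    def test_monophyly_collapse_count(self, n, g):
        labels = [f"t{i}" for i in range(n)]
        constraint = TopologyConstraint(monophyly_groups=[labels[:g]])
        tops = enumerate_rooted_topologies(labels, constraint)
        expected = n_rooted_topologies(n - g + 1) * n_rooted_topologies(g)
        assert len(tops) == expected
        clade = set(labels[:g])
        for t in tops:
            assert {l.name for l in
                    __import__("phyloconflict.tree_core",
                               fromlist=["RootedTree"]).RootedTree(
                                   t.mrca(labels[:g])).leaves()} == clade

    def test_fixed_outgroup(self):
        constraint = TopologyConstraint(fixed_outgroup="O")
        tops = enumerate_rooted_topologies(list("ABCD") + ["O"], constraint)
        assert len(tops) == 15
        for t in tops:
            names = {c.name for c in t.root.children}
            assert "O" in names

    def test_overlapping_groups_rejected(self):
        constraint = TopologyConstraint(
            monophyly_groups=[["A", "B"], ["B", "C"]])
        with pytest.raises(ConstraintError, match="overlap"):
            enumerate_rooted_topologies(list("ABCD"), constraint)

    def test_species_map_constraint(self):
        constraint = TopologyConstraint(
            species_of_sample={"m1": "mus", "m2": "mus", "a1": "att",
                               "d1": "dai"},
            monophyly_groups=[["mus"]])
        tops = enumerate_rooted_topologies(["m1", "m2", "a1", "d1"],
                                           constraint)
        # mus clade fixed -> 3 meta-leaves -> 3 topologies
        assert len(tops) == 3
        for t in tops:
            mrca = t.mrca(["m1", "m2"])
            leaves = [l.name for l in t.leaves()]
            assert sorted(leaves) == ["a1", "d1", "m1", "m2"]
            from phyloconflict.tree_core import RootedTree
            assert sorted(l.name for l in RootedTree(mrca).leaves()) == \
                ["m1", "m2"]


# ----------------------------------------------------------------------
# substitution models
# ----------------------------------------------------------------------
class TestModels:
    @pytest.mark.parametrize("model", [
        SubstitutionModel.jc69(),
        SubstitutionModel.k80(kappa=3.0),
        SubstitutionModel.hky85([0.4, 0.1, 0.2, 0.3], kappa=4.0),
        SubstitutionModel.gtr([0.3, 0.2, 0.3, 0.2],
                              [1.0, 2.5, 0.7, 1.2, 3.0, 1.0]),
    ], ids=["JC69", "K80", "HKY85", "GTR"])
    def test_rate_matrix_invariants(self, model):
        q = model.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert abs(-np.dot(model.freqs, np.diag(q)) - 1.0) < 1e-12
        # detailed balance
        flux = model.freqs[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_transition_matrix_limits(self):
        m = SubstitutionModel.hky85([0.4, 0.1, 0.2, 0.3], kappa=4.0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-10)
        p_inf = m.transition_matrix(500.0)
        assert np.allclose(p_inf, np.tile(m.freqs, (4, 1)), atol=1e-8)

    def test_gamma_rates_mean_one(self):
        m = SubstitutionModel.jc69(gamma_alpha=0.3)
        rates = m.category_rates()
        assert len(rates) == 4
        assert abs(rates.mean() - 1.0) < 1e-12
        assert np.all(np.diff(rates) > 0)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            SubstitutionModel.gtr([0.5, 0.5, 0.2, -0.2], np.ones(6))


# ----------------------------------------------------------------------
# likelihood kernel
# ----------------------------------------------------------------------
def exhaustive_loglik(tree, alignment, model):
    """Brute-force sum over all internal-state assignments per site."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    code = {b: i for i, b in enumerate("ACGT")}
    length = len(next(iter(alignment.values())))
    p_of = {id(n): model.transition_matrix(n.length)
            for n in nodes if n.parent is not None}
    total = 0.0
    for s in range(length):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            for leaf in leaves:
                state[id(leaf)] = code[alignment[leaf.name][s]]
            pr = model.freqs[state[id(tree.root)]]
            for n in nodes:
                if n.parent is not None:
                    pr *= p_of[id(n)][state[id(n.parent)], state[id(n)]]
            site += pr
        total += np.log(site)
    return total


class TestLikelihood:
    def test_identical_sequences_zero_branches(self, jc):
        tree = parse_newick("(A:0,B:0);")
        sl = site_log_likelihoods(tree, {"A": "ACGT", "B": "ACGT"}, jc)
        assert np.allclose(sl, np.log(0.25))

    def test_two_taxon_closed_form(self, jc):
        t = 0.37
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        sl = site_log_likelihoods(tree, {"A": "AAAA", "B": "AAGC"}, jc)
        match = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3)))
        mismatch = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3)))
        assert np.allclose(sl, [match, match, mismatch, mismatch],
                           atol=1e-12)

    def test_exhaustive_oracle_all_15_topologies(
            self, four_taxon_topologies, rng, jc):
        aln = {k: "".join(rng.choice(list("ACGT"), 20)) for k in "ABCD"}
        for top in four_taxon_topologies:
            tree = top.copy()
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.02, 0.6))
            assert abs(log_likelihood(tree, aln, jc)
                       - exhaustive_loglik(tree, aln, jc)) < 1e-8

    def test_exhaustive_oracle_gtr_gamma(self, rng):
        model = SubstitutionModel.gtr([0.35, 0.15, 0.25, 0.25],
                                      [1.0, 2.0, 0.5, 0.8, 3.5, 1.0])
        tree = random_tree(list("ABCD"), rng)
        aln = {k: "".join(rng.choice(list("ACGT"), 15)) for k in "ABCD"}
        assert abs(log_likelihood(tree, aln, model)
                   - exhaustive_loglik(tree, aln, model)) < 1e-8

    def test_gaps_and_ambiguities_missing(self, jc):
        tree = parse_newick("(A:0.1,B:0.1);")
        sl_gap = site_log_likelihoods(tree, {"A": "A", "B": "-"}, jc)
        # fully missing partner: site likelihood is the marginal 1/4
        assert abs(sl_gap[0] - np.log(0.25)) < 1e-12
        sl_r = site_log_likelihoods(tree, {"A": "A", "B": "R"}, jc)
        p = SubstitutionModel.jc69().transition_matrix(0.2)
        expect = 0.25 * (p[0, 0] + p[0, 2])
        assert abs(sl_r[0] - np.log(expect)) < 1e-12

    def test_rerooting_invariance(self, rng):
        model = SubstitutionModel.hky85([0.3, 0.2, 0.3, 0.2], kappa=3.0)
        tree = random_tree(list("ABCDE"), rng)
        aln = {k: "".join(rng.choice(list("ACGT"), 60)) for k in "ABCDE"}
        ref = log_likelihood(tree, aln, model)
        for og in "ABCDE":
            rerooted = tree.reroot_with_outgroup(og, fraction=0.3)
            assert abs(log_likelihood(rerooted, aln, model) - ref) < 1e-8

    def test_label_mismatch_lists_offenders(self, jc):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(AlignmentError, match="C"):
            site_log_likelihoods(tree, {"A": "A", "C": "A"}, jc)

    def test_zero_length_alignment(self, jc):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(AlignmentError):
            site_log_likelihoods(tree, {"A": "", "B": ""}, jc)


class TestOptimize:
    def test_two_taxon_jc_distance(self, rng, jc):
        n, p = 4000, 0.15
        a = rng.choice(list("ACGT"), n)
        b = a.copy()
        idx = rng.choice(n, int(p * n), replace=False)
        for i in idx:
            b[i] = rng.choice([x for x in "ACGT" if x != b[i]])
        aln = {"A": "".join(a), "B": "".join(b)}
        fitted, _ = optimize_branch_lengths(parse_newick("(A:0.1,B:0.1);"),
                                            aln, jc)
        total = sum(n.length for n in fitted.postorder()
                    if n.parent is not None)
        assert abs(total - jc_distance(p)) < 1e-3

    def test_beats_random_assignments(self, rng, jc):
        from phyloconflict.msc_sim import simulate_alignment

        true = parse_newick(
            "(((A:0.2,B:0.2):0.15,C:0.35):0.1,D:0.45);")
        aln = simulate_alignment(true, jc, 400, rng=rng)
        _, best = optimize_branch_lengths(true, aln, jc)
        for _ in range(50):
            t = true.copy()
            for node in t.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(1e-4, 1.0))
            assert log_likelihood(t, aln, jc) <= best + 1e-9

    def test_stable_under_shuffled_start(self, rng, jc):
        from phyloconflict.msc_sim import simulate_alignment

        true = parse_newick("(((A:0.1,B:0.1):0.1,C:0.2):0.1,D:0.3);")
        aln = simulate_alignment(true, jc, 300, rng=rng)
        lls = []
        for init in (0.01, 0.1, 0.4):
            _, ll = optimize_branch_lengths(true, aln, jc,
                                            initial_length=init)
            lls.append(ll)
        assert max(lls) - min(lls) < 1e-4

    def test_non_binary_rejected(self, jc):
        with pytest.raises(TreeError):
            optimize_branch_lengths(parse_newick("(A,B,C);"),
                                    {"A": "A", "B": "A", "C": "A"}, jc)


class TestModelSelection:
    def test_bic_prefers_generating_family(self, rng):
        from phyloconflict.msc_sim import simulate_alignment
        from phyloconflict.tree_core import select_model_bic

        tree = parse_newick("(((A:0.15,B:0.15):0.1,C:0.25):0.05,D:0.3);")
        # strong transition bias: K80 should beat JC69 by BIC
        aln = simulate_alignment(tree, SubstitutionModel.k80(kappa=8.0),
                                 800, rng=rng)
        best, scores = select_model_bic(tree, aln,
                                        families=("JC69", "K80"))
        assert best.family == "K80"
        assert scores["K80"] < scores["JC69"]
        # and JC69 wins on JC69 data (kappa parameter is penalized)
        aln2 = simulate_alignment(tree, SubstitutionModel.jc69(), 800,
                                  rng=rng)
        best2, scores2 = select_model_bic(tree, aln2,
                                          families=("JC69", "K80"))
        assert best2.family == "JC69"
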