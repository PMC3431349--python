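import dendropy
import numpy as np
import pytest

from sialevo import (
    AlignmentError,
    GammaRates,
    SubstitutionModel,
    between_group_divergence,
    bionj_tree,
    bootstrap_support,
    distance_matrix,
    estimate_gamma_shape,
    nj_tree,
    optimize_tree,
    pairwise_ml_distance,
    simulate_alignment,
    tree_log_likelihood,
)
from sialevo.phylo import TreeLikelihood, encode_sequence
from oracles import four_taxon_loglik, quartet_topology


def rf_distance(t1, t2):
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns, preserve_underscores=True)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestModel:
    def test_q_rows_sum_to_zero(self, wag):
        assert np.abs(wag.Q.sum(axis=1)).max() < 1e-10

    def test_detailed_balance(self, wag):
        F = wag.freqs[:, None] * wag.Q
        assert np.abs(F - F.T).max() < 1e-12

    def test_unit_expected_rate(self, wag):
        assert -np.dot(wag.freqs, np.diag(wag.Q)) == pytest.approx(1.0)

    def test_identity_at_zero(self, wag):
        assert np.abs(wag.transition_matrix(0.0) - np.eye(20)).max() < 1e-12

    def test_rows_stochastic(self, wag):
        for t in (0.01, 0.5, 2.0, 10.0):
            P = wag.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert P.min() >= 0

    def test_ergodic_limit(self, wag):
        P = wag.transition_matrix(500.0)
        assert np.abs(P - wag.freqs[None, :]).max() < 1e-6

    def test_semigroup_property(self, wag):
        rng = np.random.default_rng(0)
        for _ in range(5):
            t1, t2 = rng.uniform(0.01, 2.0, size=2)
            P12 = wag.transition_matrix(t1 + t2)
            assert np.abs(P12 - wag.transition_matrix(t1) @
                          wag.transition_matrix(t2)).max() < 1e-8

    def test_negative_branch_rejected(self, wag):
        with pytest.raises(AlignmentError):
            wag.transition_matrix(-0.1)


class TestGammaRates:
    @pytest.mark.parametrize("alpha", [0.2, 1.0, 2.6845, 5.0, 20.0])
    @pytest.mark.parametrize("K", [2, 4, 5, 8])
    def test_mean_rate_one(self, alpha, K):
        g = GammaRates.discrete(alpha, K)
        assert np.dot(g.rates, g.probs) == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(g.rates) > 0).all()

    def test_median_method_also_normalised(self):
        g = GammaRates.discrete(0.5, 5, method="median")
        assert np.dot(g.rates, g.probs) == pytest.approx(1.0, abs=1e-8)

    def test_large_shape_approaches_homogeneity(self):
        g = GammaRates.discrete(200.0, 5)
        assert np.abs(g.rates - 1).max() < 0.15

    def test_invalid_shape(self):
        with pytest.raises(AlignmentError):
            GammaRates.discrete(0.0, 5)


class TestPairwiseDistance:
    def test_identical_sequences(self, wag, gamma5):
        s = "ACDEFGHIKLMNPQRSTVWY" * 3
        assert pairwise_ml_distance(s, s, wag, gamma5) < 1e-6

    def test_symmetry(self, wag, gamma5):
        tree = dendropy.Tree.get(data="(A:0.4,B:0.4);", schema="newick")
        aln, _ = simulate_alignment(tree, wag, gamma5, 400, seed=3)
        d1 = pairwise_ml_distance(aln.row("A"), aln.row("B"), wag, gamma5)
        d2 = pairwise_ml_distance(aln.row("B"), aln.row("A"), wag, gamma5)
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_matches_grid_search_oracle(self, wag, gamma5):
        from sialevo.phylo import _pair_count_matrix, _pair_neg_loglik
        rng = np.random.default_rng(4)
        for rep in range(6):
            t = rng.uniform(0.1, 1.5)
            tree = dendropy.Tree.get(data=f"(A:{t/2},B:{t/2});", schema="newick")
            aln, _ = simulate_alignment(tree, wag, gamma5, 600,
                                        seed=int(rng.integers(2**31)))
            d = pairwise_ml_distance(aln.row("A"), aln.row("B"), wag, gamma5)
            C = _pair_count_matrix(encode_sequence(aln.row("A")),
                                   encode_sequence(aln.row("B")))
            coarse = np.arange(0.01, 4.0, 0.01)
            vals = [_pair_neg_loglik(x, C, wag, gamma5) for x in coarse]
            centre = coarse[int(np.argmin(vals))]
            fine = np.arange(max(1e-4, centre - 0.02), centre + 0.02, 1e-4)
            vals = [_pair_neg_loglik(x, C, wag, gamma5) for x in fine]
            best = fine[int(np.argmin(vals))]
            assert d == pytest.approx(best, abs=1e-3)

    def test_no_shared_columns(self, wag, gamma5):
        with pytest.raises(AlignmentError):
            pairwise_ml_distance("A--", "-CC", wag, gamma5)

    def test_recovery_at_half_substitution(self, wag, gamma5):
        """Mean estimate over replicates within 3 SE of the true d = 0.5.

        The per-replicate SE at 10k sites is about 0.01, so the mean of five
        replicates has SE about 0.0045.
        """
        ds = []
        for rep in range(5):
            tree = dendropy.Tree.get(data="(A:0.25,B:0.25);", schema="newick")
            aln, _ = simulate_alignment(tree, wag, gamma5, 10000, seed=8 + rep)
            ds.append(pairwise_ml_distance(aln.row("A"), aln.row("B"),
                                           wag, gamma5))
        assert np.mean(ds) == pytest.approx(0.5, abs=0.014)


class TestBetweenGroupDivergence:
    def test_zero_for_identical_groups(self, wag, gamma5):
        from sialevo import Alignment
        aln = Alignment(ids=["a1", "a2", "b1", "b2"],
                        seqs=["ACDEFGHIKL"] * 4)
        d, se = between_group_divergence(aln, ["a1", "a2"], ["b1", "b2"],
                                         wag, gamma5, n_bootstrap=20, seed=0)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_overlapping_groups_rejected(self, wag, gamma5):
        from sialevo import Alignment
        aln = Alignment(ids=["a", "b"], seqs=["ACD", "ACD"])
        with pytest.raises(AlignmentError):
            between_group_divergence(aln, ["a"], ["a"], wag, gamma5)

    def test_recovers_known_separation(self, wag, gamma5):
        # star clades: every between-group path is exactly 1.1
        nwk = "((a1:0.05,a2:0.05):0.5,(b1:0.05,b2:0.05):0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        aln, _ = simulate_alignment(tree, wag, gamma5, 4000, seed=9)
        d, se = between_group_divergence(aln, ["a1", "a2"], ["b1", "b2"],
                                         wag, gamma5, n_bootstrap=50, seed=1)
        assert se > 0
        assert d == pytest.approx(1.1, abs=max(3 * se, 0.05))


class TestNeighborJoining:
    def test_three_taxon_formulas(self):
        D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        t = nj_tree(D, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_five_taxon_exact(self):
        # tree ((a:1,b:2):1,(c:3,d:4):1,e:5) -> additive distances
        nwk = "((a:1,b:2):1,(c:3,d:4):1,e:5);"
        src = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = src.phylogenetic_distance_matrix()
        labels = ["a", "b", "c", "d", "e"]
        taxa = {t.label: t for t in src.taxon_namespace}
        D = np.array([[pdm.distance(taxa[x], taxa[y]) for y in labels]
                      for x in labels])
        t = nj_tree(D, labels)
        assert rf_distance(t, src) == 0
        # recovered pairwise path lengths match the input matrix
        pdm2 = t.phylogenetic_distance_matrix()
        taxa2 = {x.label: x for x in t.taxon_namespace}
        D2 = np.array([[pdm2.distance(taxa2[x], taxa2[y]) for y in labels]
                       for x in labels])
        assert np.abs(D - D2).max() < 1e-9

    def test_quartets_match_four_point_oracle(self):
        rng = np.random.default_rng(5)
        labels = ["t0", "t1", "t2", "t3"]
        for _ in range(25):
            # random additive 4-taxon matrix from a random quartet
            order = rng.permutation(4)
            bl = rng.uniform(0.2, 2.0, size=5)
            i, j, k, l = order
            nwk = (f"(({labels[i]}:{bl[0]},{labels[j]}:{bl[1]}):{bl[4]},"
                   f"{labels[k]}:{bl[2]},{labels[l]}:{bl[3]});")
            src = dendropy.Tree.get(data=nwk, schema="newick")
            pdm = src.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in src.taxon_namespace}
            D = np.array([[pdm.distance(taxa[x], taxa[y]) for y in labels]
                          for x in labels])
            t = nj_tree(D, labels)
            cherry = quartet_topology(D)
            assert rf_distance(t, src) == 0
            # taxon 0's sibling in the NJ tree matches the oracle cherry
            leaf0 = [lf for lf in t.leaf_node_iter()
                     if lf.taxon.label == "t0"][0]
            sibs = {lf.taxon.label
                    for lf in leaf0.parent_node.leaf_iter()} - {"t0"}
            if len(sibs) == 1:
                assert labels.index(sibs.pop()) == cherry[1]

    def test_matches_skbio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(6)
        labels = [f"x{i}" for i in range(7)]
        # additive matrix from a random tree plus small symmetric noise
        base = np.zeros((7, 7))
        coords = rng.uniform(0, 5, size=(7, 3))
        for i in range(7):
            for j in range(7):
                base[i, j] = np.abs(coords[i] - coords[j]).sum()
        ours = nj_tree(base, labels)
        theirs_nwk = str(skbio_nj(DistanceMatrix(base, labels)))
        theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick")
        assert rf_distance(ours, theirs) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0, 2.0], [1.5, 0, 1.0], [2.0, 1.0, 0]])
        with pytest.raises(AlignmentError):
            nj_tree(D, ["a", "b", "c"])

    def test_bionj_recovers_additive_tree_too(self):
        nwk = "((a:1,b:2):1,(c:3,d:4):1,e:5);"
        src = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = src.phylogenetic_distance_matrix()
        labels = ["a", "b", "c", "d", "e"]
        taxa = {t.label: t for t in src.taxon_namespace}
        D = np.array([[pdm.distance(taxa[x], taxa[y]) for y in labels]
                      for x in labels])
        assert rf_distance(bionj_tree(D, labels), src) == 0


class TestTreeLikelihood:
    def test_two_identical_sequences_zero_branches(self, wag, gamma5):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        from sialevo import Alignment
        aln = Alignment(ids=["A", "B"], seqs=[seq, seq])
        tree = dendropy.Tree.get(data="(A:0,B:0);", schema="newick",
                                 preserve_underscores=True)
        ll = tree_log_likelihood(tree, aln, wag, gamma5)
        expected = float(np.log(wag.freqs).sum())  # each residue once
        assert ll == pytest.approx(expected, abs=1e-4)

    def test_matches_four_taxon_brute_force(self, wag, gamma_tree):
        lengths = {"A": 0.3, "B": 0.7, "C": 0.2, "D": 0.5}
        t5 = 0.4
        nwk = (f"(A:{lengths['A']},B:{lengths['B']},"
               f"(C:{lengths['C']},D:{lengths['D']}):{t5});")
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        aln, _ = simulate_alignment(tree, wag, gamma_tree, 40, seed=10)
        got = tree_log_likelihood(tree, aln, wag, gamma_tree)
        want = four_taxon_loglik({sid: aln.row(sid) for sid in aln.ids},
                                 lengths, t5, wag, gamma_tree)
        assert abs(got - want) < 1e-8

    def test_invariant_under_rerooting(self, wag, gamma_tree):
        nwk = "((A:0.3,B:0.2):0.4,(C:0.1,D:0.6):0.2,E:0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        aln, _ = simulate_alignment(tree, wag, gamma_tree, 120, seed=11)
        ll1 = tree_log_likelihood(tree, aln, wag, gamma_tree)
        node = [lf for lf in tree.leaf_node_iter()
                if lf.taxon.label == "C"][0].parent_node
        tree.reroot_at_node(node, update_bipartitions=False)
        ll2 = tree_log_likelihood(tree, aln, wag, gamma_tree)
        assert ll1 == pytest.approx(ll2, abs=1e-6)

    def test_leaf_mismatch_rejected(self, wag, gamma5):
        from sialevo import Alignment
        aln = Alignment(ids=["A", "B"], seqs=["AC", "AC"])
        tree = dendropy.Tree.get(data="(A:0.1,X:0.1);", schema="newick")
        with pytest.raises(AlignmentError):
            tree_log_likelihood(tree, aln, wag, gamma5)

    def test_gaps_are_missing_data(self, wag, gamma5):
        from sialevo import Alignment
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick",
                                 preserve_underscores=True)
        full = Alignment(ids=["A", "B"], seqs=["AC", "AC"])
        gapped = Alignment(ids=["A", "B"], seqs=["AC-", "ACX"])
        # an all-missing column contributes likelihood 1 (log 0)
        assert tree_log_likelihood(tree, gapped, wag, gamma5) == \
            pytest.approx(tree_log_likelihood(tree, full, wag, gamma5), abs=1e-9)


class TestTreeSearch:
    def test_branch_length_optimization_monotone(self, wag, gamma_tree):
        nwk = "((A:0.3,B:0.2):0.2,(C:0.1,D:0.4):0.3,E:0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        aln, _ = simulate_alignment(tree, wag, gamma_tree, 300, seed=12)
        # perturb the lengths, then optimize
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.9
        engine = TreeLikelihood(tree, aln, wag, gamma_tree)
        before = engine.log_likelihood()
        after = engine.optimize_branch_lengths()
        assert after >= before
        assert after == pytest.approx(engine.log_likelihood(), abs=1e-9)

    def test_optimize_tree_beats_start_and_is_deterministic(self, wag, gamma_tree):
        nwk = "((A:0.5,B:0.5):0.3,(C:0.5,D:0.5):0.3,(E:0.5,F:0.9):0.1);"
        src = dendropy.Tree.get(data=nwk, schema="newick",
                                preserve_underscores=True)
        aln, _ = simulate_alignment(src, wag, gamma_tree, 400, seed=13)
        D = distance_matrix(aln, wag, gamma_tree)
        start = nj_tree(D, aln.ids)
        ll_start = tree_log_likelihood(start, aln, wag, gamma_tree)
        t1, ll1 = optimize_tree(aln, wag, gamma_tree, start="nj", D=D)
        t2, ll2 = optimize_tree(aln, wag, gamma_tree, start="nj", D=D)
        assert ll1 >= ll_start
        assert ll1 == ll2
        assert rf_distance(t1, t2) == 0

    def test_topology_recovery_long_branches(self, wag, gamma_tree):
        """The true 6-taxon topology is recovered in >=90% of replicates."""
        nwk = "((A:0.4,B:0.4):0.25,(C:0.4,D:0.4):0.25,(E:0.4,F:0.4):0.25);"
        src = dendropy.Tree.get(data=nwk, schema="newick",
                                preserve_underscores=True)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            aln, _ = simulate_alignment(src, wag, gamma_tree, 400,
                                        seed=1000 + rep)
            t, _ll = optimize_tree(aln, wag, gamma_tree, start="nj")
            if rf_distance(t, src) == 0:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestBootstrap:
    def test_supports_bounds_and_determinism(self, wag, gamma_tree):
        nwk = "((A:0.3,B:0.3):0.5,(C:0.3,D:0.3):0.5,(E:0.3,F:0.3):0.2);"
        src = dendropy.Tree.get(data=nwk, schema="newick",
                                preserve_underscores=True)
        aln, _ = simulate_alignment(src, wag, gamma_tree, 300, seed=14)
        kw = dict(n_replicates=20, seed=2, nni=False,
                  optimize_replicate_lengths=False)
        t1 = bootstrap_support(aln, wag, gamma_tree, **kw)
        t2 = bootstrap_support(aln, wag, gamma_tree, **kw)
        sup1 = sorted(n.support for n in t1.preorder_node_iter()
                      if getattr(n, "support", None) is not None)
        sup2 = sorted(n.support for n in t2.preorder_node_iter()
                      if getattr(n, "support", None) is not None)
        assert sup1 == sup2
        assert all(0 <= s <= 100 for s in sup1)

    def test_single_replicate_gives_zero_or_hundred(self, wag, gamma_tree):
        nwk = "((A:0.3,B:0.3):0.5,(C:0.3,D:0.3):0.5,E:0.3);"
        src = dendropy.Tree.get(data=nwk, schema="newick",
                                preserve_underscores=True)
        aln, _ = simulate_alignment(src, wag, gamma_tree, 200, seed=15)
        t = bootstrap_support(aln, wag, gamma_tree, n_replicates=1, seed=3,
                              nni=False, optimize_replicate_lengths=False)
        sups = {n.support for n in t.preorder_node_iter()
                if getattr(n, "support", None) is not None}
        assert sups <= {0.0, 100.0}

    def test_clear_clades_get_high_support(self, wag, gamma_tree):
        nwk = "((A:0.2,B:0.2):0.8,(C:0.2,D:0.2):0.8,(E:0.2,F:0.2):0.4);"
        src = dendropy.Tree.get(data=nwk, schema="newick",
                                preserve_underscores=True)
        aln, _ = simulate_alignment(src, wag, gamma_tree, 500, seed=16)
        t = bootstrap_support(aln, wag, gamma_tree, n_replicates=100, seed=4,
                              nni=False, optimize_replicate_lengths=False)
        sups = [n.support for n in t.preorder_node_iter()
                if getattr(n, "support", None) is not None]
        assert max(sups) >= 95.0


class TestGammaShapeEstimation:
    def test_homogeneous_data_hits_upper_bound(self, wag):
        nwk = "((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        homo = GammaRates.discrete(1.0, 1)  # single category = no variation
        aln, _ = simulate_alignment(tree, wag, homo, 800, seed=17)
        alpha = estimate_gamma_shape(tree, aln, wag, n_categories=5,
                                     bounds=(0.05, 50.0))
        assert alpha > 40.0

    def test_shape_recovery(self, wag):
        """Shape estimated on data simulated at alpha=1 lands near 1."""
        nwk = ("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,"
               "((E:0.3,F:0.3):0.2,(G:0.3,H:0.3):0.2):0.1);")
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        g1 = GammaRates.discrete(1.0, 5)
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            aln, _ = simulate_alignment(tree, wag, g1, 1200, seed=2000 + rep)
            alpha = estimate_gamma_shape(tree, aln, wag, n_categories=5)
            if 0.7 <= alpha <= 1.4:
                hits += 1
        assert hits >= n_rep - 1

    def test_estimate_is_an_optimum(self, wag, gamma_tree):
        nwk = "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        aln, _ = simulate_alignment(tree, wag, gamma_tree, 500, seed=18)
        alpha = estimate_gamma_shape(tree, aln, wag, n_categories=5)
        ll_hat = tree_log_likelihood(tree, aln, wag,
                                     GammaRates.discrete(alpha, 5))
        for probe in (alpha * 0.5, alpha * 2, 0.3, 10.0):
            ll = tree_log_likelihood(tree, aln, wag,
                                     GammaRates.discrete(probe, 5))
            assert ll_hat >= ll - 1e-6
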