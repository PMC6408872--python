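import itertools
import math

import numpy as np
import pytest

from amatox import phylo, synthdata as sd
from amatox.phylo import (Constraint, DistanceMatrix, GTRGammaParams,
                          LikelihoodEngine, conflicting_bipartitions,
                          discrete_gamma_rates, empirical_params,
                          is_monophyletic, log_likelihood, nj_tree,
                          nni_search, nucleotide_distance, optimize,
                          tree_bipartitions)
from amatox.seqio import Alignment, SeqRecord, parse_newick


from oracles import brute_force_lnl


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment([SeqRecord("a", "ACGTACGT"), SeqRecord("b", "ACGTACGT")])
        assert nucleotide_distance(aln).matrix[0, 1] == 0.0

    def test_jc_closed_form(self):
        aln = Alignment([SeqRecord("a", "A" * 40), SeqRecord("b", "A" * 36 + "CCCC")])
        p = 0.1
        expect = -0.75 * math.log(1 - 4 * p / 3)
        assert nucleotide_distance(aln).matrix[0, 1] == pytest.approx(expect)

    def test_saturation_flagged_infinite(self):
        aln = Alignment([SeqRecord("a", "ACGT" * 3), SeqRecord("b", "CATG" * 3)])
        assert not np.isfinite(nucleotide_distance(aln).matrix[0, 1])

    def test_k80_reduces_to_jc_shape(self):
        aln = Alignment([SeqRecord("a", "AAAACCCCGGGG"),
                         SeqRecord("b", "AAAGCCCAGGGC")])
        d = nucleotide_distance(aln, "K80").matrix[0, 1]
        assert d > 0 and np.isfinite(d)


class TestNJ:
    def test_additive_matrix_recovers_topology(self):
        ids = ["A", "B", "C", "D"]
        # tree ((A,B),(C,D)) with known additive distances
        m = np.array([[0, 0.4, 0.65, 0.5],
                      [0.4, 0, 0.75, 0.6],
                      [0.65, 0.75, 0, 0.35],
                      [0.5, 0.6, 0.35, 0]])
        t = nj_tree(DistanceMatrix(ids, m))
        assert tree_bipartitions(t) == {frozenset({"C", "D"})} or \
            tree_bipartitions(t) == {frozenset({"A", "B"})}

    def test_three_taxa_star(self):
        m = np.array([[0, 2.0, 3.0], [2.0, 0, 2.5], [3.0, 2.5, 0]])
        t = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        assert len(list(t.leaf_node_iter())) == 3

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 7
        base = rng.random((n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"t{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(ids, m))
        perm = list(rng.permutation(n))
        t2 = nj_tree(DistanceMatrix([ids[i] for i in perm],
                                    m[np.ix_(perm, perm)]))
        assert tree_bipartitions(t1) == tree_bipartitions(t2)

    def test_infinite_entry_rejected(self):
        m = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="model"):
            nj_tree(DistanceMatrix(["a", "b", "c"], m))


class TestLikelihood:
    def test_two_taxon_closed_form_jc(self):
        # JC limit: equal freqs, unit exchangeabilities, single rate
        params = GTRGammaParams(alpha=1.0, ncat=1)
        t = 0.2
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        aln = Alignment([SeqRecord("a", "A"), SeqRecord("b", "A")])
        total, _ = log_likelihood(tree, aln, params)
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        assert total == pytest.approx(math.log(0.25 * p_same), abs=1e-10)

    def test_pruning_equals_enumeration(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        aln, _ = sd.evolve_sequences(tree, gtr_params, 10, seed=5)
        total, site = log_likelihood(tree, aln, gtr_params)
        btotal, bsite = brute_force_lnl(tree, aln, gtr_params)
        assert total == pytest.approx(btotal, abs=1e-8)
        assert np.allclose(site, bsite, atol=1e-8)

    def test_site_vector_sums_to_total(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        aln, _ = sd.evolve_sequences(tree, gtr_params, 50, seed=6)
        total, site = log_likelihood(tree, aln, gtr_params)
        assert total == pytest.approx(site.sum(), abs=1e-6)

    def test_rerooting_invariance(self, gtr_params):
        t1 = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        t2 = parse_newick("(a:0.05,(b:0.3,(c:0.2,d:0.05):0.25):0.05);")
        aln, _ = sd.evolve_sequences(t1, gtr_params, 60, seed=7)
        l1, _ = log_likelihood(t1, aln, gtr_params)
        l2, _ = log_likelihood(t2, aln, gtr_params)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_gaps_are_missing_data(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        aln = Alignment([SeqRecord("a", "A-"), SeqRecord("b", "AN"),
                         SeqRecord("c", "AA"), SeqRecord("d", "AC")])
        total, site = log_likelihood(tree, aln, gtr_params)
        assert np.isfinite(total) and len(site) == 2

    def test_taxon_mismatch_listed(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        aln = Alignment([SeqRecord("a", "A"), SeqRecord("b", "A"),
                         SeqRecord("c", "A"), SeqRecord("ZZZ", "A")])
        with pytest.raises(ValueError, match="ZZZ"):
            log_likelihood(tree, aln, gtr_params)

    def test_invariant_class_raises_constant_site_likelihood(self):
        tree = parse_newick("((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2);")
        aln = Alignment([SeqRecord(n, "AAAA") for n in "abcd"])
        base = GTRGammaParams(alpha=1.0)
        withI = GTRGammaParams(alpha=1.0, p_inv=0.5)
        l0, _ = log_likelihood(tree, aln, base)
        l1, _ = log_likelihood(tree, aln, withI)
        assert l1 > l0


class TestDiscreteGamma:
    def test_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_large_alpha_near_uniform(self):
        rates = discrete_gamma_rates(100.0, 4)
        assert np.allclose(rates, 1.0, atol=0.15)


class TestOptimize:
    def test_branch_length_recovery(self, gtr_params):
        tree = parse_newick(
            "(((a:0.12,b:0.15):0.1,(c:0.1,d:0.2):0.08):0.1,"
            "((e:0.15,f:0.1):0.12,(g:0.2,h:0.1):0.1):0.05);")
        aln, _ = sd.evolve_sequences(tree, gtr_params, 2000, seed=8)
        fitted, _, _ = optimize(tree, aln, gtr_params, optimize_alpha=False,
                                max_rounds=3)
        it_true = phylo._ITree(tree)
        it_fit = phylo._ITree(fitted)
        errs = []
        for i in range(1, it_true.n_nodes):
            t, f = it_true.lengths[i], it_fit.lengths[i]
            if t > 0:
                errs.append(abs(f - t) / t)
        assert np.median(errs) < 0.15

    def test_fixed_point(self, gtr_params):
        tree = parse_newick("((a:0.1,b:0.3):0.15,(c:0.2,d:0.05):0.1);")
        aln, _ = sd.evolve_sequences(tree, gtr_params, 500, seed=9)
        t1, p1, l1 = optimize(tree, aln, gtr_params, optimize_alpha=False)
        t2, p2, l2 = optimize(t1, aln, p1, optimize_alpha=False)
        assert l2 - l1 < 1e-4 and l2 >= l1 - 1e-6

    def test_alpha_recovery(self):
        params = GTRGammaParams(alpha=0.5)
        tree = parse_newick(
            "(((a:0.2,b:0.25):0.15,(c:0.2,d:0.3):0.1):0.1,"
            "(e:0.3,f:0.2):0.15);")
        aln, _ = sd.evolve_sequences(tree, params, 5000, seed=10)
        _, fitted, _ = optimize(tree, aln,
                                GTRGammaParams(alpha=1.5),
                                optimize_alpha=True, max_rounds=3)
        assert abs(fitted.alpha - 0.5) / 0.5 < 0.25


class TestTopologyOps:
    def test_popb_clade_monophyletic(self):
        t = parse_newick(
            "((POPB_Le,(POPB_Ga,POPB_Am)),(POPA_Am,POP_Ga));")
        assert is_monophyletic(t, {"POPB_Le", "POPB_Ga", "POPB_Am"})
        assert not is_monophyletic(t, {"POPB_Le", "POPA_Am"})

    def test_gene_species_conflict_detected(self):
        gene = parse_newick("((Le,(Ga,Am)),(X,Y));")
        species = parse_newick("((Am,(Ga,Le)),(X,Y));")
        leaf_map = {n: n for n in ("Le", "Ga", "Am", "X", "Y")}
        conflicts = conflicting_bipartitions(gene, species, leaf_map)
        assert conflicts

    def test_identical_trees_no_conflict(self):
        t = parse_newick("((a,b),(c,(d,e)));")
        leaf_map = {n: n for n in "abcde"}
        assert conflicting_bipartitions(t, t, leaf_map) == set()

    def test_unmapped_leaf_rejected(self):
        t = parse_newick("((a,b),c);")
        with pytest.raises(ValueError, match="c"):
            conflicting_bipartitions(t, t, {"a": "a", "b": "b"})


class TestNNISearch:
    def test_recovers_true_topology(self, resolvable_8taxon_tree, gtr_params):
        hits = 0
        for seed in range(6):
            aln, _ = sd.evolve_sequences(
                resolvable_8taxon_tree, gtr_params, 2000, seed=400 + seed)
            start = nj_tree(nucleotide_distance(aln, "JC"))
            best, _ = nni_search(aln, start, gtr_params)
            hits += tree_bipartitions(best) == tree_bipartitions(
                resolvable_8taxon_tree)
        assert hits >= 5

    def test_true_clade_constraint_no_op(self, resolvable_8taxon_tree,
                                         gtr_params):
        aln, _ = sd.evolve_sequences(
            resolvable_8taxon_tree, gtr_params, 1000, seed=77)
        start = nj_tree(nucleotide_distance(aln, "JC"))
        con = Constraint([{"a", "b"}])
        if not con.satisfied(start):
            start = resolvable_8taxon_tree
        t1, l1 = nni_search(aln, start, gtr_params, constraints=con)
        assert con.satisfied(t1)

    def test_false_constraint_lowers_lnl(self, resolvable_8taxon_tree,
                                         gtr_params):
        aln, _ = sd.evolve_sequences(
            resolvable_8taxon_tree, gtr_params, 1000, seed=78)
        false_clade = {"a", "c", "e"}
        start = parse_newick(
            "((((a:0.1,c:0.1):0.1,e:0.1):0.1,(b:0.1,d:0.1):0.1):0.1,"
            "((f:0.1,g:0.1):0.1,h:0.1):0.1);")
        con = Constraint([false_clade])
        t_con, l_con = nni_search(aln, start, gtr_params, constraints=con)
        assert con.satisfied(t_con)
        t_free, l_free = nni_search(
            aln, nj_tree(nucleotide_distance(aln, "JC")), gtr_params)
        assert l_con <= l_free + 1e-6

    def test_unsatisfiable_start_rejected(self, resolvable_8taxon_tree,
                                          gtr_params):
        aln, _ = sd.evolve_sequences(
            resolvable_8taxon_tree, gtr_params, 100, seed=79)
        con = Constraint([{"a", "c"}])
        bad_start = parse_newick(
            "(((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1):0.1,"
            "((e:0.1,f:0.1):0.1,(g:0.1,h:0.1):0.1):0.1);")
        with pytest.raises(ValueError):
            nni_search(aln, bad_start, gtr_params, constraints=con)
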