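"""Distances, neighbor joining, pruning likelihood, ML fitting."""

import numpy as np
import pytest

from phylosel.models import (
    ModelParameters,
    ModelSpec,
    build_rate_matrix,
    parse_model_name,
    rate_matrix_eigen,
    transition_matrices,
)
from phylosel.phylo_engine import (
    DistanceMatrix,
    MAX_JC_DISTANCE,
    SubstitutionModel,
    fit_all_candidates,
    fit_model,
    jc_distance_matrix,
    log_likelihood,
    neighbor_joining,
)
from phylosel.seqsim import Alignment, simulate_alignment
from phylosel.treesim import PhyloTree, scale_to_height, simulate_birth_death_tree


class TestJCDistance:
    def test_identical_sequences_give_zero(self):
        aln = Alignment(["a", "b"], np.zeros((2, 100), dtype=np.int8))
        dm = jc_distance_matrix(aln)
        assert dm.d[0, 1] == 0.0

    def test_closed_form_at_p_030(self):
        codes = np.zeros((2, 100), dtype=np.int8)
        codes[1, :30] = 1  # exactly p = 0.3
        dm = jc_distance_matrix(Alignment(["a", "b"], codes))
        assert np.isclose(dm.d[0, 1], -0.75 * np.log(0.6))

    def test_saturation_capped_with_warning(self):
        codes = np.zeros((2, 100), dtype=np.int8)
        codes[1, :75] = 1  # p = 0.75
        with pytest.warns(UserWarning, match="saturated"):
            dm = jc_distance_matrix(Alignment(["a", "b"], codes))
        assert dm.d[0, 1] == MAX_JC_DISTANCE


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        # v_a = (d_ab + d_ac - d_bc)/2, etc.
        got = dict(zip(tree.taxa, tree.edge_length[:3]))
        assert np.isclose(got["a"], 0.1)
        assert np.isclose(got["b"], 0.2)
        assert np.isclose(got["c"], 0.4)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_additive_distances_recover_topology_and_lengths(self, seed, oracles):
        tree = scale_to_height(simulate_birth_death_tree(8, seed=seed), 0.8)
        un = tree.unroot()
        d = oracles.path_distance_matrix(un)
        nj = neighbor_joining(DistanceMatrix(un.taxa, d))
        assert nj.splits() == un.splits()
        # additive input: branch lengths recovered exactly
        ref = np.sort(un.edge_length[np.arange(un.n_nodes) != un.root])
        got = np.sort(nj.edge_length[np.arange(nj.n_nodes) != nj.root])
        assert np.allclose(ref, got, atol=1e-9)

    def test_four_taxa_additive_split(self, oracles):
        tree = PhyloTree.from_newick(
            "((t1:0.1,t2:0.2):0.05,t3:0.3,t4:0.15);")
        d = oracles.path_distance_matrix(tree)
        nj = neighbor_joining(DistanceMatrix(tree.taxa, d))
        assert nj.splits() == tree.splits()  # zero RF distance

    def test_agrees_with_dendropy_on_random_matrix(self):
        # independent cross-check against an established NJ implementation
        import dendropy

        rng = np.random.default_rng(5)
        n = 7
        base = rng.uniform(0.2, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        taxa = [f"t{i+1}" for i in range(n)]
        mine = neighbor_joining(DistanceMatrix(taxa, d))

        csv = "," + ",".join(taxa) + "\n" + "\n".join(
            taxa[i] + "," + ",".join(str(x) for x in d[i]) for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        dtree = pdm.nj_tree()
        nchild = len(dtree.seed_node.child_nodes())
        ref = PhyloTree.from_dendropy(dtree, rooted=nchild == 2)
        if ref.rooted:
            ref = ref.unroot()
        assert mine.splits() == ref.splits()

    def test_rejects_asymmetric_and_tiny_inputs(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(
                ["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestPruningLikelihood:
    def test_two_taxa_single_site_jc_closed_form(self):
        t = 0.4
        tree = PhyloTree.from_newick(f"(t1:{t/2},t2:{t/2});")
        codes = np.array([[0], [2]], dtype=np.int8)  # A vs G
        aln = Alignment(["t1", "t2"], codes)
        lnl = log_likelihood(aln, tree, ModelSpec("JC"), ModelParameters())
        p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        assert np.isclose(lnl, np.log(0.25 * p_diff), atol=1e-10)

    def test_matches_brute_force_on_small_trees(self, tree5, oracles, gen_params):
        rng = np.random.default_rng(17)
        for _ in range(20):
            params = oracles.random_model_parameters(rng)
            spec = ModelSpec(
                rng.choice(["JC", "HKY", "GTR", "SYM", "TrN"]),
                has_inv=bool(rng.integers(2)), has_gamma=bool(rng.integers(2)))
            aln = simulate_alignment(tree5, spec, params, 12,
                                     seed=int(rng.integers(2**31)))
            fast = log_likelihood(aln, tree5, spec, params)
            slow = oracles.brute_force_loglike(aln, tree5, spec, params)
            assert abs(fast - slow) < 1e-8

    def test_long_branch_limit_is_product_of_frequencies(self, gen_params):
        spec, params = gen_params("GTR")
        tree = PhyloTree.from_newick("(t1:50.0,t2:50.0,t3:50.0);")
        codes = np.array([[0], [1], [3]], dtype=np.int8)
        aln = Alignment(["t1", "t2", "t3"], codes)
        lnl = log_likelihood(aln, tree, spec, params)
        expected = np.log(np.prod(params.base_freqs[[0, 1, 3]]))
        assert np.isclose(lnl, expected, atol=1e-6)

    def test_taxon_mismatch_raises(self, tree5):
        aln = Alignment(["x1", "x2"], np.zeros((2, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            SubstitutionModel(aln, tree5, ModelSpec("JC"))


@pytest.fixture(scope="module")
def jc_data(tree8):
    aln = simulate_alignment(tree8, ModelSpec("JC"), ModelParameters(),
                             2000, seed=21)
    topo = neighbor_joining(jc_distance_matrix(aln))
    return aln, topo


class TestFitting:
    def test_gtr_on_jc_data_recovers_flat_exchangeabilities(self, jc_data):
        aln, topo = jc_data
        fit = fit_model(aln, topo, ModelSpec("GTR"))
        ex = fit.params.exchangeabilities
        ratio = ex.max() / ex.min()
        assert ratio < 1.6  # all rates close to equal at 2000 sites

    def test_nested_pair_loglik_ordering(self, jc_data):
        aln, topo = jc_data
        f_jc = fit_model(aln, topo, ModelSpec("JC"))
        f_hky = fit_model(aln, topo, ModelSpec("HKY"),
                          start_branch_lengths=f_jc.branch_lengths)
        assert f_hky.lnL >= f_jc.lnL - 1e-4

    def test_branch_length_vectors_share_indexing(self, jc_data):
        aln, topo = jc_data
        fits = fit_all_candidates(aln, topo,
                                  candidates=[ModelSpec("JC"),
                                              ModelSpec("K80"),
                                              ModelSpec("HKY")])
        lens = {len(f.branch_lengths) for f in fits.values()}
        assert lens == {topo.n_edges}

    def test_fit_summary_mentions_model_and_lnl(self, jc_data):
        aln, topo = jc_data
        fit = fit_model(aln, topo, ModelSpec("K80"))
        text = fit.summary()
        assert "K80" in text and "lnL" in text

    def test_alpha_recovery_hky_gamma(self, tree8, gen_params):
        spec, params = gen_params("HKY+G")
        aln = simulate_alignment(tree8, spec, params, 2000, seed=29)
        topo = neighbor_joining(jc_distance_matrix(aln))
        fit = fit_model(aln, topo, spec)
        assert fit.lnL <= 0
        assert abs(fit.params.gamma_shape - 0.67256) / 0.67256 < 0.5
        kappa = fit.params.exchangeabilities[1]
        assert 1.2 < kappa < 3.5  # generating kappa 2.0
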