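"""Sequence simulator: site processes, discrete gamma, codon model, I/O."""

import io

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare, gamma as gamma_dist

from phylosel.models import (
    ModelParameters,
    ModelSpec,
    build_rate_matrix,
    parse_model_name,
    rate_matrix_eigen,
    transition_matrices,
)
from phylosel.seqsim import (
    Alignment,
    CodonSimConfig,
    SENSE_CODONS,
    build_gy94_rate_matrix,
    gamma_category_rates,
    simulate_alignment,
    simulate_codon_alignment,
)
from phylosel.treesim import PhyloTree


@pytest.fixture(scope="module")
def two_taxon_tree():
    return PhyloTree.from_newick("(t1:0.15,t2:0.15);")


class TestGammaCategories:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.67256, 1.0, 3.0])
    def test_rates_match_numeric_integration(self, alpha):
        ncat = 4
        rates = gamma_category_rates(alpha, ncat)
        edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1),
                               a=alpha, scale=1.0 / alpha)
        for k in range(ncat):
            lo, hi = edges[k], edges[k + 1]
            num, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha,
                                                       scale=1.0 / alpha),
                          lo, hi, limit=200)
            assert np.isclose(rates[k], ncat * num, rtol=1e-5)

    def test_mean_is_exactly_one(self):
        for alpha in (0.1, 0.67256, 5.0):
            assert np.isclose(gamma_category_rates(alpha, 4).mean(), 1.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gamma_category_rates(0.0)


class TestNucleotideSimulation:
    def test_zero_branch_lengths_copy_root(self):
        tree = PhyloTree.from_newick("((t1:0,t2:0):0,(t3:0,t4:0):0);")
        aln = simulate_alignment(tree, ModelSpec("GTR"),
                                 ModelParameters(), 50, seed=1)
        assert (aln.codes == aln.codes[0]).all()

    def test_jc_saturation_matches_closed_form(self):
        # JC identity probability 1/4 + 3/4 exp(-4t/3); t = 10 is saturation
        tree = PhyloTree.from_newick("(t1:5.0,t2:5.0);")
        n = 10_000
        aln = simulate_alignment(tree, ModelSpec("JC"), ModelParameters(),
                                 n, seed=3)
        match = np.mean(aln.codes[0] == aln.codes[1])
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(match - 0.25) < 3 * se

    def test_invariable_fraction_binomial(self):
        tree = PhyloTree.from_newick("(t1:0.5,t2:0.5);")
        n = 10_000
        params = ModelParameters(p_inv=0.25)
        aln = simulate_alignment(tree, ModelSpec("JC", has_inv=True),
                                 params, n, seed=4)
        frac = np.mean(aln.site_rates == 0)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 4 * se

    def test_determinism_byte_for_byte(self, two_taxon_tree, gen_params):
        spec, params = gen_params("GTR+I+G")
        a = simulate_alignment(two_taxon_tree, spec, params, 200, seed=9)
        b = simulate_alignment(two_taxon_tree, spec, params, 200, seed=9)
        assert (a.codes == b.codes).all()
        c = simulate_alignment(two_taxon_tree, spec, params, 200, seed=10)
        assert (a.codes != c.codes).any()

    def test_two_taxon_site_patterns_match_joint_distribution(self, gen_params):
        # validates simulator against pi_i P_ij(t) end to end
        spec, params = gen_params("GTR")
        t = 0.3
        tree = PhyloTree.from_newick(f"(t1:{t/2},t2:{t/2});")
        n = 50_000
        aln = simulate_alignment(tree, spec, params, n, seed=11)
        q = build_rate_matrix(params, spec)
        eig = rate_matrix_eigen(q, params.base_freqs)
        p = transition_matrices(*eig, np.array([t]))[0]
        joint = (params.base_freqs[:, None] * p).ravel()
        counts = np.zeros(16)
        obs = aln.codes[0] * 4 + aln.codes[1]
        for k in range(16):
            counts[k] = np.sum(obs == k)
        stat, pval = chisquare(counts, joint * n)
        assert pval > 0.001

    def test_stationary_composition_on_long_tree(self, gen_params):
        spec, params = gen_params("GTR")
        tree = PhyloTree.from_newick("(t1:4.0,t2:4.0);")
        n = 50_000
        aln = simulate_alignment(tree, spec, params, n, seed=13)
        counts = np.bincount(aln.codes.ravel(), minlength=4)
        stat, pval = chisquare(counts, params.base_freqs * counts.sum())
        assert pval > 0.001

    def test_length_validation(self, two_taxon_tree):
        with pytest.raises(ValueError):
            simulate_alignment(two_taxon_tree, ModelSpec("JC"),
                               ModelParameters(), 0, seed=0)


class TestAlignmentIO:
    def test_fasta_round_trip(self, two_taxon_tree):
        aln = simulate_alignment(two_taxon_tree, ModelSpec("JC"),
                                 ModelParameters(), 60, seed=2)
        buf = io.StringIO()
        aln.to_fasta(buf)
        buf.seek(0)
        back = Alignment.from_fasta(buf)
        assert back.taxa == aln.taxa
        assert (back.codes == aln.codes).all()

    def test_phylip_round_trip(self, two_taxon_tree):
        aln = simulate_alignment(two_taxon_tree, ModelSpec("JC"),
                                 ModelParameters(), 60, seed=2)
        buf = io.StringIO()
        aln.to_phylip(buf)
        buf.seek(0)
        back = Alignment.from_phylip(buf)
        assert back.taxa == aln.taxa
        assert (back.codes == aln.codes).all()

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError):
            Alignment(["a", "a"], np.zeros((2, 3), dtype=np.int8))


class TestGY94:
    def test_generator_rows_sum_to_zero(self, gen_params):
        _, params = gen_params("GTR")
        cfg = CodonSimConfig(omega=0.016, nucleotide_params=params)
        q, pi = build_gy94_rate_matrix(cfg)
        assert q.shape == (61, 61)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(pi.sum(), 1.0)
        assert np.isclose(-(pi * np.diag(q)).sum(), 1.0)

    def test_multi_position_changes_have_zero_rate(self, gen_params):
        _, params = gen_params("GTR")
        cfg = CodonSimConfig(omega=0.016, nucleotide_params=params)
        q, _ = build_gy94_rate_matrix(cfg)
        for a in (0, 17, 42):
            for b in (5, 29, 60):
                ca, cb = SENSE_CODONS[a], SENSE_CODONS[b]
                ndiff = sum(x != y for x, y in zip(ca, cb))
                if ndiff > 1:
                    assert q[a, b] == 0.0

    def test_omega_one_equal_rates_symmetric_in_syn_nonsyn(self):
        params = ModelParameters()  # equal frequencies, equal rates
        cfg = CodonSimConfig(omega=1.0, nucleotide_params=params)
        q, pi = build_gy94_rate_matrix(cfg)
        # every single-nucleotide change has identical rate
        vals = q[q > 0]
        assert np.allclose(vals, vals[0])

    def test_simulated_codon_alignment_shape_and_no_stops(self, gen_params):
        from phylosel.treesim import scale_to_height, simulate_birth_death_tree
        _, params = gen_params("HKY")
        tree = scale_to_height(simulate_birth_death_tree(30, seed=6), 0.5)
        cfg = CodonSimConfig(omega=0.016, nucleotide_params=params,
                             length_nt=999, mutation_rate=1.0)
        aln = simulate_codon_alignment(tree, cfg, seed=8)
        assert aln.codes.shape == (30, 999)
        stops = {"TAA", "TAG", "TGA"}
        for seq in aln.sequences().values():
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & stops)

    def test_length_not_divisible_by_three_rejected(self, gen_params):
        _, params = gen_params("HKY")
        with pytest.raises(ValueError):
            CodonSimConfig(omega=0.016, nucleotide_params=params,
                           length_nt=1000)
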