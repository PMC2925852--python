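"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phylosel.models import (
    ModelParameters,
    ModelSpec,
    build_rate_matrix,
    constrain_parameters,
    rate_matrix_eigen,
    transition_matrices,
)
from phylosel.pipeline import PARAMETER_SETS, params_for_model
from phylosel.seqsim import gamma_category_rates
from phylosel.treesim import PhyloTree, scale_to_height, simulate_birth_death_tree


@pytest.fixture(scope="session")
def set_a():
    return PARAMETER_SETS["A"]


@pytest.fixture(scope="session")
def set_b():
    return PARAMETER_SETS["B"]


@pytest.fixture(scope="session")
def tree8():
    """Ultrametric 8-taxon birth-death tree of height 0.5."""
    return scale_to_height(simulate_birth_death_tree(8, seed=3), 0.5)


@pytest.fixture(scope="session")
def tree5():
    return PhyloTree.from_newick(
        "((t1:0.1,t2:0.23):0.08,(t3:0.3,t4:0.05):0.12,t5:0.4);")


# ---------------------------------------------------------------------------
# Oracles (kept deliberately independent of the package's pruning/NJ paths)
# ---------------------------------------------------------------------------


def brute_force_loglike(aln, tree, spec: ModelSpec,
                        params: ModelParameters) -> float:
    """Likelihood by exhaustive summation over internal-node states.

    Only uses the package's rate-matrix/P(t) primitives; the sum over
    histories is explicit, so it checks the pruning recursion itself.
    """
    params = constrain_parameters(params, spec)
    q = build_rate_matrix(params)
    eig = rate_matrix_eigen(q, params.base_freqs)
    rates = (gamma_category_rates(params.gamma_shape, params.ncat)
             if spec.has_gamma else np.array([1.0]))
    pinv = params.p_inv if spec.has_inv else 0.0
    pi = params.base_freqs
    tipidx = {t: i for i, t in enumerate(aln.taxa)}
    internal = [v for v in range(tree.n_nodes) if v >= tree.ntips]
    lnL = 0.0
    for s in range(aln.nsites):
        site = 0.0
        for r in rates:
            P = {v: transition_matrices(
                *eig, np.array([tree.edge_length[v] * r]))[0]
                for v in range(tree.n_nodes) if v != tree.root}
            tot = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = {v: aln.codes[tipidx[tree.taxa[v]], s]
                      for v in range(tree.ntips)}
                st.update(dict(zip(internal, assign)))
                prob = pi[st[tree.root]]
                for v in range(tree.n_nodes):
                    if v != tree.root:
                        prob *= P[v][st[tree.parent[v]], st[v]]
                tot += prob
            site += tot / len(rates)
        x = aln.codes[:, s]
        const = pi[x[0]] if (x == x[0]).all() else 0.0
        lnL += np.log(pinv * const + (1.0 - pinv) * site)
    return lnL


def path_distance_matrix(tree: PhyloTree) -> np.ndarray:
    """Tip-to-tip path lengths by explicit parent-chain walking."""
    n = tree.ntips
    chains = []
    for v in range(n):
        chain, x, dist = {}, v, 0.0
        while x >= 0:
            chain[x] = dist
            if tree.parent[x] >= 0:
                dist += tree.edge_length[x]
            x = tree.parent[x]
        chains.append(chain)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, dist = j, 0.0
            while x not in chains[i]:
                dist += tree.edge_length[x]
                x = tree.parent[x]
            d[i, j] = d[j, i] = dist + chains[i][x]
    return d


def random_model_parameters(rng: np.random.Generator) -> ModelParameters:
    freqs = rng.dirichlet(np.full(4, 5.0))
    ex = rng.uniform(0.3, 5.0, size=6)
    ex /= ex[5]
    return ModelParameters(freqs, ex,
                           gamma_shape=float(rng.uniform(0.3, 2.0)),
                           p_inv=float(rng.uniform(0.0, 0.5)))


@pytest.fixture(scope="session")
def oracles():
    class _O:
        brute_force_loglike = staticmethod(brute_force_loglike)
        path_distance_matrix = staticmethod(path_distance_matrix)
        random_model_parameters = staticmethod(random_model_parameters)
    return _O


@pytest.fixture(scope="session")
def gen_params():
    def _make(name: str, pset: str = "A"):
        from phylosel.models import parse_model_name
        spec = parse_model_name(name)
        return spec, params_for_model(spec, PARAMETER_SETS[pset])
    return _make
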