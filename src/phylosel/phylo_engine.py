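"""Distance trees and maximum-likelihood model fits on a fixed topology.

The workflow mirrors the classic ModelTest/PAUP* pipeline: build one
neighbor-joining (NJ) starting tree from Jukes-Cantor distances, then
optimise every candidate model's free parameters *and* all branch lengths on
that fixed topology.  The topology is never re-estimated, which also
guarantees that branch-length vectors are comparable across models (as the
decision-theory criterion requires).

Likelihoods use Felsenstein's pruning algorithm over compressed site
patterns, with per-node scaling for numerical stability.  For a model with
invariable sites the site likelihood is

    L_s = p_inv * pi[x_s] * [site s constant]  +  (1 - p_inv) * mean_c L_s(r_c)

where the mean runs over the discrete-gamma categories (a single unit-rate
category without +G).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import (
    ModelParameters,
    ModelSpec,
    build_rate_matrix,
    candidate_models,
    constrain_parameters,
    is_nested,
    rate_matrix_eigen,
    transition_matrices,
)
from .seqsim import Alignment, gamma_category_rates
from .treesim import PhyloTree

__all__ = [
    "DistanceMatrix",
    "jc_distance_matrix",
    "neighbor_joining",
    "log_likelihood",
    "SubstitutionModel",
    "SubstitutionModelResults",
    "fit_model",
    "fit_all_candidates",
]

#: ceiling applied to saturated pairwise distances
MAX_JC_DISTANCE = 5.0

# optimiser bounds (documented numerical safety rails).  The alpha ceiling is
# deliberately huge: at the +I/+I+G boundary the gamma shape diverges, and a
# low ceiling would break lnL monotonicity across nested models.
_ALPHA_BOUNDS = (0.01, 1e6)
_RATE_BOUNDS = (1e-4, 1e4)
_PINV_MAX = 0.99
_BRANCH_BOUNDS = (1e-8, 20.0)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


def jc_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances, d = -3/4 ln(1 - 4p/3).

    Saturated pairs (mismatch proportion p >= 0.75) are capped at
    :data:`MAX_JC_DISTANCE` with a warning rather than raising.
    """
    codes = alignment.codes
    n = alignment.ntaxa
    if n < 2:
        raise ValueError("need at least two taxa")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(codes[i] != codes[j]))
            if p >= 0.75:
                warnings.warn(
                    f"saturated distance between {alignment.taxa[i]} and "
                    f"{alignment.taxa[j]} (p={p:.3f}); capped at {MAX_JC_DISTANCE}")
                dist = MAX_JC_DISTANCE
            else:
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
                dist = min(dist, MAX_JC_DISTANCE)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(alignment.taxa), d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted binary tree.

    Deterministic: ties in the Q criterion are broken by the lowest
    (row-major) taxon-pair index.  Negative branch-length estimates are
    clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    # active cluster -> node id in the output arrays
    total_nodes = 2 * n - 2  # n tips + (n - 2) internal incl. trifurcating root
    parent = np.full(total_nodes, -1, dtype=int)
    lengths = np.zeros(total_nodes)
    next_node = n
    active = list(range(n))
    d = dm.d.copy()
    idx = list(range(n))  # node id of each row of d

    while len(active) > 3:
        m = len(active)
        sub = d
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        vi = max(0.0, 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = max(0.0, sub[i, j] - (0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        u = next_node
        next_node += 1
        parent[idx[i]] = u
        parent[idx[j]] = u
        lengths[idx[i]] = vi
        lengths[idx[j]] = vj
        dnew = 0.5 * (sub[i, :] + sub[j, :] - sub[i, j])
        dnew = np.maximum(dnew, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.empty((m - 1, m - 1))
        d[: m - 2, : m - 2] = sub[np.ix_(keep, keep)]
        d[m - 2, : m - 2] = d[: m - 2, m - 2] = dnew[keep]
        d[m - 2, m - 2] = 0.0
        idx = [idx[k] for k in keep] + [u]
        active = idx

    # connect the last three clusters through the (trifurcating) root
    a, b, c = idx
    root = next_node
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    parent[a] = parent[b] = parent[c] = root
    lengths[a] = max(0.0, 0.5 * (dab + dac - dbc))
    lengths[b] = max(0.0, 0.5 * (dab + dbc - dac))
    lengths[c] = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(dm.taxa, parent[: root + 1], lengths[: root + 1],
                     rooted=False)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _compress(alignment: Alignment, taxa_order: list[str]):
    """Unique site patterns, their weights, and constant-site states."""
    order = [alignment.taxa.index(t) for t in taxa_order]
    cols = alignment.codes[order].T  # (S, ntaxa)
    patterns, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True)
    pat = patterns.T  # (ntaxa, P)
    const = np.where((pat == pat[0]).all(axis=0), pat[0], -1)
    return pat, counts.astype(float), const.astype(int)


class _TreeData:
    """Static traversal data for one topology."""

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self.root = tree.root
        self.post_internal = [v for v in tree.postorder if v >= tree.ntips]
        self.pre_nodes = [v for v in reversed(tree.postorder) if v != tree.root]
        self.edge_nodes = tree.edge_nodes


class SubstitutionModel:
    """Maximum-likelihood GTR-family model on a fixed tree topology.

    A statsmodels-style model object: construct from data (an alignment, a
    topology and a :class:`~phylosel.models.ModelSpec`), then call
    :meth:`fit` to obtain a :class:`SubstitutionModelResults`.
    """

    def __init__(self, alignment: Alignment, tree: PhyloTree,
                 spec: ModelSpec, ncat: int = 4):
        missing = set(tree.taxa) ^ set(alignment.taxa)
        if missing:
            raise ValueError(f"taxon mismatch between tree and alignment: {missing}")
        self.alignment = alignment
        self.tree = tree.copy()
        self.spec = spec
        self.ncat = ncat
        self.n_sites = alignment.nsites
        self.patterns, self.weights, self.const_state = _compress(
            alignment, self.tree.taxa)
        self.npat = self.patterns.shape[1]
        self.data = _TreeData(self.tree)
        # one-hot tip partials shared by every model on this topology
        eye = np.eye(4)
        self._tip_partial = [
            np.broadcast_to(eye[:, self.patterns[v]], (1, 4, self.npat))
            for v in range(self.tree.ntips)]

    # -- core likelihood ---------------------------------------------------

    def _site_rates(self, params: ModelParameters) -> np.ndarray:
        if self.spec.has_gamma:
            return gamma_category_rates(params.gamma_shape, self.ncat)
        return np.ones(1)

    def _edge_matrices(self, params, branch_lengths, rates):
        q = build_rate_matrix(params)
        eig = rate_matrix_eigen(q, params.base_freqs)
        ts = branch_lengths[:, None] * rates[None, :]
        p = transition_matrices(*eig, ts)  # (E, C, 4, 4)
        return eig, p

    def _up_pass(self, pmats, edge_index):
        """Post-order partials.  Returns (partials, scales, contribs)."""
        C = pmats.shape[1]
        partial: list = [None] * self.tree.n_nodes
        scale = np.zeros((self.tree.n_nodes, self.npat))
        contrib: list = [None] * self.tree.n_nodes
        for v in range(self.tree.ntips):
            partial[v] = np.broadcast_to(self._tip_partial[v], (C, 4, self.npat))
        for u in self.data.post_internal:
            acc = None
            sc = np.zeros(self.npat)
            for v in self.tree.children[u]:
                pv = pmats[edge_index[v]]
                cont = np.einsum("cij,cjp->cip", pv, partial[v])
                contrib[v] = cont
                sc += scale[v]
                acc = cont if acc is None else acc * cont
            m = acc.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            partial[u] = acc / m
            scale[u] = sc + np.log(m)
            # contribs keep their own (child) scale; record for down pass
        return partial, scale, contrib

    def _root_site_likelihood(self, params, partial, scale):
        pi = params.base_freqs
        root = self.data.root
        lik = np.einsum("i,cip->p", pi, partial[root]) / partial[root].shape[0]
        return lik, scale[root]

    def _combine_invariant(self, params, lik_scaled, logscale):
        """Per-pattern log-likelihood including the invariable-site class."""
        with np.errstate(divide="ignore"):
            log_var = np.log(lik_scaled) + logscale
        if self.spec.has_inv and params.p_inv > 0:
            pinv = params.p_inv
            const_pi = np.where(
                self.const_state >= 0,
                params.base_freqs[np.clip(self.const_state, 0, 3)], 0.0)
            with np.errstate(divide="ignore"):
                log_inv = np.log(pinv * const_pi)
            return np.logaddexp(log_inv, np.log1p(-pinv) + log_var)
        return log_var

    def loglike(self, params: ModelParameters,
                branch_lengths: np.ndarray | None = None) -> float:
        """Log-likelihood of the alignment under ``params`` (Felsenstein pruning)."""
        params = constrain_parameters(params, self.spec)
        if branch_lengths is None:
            branch_lengths = self.tree.branch_lengths()
        rates = self._site_rates(params)
        edge_index = {int(v): k for k, v in enumerate(self.data.edge_nodes)}
        _, pmats = self._edge_matrices(params, np.asarray(branch_lengths), rates)
        partial, scale, _ = self._up_pass(pmats, edge_index)
        lik, logscale = self._root_site_likelihood(params, partial, scale)
        logl = self._combine_invariant(params, lik, logscale)
        return float(np.dot(self.weights, logl))

    # -- parameter packing -------------------------------------------------

    def _free_structure(self):
        spec = self.spec
        classes = np.asarray(spec.rate_classes)
        ref = classes[5]
        free_classes = [c for c in sorted(set(classes)) if c != ref]
        return classes, ref, free_classes

    def _pack(self, params: ModelParameters) -> np.ndarray:
        spec = self.spec
        classes, ref, free_classes = self._free_structure()
        x = []
        if not spec.equal_freqs:
            pi = np.clip(params.base_freqs, 1e-8, None)
            x.extend(np.log(pi[:3] / pi[3]))
        for c in free_classes:
            val = params.exchangeabilities[classes == c].mean()
            x.append(np.log(np.clip(val, *_RATE_BOUNDS)))
        if spec.has_gamma:
            a = params.gamma_shape if params.gamma_shape else 0.5
            x.append(np.log(np.clip(a, *_ALPHA_BOUNDS)))
        if spec.has_inv:
            p = min(max(params.p_inv, 1e-6), _PINV_MAX - 1e-6) / _PINV_MAX
            x.append(np.log(p / (1.0 - p)))
        return np.array(x)

    def _unpack(self, x: np.ndarray) -> ModelParameters:
        spec = self.spec
        classes, ref, free_classes = self._free_structure()
        k = 0
        if spec.equal_freqs:
            freqs = np.full(4, 0.25)
        else:
            z = np.concatenate([x[:3], [0.0]])
            z = np.exp(z - z.max())
            freqs = z / z.sum()
            k = 3
        ex = np.ones(6)
        for c in free_classes:
            ex[classes == c] = np.exp(x[k])
            k += 1
        alpha = None
        if spec.has_gamma:
            alpha = float(np.exp(x[k]))
            k += 1
        pinv = 0.0
        if spec.has_inv:
            pinv = _PINV_MAX / (1.0 + np.exp(-x[k]))
            k += 1
        return ModelParameters(freqs, ex, alpha, pinv, self.ncat)

    def _bounds(self):
        spec = self.spec
        _, _, free_classes = self._free_structure()
        b = []
        if not spec.equal_freqs:
            b.extend([(-12.0, 12.0)] * 3)
        b.extend([tuple(np.log(_RATE_BOUNDS))] * len(free_classes))
        if spec.has_gamma:
            b.append(tuple(np.log(_ALPHA_BOUNDS)))
        if spec.has_inv:
            b.append((-12.0, 12.0))
        return b

    def start_params(self) -> ModelParameters:
        """Data-informed starting values (empirical frequencies, kappa = 4)."""
        counts = np.bincount(self.alignment.codes.ravel(), minlength=4)
        freqs = counts / counts.sum()
        ex = np.ones(6)
        ex[1] = ex[4] = 4.0  # transitions usually exceed transversions
        return constrain_parameters(
            ModelParameters(freqs if not self.spec.equal_freqs else np.full(4, 0.25),
                            ex, 0.5 if self.spec.has_gamma else None,
                            0.1 if self.spec.has_inv else 0.0, self.ncat),
            self.spec)

    # -- branch-length optimisation ----------------------------------------

    def _down_pass(self, pmats, edge_index, partial, scale, contrib):
        """Outside partials G[v] for every non-root node."""
        tree = self.tree
        C = pmats.shape[1]
        G: list = [None] * tree.n_nodes
        gscale = np.zeros((tree.n_nodes, self.npat))
        pi = None
        for v in self.data.pre_nodes:
            u = tree.parent[v]
            sibs = [w for w in tree.children[u] if w != v]
            acc = None
            sc = np.zeros(self.npat)
            for w in sibs:
                acc = contrib[w] if acc is None else acc * contrib[w]
                sc += scale[w]
            if u == self.data.root:
                base = acc
            else:
                pu = pmats[edge_index[u]]
                down = np.einsum("cik,cip->ckp", pu, G[u])
                base = down * acc if acc is not None else down
                sc += gscale[u]
            if u == self.data.root:
                base = base * self._pi_cache[None, :, None]
            m = base.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            G[v] = base / m
            gscale[v] = sc + np.log(m)
        return G, gscale

    def _optimize_branches(self, params: ModelParameters,
                           branch_lengths: np.ndarray,
                           sweeps: int = 2) -> tuple[np.ndarray, float]:
        """Coordinate-ascent sweeps over edges using cached outside partials.

        Within a sweep the outside partials are held fixed (recomputed at the
        start of each sweep); a sweep that fails to improve the exact
        log-likelihood is rolled back.
        """
        params = constrain_parameters(params, self.spec)
        rates = self._site_rates(params)
        edge_nodes = self.data.edge_nodes
        edge_index = {int(v): k for k, v in enumerate(edge_nodes)}
        self._pi_cache = params.base_freqs
        bl = np.asarray(branch_lengths, dtype=float).copy()
        best = self.loglike(params, bl)
        C = len(rates)
        wcat = 1.0 / C
        for _ in range(sweeps):
            eig, pmats = self._edge_matrices(params, bl, rates)
            partial, scale, contrib = self._up_pass(pmats, edge_index)
            G, gscale = self._down_pass(pmats, edge_index, partial, scale, contrib)
            new_bl = bl.copy()
            for k, v in enumerate(edge_nodes):
                gv, upv = G[v], partial[v]
                logoff = gscale[v] + scale[v]
                pre = np.einsum("cip,cjp->cijp", gv, upv)

                def neg(t):
                    pm = transition_matrices(*eig, t * rates)
                    lik = wcat * np.einsum("cijp,cij->p", pre, pm)
                    logl = self._combine_invariant(params, lik, logoff)
                    return -float(np.dot(self.weights, logl))

                res = minimize_scalar(
                    neg, bounds=_BRANCH_BOUNDS, method="bounded",
                    options={"xatol": 1e-7, "maxiter": 40})
                new_bl[k] = res.x
            cand = self.loglike(params, new_bl)
            if cand >= best - 1e-9:
                bl, best = new_bl, max(cand, best)
            else:
                break
        return bl, best

    # -- fitting -----------------------------------------------------------

    def fit(self, start_params: ModelParameters | None = None,
            start_branch_lengths: np.ndarray | None = None,
            tol: float = 1e-6, max_outer: int = 8,
            optimize_branch_lengths: bool = True,
            maxiter: int = 60) -> "SubstitutionModelResults":
        """Jointly optimise free model parameters and branch lengths.

        Alternates bounded quasi-Newton updates of the transformed model
        parameters with coordinate-ascent sweeps over branch lengths, until
        the log-likelihood improves by less than ``tol`` between outer
        iterations.
        """
        params = constrain_parameters(
            start_params if start_params is not None else self.start_params(),
            self.spec)
        if start_branch_lengths is None:
            bl = np.maximum(self.tree.branch_lengths(), 1e-6)
        else:
            bl = np.maximum(np.asarray(start_branch_lengths, float), 1e-8).copy()
        nfree = len(self._pack(params))
        best = self.loglike(params, bl)
        converged = False
        for _ in range(max_outer):
            prev = best
            if optimize_branch_lengths:
                bl, best = self._optimize_branches(params, bl)
            if nfree:
                x0 = self._pack(params)

                def neg(x):
                    return -self.loglike(self._unpack(x), bl)

                res = minimize(neg, x0, method="L-BFGS-B",
                               bounds=self._bounds(),
                               options={"maxiter": maxiter, "ftol": 1e-10})
                if -res.fun > best:
                    params = constrain_parameters(self._unpack(res.x), self.spec)
                    best = -res.fun
            if best - prev < tol:
                converged = True
                break
        return SubstitutionModelResults(
            model=self, spec=self.spec, lnL=best, params=params,
            branch_lengths=bl, n_sites=self.n_sites, converged=converged)


@dataclass
class SubstitutionModelResults:
    """Optimised fit of one model on one dataset (a ModelFit)."""

    model: SubstitutionModel
    spec: ModelSpec
    lnL: float
    params: ModelParameters
    branch_lengths: np.ndarray
    n_sites: int
    converged: bool

    @property
    def K(self) -> int:
        return self.spec.free_params

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec.name}",
            f"lnL: {self.lnL:.4f}   K: {self.K}   sites: {self.n_sites}   "
            f"converged: {self.converged}",
            "base frequencies: " + "  ".join(
                f"{x:.4f}" for x in self.params.base_freqs),
            "exchangeabilities (AC AG AT CG CT GT): " + "  ".join(
                f"{x:.4f}" for x in self.params.exchangeabilities),
        ]
        if self.spec.has_gamma:
            lines.append(f"gamma shape (alpha): {self.params.gamma_shape:.4f}")
        if self.spec.has_inv:
            lines.append(f"prop. invariable sites: {self.params.p_inv:.4f}")
        lines.append(f"tree length: {self.branch_lengths.sum():.4f}")
        return "\n".join(lines)


def log_likelihood(alignment: Alignment, tree: PhyloTree, spec: ModelSpec,
                   params: ModelParameters) -> float:
    """Convenience wrapper: pruning log-likelihood without any optimisation."""
    return SubstitutionModel(alignment, tree, spec).loglike(params)


def fit_model(alignment: Alignment, topology: PhyloTree, spec: ModelSpec,
              **fit_kwargs) -> SubstitutionModelResults:
    """Fit one candidate model on the dataset's fixed (NJ) topology."""
    return SubstitutionModel(alignment, topology, spec).fit(**fit_kwargs)


def fit_all_candidates(alignment: Alignment, topology: PhyloTree,
                       candidates: list[ModelSpec] | None = None,
                       tol: float = 1e-3, max_outer: int = 6,
                       maxiter: int = 40) -> dict[str, SubstitutionModelResults]:
    """Fit the full candidate set, warm-starting each model from a nested parent.

    Models are fitted simple-to-complex; each inherits its parent's optimised
    branch lengths and (where meaningful) exchangeabilities/frequencies,
    which both speeds up and stabilises the optimisation.
    """
    if candidates is None:
        candidates = candidate_models()
    fits: dict[str, SubstitutionModelResults] = {}
    specs = {s.name: s for s in candidates}

    def _convert(src: SubstitutionModelResults, spec: ModelSpec) -> ModelParameters:
        # a nested model's parameters are valid under the larger model; new
        # flags start near their null values so the start log-likelihood is
        # (almost) the parent's optimum
        p = src.params.copy()
        if spec.has_gamma and p.gamma_shape is None:
            p.gamma_shape = 1e5
        if spec.has_inv and p.p_inv == 0.0:
            p.p_inv = 1e-3
        return p

    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].free_params,
                                  candidates[i].name))
    for i in order:
        spec = candidates[i]
        model = SubstitutionModel(alignment, topology, spec)
        # warm start: best already-fitted model nested within this one
        best_start, best_bl, best_val = None, None, -np.inf
        parents = [f for name, f in fits.items()
                   if is_nested(specs[name], spec)]
        parents.sort(key=lambda f: -f.lnL)
        for src in parents[:3]:
            p = _convert(src, spec)
            val = model.loglike(p, src.branch_lengths)
            if val > best_val:
                best_start, best_bl, best_val = p, src.branch_lengths, val
        fit = model.fit(
            start_params=best_start, start_branch_lengths=best_bl,
            tol=tol, max_outer=max_outer, maxiter=maxiter)
        # boundary fallback: when a nested model fits better (its extra
        # parameters want their null values), adopt its solution at the
        # boundary of the larger model's parameter space
        for src in parents:
            if src.lnL <= fit.lnL:
                continue
            p = src.params.copy()
            if spec.has_gamma and p.gamma_shape is None:
                p.gamma_shape = _ALPHA_BOUNDS[1]
            if spec.has_inv and p.p_inv == 0.0:
                p.p_inv = 0.0
            val = model.loglike(p, src.branch_lengths)
            if val > fit.lnL:
                fit = SubstitutionModelResults(
                    model=model, spec=spec, lnL=val, params=p,
                    branch_lengths=np.asarray(src.branch_lengths, float).copy(),
                    n_sites=model.n_sites, converged=src.converged)
        fits[spec.name] = fit
    return fits
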