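"""Alignment simulation along a tree under GTR-family and GY94 codon models.

Sites evolve independently under a stationary, time-reversible, homogeneous
Markov process.  Root states are drawn from the stationary distribution;
states propagate tipward with transition matrices P(t r) = expm(Q t r),
where r is the per-site rate multiplier.  Rate heterogeneity follows the
standard discrete-gamma scheme (equiprobable categories, each category rate
the mean of its quantile interval, overall mean one); invariable sites have
rate zero and therefore show the single root-drawn state at every tip.

Note the Seq-Gen convention for +I+G: variable sites keep mean rate one, so
the realised number of substitutions per unit branch length is (1 - p_inv).
The likelihood engine uses the same convention, so inference and simulation
are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .models import (
    NUCLEOTIDES,
    ModelParameters,
    ModelSpec,
    build_rate_matrix,
    constrain_parameters,
    rate_matrix_eigen,
    transition_matrices,
)
from .treesim import PhyloTree

__all__ = [
    "Alignment",
    "gamma_category_rates",
    "draw_site_rates",
    "simulate_alignment",
    "CodonSimConfig",
    "build_gy94_rate_matrix",
    "simulate_codon_alignment",
]


@dataclass
class Alignment:
    """Nucleotide alignment as an (ntaxa, nsites) int8 matrix (A,C,G,T = 0..3)."""

    taxa: list[str]
    codes: np.ndarray
    site_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (ntaxa, nsites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def ntaxa(self) -> int:
        return self.codes.shape[0]

    @property
    def nsites(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> dict[str, str]:
        lut = np.array(list(NUCLEOTIDES))
        return {t: "".join(lut[row]) for t, row in zip(self.taxa, self.codes)}

    # -- I/O ---------------------------------------------------------------

    def to_fasta(self, path_or_handle) -> None:
        records = [SeqRecord(Seq(s), id=t, description="")
                   for t, s in self.sequences().items()]
        SeqIO.write(records, path_or_handle, "fasta")

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(path_or_handle, "fasta"):
            taxa.append(rec.id)
            rows.append(_encode(str(rec.seq)))
        return cls(taxa, np.vstack(rows))

    def to_phylip(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write(f" {self.ntaxa} {self.nsites}\n")
            for t, s in self.sequences().items():
                handle.write(f"{t:<10s}{s}\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_phylip(cls, handle) -> "Alignment":
        close = False
        if isinstance(handle, str):
            handle, close = open(handle), True
        try:
            header = handle.readline().split()
            ntaxa, nsites = int(header[0]), int(header[1])
            taxa, rows = [], []
            for _ in range(ntaxa):
                line = handle.readline().rstrip("\n")
                taxa.append(line[:10].strip())
                rows.append(_encode(line[10:].strip()))
        finally:
            if close:
                handle.close()
        codes = np.vstack(rows)
        if codes.shape != (ntaxa, nsites):
            raise ValueError("malformed relaxed PHYLIP input")
        return cls(taxa, codes)


_ENC = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(arr < 0):
        raise ValueError("non-ACGT character in sequence")
    return arr


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Discrete-gamma category rates (mean of each quantile interval).

    The gamma has shape ``alpha`` and mean one; categories are equiprobable,
    so the rates average exactly to one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    from scipy.stats import gamma as _gamma
    edges = _gamma.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X in (a,b)] = I(alpha+1, b*alpha) - I(alpha+1, a*alpha) for mean-1 gamma
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    upper[-1] = 1.0
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return ncat * (upper - lower)


def draw_site_rates(spec: ModelSpec, params: ModelParameters, length: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-site rate multipliers under the model's +I/+G structure."""
    rates = np.ones(length)
    if spec.has_gamma:
        cat_rates = gamma_category_rates(params.gamma_shape, params.ncat)
        rates = cat_rates[rng.integers(0, params.ncat, size=length)]
    if spec.has_inv:
        rates[rng.random(length) < params.p_inv] = 0.0
    return rates


def _evolve(tree: PhyloTree, root_states: np.ndarray, site_rates: np.ndarray,
            evals, right, left, rng: np.random.Generator) -> np.ndarray:
    """Propagate states from the root to the tips, vectorised per rate class."""
    nsites = len(root_states)
    states = np.empty((tree.n_nodes, nsites), dtype=np.int8)
    states[tree.root] = root_states
    uniq, inverse = np.unique(site_rates, return_inverse=True)
    groups = [np.flatnonzero(inverse == k) for k in range(len(uniq))]
    for v in reversed(tree.postorder):  # preorder
        if v == tree.root:
            continue
        t = tree.edge_length[v]
        parent_states = states[tree.parent[v]]
        child = np.empty(nsites, dtype=np.int8)
        for r, idx in zip(uniq, groups):
            if len(idx) == 0:
                continue
            if r == 0.0 or t * r == 0.0:
                child[idx] = parent_states[idx]
                continue
            p = transition_matrices(evals, right, left, np.array([t * r]))[0]
            cum = np.cumsum(p, axis=1)
            u = rng.random(len(idx))
            child[idx] = np.argmax(
                u[:, None] < cum[parent_states[idx]], axis=1)
        states[v] = child
    return states[: tree.ntips]


def simulate_alignment(tree: PhyloTree, spec: ModelSpec,
                       params: ModelParameters, length: int,
                       seed: int = 0) -> Alignment:
    """Simulate a nucleotide alignment of ``length`` sites along ``tree``."""
    if length <= 0:
        raise ValueError("length must be positive")
    params = constrain_parameters(params, spec)
    if spec.has_gamma and params.gamma_shape is None:
        raise ValueError("gamma model requires gamma_shape")
    rng = np.random.default_rng(seed)
    q = build_rate_matrix(params)
    evals, right, left = rate_matrix_eigen(q, params.base_freqs)
    site_rates = draw_site_rates(spec, params, length, rng)
    root_states = rng.choice(4, size=length, p=params.base_freqs).astype(np.int8)
    codes = _evolve(tree, root_states, site_rates, evals, right, left, rng)
    return Alignment(list(tree.taxa), codes, site_rates=site_rates)


# ---------------------------------------------------------------------------
# GY94 codon model
# ---------------------------------------------------------------------------

_STANDARD_TABLE = unambiguous_dna_by_id[1]


def _sense_codons() -> list[str]:
    stops = set(_STANDARD_TABLE.stop_codons)
    return [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES
            for c in NUCLEOTIDES if a + b + c not in stops]


SENSE_CODONS = _sense_codons()
_AA = {c: _STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS}


@dataclass
class CodonSimConfig:
    """Settings for GY94 codon simulation.

    ``omega`` is the nonsynonymous/synonymous rate ratio (constant across
    sites); ``nucleotide_params`` supplies the single-nucleotide
    exchangeabilities and the position-independent base frequencies (1x4);
    ``mutation_rate`` scales the guide tree's branch lengths.  ``spec``
    carries the +I/+G structure of the crossed GTR-family model, acting as
    site-rate multipliers on codon sites.
    """

    omega: float
    nucleotide_params: ModelParameters
    length_nt: int = 999
    mutation_rate: float = 1.0
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.length_nt % 3 != 0:
            raise ValueError("length_nt must be divisible by 3")


def build_gy94_rate_matrix(config: CodonSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Normalised 61x61 GY94 generator and the codon stationary frequencies.

    Codon pairs differing at more than one position have rate zero; a single
    difference contributes (target codon frequency) x (nucleotide
    exchangeability of the changed base pair), times omega when the change is
    nonsynonymous under the universal genetic code.
    """
    params = config.nucleotide_params
    pi_nt = params.base_freqs
    ex = params.exchangeabilities
    pair_idx = {}
    from .models import PAIR_ORDER
    for k, pair in enumerate(PAIR_ORDER):
        i, j = NUCLEOTIDES.index(pair[0]), NUCLEOTIDES.index(pair[1])
        pair_idx[(i, j)] = pair_idx[(j, i)] = k
    codons = SENSE_CODONS
    n = len(codons)
    enc = [np.array([NUCLEOTIDES.index(c) for c in cod]) for cod in codons]
    pi = np.array([pi_nt[e].prod() for e in enc])
    pi = pi / pi.sum()
    q = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            diff = np.flatnonzero(enc[a] != enc[b])
            if len(diff) != 1:
                continue
            pos = diff[0]
            rate = ex[pair_idx[(enc[a][pos], enc[b][pos])]] * pi[b]
            if _AA[codons[a]] != _AA[codons[b]]:
                rate *= config.omega
            q[a, b] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu, pi


def simulate_codon_alignment(tree: PhyloTree, config: CodonSimConfig,
                             seed: int = 0) -> Alignment:
    """Simulate a codon alignment and return it as nucleotide characters.

    Branch lengths are ``mutation_rate`` times the guide tree's, in expected
    codon substitutions per codon site.  No stop codons ever appear.
    """
    ncodons = config.length_nt // 3
    rng = np.random.default_rng(seed)
    q, pi = build_gy94_rate_matrix(config)
    evals, right, left = rate_matrix_eigen(q, pi)
    spec = config.spec or ModelSpec("GTR")
    site_rates = draw_site_rates(spec, config.nucleotide_params, ncodons, rng)
    work = tree.copy()
    work.edge_length = work.edge_length * config.mutation_rate
    root_states = rng.choice(len(pi), size=ncodons, p=pi).astype(np.int16)
    # _evolve assumes int8 alphabets; replicate its loop for the 61-state case
    states = np.empty((work.n_nodes, ncodons), dtype=np.int16)
    states[work.root] = root_states
    uniq, inverse = np.unique(site_rates, return_inverse=True)
    groups = [np.flatnonzero(inverse == k) for k in range(len(uniq))]
    for v in reversed(work.postorder):
        if v == work.root:
            continue
        t = work.edge_length[v]
        parent_states = states[work.parent[v]]
        child = np.empty(ncodons, dtype=np.int16)
        for r, idx in zip(uniq, groups):
            if len(idx) == 0:
                continue
            if t * r == 0.0:
                child[idx] = parent_states[idx]
                continue
            p = transition_matrices(evals, right, left, np.array([t * r]))[0]
            cum = np.cumsum(p, axis=1)
            u = rng.random(len(idx))
            child[idx] = np.argmax(u[:, None] < cum[parent_states[idx]], axis=1)
        states[v] = child
    tip_states = states[: work.ntips]
    codon_codes = np.array(
        [[NUCLEOTIDES.index(c) for c in cod] for cod in SENSE_CODONS],
        dtype=np.int8)
    codes = codon_codes[tip_states].reshape(work.ntips, config.length_nt)
    return Alignment(list(tree.taxa), codes,
                     site_rates=np.repeat(site_rates, 3))
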