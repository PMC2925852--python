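"""GTR model family: specifications, parameters, and rate-matrix construction.

The general time-reversible (GTR) model assigns each unordered nucleotide pair
an exchangeability and each nucleotide a stationary frequency.  Named
sub-models of the family constrain the six exchangeabilities into equality
classes and/or force equal base frequencies.  Two standard extensions are
supported: a proportion of invariable sites (+I) and discrete-gamma rate
heterogeneity among sites (+G).

The candidate set used throughout the package is the standard 56-model set
(14 base models x {none, +I, +G, +I+G}), i.e. the "7 substitution schemes,
with and without equal frequencies" convention of ModelTest/jModelTest.  The
24-model generating set restricts the base models to JC, F81, K80, HKY, SYM
and GTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "PAIR_ORDER",
    "BASE_MODELS",
    "ModelSpec",
    "ModelParameters",
    "candidate_models",
    "generating_models",
    "build_rate_matrix",
    "free_parameters",
    "model_category",
    "parse_model_name",
]

NUCLEOTIDES = "ACGT"

#: order of the six unordered nucleotide pairs used for exchangeabilities
PAIR_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

# Exchangeability equality classes per base model, one integer label per pair
# in PAIR_ORDER.  The class containing GT is the reference class (rate 1), so
# the number of free rate parameters is (number of classes) - 1.
_RATE_CLASSES = {
    "JC": (0, 0, 0, 0, 0, 0),
    "K80": (0, 1, 0, 0, 1, 0),      # transitions AG=CT vs transversions
    "TrNef": (0, 1, 0, 0, 2, 0),    # AG != CT
    "K81": (0, 1, 2, 2, 1, 0),      # AC=GT, AT=CG, AG=CT
    "TIMef": (0, 1, 2, 2, 3, 0),
    "TVMef": (1, 2, 3, 4, 2, 0),    # AG=CT, transversions free
    "SYM": (1, 2, 3, 4, 5, 0),
}

# base model name -> (equal_freqs, rate-class key)
_BASE_DEF = {
    "JC": (True, "JC"),
    "F81": (False, "JC"),
    "K80": (True, "K80"),
    "HKY": (False, "K80"),
    "TrNef": (True, "TrNef"),
    "TrN": (False, "TrNef"),
    "K81": (True, "K81"),
    "K81uf": (False, "K81"),
    "TIMef": (True, "TIMef"),
    "TIM": (False, "TIMef"),
    "TVMef": (True, "TVMef"),
    "TVM": (False, "TVMef"),
    "SYM": (True, "SYM"),
    "GTR": (False, "SYM"),
}

BASE_MODELS = tuple(_BASE_DEF)

#: base models used to generate data in the simulation study
GENERATING_BASES = ("JC", "F81", "K80", "HKY", "SYM", "GTR")


def _base_free_params(base: str) -> int:
    equal_freqs, key = _BASE_DEF[base]
    n_classes = len(set(_RATE_CLASSES[key]))
    return (n_classes - 1) + (0 if equal_freqs else 3)


@dataclass(frozen=True)
class ModelSpec:
    """A named member of the GTR family, e.g. ``HKY+I+G``."""

    base: str
    has_inv: bool = False
    has_gamma: bool = False

    def __post_init__(self) -> None:
        if self.base not in _BASE_DEF:
            raise KeyError(f"unknown base model: {self.base!r}")

    @property
    def name(self) -> str:
        suffix = ("+I" if self.has_inv else "") + ("+G" if self.has_gamma else "")
        return self.base + suffix

    @property
    def equal_freqs(self) -> bool:
        return _BASE_DEF[self.base][0]

    @property
    def rate_classes(self) -> tuple[int, ...]:
        return _RATE_CLASSES[_BASE_DEF[self.base][1]]

    @property
    def n_rate_params(self) -> int:
        return len(set(self.rate_classes)) - 1

    @property
    def free_params(self) -> int:
        return _base_free_params(self.base) + int(self.has_inv) + int(self.has_gamma)

    @property
    def category(self) -> str:
        return model_category(self)

    def drop_flags(self) -> "ModelSpec":
        return ModelSpec(self.base)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def parse_model_name(name: str) -> ModelSpec:
    """Parse a plain-text model name such as ``"GTR+I+G"``."""
    parts = name.split("+")
    base = parts[0]
    flags = set(parts[1:])
    bad = flags - {"I", "G"}
    if bad:
        raise KeyError(f"unknown model suffix {sorted(bad)} in {name!r}")
    return ModelSpec(base, has_inv="I" in flags, has_gamma="G" in flags)


def model_category(spec: ModelSpec) -> str:
    """Classify a model by its rate-heterogeneity extensions."""
    return {
        (False, False): "base",
        (True, False): "base+I",
        (False, True): "base+G",
        (True, True): "base+I+G",
    }[(spec.has_inv, spec.has_gamma)]


def free_parameters(spec: ModelSpec | str) -> int:
    """Number of free substitution-model parameters (0-10 over the family)."""
    if isinstance(spec, str):
        spec = parse_model_name(spec)
    return spec.free_params


_FLAG_COMBOS = ((False, False), (True, False), (False, True), (True, True))


def candidate_models() -> list[ModelSpec]:
    """The 56-model candidate set (14 bases x 4 extension combinations)."""
    return [ModelSpec(b, i, g) for b in BASE_MODELS for (i, g) in _FLAG_COMBOS]


def generating_models() -> list[ModelSpec]:
    """The 24 models used to generate data (6 bases x 4 combinations)."""
    return [ModelSpec(b, i, g) for b in GENERATING_BASES for (i, g) in _FLAG_COMBOS]


def is_nested(inner: ModelSpec, outer: ModelSpec) -> bool:
    """True when ``inner`` is a special case of ``outer``.

    Requires: inner's flags are a subset of outer's, inner's frequencies are
    not freer than outer's, and outer's exchangeability partition refines
    inner's.
    """
    if inner == outer:
        return False
    if inner.has_inv and not outer.has_inv:
        return False
    if inner.has_gamma and not outer.has_gamma:
        return False
    if not inner.equal_freqs and outer.equal_freqs:
        return False
    mapped: dict[int, set[int]] = {}
    for a, b in zip(outer.rate_classes, inner.rate_classes):
        mapped.setdefault(a, set()).add(b)
    if any(len(v) > 1 for v in mapped.values()):
        return False
    return inner.free_params < outer.free_params


@dataclass
class ModelParameters:
    """Numerical parameter values for a GTR-family model.

    Exchangeabilities follow :data:`PAIR_ORDER` and are relative to GT = 1.
    ``gamma_shape`` is the shape of the mean-one gamma distribution of
    among-site rates (approximated by ``ncat`` equiprobable discrete
    categories); ``p_inv`` is the proportion of invariable (rate-zero) sites.
    """

    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    gamma_shape: float | None = None
    p_inv: float = 0.0
    ncat: int = 4

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.base_freqs.shape != (4,):
            raise ValueError("base_freqs must have length 4")
        if self.exchangeabilities.shape != (6,):
            raise ValueError("exchangeabilities must have length 6")
        if np.any(self.base_freqs < 0) or np.any(self.exchangeabilities < 0):
            raise ValueError("negative rate or frequency")
        if abs(self.base_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.base_freqs.copy(), self.exchangeabilities.copy(),
            self.gamma_shape, self.p_inv, self.ncat)

    @classmethod
    def from_kappa(cls, kappa: float, base_freqs=None, **kw) -> "ModelParameters":
        """K80/HKY-style parameterisation: transitions get rate kappa."""
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        if base_freqs is None:
            base_freqs = np.full(4, 0.25)
        return cls(base_freqs=base_freqs, exchangeabilities=ex, **kw)

    @property
    def kappa(self) -> float:
        """Transition/transversion exchangeability ratio implied by the rates."""
        ex = self.exchangeabilities
        ti = (ex[1] + ex[4]) / 2.0
        tv = (ex[0] + ex[2] + ex[3] + ex[5]) / 4.0
        return ti / tv


def constrain_parameters(params: ModelParameters, spec: ModelSpec) -> ModelParameters:
    """Pin parameters that are not free under ``spec`` to their null values."""
    out = params.copy()
    if spec.equal_freqs:
        out.base_freqs = np.full(4, 0.25)
    classes = np.asarray(spec.rate_classes)
    ex = np.empty(6)
    for c in np.unique(classes):
        ex[classes == c] = out.exchangeabilities[classes == c].mean()
    ex = ex / ex[5]  # GT = 1
    out.exchangeabilities = ex
    if not spec.has_inv:
        out.p_inv = 0.0
    if not spec.has_gamma:
        out.gamma_shape = None
    return out


def build_rate_matrix(params: ModelParameters,
                      spec: ModelSpec | None = None) -> np.ndarray:
    """Build the normalised 4x4 instantaneous rate matrix Q.

    Q_ij = s_ij * pi_j for i != j (s the symmetric exchangeabilities), rows
    sum to zero, and Q is scaled so that -sum_i pi_i Q_ii = 1, i.e. branch
    lengths are expected substitutions per site.  If ``spec`` is given the
    parameters are first constrained to the model's equality classes.
    """
    if spec is not None:
        params = constrain_parameters(params, spec)
    pi = params.base_freqs
    s = np.zeros((4, 4))
    for k, pair in enumerate(PAIR_ORDER):
        i, j = NUCLEOTIDES.index(pair[0]), NUCLEOTIDES.index(pair[1])
        s[i, j] = s[j, i] = params.exchangeabilities[k]
    q = s * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / mu


def rate_matrix_eigen(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible Q via its symmetrised form.

    Returns ``(evals, right, left)`` with ``expm(Q t) = right @ diag(exp(evals t)) @ left``.
    """
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = (b + b.T) / 2.0  # enforce exact symmetry
    evals, u = np.linalg.eigh(b)
    right = u / d[:, None]
    left = u.T * d[None, :]
    return evals, right, left


def transition_matrices(evals, right, left, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for a batch of branch lengths, shape (..., 4, 4)."""
    lengths = np.asarray(lengths, dtype=float)
    e = np.exp(lengths[..., None] * evals)  # (..., 4)
    p = np.einsum("ik,...k,kj->...ij", right, e, left)
    np.clip(p, 0.0, None, out=p)
    # renormalise away eigen round-off so rows are exact distributions
    p /= p.sum(axis=-1, keepdims=True)
    return p
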