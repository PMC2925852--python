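"""Best-fit model selection: hLRT, AIC/AICc, BIC, and decision theory (DT).

All four criteria operate on a table of maximum-likelihood fits of the 56
candidate models on one dataset (shared NJ topology).  The hierarchical
likelihood-ratio test walks a fixed staged hierarchy of nested pairwise
tests; AIC/AICc/BIC are penalised-likelihood argmins; DT minimises the
expected branch-length loss, weighting pairwise branch-length distances
between models by BIC-derived posterior weights (the DT-ModSel construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .models import ModelSpec, parse_model_name
from .phylo_engine import SubstitutionModelResults

__all__ = [
    "LRTResult",
    "SelectionResult",
    "lrt",
    "aic",
    "aicc",
    "bic",
    "bic_weights",
    "HlrtHierarchy",
    "DEFAULT_HLRT_HIERARCHY",
    "SYMMETRIC_HLRT_HIERARCHY",
    "hlrt_select",
    "information_criterion_select",
    "dt_select",
    "select_all",
    "CRITERIA",
]

CRITERIA = ("hLRT", "AIC", "BIC", "DT")


@dataclass
class LRTResult:
    """One pairwise likelihood-ratio test between nested models."""

    null: str
    alternative: str
    delta: float
    raw_delta: float
    df: int
    mixed: bool
    p_value: float
    rejected: bool


def lrt(lnL0: float, lnL1: float, df: int, mixed: bool = False,
        null: str = "", alternative: str = "", alpha: float | None = None) -> LRTResult:
    """Likelihood-ratio test of a simple (null) vs a complex model.

    delta = 2(lnL1 - lnL0) is referred to a chi-square with ``df`` degrees of
    freedom, or — for boundary hypotheses such as adding +I or +G — to the
    mixed distribution 0.5*chi2_0 + 0.5*chi2_1, whose tail is half the chi2_1
    tail (and 1 at delta <= 0).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    raw = 2.0 * (lnL1 - lnL0)
    delta = max(raw, 0.0)  # clamp numerical noise; raw value retained
    if mixed:
        p = 1.0 if delta <= 0 else 0.5 * float(chi2.sf(delta, 1))
    else:
        p = float(chi2.sf(delta, df))
    rejected = alpha is not None and p < alpha
    return LRTResult(null, alternative, delta, raw, df, mixed, p, rejected)


def aic(lnL: float, K: int) -> float:
    return -2.0 * lnL + 2.0 * K


def aicc(lnL: float, K: int, n: int) -> float:
    if n <= K + 1:
        raise ValueError("AICc requires n > K + 1")
    return -2.0 * lnL + 2.0 * K * n / (n - K - 1.0)


def bic(lnL: float, K: int, n: int) -> float:
    return -2.0 * lnL + K * np.log(n)


@dataclass
class SelectionResult:
    """Chosen best-fit model for one dataset under one criterion."""

    criterion: str
    chosen: ModelSpec
    scores: dict[str, float] = field(default_factory=dict)
    trace: list[LRTResult] = field(default_factory=list)
    dataset_id: str = ""
    tie: bool = False


def _argmin_with_ties(scores: dict[str, float], atol: float = 1e-9):
    """Smallest score; ties broken by fewer free parameters, then name."""
    best = min(scores.values())
    tied = [name for name, s in scores.items() if s <= best + atol]
    tied.sort(key=lambda nm: (parse_model_name(nm).free_params, nm))
    return tied[0], len(tied) > 1


# ---------------------------------------------------------------------------
# hLRT
# ---------------------------------------------------------------------------


@dataclass
class HlrtHierarchy:
    """A staged hierarchy of nested pairwise tests, expressed as data.

    ``base_stages`` is an ordered list of mappings {current base model:
    (alternative base model, df)}; a stage whose mapping does not contain the
    current base is skipped.  After the base model is settled, rate
    heterogeneity (+G) and then invariable sites (+I) are tested with the
    mixed boundary distribution (+I last, as in the ModelTest default).
    """

    base_stages: list[dict[str, tuple[str, int]]]
    flag_order: tuple[str, ...] = ("G", "I")

    def reachable_models(self) -> set[str]:
        """All terminal models this hierarchy can select."""
        bases = {"JC"}
        for stage in self.base_stages:
            for cur, (alt, _) in stage.items():
                if cur in bases:
                    bases.add(alt)
        out = set()
        for b in bases:
            for suffix in ("", "+I", "+G", "+I+G"):
                out.add(b + suffix)
        return out


#: Default hierarchy: frequencies, ti/tv, equal ti rates, then the
#: transversion-rate ladder on the unequal-frequency side only.  The
#: equal-frequency branch terminates its rate ladder at TrNef, so SYM-like
#: models are never selected (the structural behaviour reported for the
#: ModelTest default hierarchy).
DEFAULT_HLRT_HIERARCHY = HlrtHierarchy(base_stages=[
    {"JC": ("F81", 3)},                       # equal base frequencies?
    {"JC": ("K80", 1), "F81": ("HKY", 1)},    # ti = tv?
    {"K80": ("TrNef", 1), "HKY": ("TrN", 1)},  # equal transition rates?
    {"TrN": ("TIM", 1)},                      # two transversion classes?
    {"TIM": ("GTR", 2)},                      # all transversion rates free?
])

#: Alternative hierarchy whose equal-frequency branch continues to SYM;
#: provided for introspection of hierarchy dependence.
SYMMETRIC_HLRT_HIERARCHY = HlrtHierarchy(base_stages=[
    {"JC": ("F81", 3)},
    {"JC": ("K80", 1), "F81": ("HKY", 1)},
    {"K80": ("TrNef", 1), "HKY": ("TrN", 1)},
    {"TrNef": ("TIMef", 1), "TrN": ("TIM", 1)},
    {"TIMef": ("SYM", 2), "TIM": ("GTR", 2)},
])


def hlrt_select(fits: dict[str, SubstitutionModelResults], alpha: float = 0.01,
                hierarchy: HlrtHierarchy = DEFAULT_HLRT_HIERARCHY,
                dataset_id: str = "") -> SelectionResult:
    """Hierarchical LRT model selection at significance level ``alpha``.

    Walks the staged hierarchy from JC: each stage tests the current model
    against a more complex alternative and moves to the alternative when the
    test rejects (p < alpha).  +G and then +I are tested with the mixed
    boundary distribution.  Returns the terminal model with the full trace.
    """

    def lnl(name: str) -> float:
        if name not in fits:
            raise KeyError(f"missing fit for model {name} on the hLRT path")
        return fits[name].lnL

    trace: list[LRTResult] = []
    current = "JC"
    for stage in hierarchy.base_stages:
        if current not in stage:
            continue
        alt, df = stage[current]
        res = lrt(lnl(current), lnl(alt), df, mixed=False,
                  null=current, alternative=alt, alpha=alpha)
        trace.append(res)
        if res.rejected:
            current = alt
    suffix = ""
    for flag in hierarchy.flag_order:
        null_name = current + suffix
        alt_suffix = "+" + flag if suffix == "" else _merge_suffix(suffix, flag)
        alt_name = current + alt_suffix
        res = lrt(lnl(null_name), lnl(alt_name), 1, mixed=True,
                  null=null_name, alternative=alt_name, alpha=alpha)
        trace.append(res)
        if res.rejected:
            suffix = alt_suffix
    chosen = parse_model_name(current + suffix)
    return SelectionResult("hLRT", chosen, trace=trace, dataset_id=dataset_id)


def _merge_suffix(suffix: str, flag: str) -> str:
    flags = set(suffix.strip("+").split("+")) | {flag}
    return "".join("+" + f for f in ("I", "G") if f in flags)


# ---------------------------------------------------------------------------
# Information criteria and DT
# ---------------------------------------------------------------------------


def information_criterion_select(fits: dict[str, SubstitutionModelResults],
                                 criterion: str, n: int,
                                 dataset_id: str = "") -> SelectionResult:
    """argmin of AIC, AICc or BIC over the candidate set."""
    fun = {"AIC": lambda f: aic(f.lnL, f.K),
           "AICc": lambda f: aicc(f.lnL, f.K, n),
           "BIC": lambda f: bic(f.lnL, f.K, n)}[criterion]
    scores = {name: fun(f) for name, f in fits.items()}
    best, tie = _argmin_with_ties(scores)
    return SelectionResult(criterion, parse_model_name(best), scores=scores,
                           dataset_id=dataset_id, tie=tie)


def bic_weights(bic_scores: np.ndarray) -> np.ndarray:
    """Posterior model weights exp(-dBIC/2), normalised; shift-invariant."""
    d = bic_scores - bic_scores.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def dt_select(fits: dict[str, SubstitutionModelResults], n: int,
              dataset_id: str = "", norm: float = 2.0) -> SelectionResult:
    """Decision-theory selection (DT-ModSel).

    Risk of model i is R_i = sum_j ||B_i - B_j|| * w_j with B the models'
    branch-length vectors on the shared topology and w the BIC weights; the
    model with minimal risk is chosen.
    """
    names = sorted(fits)
    vecs = []
    for name in names:
        blv = fits[name].branch_lengths
        if blv is None:
            raise ValueError(f"missing branch-length vector for {name}")
        vecs.append(np.asarray(blv, dtype=float))
    B = np.vstack(vecs)
    scores = np.array([bic(fits[nm].lnL, fits[nm].K, n) for nm in names])
    w = bic_weights(scores)
    diff = B[:, None, :] - B[None, :, :]
    dist = np.linalg.norm(diff, ord=norm, axis=2)
    risk = dist @ w
    risk_map = dict(zip(names, risk))
    best, tie = _argmin_with_ties(risk_map, atol=1e-12)
    return SelectionResult("DT", parse_model_name(best), scores=risk_map,
                           dataset_id=dataset_id, tie=tie)


def select_all(fits: dict[str, SubstitutionModelResults], n: int,
               alpha: float = 0.01,
               hierarchy: HlrtHierarchy = DEFAULT_HLRT_HIERARCHY,
               dataset_id: str = "") -> dict[str, SelectionResult]:
    """Apply all four criteria to one dataset's fit table."""
    return {
        "hLRT": hlrt_select(fits, alpha=alpha, hierarchy=hierarchy,
                            dataset_id=dataset_id),
        "AIC": information_criterion_select(fits, "AIC", n, dataset_id),
        "BIC": information_criterion_select(fits, "BIC", n, dataset_id),
        "DT": dt_select(fits, n, dataset_id),
    }


# ---------------------------------------------------------------------------
# High-level model-selection object
# ---------------------------------------------------------------------------


class ModelSelection:
    """Model-selection analysis of one alignment (ModelTest-style workflow).

    Construct from an alignment; :meth:`fit` builds the NJ starting tree
    from Jukes-Cantor distances, fits every candidate model by maximum
    likelihood on that fixed topology, and applies all four criteria.
    """

    def __init__(self, alignment, candidates=None, ncat: int = 4,
                 alpha: float = 0.01,
                 hierarchy: HlrtHierarchy = DEFAULT_HLRT_HIERARCHY):
        from .models import candidate_models
        self.alignment = alignment
        self.candidates = candidates or candidate_models()
        self.ncat = ncat
        self.alpha = alpha
        self.hierarchy = hierarchy

    def fit(self, **fit_kwargs) -> "ModelSelectionResults":
        from .phylo_engine import fit_all_candidates, jc_distance_matrix, neighbor_joining
        topology = neighbor_joining(jc_distance_matrix(self.alignment))
        fits = fit_all_candidates(self.alignment, topology,
                                  candidates=self.candidates, **fit_kwargs)
        selections = select_all(fits, self.alignment.nsites,
                                alpha=self.alpha, hierarchy=self.hierarchy)
        return ModelSelectionResults(self, topology, fits, selections)


class ModelSelectionResults:
    """Fit table and criterion choices for one dataset."""

    def __init__(self, model: ModelSelection, topology, fits, selections):
        self.model = model
        self.topology = topology
        self.fits = fits
        self.selections = selections

    @property
    def chosen(self) -> dict[str, str]:
        return {c: r.chosen.name for c, r in self.selections.items()}

    def score_table(self):
        import pandas as pd
        n = self.model.alignment.nsites
        rows = []
        for name, f in sorted(self.fits.items()):
            rows.append({
                "model": name, "K": f.K, "lnL": f.lnL,
                "AIC": aic(f.lnL, f.K), "BIC": bic(f.lnL, f.K, n),
                "DT_risk": self.selections["DT"].scores.get(name, float("nan")),
                "converged": f.converged,
            })
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        tab = self.score_table()
        lines = [
            f"Model selection over {len(self.fits)} candidates "
            f"({self.model.alignment.ntaxa} taxa, "
            f"{self.model.alignment.nsites} sites)",
            "",
            "best-fit model per criterion:",
        ]
        for crit, name in self.chosen.items():
            lines.append(f"  {crit:>4s}: {name}")
        lines.append("")
        best = tab.sort_values("BIC").head(5)
        lines.append("top 5 models by BIC:")
        lines.append(best[["K", "lnL", "AIC", "BIC"]].to_string(
            float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)
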