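"""Performance statistics for the simulation study.

Given per-dataset model selections for each criterion, this module computes
the study's summary statistics:

* accuracy — percentage of replicates in which a criterion recovered the
  generating model;
* precision — number of distinct best-fit models a criterion selected across
  a replicate set (smaller = more precise);
* dissimilarity — percentage of datasets on which two criteria disagree,
  (N - m)/N x 100;
* agreement profile — how often the four criteria jointly selected 1, 2, 3
  or 4 distinct models;
* model-bias tables — composition of recovered models by category, compared
  between criteria with chi-square homogeneity tests (pairwise comparisons
  Bonferroni-corrected);
* randomized-block ANOVA with LSD post-hoc tests (blocks = generating
  models, treatments = criteria).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, t as t_dist

from .criteria import CRITERIA
from .models import ModelSpec, free_parameters, model_category, parse_model_name

__all__ = [
    "accuracy",
    "precision",
    "dissimilarity",
    "agreement_profile",
    "chi2_homogeneity",
    "model_bias_tables",
    "randomized_block_anova",
    "PerformanceRecord",
    "PairwiseAgreement",
    "performance_table",
    "dissimilarity_table",
]


def _names(selections) -> list[str]:
    out = []
    for s in selections:
        if isinstance(s, ModelSpec):
            out.append(s.name)
        else:
            out.append(str(s))
    return out


def accuracy(selections, true_model: ModelSpec | str) -> float:
    """Recovery rate of the generating model, in percent."""
    sel = _names(selections)
    if not sel:
        raise ValueError("empty selection list")
    truth = true_model.name if isinstance(true_model, ModelSpec) else true_model
    return 100.0 * sum(s == truth for s in sel) / len(sel)


def precision(selections) -> int:
    """Number of distinct best-fit models selected across the replicates."""
    sel = _names(selections)
    if not sel:
        raise ValueError("empty selection list")
    return len(set(sel))


def dissimilarity(sel1, sel2) -> float:
    """(N - m)/N x 100 where m counts datasets with identical choices."""
    a, b = _names(sel1), _names(sel2)
    if len(a) != len(b):
        raise ValueError("selection lists must be aligned by dataset")
    n = len(a)
    m = sum(x == y for x, y in zip(a, b))
    return 100.0 * (n - m) / n


def agreement_profile(per_dataset_choices) -> np.ndarray:
    """Percentages of datasets with 1, 2, 3 and 4 distinct chosen models.

    ``per_dataset_choices`` is an iterable of 4-tuples (one model per
    criterion per dataset).  The four percentages sum to 100.
    """
    counts = np.zeros(4)
    total = 0
    for choices in per_dataset_choices:
        names = _names(choices)
        if len(names) != 4:
            raise ValueError("expected one choice per criterion (4)")
        counts[len(set(names)) - 1] += 1
        total += 1
    if total == 0:
        raise ValueError("no datasets")
    return 100.0 * counts / total


@dataclass
class PerformanceRecord:
    condition_id: str
    generating_model: str
    criterion: str
    accuracy_pct: float
    precision_count: int
    n_replicates: int


@dataclass
class PairwiseAgreement:
    condition_id: str
    generating_model: str
    pair: tuple[str, str]
    m_same: int
    n: int

    @property
    def dissimilarity_pct(self) -> float:
        return 100.0 * (self.n - self.m_same) / self.n


def performance_table(selections: pd.DataFrame,
                      condition_id: str = "") -> pd.DataFrame:
    """Tidy accuracy/precision table from a per-dataset selection frame.

    ``selections`` must have columns ``true_model`` plus one column per
    criterion, one row per dataset.
    """
    rows = []
    for truth, grp in selections.groupby("true_model", sort=False):
        for crit in CRITERIA:
            rows.append({
                "condition_id": condition_id,
                "true_model": truth,
                "criterion": crit,
                "accuracy_pct": accuracy(grp[crit], truth),
                "precision": precision(grp[crit]),
                "n_replicates": len(grp),
            })
    return pd.DataFrame(rows)


def dissimilarity_table(selections: pd.DataFrame,
                        condition_id: str = "",
                        by_model: bool = True) -> pd.DataFrame:
    """Pairwise dissimilarity of the criteria, optionally per generating model."""
    rows = []
    groups = (selections.groupby("true_model", sort=False)
              if by_model and "true_model" in selections
              else [("all", selections)])
    for truth, grp in groups:
        for c1, c2 in combinations(CRITERIA, 2):
            rows.append({
                "condition_id": condition_id,
                "true_model": truth,
                "pair": f"{c1}-{c2}",
                "dissimilarity_pct": dissimilarity(grp[c1], grp[c2]),
                "n": len(grp),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-bias chi-square homogeneity tests
# ---------------------------------------------------------------------------


def chi2_homogeneity(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on an r x k count table.

    Zero-total columns must be removed/pooled beforehand.  Returns
    (statistic, df, p-value).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D count table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero-count row or column; pool categories first")
    expected = row * col / total
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df, float(chi2.sf(stat, df))


def _pool_zero_columns(table: np.ndarray, labels: list[str]):
    """Pool zero-total columns into their left neighbour (right for the first).

    Category labels are ordered (model categories or free-parameter counts),
    so pooling with an adjacent column keeps the comparison interpretable.
    """
    table = np.asarray(table, dtype=float).copy()
    labels = list(labels)
    while table.shape[1] > 1:
        totals = table.sum(axis=0)
        zeros = np.flatnonzero(totals == 0)
        if len(zeros) == 0:
            break
        j = int(zeros[0])
        k = j - 1 if j > 0 else j + 1
        table[:, k] += table[:, j]
        labels[k] = f"{labels[min(j, k)]}|{labels[max(j, k)]}"
        table = np.delete(table, j, axis=1)
        del labels[j]
    return table, labels


def model_bias_tables(selections: pd.DataFrame,
                      classify: str = "category",
                      recovered_only: bool = True,
                      family_alpha: float = 0.05) -> dict:
    """Composition of selected models per criterion, with homogeneity tests.

    ``classify`` is ``"category"`` (base/+I/+G/+I+G, df 3) or ``"nparams"``
    (11 free-parameter classes, df 10).  By default only recovered models
    (selection == generating model) are tabulated; ``recovered_only=False``
    tabulates all selections.  Pairwise comparisons between criteria use a
    Bonferroni-corrected level family_alpha / (number of pairs).
    """
    if classify == "category":
        labels = ["base", "base+I", "base+G", "base+I+G"]
        keyfun = lambda nm: model_category(parse_model_name(nm))
    elif classify == "nparams":
        labels = [str(k) for k in range(11)]
        keyfun = lambda nm: str(free_parameters(nm))
    else:
        raise ValueError("classify must be 'category' or 'nparams'")

    counts = pd.DataFrame(0, index=list(CRITERIA), columns=labels)
    for crit in CRITERIA:
        chosen = selections[crit]
        if recovered_only:
            chosen = chosen[chosen == selections["true_model"]]
        for nm in chosen:
            counts.loc[crit, keyfun(nm)] += 1

    table, kept = _pool_zero_columns(counts.to_numpy(), labels)
    stat, df, p = chi2_homogeneity(table)
    n_pairs = len(list(combinations(CRITERIA, 2)))
    alpha_corrected = family_alpha / n_pairs
    pairwise = []
    for c1, c2 in combinations(CRITERIA, 2):
        sub = counts.loc[[c1, c2]].to_numpy()
        sub, _ = _pool_zero_columns(sub, labels)
        s, d, pv = chi2_homogeneity(sub)
        pairwise.append({"pair": f"{c1}-{c2}", "chi2": s, "df": d,
                         "p_value": pv,
                         "significant": pv < alpha_corrected})
    return {
        "counts": counts,
        "pooled_labels": kept,
        "overall": {"chi2": stat, "df": df, "p_value": p},
        "pairwise": pd.DataFrame(pairwise),
        "alpha_corrected": alpha_corrected,
    }


# ---------------------------------------------------------------------------
# Randomized-block ANOVA + LSD
# ---------------------------------------------------------------------------


def randomized_block_anova(values: pd.DataFrame, alpha: float = 0.01,
                           gate_lsd: bool = True) -> dict:
    """Two-way randomized-block ANOVA with LSD pairwise comparisons.

    ``values`` is a complete blocks x treatments table (rows = generating
    models, columns = criteria).  The classical decomposition
    SS_total = SS_treat + SS_block + SS_error is used; LSD compares treatment
    means with t-tests on the error mean square.  When ``gate_lsd`` is set
    the LSD decisions are additionally reported only if the omnibus
    treatment F-test is significant at ``alpha``.
    """
    x = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells in the block design")
    b, t = x.shape
    grand = x.mean()
    treat_means = x.mean(axis=0)
    block_means = x.mean(axis=1)
    ss_treat = b * ((treat_means - grand) ** 2).sum()
    ss_block = t * ((block_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_treat - ss_block
    df_treat, df_block = t - 1, b - 1
    df_error = (b - 1) * (t - 1)
    ms_treat = ss_treat / df_treat
    ms_block = ss_block / df_block
    ms_error = ss_error / df_error if df_error > 0 else np.nan
    if ms_error == 0 or not np.isfinite(ms_error):
        f_treat = 0.0 if ss_treat == 0 else np.inf
        f_block = 0.0 if ss_block == 0 else np.inf
    else:
        f_treat = ms_treat / ms_error
        f_block = ms_block / ms_error
    p_treat = float(f_dist.sf(f_treat, df_treat, df_error)) if np.isfinite(f_treat) else 0.0
    p_block = float(f_dist.sf(f_block, df_block, df_error)) if np.isfinite(f_block) else 0.0

    lsd_rows = []
    se = np.sqrt(2.0 * ms_error / b) if np.isfinite(ms_error) else np.nan
    tcrit = t_dist.ppf(1.0 - alpha / 2.0, df_error)
    for (i, c1), (j, c2) in combinations(enumerate(values.columns), 2):
        diff = treat_means[i] - treat_means[j]
        if se and np.isfinite(se) and se > 0:
            tstat = diff / se
            pv = 2.0 * float(t_dist.sf(abs(tstat), df_error))
            sig = abs(diff) > tcrit * se
        else:
            tstat, pv, sig = 0.0, 1.0, False
        lsd_rows.append({"pair": f"{c1}-{c2}", "mean_diff": diff,
                         "t": tstat, "p_value": pv, "significant": bool(sig)})
    lsd = pd.DataFrame(lsd_rows)
    omnibus_significant = p_treat < alpha
    return {
        "treatment": {"F": float(f_treat), "df": (df_treat, df_error),
                      "p_value": p_treat, "ms": ms_treat},
        "block": {"F": float(f_block), "df": (df_block, df_error),
                  "p_value": p_block, "ms": ms_block},
        "ms_error": float(ms_error),
        "lsd": lsd,
        "lsd_gated": lsd if (not gate_lsd or omnibus_significant)
        else lsd.assign(significant=False),
        "omnibus_significant": bool(omnibus_significant),
        "treatment_means": dict(zip(values.columns, treat_means)),
    }
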