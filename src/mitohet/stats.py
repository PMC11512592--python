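"""Cohort-level statistics of mtDNA mutation incidence.

Operates on a per-sample count table (one row per sample: group, age, and
mutation counts per category) and reproduces the study-style analyses:
group means with ranges, two-tailed homoscedastic t-tests between case and
control groups, age-adjusted logistic and multinomial logistic regressions
of case status on mutation burden (Wald inference), and Poisson regressions
of mutation count on age (log link, slope per year). P-values are two-tailed
and reported unadjusted; the only multiple-testing correction in the
pipeline is the per-site Bonferroni inside the variant caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when a model cannot be estimated from the given table
    (zero variance, empty groups, perfect separation)."""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    min: float
    max: float


def group_means(table: pd.DataFrame, category: str) -> dict[str, GroupSummary]:
    """Mean (range) of one count category per group — Table-1 style."""
    if category not in table.columns:
        raise KeyError(f"category {category!r} not in table")
    out = {}
    for group, sub in table.groupby("group", sort=False):
        vals = sub[category].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        out[group] = GroupSummary(
            group=group,
            n=len(vals),
            mean=float(vals.mean()),
            min=float(vals.min()),
            max=float(vals.max()),
        )
    return out


def two_group_ttest(
    table: pd.DataFrame,
    category: str,
    groups_a: list[str] | str,
    groups_b: list[str] | str,
) -> tuple[float, float]:
    """Two-tailed homoscedastic (pooled-variance) Student's t-test.

    ``groups_a`` / ``groups_b`` may pool several group labels (e.g. all
    controls vs all carriers). Returns (t, p).
    """
    if isinstance(groups_a, str):
        groups_a = [groups_a]
    if isinstance(groups_b, str):
        groups_b = [groups_b]
    x = table.loc[table["group"].isin(groups_a), category].to_numpy(dtype=float)
    y = table.loc[table["group"].isin(groups_b), category].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("both groups need n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def logistic_age_adjusted(
    table: pd.DataFrame,
    category: str,
    case_groups: list[str],
    control_groups: list[str],
) -> dict[str, float]:
    """Age-adjusted logistic regression of case status on mutation count.

    Model: case ~ count + age. Returns the odds ratio per unit count with
    its Wald two-tailed p-value. Perfect separation raises
    :class:`DegenerateDataError`.
    """
    sub = table[table["group"].isin(case_groups + control_groups)].copy()
    y = sub["group"].isin(case_groups).astype(float).to_numpy()
    if y.min() == y.max():
        raise DegenerateDataError("both outcomes must be present")
    X = sm.add_constant(sub[[category, "age"]].to_numpy(dtype=float))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise DegenerateDataError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise DegenerateDataError("non-finite standard errors (separation?)")
    beta = float(fit.params[1])
    return {
        "odds_ratio": float(np.exp(beta)),
        "beta": beta,
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
    }


def multinomial_age_adjusted(
    table: pd.DataFrame,
    category: str,
    stage_groups: list[str],
    control_groups: list[str],
) -> dict[str, dict[str, float]]:
    """Age-adjusted multinomial logistic regression over disease stages.

    Controls form the base outcome; each stage in ``stage_groups`` gets its
    own odds ratio per unit count with a Wald p-value.
    """
    sub = table[table["group"].isin(stage_groups + control_groups)].copy()
    levels = ["__control__"] + list(stage_groups)
    outcome = np.where(
        sub["group"].isin(control_groups), "__control__", sub["group"]
    )
    codes = pd.Categorical(outcome, categories=levels).codes
    if len(np.unique(codes)) < 2:
        raise DegenerateDataError("need controls plus at least one stage")
    X = sm.add_constant(sub[[category, "age"]].to_numpy(dtype=float))
    try:
        fit = sm.MNLogit(codes, X).fit(disp=0, maxiter=400)
    except Exception as exc:
        raise DegenerateDataError(f"multinomial fit failed: {exc}") from exc
    out = {}
    params = np.atleast_2d(np.asarray(fit.params))  # (k_vars, n_stages)
    bse = np.atleast_2d(np.asarray(fit.bse))
    for j, stage in enumerate(stage_groups):
        beta = float(params[1, j])
        se = float(bse[1, j])
        z = beta / se if se > 0 else np.nan
        out[stage] = {
            "odds_ratio": float(np.exp(beta)),
            "beta": beta,
            "se": se,
            "p": float(2.0 * sps.norm.sf(abs(z))),
        }
    return out


def poisson_age_trend(
    table: pd.DataFrame,
    category: str,
    groups: list[str] | None = None,
) -> dict[str, float]:
    """Poisson regression of mutation count on age (log link).

    Returns the slope per year of age (beta), its SE and the two-tailed
    Wald p-value — Table-2 style. ``groups`` restricts the fit to a subset
    of group labels.
    """
    sub = table if groups is None else table[table["group"].isin(groups)]
    if len(sub) < 3:
        raise DegenerateDataError("need at least 3 samples")
    y = sub[category].to_numpy(dtype=float)
    if y.sum() == 0:
        raise DegenerateDataError("all counts are zero")
    X = sm.add_constant(sub["age"].to_numpy(dtype=float))
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return {
        "beta": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
    }


def incidence_report(
    table: pd.DataFrame,
    categories: list[str],
    case_groups: list[str],
    control_groups: list[str],
) -> pd.DataFrame:
    """Table-1-style report: per-group mean (range) per category plus the
    pooled controls-vs-cases t-test p-value."""
    rows = []
    for cat in categories:
        summaries = group_means(table, cat)
        row = {"category": cat}
        for g, s in summaries.items():
            row[f"{g}_mean"] = round(s.mean, 2)
            row[f"{g}_range"] = f"{s.min:g}-{s.max:g}"
        try:
            _, p = two_group_ttest(table, cat, control_groups, case_groups)
            row["p_ttest"] = p
        except DegenerateDataError:
            row["p_ttest"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def age_trend_report(
    table: pd.DataFrame, categories: list[str], group_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Table-2-style report: Poisson age slope (SE, p) per category for each
    named set of groups."""
    rows = []
    for cat in categories:
        row = {"category": cat}
        for name, gs in group_sets.items():
            try:
                fit = poisson_age_trend(table, cat, gs)
                row[f"{name}_beta"] = fit["beta"]
                row[f"{name}_se"] = fit["se"]
                row[f"{name}_p"] = fit["p"]
            except DegenerateDataError:
                row[f"{name}_beta"] = np.nan
                row[f"{name}_se"] = np.nan
                row[f"{name}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
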