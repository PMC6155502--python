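"""Group-comparison statistics for tidy pre/post cohort tables.

A cohort table is a tidy DataFrame with columns ``subject``, ``group``
(RMT/SHAM), ``time`` (pre/post), ``variable`` and ``value``. This module
layers the study-level statistical treatment on top of it: percent
changes, within-group paired t-tests, between-group t-tests, the
split-plot (mixed-design) two-way repeated-measures ANOVA with
Holm-Sidak-adjusted post-hoc contrasts, and small derived quantities
(total lung capacity). Normality (Shapiro-Wilk) is reported for
information but never gates an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DesignError, DomainError

__all__ = [
    "ComparisonResult", "percent_change", "total_lung_capacity", "paired_t",
    "unpaired_t", "holm_sidak", "two_way_rm_anova", "validate_cohort",
    "shapiro_report", "group_summary",
]

COHORT_COLUMNS = ["subject", "group", "time", "variable", "value"]


@dataclass
class ComparisonResult:
    """Outcome of a single statistical comparison."""

    effect: float        # mean difference (or F-test effect size context)
    statistic: float
    p_value: float
    test_name: str
    adjusted: bool = False


def percent_change(pre: float, post: float) -> float:
    """(post - pre) / pre * 100; scale-invariant in (pre, post)."""
    if pre == 0:
        raise DomainError("percent change undefined for a zero baseline")
    return (post - pre) / pre * 100.0


def total_lung_capacity(rv: float, fvc: float) -> float:
    """Total lung capacity as residual volume + forced vital capacity (l)."""
    if rv < 0 or fvc <= 0:
        raise DomainError("RV must be >= 0 and FVC > 0")
    return rv + fvc


def paired_t(pre, post) -> ComparisonResult:
    """Two-sided paired Student's t-test.

    Identical paired samples (all differences exactly zero) return
    t = 0, p = 1 — no evidence of change. Zero-variance differences with
    a nonzero mean carry no usable error estimate and raise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise DegenerateDataError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 2:
        raise DegenerateDataError("paired t-test needs n >= 2 pairs")
    diff = post - pre
    if np.all(diff == 0):
        return ComparisonResult(0.0, 0.0, 1.0, "paired t")
    if np.var(diff, ddof=1) == 0:
        raise DegenerateDataError("zero variance of nonzero differences")
    t, p = sps.ttest_rel(post, pre)
    return ComparisonResult(float(diff.mean()), float(t), float(p), "paired t")


def unpaired_t(a, b) -> ComparisonResult:
    """Two-sided independent-samples Student's t-test (equal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("unpaired t-test needs n >= 2 per group")
    t, p = sps.ttest_ind(a, b)
    return ComparisonResult(float(a.mean() - b.mean()), float(t), float(p),
                            "unpaired t")


def holm_sidak(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted raw p_i are compared against 1 - (1-alpha)^(1/(m-i+1)); the
    returned adjusted p-values are monotone in the raw ordering and
    reduce to the unadjusted value for m = 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, alpha=alpha, method="holm-sidak")[1]


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the tidy-cohort schema and uniqueness invariants."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise DesignError(f"cohort table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "time", "variable"])
    if dup.any():
        raise DesignError("duplicate (subject, time, variable) rows")
    groups_per_subject = table.groupby("subject")["group"].nunique()
    if (groups_per_subject > 1).any():
        raise DesignError("each subject must belong to exactly one group")


def _pivot_variable(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    sub = table.loc[table["variable"] == variable]
    if sub.empty:
        raise DesignError(f"variable {variable!r} not in cohort table")
    wide = sub.pivot_table(
        index=["subject", "group"], columns="time", values="value",
        aggfunc="first",
    ).reset_index()
    if not {"pre", "post"}.issubset(wide.columns) or wide[["pre", "post"]].isna().any().any():
        raise DesignError(f"variable {variable!r}: incomplete pre/post design")
    return wide


def two_way_rm_anova(
    table: pd.DataFrame, variable: str, alpha: float = 0.05
) -> dict[str, ComparisonResult]:
    """Mixed-design (split-plot) two-way ANOVA: group (between) x time (within).

    Returns F tests for the group and time main effects and the
    group x time interaction; when the interaction is significant at
    ``alpha``, the four simple-effect contrasts (pre vs post within each
    group, RMT vs SHAM at each time) are added with Holm-Sidak-adjusted
    p-values under keys ``contrast:<name>``.
    """
    validate_cohort(table)
    wide = _pivot_variable(table, variable)
    counts = wide.groupby("group").size()
    if len(counts) != 2:
        raise DesignError("design needs exactly two groups")
    long = wide.melt(
        id_vars=["subject", "group"], value_vars=["pre", "post"],
        var_name="time", value_name="value",
    )
    aov = pg.mixed_anova(
        data=long, dv="value", within="time", subject="subject", between="group"
    ).set_index("Source")
    out: dict[str, ComparisonResult] = {}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for source, key in (("group", "group"), ("time", "time"),
                        ("Interaction", "interaction")):
        row = aov.loc[source]
        out[key] = ComparisonResult(
            effect=float(row.get("np2", np.nan)),
            statistic=float(row["F"]), p_value=float(row[p_col]),
            test_name="mixed ANOVA F",
        )
    if out["interaction"].p_value < alpha:
        g1, g2 = sorted(counts.index)
        by_group = {g: wide.loc[wide["group"] == g] for g in (g1, g2)}
        contrasts = [
            (f"{g1} pre vs post", paired_t(by_group[g1]["pre"], by_group[g1]["post"])),
            (f"{g2} pre vs post", paired_t(by_group[g2]["pre"], by_group[g2]["post"])),
            (f"{g1} vs {g2} at pre",
             unpaired_t(by_group[g1]["pre"], by_group[g2]["pre"])),
            (f"{g1} vs {g2} at post",
             unpaired_t(by_group[g1]["post"], by_group[g2]["post"])),
        ]
        adj = holm_sidak([c.p_value for _, c in contrasts], alpha)
        for (name, c), p_adj in zip(contrasts, adj):
            out[f"contrast:{name}"] = ComparisonResult(
                effect=c.effect, statistic=c.statistic, p_value=float(p_adj),
                test_name=c.test_name + " (Holm-Sidak)", adjusted=True,
            )
    return out


def shapiro_report(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Shapiro-Wilk normality p-values per group x time cell (informational)."""
    sub = table.loc[table["variable"] == variable]
    rows = []
    for (g, t), cell in sub.groupby(["group", "time"]):
        vals = cell["value"].to_numpy()
        if vals.size >= 3:
            w, p = sps.shapiro(vals)
        else:
            w, p = np.nan, np.nan
        rows.append({"group": g, "time": t, "W": w, "p_value": p, "n": vals.size})
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group table: cell means +- SD, percent change, tests.

    Mirrors the layout of a pre/post trial report: one row per variable
    per group with pre and post summaries, the percent change of the
    group means, the within-group paired-t p-value, and the mixed-ANOVA
    interaction p-value.
    """
    validate_cohort(table)
    rows = []
    for variable in table["variable"].unique():
        wide = _pivot_variable(table, variable)
        anova = two_way_rm_anova(table, variable, alpha)
        for g, sub in wide.groupby("group"):
            pre, post = sub["pre"].to_numpy(), sub["post"].to_numpy()
            rows.append({
                "variable": variable,
                "group": g,
                "n": pre.size,
                "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
                "post_mean": post.mean(), "post_sd": post.std(ddof=1),
                "percent_change": percent_change(pre.mean(), post.mean()),
                "paired_t_p": paired_t(pre, post).p_value,
                "interaction_p": anova["interaction"].p_value,
            })
    return pd.DataFrame(rows)
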