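"""Closed-form group statistics: one-way ANOVA, Fisher's LSD, chi-square, paired t.

These are the inferential tests used on per-animal behavioral metrics and
per-neuron electrophysiology summaries.  All statistics are computed from
their textbook sums-of-squares forms; only the reference tail distributions
(F, t, chi-square) come from scipy.  All p-values are two-sided and no
multiplicity correction is applied beyond the logic of the LSD procedure
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "TestResult",
    "one_way_anova",
    "fisher_lsd",
    "chi_square_proportions",
    "paired_t",
    "group_summary",
    "analyze_metrics_table",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` is a scalar for t and chi-square tests, an ``(df1, df2)`` pair for
    the F test.  ``degenerate`` marks inputs with zero within-group (or
    difference) variance, where the statistic has no finite sampling
    distribution; the ``note`` says why.
    """

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    degenerate: bool = False
    note: str = ""

    def summary(self) -> str:
        if isinstance(self.df, tuple):
            df_txt = f"({self.df[0]:g}, {self.df[1]:g})"
        else:
            df_txt = f"{self.df:g}"
        line = f"{self.test}: statistic = {self.statistic:.4g}, df = {df_txt}, p = {self.p_value:.4g}"
        if self.degenerate:
            line += f"  [degenerate: {self.note}]"
        return line


def _split_groups(
    table: pd.DataFrame, value_col: str, group_col: str
) -> dict[str, np.ndarray]:
    if group_col not in table.columns or value_col not in table.columns:
        raise ValidationError(f"table needs columns {group_col!r} and {value_col!r}")
    groups = {
        str(name): np.asarray(sub[value_col], dtype=float)
        for name, sub in table.groupby(group_col, sort=False)
    }
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise InvalidParameterError(f"group {name!r} has fewer than 2 subjects")
        if np.any(~np.isfinite(vals)):
            raise ValidationError(f"group {name!r} contains non-finite values")
    return groups


def _anova_sums(groups: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = k - 1
    df_within = n_total - k
    return ss_between, ss_within, df_between, df_within


def one_way_anova(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within, df (k-1, N-k)."""
    groups = _split_groups(table, value_col, group_col)
    ssb, ssw, dfb, dfw = _anova_sums(groups)
    if ssw == 0:
        if ssb == 0:
            return TestResult(
                "one_way_anova", float("nan"), (dfb, dfw), float("nan"),
                degenerate=True, note="all observations identical",
            )
        return TestResult(
            "one_way_anova", float("inf"), (dfb, dfw), 0.0,
            degenerate=True, note="zero within-group variance",
        )
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return TestResult("one_way_anova", float(f), (dfb, dfw), p)


def fisher_lsd(
    table: pd.DataFrame,
    pair: tuple[str, str],
    value_col: str = "value",
    group_col: str = "group",
) -> TestResult:
    """Fisher's LSD pairwise t using the pooled ANOVA within-group mean square.

    t = (m_i - m_j) / sqrt(MS_within * (1/n_i + 1/n_j)), df = N - k.
    """
    groups = _split_groups(table, value_col, group_col)
    a, b = (str(g) for g in pair)
    for g in (a, b):
        if g not in groups:
            raise InvalidParameterError(f"group {g!r} not in table")
    _, ssw, _, dfw = _anova_sums(groups)
    if ssw == 0:
        same = groups[a].mean() == groups[b].mean()
        return TestResult(
            "fisher_lsd", 0.0 if same else float("inf"), dfw, 1.0 if same else 0.0,
            degenerate=True, note="zero within-group variance",
        )
    ms_within = ssw / dfw
    va, vb = groups[a], groups[b]
    t = (va.mean() - vb.mean()) / np.sqrt(ms_within * (1 / va.size + 1 / vb.size))
    p = 2.0 * float(sps.t.sf(abs(t), dfw))
    return TestResult(f"fisher_lsd[{a} vs {b}]", float(t), dfw, p)


def chi_square_proportions(contingency: np.ndarray) -> TestResult:
    """Pearson chi-square on an r x c count table, df = (r-1)(c-1).

    No continuity correction.  A zero row or column marginal leaves the
    expected counts undefined and raises.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise InvalidParameterError("contingency table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateMarginalError("a zero marginal leaves expected counts undefined")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("chi_square_proportions", chi2, df, p)


class DegenerateMarginalError(ValidationError):
    """A contingency-table marginal is zero."""


def paired_t(before: np.ndarray, after: np.ndarray) -> TestResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = after - before, df = n-1."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise InvalidParameterError("before/after must be equal-length 1-D vectors")
    n = before.size
    if n < 2:
        raise InvalidParameterError("paired t needs n >= 2")
    d = after - before
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if np.all(d == 0):
            return TestResult(
                "paired_t", 0.0, n - 1, 1.0, degenerate=True, note="all differences zero"
            )
        return TestResult(
            "paired_t", float("inf"), n - 1, 0.0,
            degenerate=True, note="zero-variance nonzero differences",
        )
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult("paired_t", t, n - 1, p)


def group_summary(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> pd.DataFrame:
    """Per-group n, mean and SEM (the reporting convention for these assays)."""
    out = (
        table.groupby(group_col, sort=False)[value_col]
        .agg(n="size", mean="mean", sd=lambda v: np.std(v, ddof=1))
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def analyze_metrics_table(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Tidy results for each metric column: omnibus ANOVA plus all pairwise LSD tests.

    Returns one row per (metric, test) with columns
    ``metric, test, statistic, df, p_value, degenerate``.
    """
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c not in (group_col, "subject_id") and pd.api.types.is_numeric_dtype(table[c])
        ]
    group_names = [str(g) for g in table[group_col].drop_duplicates()]
    rows = []

    def _row(metric: str, res: TestResult):
        df_txt = (
            f"({res.df[0]:g}, {res.df[1]:g})" if isinstance(res.df, tuple) else f"{res.df:g}"
        )
        rows.append(
            {
                "metric": metric,
                "test": res.test,
                "statistic": res.statistic,
                "df": df_txt,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )

    for metric in metrics:
        _row(metric, one_way_anova(table, metric, group_col))
        for i, a in enumerate(group_names):
            for b in group_names[i + 1 :]:
                _row(metric, fisher_lsd(table, (a, b), metric, group_col))
    return pd.DataFrame(rows)
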