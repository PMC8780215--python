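"""Two-group cohort statistics for electrophysiological and clinical data.

Implements the statistical plan used for the CMAP-scan study tables:
Kolmogorov-Smirnov normality screening (Lilliefors-corrected by Monte Carlo,
since the Gaussian parameters are estimated from the sample), selection
between the independent-samples t-test and the Mann-Whitney U test,
mean +/- SD vs median (min-max) reporting, and Pearson correlations between
motor unit number estimates and clinical scores.

No multiple-testing correction is applied, matching the reporting convention
of the study design this reproduces.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "GroupSummary",
    "GroupComparison",
    "CorrelationResult",
    "CohortReport",
    "summarize",
    "normality_test",
    "compare_groups",
    "pearson_correlation",
    "run_cohort_analysis",
]

#: columns the analysis knows about, beyond subject_id/group
NUMERIC_COLUMNS = ("age", "years_injury", "grassp", "grip_kg", "pinch_kg",
                   "mune", "cmap_mV", "d50")
CATEGORICAL_COLUMNS = ("gender", "hand", "level", "ais")
ELECTROPHYS_COLUMNS = ("mune", "cmap_mV", "d50")
CORRELATION_COLUMNS = ("mune", "cmap_mV", "pinch_kg", "grip_kg", "grassp",
                       "years_injury")


@dataclass
class CohortTable:
    """Per-subject cohort rows (one row per subject, `group` column required).

    Clinical fields may be missing (NaN) — per-subject clinical data are not
    available for control subjects.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"cohort table is missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        for col in NUMERIC_COLUMNS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValueError(f"column {col!r} contains negative values")
                self.df[col] = vals

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def column(self, name: str, group: str | None = None) -> np.ndarray:
        """Non-missing values of a numeric column, optionally for one group."""
        df = self.df if group is None else self.df[self.df["group"] == group]
        return df[name].dropna().to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    normality_p: float
    report_form: str  # "mean ± sd" or "median (min–max)"

    def __str__(self) -> str:
        if self.report_form == "mean ± sd":
            return f"{self.mean:g} ± {self.sd:g}"
        return f"{self.median:g} ({self.min:g}–{self.max:g})"


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summaries: dict
    test_used: str  # "t-test" or "mann-whitney"
    statistic: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n: int


def _ks_statistic(values: np.ndarray) -> float:
    """One-sample KS statistic against a Gaussian with the sample's mean/SD."""
    x = np.sort(values)
    n = x.size
    u = stats.norm.cdf((x - x.mean()) / x.std(ddof=1))
    grid = np.arange(1, n + 1) / n
    return float(max((grid - u).max(), (u - (grid - 1 / n)).max()))


@functools.lru_cache(maxsize=64)
def _lilliefors_null_table(n: int, n_sims: int) -> np.ndarray:
    """Monte-Carlo null distribution of the KS statistic with estimated
    Gaussian parameters (Lilliefors correction).  Fixed internal seed so the
    normality decision is deterministic."""
    rng = np.random.default_rng(20210630)
    samples = rng.standard_normal((n_sims, n))
    samples.sort(axis=1)
    means = samples.mean(axis=1, keepdims=True)
    sds = samples.std(axis=1, ddof=1, keepdims=True)
    u = stats.norm.cdf((samples - means) / sds)
    grid = np.arange(1, n + 1) / n
    d = np.maximum((grid - u).max(axis=1), (u - (grid - 1 / n)).max(axis=1))
    return np.sort(d)


def normality_test(values, method: str = "lilliefors-mc", n_sims: int = 2000) -> float:
    """Kolmogorov-Smirnov normality p-value.

    Default is a Monte-Carlo Lilliefors test: the null distribution of the KS
    statistic under Gaussian data with estimated mean/SD is simulated once
    per sample size (cached, fixed seed).  ``method="asymptotic"`` uses the
    plain one-sample KS p-value instead (anticonservative with estimated
    parameters).  A zero-variance sample returns p = 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 values")
    if np.ptp(x) == 0:
        warnings.warn("zero-variance sample: normality undefined, returning p=0",
                      stacklevel=2)
        return 0.0
    if method == "asymptotic":
        return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    if method != "lilliefors-mc":
        raise ValueError(f"unknown method {method!r}")
    d = _ks_statistic(x)
    null = _lilliefors_null_table(x.size, n_sims)
    return float((1 + np.sum(null >= d)) / (n_sims + 1))


def summarize(values, alpha: float = 0.05) -> GroupSummary:
    """Summary of one variable: n, mean, sample SD (n-1), median, min, max,
    normality p, and the reporting form the normality decision implies."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("summarize needs at least 2 values")
    if x.size >= 3:
        p = normality_test(x)
    else:
        p = float("nan")  # too few values to screen; report parametrically
    normal = not (p < alpha)
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
        normality_p=p,
        report_form="mean ± sd" if normal else "median (min–max)",
    )


def compare_groups(a, b, alpha: float = 0.05, variable: str = "") -> GroupComparison:
    """Two-group comparison with the normality-driven test choice.

    If both samples pass the KS normality screen at ``alpha``, a two-sided
    equal-variance independent-samples t-test is used; otherwise a two-sided
    Mann-Whitney U test (exact for combined n <= 8 without ties, normal
    approximation with tie correction otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sa, sb = summarize(a, alpha), summarize(b, alpha)
    both_normal = sa.report_form == "mean ± sd" and sb.report_form == "mean ± sd"
    if both_normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        test = "t-test"
    else:
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann-whitney"
    return GroupComparison(
        variable=variable,
        summaries={"a": sa, "b": sb},
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def pearson_correlation(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with the two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson correlation needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), int(x.size))


@dataclass
class CohortReport:
    """Output of :func:`run_cohort_analysis`."""

    summaries: dict  # {group: {variable: GroupSummary}}
    comparisons: dict  # {variable: GroupComparison}
    correlations: pd.DataFrame  # Pearson r matrix
    correlation_pvalues: pd.DataFrame
    correlation_group: str | None = None

    def to_text(self) -> str:
        lines = []
        groups = list(self.summaries)
        header = f"{'variable':<14}" + "".join(f"{g:>24}" for g in groups)
        if self.comparisons:
            header += f"{'test':>14}{'p':>10}"
        lines.append(header)
        variables = list(next(iter(self.summaries.values()), {}))
        for var in variables:
            row = f"{var:<14}"
            for g in groups:
                s = self.summaries[g].get(var)
                row += f"{str(s) if s else '-':>24}"
            cmp_ = self.comparisons.get(var)
            if cmp_:
                row += f"{cmp_.test_used:>14}{cmp_.p_value:>10.3g}"
            elif self.comparisons:
                row += f"{'-':>14}{'-':>10}"
            lines.append(row)
        if not self.correlations.empty:
            scope = f" ({self.correlation_group} group)" if self.correlation_group else ""
            lines.append("")
            lines.append(f"Pearson correlations{scope}:")
            lines.append(self.correlations.round(2).to_string())
        return "\n".join(lines)


def run_cohort_analysis(table: CohortTable, alpha: float = 0.05,
                        correlation_group: str = "SCI") -> CohortReport:
    """Full cohort analysis: per-group summaries of the electrophysiological
    and clinical variables, two-group comparisons when two groups are
    present, and the Pearson correlation matrix among MUNE, CMAP and the
    clinical scores (within ``correlation_group`` when that group exists).

    Unknown numeric columns are ignored with a warning.
    """
    known = (set(NUMERIC_COLUMNS) | set(CATEGORICAL_COLUMNS)
             | {"subject_id", "group", "mune_true"})
    unknown = [c for c in table.df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)

    present = [c for c in NUMERIC_COLUMNS if c in table.df.columns]
    groups = table.groups
    summaries: dict = {}
    for g in groups:
        summaries[g] = {}
        for var in present:
            vals = table.column(var, group=g)
            if vals.size >= 2:
                summaries[g][var] = summarize(vals, alpha)

    comparisons: dict = {}
    if len(groups) >= 2:
        g1, g2 = groups[0], groups[1]
        for var in present:
            a, b = table.column(var, group=g1), table.column(var, group=g2)
            if a.size >= 2 and b.size >= 2:
                comparisons[var] = compare_groups(a, b, alpha, variable=var)

    corr_group = correlation_group if correlation_group in groups else None
    sub = table.df if corr_group is None else table.df[table.df["group"] == corr_group]
    corr_cols = [c for c in CORRELATION_COLUMNS if c in sub.columns
                 and sub[c].notna().sum() >= 3 and np.ptp(sub[c].dropna()) > 0]
    rmat = pd.DataFrame(np.eye(len(corr_cols)), index=corr_cols, columns=corr_cols)
    pmat = pd.DataFrame(np.zeros((len(corr_cols), len(corr_cols))),
                        index=corr_cols, columns=corr_cols)
    for i, ci in enumerate(corr_cols):
        for cj in corr_cols[i + 1:]:
            pair = sub[[ci, cj]].dropna()
            res = pearson_correlation(pair[ci], pair[cj], ci, cj)
            rmat.loc[ci, cj] = rmat.loc[cj, ci] = res.r
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = res.p_value
    return CohortReport(summaries, comparisons, rmat, pmat, corr_group)
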