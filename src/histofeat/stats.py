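"""Two-group comparison of per-subject feature tables.

The procedure mirrors a common clinical-imaging analysis: each feature is
screened per group with a one-sample Kolmogorov-Smirnov test against a
normal with the group's own mean and SD; if both groups pass (p > 0.05)
the groups are compared with a pooled-variance Student's t-test, otherwise
with a Mann-Whitney U test. All p-values are two-tailed and no
multiple-testing correction is applied (each comparison table says so in
its footer).

A summary-level t-test (:func:`summary_student_t`) reproduces pooled
t-tests exactly from (n, mean, SD) triplets alone, which is how published
group tables can be re-tested without raw data.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError, SchemaError
from .features import FEATURE_NAMES

__all__ = [
    "GroupSummary",
    "ComparisonRow",
    "FEATURE_DISPLAY_NAMES",
    "ks_normality",
    "student_t",
    "summary_student_t",
    "mann_whitney",
    "compare_cohorts",
    "write_comparison_table",
    "read_comparison_table",
]

#: Feature key -> display name, in canonical report order.
FEATURE_DISPLAY_NAMES: dict[str, str] = {
    "mean_intensity": "Mean",
    "sd_intensity": "Standard deviation",
    "min_intensity": "Minimum",
    "max_intensity": "Maximum",
    "median_intensity": "Median",
    "variance": "Variance",
    "entropy": "Entropy",
    "size_pct_lower": "Size %Lower",
    "size_pct_upper": "Size %Upper",
    "size_pct_mean": "Size %Mean",
    "kurtosis": "Kurtosis",
    "skewness": "Skewness",
    "uniformity": "Uniformity",
    "area_cm2": "Area (cm2)",
}

_NO_CORRECTION_FOOTER = (
    "p-values are two-tailed and uncorrected for multiple comparisons"
)


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample SD (divide-by-(n-1)) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("group summary needs n >= 2")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclasses.dataclass(frozen=True)
class ComparisonRow:
    """One feature's two-group comparison, mirroring a report-table row."""

    feature_name: str
    control: GroupSummary
    case: GroupSummary
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    df: float | None
    p_two_tailed: float
    significant: bool


def ks_normality(values: Sequence[float], lilliefors: bool = False) -> float:
    """One-sample KS test of normality with estimated mean and SD.

    By default the asymptotic KS p-value is returned (parameters treated
    as known, the classical software default); ``lilliefors=True``
    corrects for the estimated parameters via
    ``statsmodels.stats.diagnostic.lilliefors``. Constant input returns
    p = 0.0 (normality is untestable and the data are certainly not an
    absolutely continuous normal sample).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ParameterError("normality screen needs n >= 4")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return 0.0
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
        return float(p)
    _, p = sps.kstest(x, "norm", args=(float(x.mean()), sd))
    return float(p)


def student_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test; pooled-variance by default, Welch on request.

    Returns ``(t, df, p_two_tailed)`` with ``df = n_a + n_b - 2`` for the
    pooled form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise DegenerateInputError("zero pooled variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summary_student_t(
    a: GroupSummary, b: GroupSummary, welch: bool = False
) -> tuple[float, float, float]:
    """Pooled t-test computed from group summaries alone.

    Identical (to floating-point precision) to :func:`student_t` applied
    to any raw samples with exactly those n/mean/SD.
    """
    if a.sd == 0.0 and b.sd == 0.0:
        raise DegenerateInputError("zero pooled variance in both groups")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    df = a.n + b.n - 2 if not welch else float(res.df) if hasattr(res, "df") else math.nan
    return float(res.statistic), float(df), float(res.pvalue)


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties; two-tailed p.

    Exact enumeration is used for small samples (``n_a + n_b <= 12``,
    no ties); otherwise the normal approximation with tie and continuity
    correction. Returns ``(U, p)`` with U counting pairs where a value of
    the first group exceeds one of the second.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ParameterError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(
    feature_table: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    control_label: str = "control",
    normality_alpha: float = 0.05,
    lilliefors: bool = False,
    welch: bool = False,
) -> list[ComparisonRow]:
    """Compare the two groups of a feature table, feature by feature.

    For each feature (in canonical report order) both groups are screened
    with :func:`ks_normality`; if both screen p-values exceed
    ``normality_alpha``, a pooled Student's t-test compares the groups,
    otherwise a Mann-Whitney U test. Rows record which test ran.
    ``control_label`` names the reference group; the other label is the
    case group. The t statistic is control minus case (a negative t means
    the case group is higher).
    """
    if group_col not in feature_table.columns:
        raise SchemaError(f"feature table has no {group_col!r} column")
    labels = list(pd.unique(feature_table[group_col]))
    if len(labels) != 2:
        raise ParameterError(
            f"expected exactly 2 group labels, found {labels}"
        )
    if control_label not in labels:
        raise ParameterError(
            f"control label {control_label!r} absent from table"
        )
    case_label = next(l for l in labels if l != control_label)
    missing = [f for f in FEATURE_NAMES if f not in feature_table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    g_ctrl = feature_table[feature_table[group_col] == control_label]
    g_case = feature_table[feature_table[group_col] == case_label]
    if len(g_ctrl) < 2 or len(g_case) < 2:
        raise ParameterError("each group needs at least 2 subjects")

    rows: list[ComparisonRow] = []
    for feat in FEATURE_NAMES:
        a = g_ctrl[feat].to_numpy(dtype=float)
        b = g_case[feat].to_numpy(dtype=float)
        if min(len(a), len(b)) < 4:
            # too small to screen; fall back to the parametric default
            normal = True
        else:
            normal = (
                ks_normality(a, lilliefors=lilliefors) > normality_alpha
                and ks_normality(b, lilliefors=lilliefors) > normality_alpha
            )
        if normal:
            t, df, p = student_t(a, b, welch=welch)
            test, stat = "student_t", t
        else:
            u, p = mann_whitney(a, b)
            test, stat, df = "mann_whitney", u, None
        rows.append(
            ComparisonRow(
                feature_name=FEATURE_DISPLAY_NAMES[feat],
                control=GroupSummary.from_values(a),
                case=GroupSummary.from_values(b),
                test_used=test,
                statistic=stat,
                df=df,
                p_two_tailed=p,
                significant=bool(p < alpha),
            )
        )
    return rows


_COMPARISON_COLUMNS = (
    "feature",
    "control_n",
    "control_mean",
    "control_sd",
    "case_n",
    "case_mean",
    "case_sd",
    "test_used",
    "statistic",
    "df",
    "p_two_tailed",
    "significant",
)


def write_comparison_table(
    rows: Sequence[ComparisonRow], path: str | Path
) -> Path:
    """Write comparison rows as CSV; the footer comment notes that the
    p-values are uncorrected."""
    df = pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "control_n": r.control.n,
                "control_mean": r.control.mean,
                "control_sd": r.control.sd,
                "case_n": r.case.n,
                "case_mean": r.case.mean,
                "case_sd": r.case.sd,
                "test_used": r.test_used,
                "statistic": r.statistic,
                "df": "" if r.df is None else r.df,
                "p_two_tailed": r.p_two_tailed,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=list(_COMPARISON_COLUMNS),
    )
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        df.to_csv(fh, index=False, float_format="%.12g")
        fh.write(f"# {_NO_CORRECTION_FOOTER}\n")
    return path


def read_comparison_table(path: str | Path) -> pd.DataFrame:
    """Read a comparison CSV written by :func:`write_comparison_table`."""
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != list(_COMPARISON_COLUMNS):
        raise SchemaError(f"{path}: unexpected comparison-table columns")
    return df
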