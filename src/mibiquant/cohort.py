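"""Cohort-level statistical comparisons between parameter tables.

Implements the normality-gated testing scheme used for small imaging
cohorts: a Shapiro–Wilk test (alpha = 0.05) decides between parametric and
non-parametric branches; continuous variables are summarised as mean (SD)
when normal and median (IQR) otherwise; paired comparisons use the paired
t-test or the Wilcoxon signed-rank test on the differences; unpaired
comparisons use the independent t-test or the Mann–Whitney U test.
Spearman's rank correlation quantifies monotone association between the
paired modalities.  No multiple-testing correction is applied; every
result records which test actually ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Summary",
    "ComparisonResult",
    "summarize",
    "compare_paired",
    "compare_unpaired",
    "levene_variance",
    "NORMALITY_ALPHA",
]

NORMALITY_ALPHA = 0.05
#: Exact Wilcoxon null distribution up to this n, normal approximation above.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class Summary:
    """Location/spread summary of one variable, form gated on normality."""

    n: int
    normal: bool | None  # None when n < 3 (gate not applicable)
    mean: float
    sd: float
    median: float
    iqr: float
    shapiro_p: float = float("nan")

    @property
    def form(self) -> str:
        return "mean (SD)" if self.normal else "median (IQR)"

    def __str__(self) -> str:
        if self.normal:
            return f"{self.mean:.2f} ({self.sd:.2f})"
        return f"{self.median:.2f} ({self.iqr:.2f})"


@dataclass
class ComparisonResult:
    """Outcome of one two-arm comparison."""

    name: str
    test: str  # paired-t | wilcoxon | independent-t | mann-whitney
    statistic: float
    p_value: float
    summary_x: Summary
    summary_y: Summary
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    n: int = 0
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "x": str(self.summary_x),
            "y": str(self.summary_y),
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "notes": self.notes,
        }


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def _is_normal(values: np.ndarray) -> tuple[bool, float]:
    if np.ptp(values) == 0:
        return False, float("nan")  # Shapiro undefined on constants
    stat_p = stats.shapiro(values).pvalue
    return bool(stat_p >= NORMALITY_ALPHA), float(stat_p)


def summarize(values) -> Summary:
    """Summarise a variable, choosing the form by a Shapiro–Wilk gate.

    Quartiles use linear interpolation (type-7), IQR = Q3 - Q1.  With
    fewer than 3 observations the gate cannot run; the summary is returned
    with ``normal=None`` (printed as median (IQR)).
    """
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty variable")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    normal: bool | None
    if arr.size < 3:
        normal, p = None, float("nan")
    else:
        normal, p = _is_normal(arr)
    return Summary(
        n=int(arr.size),
        normal=normal,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(np.median(arr)),
        iqr=float(q3 - q1),
        shapiro_p=p,
    )


def _wilcoxon(diff: np.ndarray) -> tuple[float, float]:
    nz = diff[diff != 0]
    if nz.size == 0:
        return float("nan"), 1.0  # all ties: no evidence of a shift
    method = "exact" if nz.size <= WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(nz, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def compare_paired(x, y, name: str = "") -> ComparisonResult:
    """Paired two-arm comparison with a normality-gated test choice.

    Pairs with a missing entry on either side are dropped.  The paired
    differences are Shapiro–Wilk-tested: normal differences go to the
    paired t-test, otherwise the Wilcoxon signed-rank test (exact null for
    n <= 25, normal approximation with continuity correction above).
    Spearman's rho of the retained pairs is recorded alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arms must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = x - y
    normal, _ = _is_normal(diff)
    if normal:
        res = stats.ttest_rel(x, y)
        test, statistic, p = "paired-t", float(res.statistic), float(res.pvalue)
    else:
        statistic, p = _wilcoxon(diff)
        test = "wilcoxon"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho, rho_p = float("nan"), float("nan")
    else:
        sp = stats.spearmanr(x, y)
        rho, rho_p = float(sp.statistic), float(sp.pvalue)
    return ComparisonResult(
        name=name,
        test=test,
        statistic=statistic,
        p_value=p,
        summary_x=summarize(x),
        summary_y=summarize(y),
        spearman_rho=rho,
        spearman_p=rho_p,
        n=int(x.size),
    )


def compare_unpaired(x, y, name: str = "") -> ComparisonResult:
    """Independent two-arm comparison (t-test or Mann–Whitney U).

    The parametric branch runs only when both arms pass the Shapiro–Wilk
    gate.
    """
    x, y = _clean(x), _clean(y)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per arm")
    normal = _is_normal(x)[0] and _is_normal(y)[0]
    if normal:
        res = stats.ttest_ind(x, y)
        test = "independent-t"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann-whitney"
    return ComparisonResult(
        name=name,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_x=summarize(x),
        summary_y=summarize(y),
        n=int(min(x.size, y.size)),
    )


def levene_variance(x, y, name: str = "") -> ComparisonResult:
    """Brown–Forsythe/Levene test of equal spread between two arms.

    Offered for variability comparisons between modalities; reported as a
    spread test, separate from the location tests above.
    """
    x, y = _clean(x), _clean(y)
    res = stats.levene(x, y, center="median")
    return ComparisonResult(
        name=name,
        test="levene",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_x=summarize(x),
        summary_y=summarize(y),
        n=int(min(x.size, y.size)),
        notes="spread comparison (Brown-Forsythe)",
    )
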