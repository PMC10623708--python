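"""Case-control statistics: 2x2 odds ratios, descriptive comparisons,
logistic screening and ROC evaluation.

Conventions, fixed so the univariate layer is exactly reproducible:

* Odds ratios from 2x2 tables use the cross-product estimate with a Woolf
  (log-scale Wald) confidence interval, SE = sqrt(1/a+1/b+1/c+1/d),
  normal quantile at the stated level, no continuity correction.
* Qualitative group comparisons use Pearson's chi-square without Yates
  correction when every expected cell is >= 5, Fisher's exact test
  otherwise.
* Quantitative comparisons gate on Shapiro-Wilk per group at alpha 0.05:
  Mann-Whitney U if either group is non-normal, Welch-free two-sample t
  otherwise.
* The univariate logistic screen keeps variables with p < 0.05 for the
  joint model; the joint model's per-record predicted probability is the
  ROC score.  The operating point maximizes Youden's J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import PatientRecord, records_to_dataframe

MODEL_VARIABLES = [
    "heavy_smoker", "cea", "ca125", "ca199",
    "other_nodules", "focal_fibrosis", "bulla",
    "dist1_indicator", "dist2_indicator",
]

BINARY_VARIABLES = {"heavy_smoker", "ex_or_current_smoker", "other_nodules",
                    "focal_fibrosis", "bulla", "dist1_indicator",
                    "dist2_indicator"}


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; the Woolf interval is undefined."""


class DegenerateTestError(ValueError):
    """The variable is constant; no group comparison is possible."""


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


class CollinearityError(ValueError):
    """Singular design matrix; lists the offending terms."""

    def __init__(self, terms: Sequence[str]):
        self.terms = list(terms)
        super().__init__(f"collinear terms: {', '.join(self.terms)}")


# ---------------------------------------------------------------------------
# 2x2 odds ratios
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """a: exposed cases, b: unexposed cases, c: exposed controls,
    d: unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord],
                     variable: str) -> "ContingencyTable":
        df = records_to_dataframe(records)
        v = df[variable].astype(int)
        y = df["outcome"].astype(int)
        return cls(a=int(((y == 1) & (v == 1)).sum()),
                   b=int(((y == 1) & (v == 0)).sum()),
                   c=int(((y == 0) & (v == 1)).sum()),
                   d=int(((y == 0) & (v == 0)).sum()))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class ORResult:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "woolf"

    def rounded(self, nd: int = 3) -> Tuple[float, float, float]:
        return (round(self.or_value, nd), round(self.ci_low, nd),
                round(self.ci_high, nd))


def odds_ratio_2x2(table: ContingencyTable,
                   confidence: float = 0.95) -> ORResult:
    """Cross-product odds ratio with a Woolf confidence interval.

    OR = (a*d)/(b*c); the CI is exp(log OR ± z * SE) with
    SE = sqrt(1/a + 1/b + 1/c + 1/d); the p-value is the two-sided Wald
    test of log OR = 0.  Any zero cell raises :class:`ZeroCellError` —
    no silent continuity correction is applied.
    """
    for name in "abcd":
        if getattr(table, name) == 0:
            raise ZeroCellError(
                f"cell {name} is zero; Woolf interval undefined")
    a, b, c, d = table.a, table.b, table.c, table.d
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    log_or = math.log(or_value)
    p = 2.0 * sps.norm.sf(abs(log_or) / se)
    return ORResult(or_value=or_value,
                    ci_low=math.exp(log_or - z * se),
                    ci_high=math.exp(log_or + z * se),
                    p_value=p)


# ---------------------------------------------------------------------------
# descriptive group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    variable: str
    test: str          # "chi2" | "fisher" | "mannwhitney" | "ttest"
    statistic: float
    p_value: float


def group_compare(records: Sequence[PatientRecord], variable: str,
                  alpha_normality: float = 0.05) -> GroupTestResult:
    """Compare one variable between cases and controls.

    Binary variables: chi-square (no Yates correction) when all expected
    cells are >= 5, otherwise Fisher's exact test.  Continuous variables:
    Shapiro-Wilk per group; Mann-Whitney U if either group departs from
    normality at ``alpha_normality``, else a two-sample t test.
    """
    df = records_to_dataframe(records)
    if variable not in df.columns:
        raise KeyError(variable)
    x = df[variable]
    if x.nunique() <= 1:
        raise DegenerateTestError(f"{variable} is constant across the cohort")
    case = x[df["outcome"] == 1].to_numpy()
    ctrl = x[df["outcome"] == 0].to_numpy()

    if variable in BINARY_VARIABLES:
        tab = ContingencyTable.from_records(records, variable).as_array()
        expected = sps.contingency.expected_freq(tab)
        if (expected >= 5).all():
            stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
            return GroupTestResult(variable, "chi2", float(stat), float(p))
        stat, p = sps.fisher_exact(tab)
        return GroupTestResult(variable, "fisher", float(stat), float(p))

    normal = all(sps.shapiro(g).pvalue >= alpha_normality
                 for g in (case, ctrl) if len(g) >= 3)
    if normal:
        stat, p = sps.ttest_ind(case, ctrl)
        return GroupTestResult(variable, "ttest", float(stat), float(p))
    stat, p = sps.mannwhitneyu(case, ctrl, alternative="two-sided")
    return GroupTestResult(variable, "mannwhitney", float(stat), float(p))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    terms: List[str]                  # excludes the intercept
    coefficients: np.ndarray          # log-odds incl. intercept, const first
    or_values: np.ndarray             # exp(coef) for the non-intercept terms
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    predicted: np.ndarray             # per-record probability ("joint predicted value")
    converged: bool = True

    def term_or(self, term: str) -> Tuple[float, float, float, float]:
        i = self.terms.index(term)
        return (float(self.or_values[i]), float(self.ci_low[i]),
                float(self.ci_high[i]), float(self.p_values[i]))


def _fit_logit(y: np.ndarray, X: pd.DataFrame,
               confidence: float = 0.95) -> LogisticFit:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    terms = list(X.columns)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        offending = []
        for j, t in enumerate(terms, start=1):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offending.append(t)
        raise CollinearityError(offending or terms)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or \
            not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 50:
        raise ConvergenceError(
            "logistic fit did not converge (possible perfect separation)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    coefs = res.params[1:]
    ses = res.bse[1:]
    return LogisticFit(
        terms=terms,
        coefficients=np.asarray(res.params),
        or_values=np.exp(coefs),
        ci_low=np.exp(coefs - z * ses),
        ci_high=np.exp(coefs + z * ses),
        p_values=np.asarray(res.pvalues[1:]),
        predicted=np.asarray(res.predict(design)),
    )


def fit_univariate(records: Sequence[PatientRecord], variable: str,
                   confidence: float = 0.95) -> LogisticFit:
    """Single-predictor binary logistic model by maximum likelihood."""
    df = records_to_dataframe(records)
    y = df["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateTestError("outcome does not vary")
    return _fit_logit(y, df[[variable]], confidence=confidence)


def fit_multivariate(records: Sequence[PatientRecord],
                     variables: Sequence[str] = MODEL_VARIABLES,
                     alpha_select: float = 0.05,
                     confidence: float = 0.95,
                     ) -> Tuple[LogisticFit, List[str]]:
    """Univariate screen then joint fit.

    Each candidate variable is first fit alone; those with Wald p <
    ``alpha_select`` enter the joint model together.  Returns the joint
    fit and the selected variable list (in candidate order).
    """
    df = records_to_dataframe(records)
    y = df["outcome"].to_numpy(dtype=float)
    selected = []
    for v in variables:
        try:
            uni = fit_univariate(records, v, confidence=confidence)
        except (ConvergenceError, DegenerateTestError, CollinearityError):
            # constant predictors surface as rank deficiency
            continue
        if uni.p_values[0] < alpha_select:
            selected.append(v)
    if not selected:
        raise DegenerateTestError(
            f"no variable passed the univariate screen at p < {alpha_select}")
    return _fit_logit(y, df[selected], confidence=confidence), selected


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    ci_method: str = "delong"


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_auc_variance(y: np.ndarray, scores: np.ndarray) -> Tuple[float, float]:
    """AUC and its DeLong variance from the placement values.

    Structural components: V10_i = fraction of controls scored below case
    i (ties half-weighted), V01_j analogously for controls; the variance
    is s10/m + s01/n.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateTestError("ROC undefined: single-class outcome")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc ** 2)
            + (n - 1) * (q2 - auc ** 2)) / (m * n)


def roc_analysis(y_true: np.ndarray, scores: np.ndarray,
                 confidence: float = 0.95,
                 ci_method: str = "delong") -> ROCResult:
    """Empirical ROC with trapezoidal AUC, CI and the Youden point.

    The AUC equals the Mann-Whitney concordance probability (ties count
    one half).  The operating point maximizes Youden's J = sensitivity +
    specificity - 1; among ties the highest-sensitivity point is taken.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateTestError("ROC undefined: single-class outcome")
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    m, n = int((y == 1).sum()), int((y == 0).sum())
    if ci_method == "delong":
        auc_d, var = delong_auc_variance(y, scores)
        auc = auc_d
    elif ci_method == "hanley-mcneil":
        var = _hanley_mcneil_variance(auc, m, n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(max(var, 0.0))

    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[-1])  # thresholds decrease: last max has top sensitivity
    return ROCResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
        fpr=fpr, tpr=tpr, thresholds=thresholds,
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# simulation utilities
# ---------------------------------------------------------------------------

def simulate_null_coverage(n_sims: int = 1000, n_case: int = 200,
                           n_control: int = 200, prevalence: float = 0.5,
                           confidence: float = 0.95, seed: int = 0) -> float:
    """Empirical coverage of the Woolf interval under a null exposure.

    Draws per-group exposed counts from the same binomial in cases and
    controls (true OR = 1), computes the ``confidence``-level Woolf
    interval for each simulated 2x2 table, and returns the fraction
    containing 1.  Tables with a zero cell (where the interval is
    undefined) are excluded from the denominator.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    valid = 0
    for _ in range(n_sims):
        a = int(rng.binomial(n_case, prevalence))
        c = int(rng.binomial(n_control, prevalence))
        table = ContingencyTable(a=a, b=n_case - a, c=c, d=n_control - c)
        try:
            res = odds_ratio_2x2(table, confidence=confidence)
        except ZeroCellError:
            continue
        valid += 1
        covered += int(res.ci_low <= 1.0 <= res.ci_high)
    if valid == 0:
        raise DegenerateTestError("all simulated tables had a zero cell")
    return covered / valid


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def format_percent(k: int, n: int) -> str:
    """Count with one-decimal percentage, trailing ".0" dropped: "24(50%)"."""
    pct = round(100.0 * k / n, 1) if n else 0.0
    return f"{k}({pct:g}%)"


def _fmt_median_iqr(x: np.ndarray) -> str:
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    return f"{round(float(med), 2):g}({round(float(q3 - q1), 2):g})"


_TABLE1_LAYOUT = [
    ("age", "Age, years", "quantitative"),
    ("ex_or_current_smoker", "Ex-or-current smokers", "binary"),
    ("heavy_smoker", "Pack-years >= 20", "binary"),
    ("cea", "CEA(ng/ml)", "quantitative"),
    ("ca125", "CA125(U/ml)", "quantitative"),
    ("ca199", "CA199(U/ml)", "quantitative"),
    ("other_nodules", "Other nodules", "binary"),
    ("focal_fibrosis", "Focal fibrosis", "binary"),
    ("bulla", "Bulla", "binary"),
]

_INTERVAL_ROWS = [
    ("dist1_indicator", "Interval distribution 1",
     "[-950,-850)", "[-850,-750)"),
    ("dist2_indicator", "Interval distribution 2",
     "[-950,-900)", "[-900,-850)"),
]


def build_table1(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort description: n(%) or median(IQR) per group, with p-values.

    Binary rows render as "k(p%)" with the percentage at one decimal;
    the interval features render as two category rows (reference
    lower-HU interval first), sharing one p-value, as in a standard
    case-control characteristics table.
    """
    df = records_to_dataframe(records)
    case = df[df["outcome"] == 1]
    ctrl = df[df["outcome"] == 0]
    n1, n0 = len(case), len(ctrl)
    rows = []

    def pval(variable):
        try:
            return round(group_compare(records, variable).p_value, 3)
        except DegenerateTestError:
            return float("nan")

    for var, label, kind in _TABLE1_LAYOUT:
        if kind == "binary":
            rows.append({
                "variable": label,
                "case": format_percent(int(case[var].sum()), n1),
                "control": format_percent(int(ctrl[var].sum()), n0),
                "p_value": pval(var),
            })
        else:
            rows.append({
                "variable": label,
                "case": _fmt_median_iqr(case[var].to_numpy()),
                "control": _fmt_median_iqr(ctrl[var].to_numpy()),
                "p_value": pval(var),
            })

    for var, header, ref_label, alt_label in _INTERVAL_ROWS:
        p = pval(var)
        k1, k0 = int(case[var].sum()), int(ctrl[var].sum())
        rows.append({"variable": header, "case": "", "control": "",
                     "p_value": p})
        rows.append({"variable": f"  {ref_label}",
                     "case": format_percent(n1 - k1, n1),
                     "control": format_percent(n0 - k0, n0),
                     "p_value": float("nan")})
        rows.append({"variable": f"  {alt_label}",
                     "case": format_percent(k1, n1),
                     "control": format_percent(k0, n0),
                     "p_value": float("nan")})
    return pd.DataFrame(rows, columns=["variable", "case", "control", "p_value"])


def build_table2(records: Sequence[PatientRecord],
                 variables: Sequence[str] = MODEL_VARIABLES,
                 alpha_select: float = 0.05,
                 ) -> Tuple[pd.DataFrame, Optional[LogisticFit], List[str]]:
    """Univariate and multivariate odds-ratio table.

    One row per candidate variable with the univariate logistic OR
    (95% CI) and p-value; multivariate columns filled for the variables
    that passed the screen.  ORs are reported to 3 decimals.
    """
    rows = []
    uni_results: Dict[str, LogisticFit] = {}
    for v in variables:
        try:
            uni_results[v] = fit_univariate(records, v)
        except (ConvergenceError, DegenerateTestError):
            uni_results[v] = None
    try:
        multi, selected = fit_multivariate(records, variables,
                                           alpha_select=alpha_select)
    except (DegenerateTestError, ConvergenceError, CollinearityError):
        multi, selected = None, []

    for v in variables:
        uni = uni_results[v]
        row = {"variable": v, "or_univariate": np.nan, "ci_univariate": "",
               "p_univariate": np.nan, "or_multivariate": np.nan,
               "ci_multivariate": "", "p_multivariate": np.nan}
        if uni is not None:
            orv, lo, hi, p = uni.term_or(v)
            row.update(or_univariate=round(orv, 3),
                       ci_univariate=f"({round(lo, 3):g} ~ {round(hi, 3):g})",
                       p_univariate=round(p, 3))
        if multi is not None and v in selected:
            orv, lo, hi, p = multi.term_or(v)
            row.update(or_multivariate=round(orv, 3),
                       ci_multivariate=f"({round(lo, 3):g} ~ {round(hi, 3):g})",
                       p_multivariate=round(p, 3))
        rows.append(row)
    return pd.DataFrame(rows), multi, selected
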