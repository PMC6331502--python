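"""The group-comparison and correlation battery used by the analysis pipeline.

Pure functions over summary statistics or tidy arrays:

* pooled-variance independent t-tests with Cohen's d (pooled SD denominator);
* mixed-design repeated-measures ANOVA reported via the multivariate approach
  (Wilks' lambda on within-subject difference scores, exact F for
  single-degree hypotheses, Rao's approximation otherwise) with partial
  eta squared;
* normality-gated correlations (Pearson, or Spearman when a Shapiro-Wilk test
  rejects normality at alpha = .05), p-values from the t approximation on
  n - 2 degrees of freedom, with directional one-tailed handling;
* Tukey 1.5 x IQR outlier fences (Tukey hinges by default, SPSS-style
  weighted-average quartiles as an option);
* comparison of independent correlations (Fisher's r-to-z) and of dependent
  correlations sharing one variable (Steiger's Z);
* Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult", "AnovaResult", "CorrelationResult", "CorrComparisonResult",
    "pooled_t_and_d", "eta_p2_from_F", "mixed_anova", "correlation",
    "p_from_r", "tukey_outliers", "fisher_z", "steiger_z", "bonferroni",
    "shapiro_wilk",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d, pooled-SD denominator


@dataclass(frozen=True)
class AnovaResult:
    effect: str  # "group", "within", or "interaction"
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    wilks_lambda: float | None = None  # multivariate effects only


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    r: float
    n: int
    p: float
    tails: int
    normality_gate: tuple = ()  # Shapiro-Wilk p-values that chose the method


@dataclass(frozen=True)
class CorrComparisonResult:
    kind: str  # "independent_fisher" or "dependent_steiger"
    z: float
    p: float
    inputs: dict = field(default_factory=dict)


# ---------------------------------------------------------------- t / d ----

def pooled_t_and_d(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> TTestResult:
    """Independent-samples t-test and Cohen's d from group summary statistics.

    Pooled SD: s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2));
    t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2)); d = (m1 - m2) / s_p.
    With equal n, s_p reduces to sqrt((s1^2 + s2^2)/2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df)
    diff = mean1 - mean2
    if sp == 0.0:
        if diff != 0.0:
            raise ZeroDivisionError("zero pooled SD with nonzero mean difference")
        return TTestResult(0.0, df, 1.0, 0.0)
    t = diff / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t, df, p, diff / sp)


def eta_p2_from_F(F: float, df1: float, df2: float) -> float:
    """Partial eta squared implied by an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


# ------------------------------------------------------------ mixed ANOVA ----

def _wilks_test(effect: str, L: np.ndarray, B: np.ndarray, XtX_inv: np.ndarray,
                E: np.ndarray, ve: int) -> AnovaResult:
    """Wilks' lambda test of L @ B = 0 in a multivariate linear model."""
    H_mid = np.linalg.inv(L @ XtX_inv @ L.T)
    LB = L @ B
    H = LB.T @ H_mid @ LB
    p = E.shape[0]          # number of difference-score variates
    q = L.shape[0]          # hypothesis degrees of freedom
    det_E = np.linalg.det(E)
    det_EH = np.linalg.det(E + H)
    if det_EH <= 0 or det_E < 0:
        raise np.linalg.LinAlgError("singular error SSCP (rank-deficient design)")
    lam = det_E / det_EH
    if q == 1:
        df1 = float(p)
        df2 = float(ve - p + 1)
        F = (df2 / df1) * (1.0 - lam) / lam if lam > 0 else math.inf
        eta = 1.0 - lam
    else:  # Rao's F approximation
        s = math.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0)) \
            if (p * p + q * q - 5.0) > 0 else 1.0
        df1 = float(p * q)
        df2 = s * (ve - (p - q + 1.0) / 2.0) - (p * q - 2.0) / 2.0
        lam_s = lam ** (1.0 / s)
        F = ((1.0 - lam_s) / lam_s) * (df2 / df1) if lam_s > 0 else math.inf
        eta = 1.0 - lam_s
    p_value = float(sps.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return AnovaResult(effect, float(F), df1, df2, p_value, float(eta), float(lam))


def mixed_anova(data, groups) -> dict[str, AnovaResult]:
    """Mixed-design repeated-measures ANOVA (multivariate approach).

    ``data`` is an (N subjects x k within-levels) matrix of the dependent
    variable; ``groups`` the between-subject factor labels.  Returns the
    between-subjects ``group`` effect (classical F on subject means) plus the
    ``within`` and ``interaction`` effects tested multivariately on the k-1
    successive difference scores: Wilks' lambda with error df N - g, giving
    the exact F(k-1, N - g - (k-1) + 1) for two groups.  Partial eta squared
    is F*df1/(F*df1+df2) between subjects and 1 - lambda^(1/s) multivariately.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("data must be an N x k matrix with k >= 2 within levels")
    if not np.all(np.isfinite(Y)):
        raise ValueError("data must be complete (no missing cells)")
    labels = np.asarray(groups)
    if labels.shape[0] != Y.shape[0]:
        raise ValueError("groups length must match the number of subjects")
    N, k = Y.shape
    unique = list(dict.fromkeys(labels.tolist()))
    g = len(unique)
    if any(np.sum(labels == u) < 2 for u in unique):
        raise ValueError("each group needs at least 2 subjects")

    # Between-subjects effect: one-way ANOVA on subject means.
    means = Y.mean(axis=1)
    grand = means.mean()
    group_means = {u: means[labels == u].mean() for u in unique}
    ss_between = sum(np.sum(labels == u) * (group_means[u] - grand) ** 2
                     for u in unique)
    ss_within = sum(float(np.sum((means[labels == u] - group_means[u]) ** 2))
                    for u in unique)
    df1_b, df2_b = g - 1, N - g
    if ss_within == 0.0:
        F_b = math.inf if ss_between > 0 else 0.0
    else:
        F_b = (ss_between / df1_b) / (ss_within / df2_b)
    p_b = float(sps.f.sf(F_b, df1_b, df2_b)) if math.isfinite(F_b) else 0.0
    results = {"group": AnovaResult("group", float(F_b), float(df1_b),
                                    float(df2_b), p_b,
                                    eta_p2_from_F(F_b, df1_b, df2_b)
                                    if math.isfinite(F_b) else 1.0)}

    # Multivariate within-subject tests on successive difference scores.
    D = Y[:, 1:] - Y[:, :-1]                       # N x (k-1)
    # Effect-coded design: intercept + (g-1) group contrasts (Type III means).
    X = np.ones((N, g))
    for j, u in enumerate(unique[:-1]):
        X[:, j + 1] = np.where(labels == u, 1.0, 0.0)
    # effect coding: last group carries -1 on every contrast column
    for j in range(1, g):
        X[labels == unique[-1], j] = -1.0
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ D
    resid = D - X @ B
    E = resid.T @ resid
    ve = N - g
    L_within = np.zeros((1, g)); L_within[0, 0] = 1.0
    L_inter = np.zeros((g - 1, g)); L_inter[:, 1:] = np.eye(g - 1)
    results["within"] = _wilks_test("within", L_within, B, XtX_inv, E, ve)
    results["interaction"] = _wilks_test("interaction", L_inter, B, XtX_inv, E, ve)
    return results


# ------------------------------------------------------------ correlations ----

def p_from_r(r: float, n: int, tails: int = 2, direction: str | None = None) -> float:
    """p-value for a correlation via the t approximation on n-2 df.

    One-tailed p is half the two-tailed p when the observed sign matches the
    pre-stated ``direction`` ("negative"/"positive"), else 1 - p/2.
    """
    if not (-1.0 < r < 1.0):
        return 0.0 if abs(r) == 1.0 else math.nan
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p2 = 2.0 * sps.t.sf(abs(t), df)
    if tails == 2:
        return p2
    if tails != 1:
        raise ValueError("tails must be 1 or 2")
    if direction not in ("negative", "positive"):
        raise ValueError("one-tailed tests need direction 'negative' or 'positive'")
    matches = (r < 0) if direction == "negative" else (r > 0)
    return p2 / 2.0 if matches or r == 0 else 1.0 - p2 / 2.0


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); errors on degenerate input."""
    x = np.asarray(values, dtype=float)
    if x.size < 4 or x.size > 2000:
        raise ValueError("Shapiro-Wilk supported for 4 <= n <= 2000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def correlation(x, y, tails: int = 2, gate: str = "auto",
                direction: str | None = None, alpha: float = 0.05) -> CorrelationResult:
    """Correlate two samples with a Shapiro-Wilk normality gate.

    ``gate='auto'`` uses Pearson unless either variable rejects normality at
    ``alpha``, in which case Spearman's rho is used; ``gate='pearson'`` or
    ``'spearman'`` forces the method.  p-values use the t approximation so
    that printed one-tailed values are reproduced for both methods.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = xv.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("zero-variance variable: correlation undefined")
    gate_ps: tuple = ()
    if gate == "auto":
        gate_ps = (shapiro_wilk(xv)[1], shapiro_wilk(yv)[1])
        method = "spearman" if min(gate_ps) < alpha else "pearson"
    elif gate in ("pearson", "spearman"):
        method = gate
    else:
        raise ValueError("gate must be 'auto', 'pearson' or 'spearman'")
    if method == "pearson":
        r = float(sps.pearsonr(xv, yv).statistic)
    else:
        r = float(sps.spearmanr(xv, yv).statistic)
    return CorrelationResult(method, r, n, p_from_r(r, n, tails, direction),
                             tails, gate_ps)


# ----------------------------------------------------------- outliers ----

def _tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    s = np.sort(x)
    n = s.size
    half = (n + 1) // 2
    lower = s[:half]
    upper = s[-half:]
    return float(np.median(lower)), float(np.median(upper))


def tukey_outliers(values, method: str = "hinges") -> list[int]:
    """Indices of values outside the 1.5 x IQR fences.

    ``method='hinges'`` uses Tukey's fourths (median of each half, median
    included when n is odd); ``method='haverage'`` uses the weighted-average
    quartile definition SPSS applies in EXAMINE.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 for fences")
    if method == "hinges":
        q1, q3 = _tukey_hinges(x)
    elif method == "haverage":
        q1, q3 = np.percentile(x, [25, 75], method="weibull")
    else:
        raise ValueError("method must be 'hinges' or 'haverage'")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [int(i) for i in np.flatnonzero((x < lo) | (x > hi))]


# ------------------------------------------- correlation comparisons ----

def fisher_z(r1: float, n1: int, r2: float, n2: int) -> CorrComparisonResult:
    """Compare two correlations from independent samples (r-to-z transform).

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
        if n < 4:
            raise ValueError("need n >= 4 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return CorrComparisonResult("independent_fisher", z, 2.0 * sps.norm.sf(abs(z)),
                                {"r1": r1, "n1": n1, "r2": r2, "n2": n2})


def steiger_z(r12: float, r13: float, r23: float, n: int) -> CorrComparisonResult:
    """Steiger's Z for two dependent correlations sharing variable 1.

    Tests H0: rho12 = rho13 given the inter-correlation r23 of the two
    non-shared variables, using Fisher-transformed correlations and the
    shared-variable covariance correction (Steiger 1980, Eq. 14 with the
    pooled estimate rbar = (r12 + r13)/2).
    """
    if n < 5:
        raise ValueError("need n >= 5")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("(r12, r13, r23) is not a valid correlation matrix")
    if not (abs(r12) < 1.0 and abs(r13) < 1.0):
        raise ValueError("correlations must satisfy |r| < 1")
    rbar = 0.5 * (r12 + r13)
    psi = r23 * (1.0 - 2.0 * rbar ** 2) - 0.5 * rbar ** 2 * (
        1.0 - 2.0 * rbar ** 2 - r23 ** 2)
    s = psi / (1.0 - rbar ** 2) ** 2
    z = (math.atanh(r12) - math.atanh(r13)) * math.sqrt(
        (n - 3.0) / (2.0 - 2.0 * s))
    return CorrComparisonResult("dependent_steiger", z, 2.0 * sps.norm.sf(abs(z)),
                                {"r12": r12, "r13": r13, "r23": r23, "n": n})


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni decisions: significant iff p < alpha/m (m defaults to len)."""
    ps = list(p_values)
    m = m if m is not None else len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return {
        "threshold": threshold,
        "significant": [p < threshold for p in ps],
        "adjusted_p": [min(1.0, p * m) for p in ps],
    }
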