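"""Case-control statistics for per-subject haemodynamic metric tables.

The analysis mirrors the standard small-cohort workflow: Shapiro-Wilk
normality screening routes each metric to Student's t or Mann-Whitney U;
the dirWSSG split is tested with Fisher's exact test and summarised as a
Wald odds ratio; candidate predictors pass a univariate logistic screen
(p < 0.1) deduplicated by Spearman correlation (p < 0.05 pairs keep the
stronger candidate); the survivors enter a multivariate logistic model whose
linear predictor provides the risk score; discrimination is quantified by an
empirical ROC curve with a Youden-optimal cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "Contingency2x2",
    "LogisticModel",
    "RocResult",
    "GroupComparison",
    "SeparationError",
    "normality_test",
    "compare_groups",
    "fisher_exact",
    "odds_ratio_wald",
    "spearman",
    "logistic_fit",
    "select_variables",
    "logistic_score",
    "roc",
    "validate_cohort",
    "contingency_from_cohort",
    "analyze_cohort",
    "CohortReport",
]

METRICS = ("WSS", "WSSG", "absWSSG", "OSI", "dirWSSG")
REQUIRED_COLUMNS = ("subject_id", "group") + METRICS


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class Contingency2x2:
    """Counts: a = case/dir+, b = control/dir+, c = case/dir-, d = control/dir-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald inference per coefficient."""

    names: list[str]
    coef: np.ndarray  # includes intercept first
    se: np.ndarray
    odds_ratios: np.ndarray  # exp(coef), intercept included for completeness
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_sensitivity: float
    optimal_specificity: float


@dataclass
class GroupComparison:
    test: str  # "mann-whitney" | "t-test"
    statistic: float
    p_value: float
    median_x: float
    iqr_x: tuple[float, float]
    median_y: float
    iqr_y: tuple[float, float]


def normality_test(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk (W, p); degenerate (constant) samples are rejected."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def compare_groups(x: np.ndarray, y: np.ndarray, alpha_normal: float = 0.05,
                   min_n_parametric: int = 8) -> GroupComparison:
    """Two-group comparison routed by normality.

    Both groups Shapiro-normal (p > ``alpha_normal``) -> Student's t;
    otherwise Mann-Whitney U (exact for small untied samples, tie-corrected
    normal approximation otherwise).  Groups smaller than
    ``min_n_parametric`` go nonparametric outright — Shapiro-Wilk has no
    power there.  Summaries are median (25th-75th pct).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    try:
        normal = (min(len(x), len(y)) >= min_n_parametric
                  and normality_test(x)[1] > alpha_normal
                  and normality_test(y)[1] > alpha_normal)
    except ValueError:
        normal = False
    if normal:
        stat, p = stats.ttest_ind(x, y, equal_var=True)
        name = "t-test"
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        name = "mann-whitney"
    qx = np.percentile(x, [25, 75])
    qy = np.percentile(y, [25, 75])
    return GroupComparison(test=name, statistic=float(stat), p_value=float(p),
                           median_x=float(np.median(x)), iqr_x=(float(qx[0]), float(qx[1])),
                           median_y=float(np.median(y)), iqr_y=(float(qy[0]), float(qy[1])))


def fisher_exact(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p (probability-mass rule over fixed margins)."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio_wald(t: Contingency2x2) -> tuple[float, float, float, bool]:
    """(OR, CI95 low, CI95 high, corrected) with the Wald log-OR interval.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.96  # conventional reporting value for the 95% Wald interval
    return (float(or_), float(np.exp(np.log(or_) - z * se)),
            float(np.exp(np.log(or_) + z * se)), corrected)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation (rho, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("Spearman needs paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def logistic_fit(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                 names: list[str] | None = None, tol: float = 1e-8,
                 maxiter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald ORs, CIs and p-values.

    Fitting is Newton / IRLS via statsmodels.  Perfect separation raises
    :class:`SeparationError`; non-convergence is flagged, never silent.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError("perfect separation: logistic MLE does not exist") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = stats.norm.ppf(0.975)
    return LogisticModel(
        names=["intercept"] + list(names),
        coef=coef,
        se=se,
        odds_ratios=np.exp(coef),
        ci_low=np.exp(coef - z * se),
        ci_high=np.exp(coef + z * se),
        p_values=np.asarray(res.pvalues),
        converged=converged,
        n_obs=int(len(y)),
    )


def select_variables(univariate_p: dict[str, float],
                     correlations: dict[tuple[str, str], tuple[float, float]],
                     p_enter: float = 0.1, corr_alpha: float = 0.05) -> list[str]:
    """Univariate screen + correlation dedup.

    Keep candidates with univariate p < ``p_enter``; among any pair whose
    correlation is significant (p < ``corr_alpha``) keep the one with the
    smaller univariate p.  Returns the kept names sorted alphabetically.
    """
    candidates = sorted((p, name) for name, p in univariate_p.items() if p < p_enter)
    corr_p = {}
    for (a, b), (_, p) in correlations.items():
        corr_p[frozenset((a, b))] = p
    kept: list[str] = []
    for p, name in candidates:
        clash = any(corr_p.get(frozenset((name, k)), 1.0) < corr_alpha for k in kept)
        if not clash:
            kept.append(name)
    return sorted(kept)


def logistic_score(wss: float | np.ndarray, wssg: float | np.ndarray,
                   coef: tuple[float, float, float] | LogisticModel) -> np.ndarray | float:
    """Risk score 1 / (1 + exp(-(b0 + b1*WSS + b2*WSSG))).

    ``coef`` is either an (intercept, WSS, WSSG) triple or a fitted two-
    predictor :class:`LogisticModel` in that column order.
    """
    if isinstance(coef, LogisticModel):
        b0, b1, b2 = coef.coef[:3]
    else:
        b0, b1, b2 = coef
    eta = b0 + b1 * np.asarray(wss, dtype=float) + b2 * np.asarray(wssg, dtype=float)
    out = 1.0 / (1.0 + np.exp(-eta))
    return float(out) if np.ndim(out) == 0 else out


def roc(scores: np.ndarray, labels: np.ndarray, cutoff_rule: str = "youden") -> RocResult:
    """Empirical ROC over all unique score thresholds.

    AUC by trapezoid; the optimal cutoff maximises Youden's J = sensitivity +
    specificity - 1, ties broken toward the higher sensitivity.
    """
    if cutoff_rule != "youden":
        raise ValueError(f"unknown cutoff rule {cutoff_rule!r}")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    cand = np.flatnonzero(j >= best_j - 1e-12)
    best = cand[np.argmax(tpr[cand])]
    return RocResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        optimal_cutoff=float(thr[best]),
        optimal_sensitivity=float(tpr[best]),
        optimal_specificity=float(1.0 - fpr[best]),
    )


# ---------------------------------------------------------------------------
# table-level pipeline


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema and range checks; Jensen consistency is a warning only
    (marginally calibrated synthetic cohorts need not satisfy it row-wise)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    groups = set(df["group"].unique())
    if groups - {"case", "control"} or len(groups) < 2:
        raise ValueError("group column must contain both 'case' and 'control'")
    if df["OSI"].min() < 0 or df["OSI"].max() > 0.5:
        raise ValueError("OSI out of [0, 0.5]")
    if set(df["dirWSSG"].unique()) - {0, 1}:
        raise ValueError("dirWSSG must be encoded 1 (positive) / 0 (negative)")
    if np.any(df["absWSSG"] < np.abs(df["WSSG"]) - 1e-9):
        # holds for any pipeline-computed region (Jensen), but marginally
        # calibrated synthetic cohorts need not satisfy it row-wise
        warnings.warn("some rows violate absWSSG >= |WSSG|")


def contingency_from_cohort(df: pd.DataFrame) -> Contingency2x2:
    case = df["group"] == "case"
    pos = df["dirWSSG"] == 1
    return Contingency2x2(a=int((case & pos).sum()), b=int((~case & pos).sum()),
                          c=int((case & ~pos).sum()), d=int((~case & ~pos).sum()))


@dataclass
class CohortReport:
    """Everything the study-level analysis produces."""

    group_comparisons: pd.DataFrame  # per metric: medians, IQRs, test, p
    contingency: Contingency2x2
    fisher_p: float
    odds_ratio: tuple[float, float, float, bool]
    univariate: pd.DataFrame  # per predictor: OR, CI, p
    correlations: dict
    selected: list[str]
    multivariate: LogisticModel | None
    roc_wssg: RocResult | None
    roc_combined: RocResult | None
    score_coefficients: tuple[float, float, float] | None = None
    notes: list[str] = field(default_factory=list)


def analyze_cohort(df: pd.DataFrame) -> CohortReport:
    """Full case-control analysis of a cohort table.

    Produces the group-comparison summary, the dirWSSG contingency analysis,
    the univariate logistic screen, the Spearman correlation dedup, the
    multivariate model with its scoring coefficients, and ROC curves for raw
    WSSG and for the multivariate risk score.
    """
    validate_cohort(df)
    y = (df["group"] == "case").to_numpy(dtype=int)
    notes: list[str] = []

    rows = []
    for m in ("WSS", "WSSG", "absWSSG", "OSI"):
        cmp_ = compare_groups(df.loc[y == 1, m], df.loc[y == 0, m])
        rows.append({
            "metric": m, "test": cmp_.test, "p": cmp_.p_value,
            "case_median": cmp_.median_x, "case_q25": cmp_.iqr_x[0], "case_q75": cmp_.iqr_x[1],
            "control_median": cmp_.median_y, "control_q25": cmp_.iqr_y[0],
            "control_q75": cmp_.iqr_y[1],
        })
    table1 = pd.DataFrame(rows)

    cont = contingency_from_cohort(df)
    fisher_p = fisher_exact(cont)
    or_ci = odds_ratio_wald(cont)

    uni_rows = []
    uni_p = {}
    for m in METRICS:
        try:
            model = logistic_fit(df[[m]].to_numpy(), y, names=[m])
            uni_rows.append({"metric": m, "OR": model.odds_ratios[1],
                             "ci_low": model.ci_low[1], "ci_high": model.ci_high[1],
                             "p": model.p_values[1]})
            uni_p[m] = float(model.p_values[1])
        except SeparationError:
            notes.append(f"univariate fit for {m} separated; excluded from screen")
    univariate = pd.DataFrame(uni_rows)

    correlations = {}
    for i, a in enumerate(METRICS):
        for b in METRICS[i + 1:]:
            try:
                correlations[(a, b)] = spearman(df[a], df[b])
            except ValueError:
                continue

    selected = select_variables(uni_p, correlations)
    multivariate = None
    score_coefs = None
    roc_combined = None
    if selected:
        try:
            multivariate = logistic_fit(df[selected], y)
            if not multivariate.converged:
                notes.append("multivariate fit did not converge")
            score = multivariate.predict(df[selected].to_numpy(dtype=float))
            roc_combined = roc(score, y)
            if selected == ["WSS", "WSSG"]:
                score_coefs = tuple(float(c) for c in multivariate.coef[:3])
        except SeparationError:
            notes.append("multivariate fit separated")
    roc_wssg = roc(df["WSSG"].to_numpy(dtype=float), y)

    return CohortReport(group_comparisons=table1, contingency=cont, fisher_p=fisher_p,
                        odds_ratio=or_ci, univariate=univariate, correlations=correlations,
                        selected=selected, multivariate=multivariate, roc_wssg=roc_wssg,
                        roc_combined=roc_combined, score_coefficients=score_coefs,
                        notes=notes)
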