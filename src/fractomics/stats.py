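"""Outcome modelling: univariate screening, logistic fits, ROC and CV.

The analysis pipeline mirrors common radiomics practice for a binary
endpoint (here 5-year disease-free survival, 5yDFS): each feature is
screened with a two-group test routed by Shapiro-Wilk normality
(t-test when both groups look normal, Wilcoxon-Mann-Whitney otherwise);
the best feature enters a single-covariate logistic regression per
cohort; model discrimination is summarized by the AUC with a
class-stratified percentile bootstrap CI, an operating point chosen by
Youden's J, and repeated stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.model_selection import StratifiedKFold

NORMALITY_ALPHA = 0.05


class InsufficientDataError(ValueError):
    """Too few observations for the requested test or fit."""


class SingleClassError(ValueError):
    """Both outcome classes must be present."""


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class LogisticModel:
    """Single-feature logistic model: logit p = beta0 + beta1 * x.

    ``se*`` are Wald standard errors from the observed information,
    ``p*`` the two-sided Wald p-values. Models built from published
    coefficient tables may carry NaN standard errors.
    """

    beta0: float
    beta1: float
    se0: float = float("nan")
    se1: float = float("nan")
    p0: float = float("nan")
    p1: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return {
            "beta0": self.beta0, "beta1": self.beta1,
            "se0": self.se0, "se1": self.se1,
            "p0": self.p0, "p1": self.p1,
        }


def predict_prob(model: LogisticModel, fd: float | np.ndarray) -> float | np.ndarray:
    """Predicted outcome probability: inverse-logit(beta0 + beta1 * fd)."""
    eta = model.beta0 + model.beta1 * np.asarray(fd, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.isscalar(fd) or np.ndim(fd) == 0 else p


def route_test(values_group0: np.ndarray, values_group1: np.ndarray) -> str:
    """Choose 't' when Shapiro-Wilk accepts normality in both groups, else 'WMW'."""
    g0 = np.asarray(values_group0, dtype=float)
    g1 = np.asarray(values_group1, dtype=float)
    if len(g0) < 3 or len(g1) < 3:
        raise InsufficientDataError("Shapiro-Wilk needs >= 3 values per group")
    p0 = sps.shapiro(g0).pvalue
    p1 = sps.shapiro(g1).pvalue
    return "t" if (p0 >= NORMALITY_ALPHA and p1 >= NORMALITY_ALPHA) else "WMW"


@dataclass
class UnivariateResult:
    feature_name: str
    normality_p: float
    test_used: str
    p_value: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < 0.05


def univariate_screen(
    table: pd.DataFrame,
    outcome: str = "dfs5y",
    feature_columns: list[str] | None = None,
) -> list[UnivariateResult]:
    """Screen every feature column for a two-group outcome difference.

    Missing values are dropped pairwise; constant features are excluded.
    Results are sorted by ascending p-value.
    """
    y = table[outcome].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise SingleClassError("outcome has a single class")
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns
            if c not in (outcome, "patient_id", "regimen")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    results = []
    for col in feature_columns:
        x = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(x)
        xv, yv = x[keep], y[keep]
        g0 = xv[yv == classes[0]]
        g1 = xv[yv == classes[1]]
        if len(g0) < 3 or len(g1) < 3 or np.ptp(xv) == 0:
            continue  # constant or too sparse: no variance to test
        test = route_test(g0, g1)
        norm_p = min(sps.shapiro(g0).pvalue, sps.shapiro(g1).pvalue)
        if test == "t":
            p = sps.ttest_ind(g0, g1).pvalue
        else:
            p = sps.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
        results.append(UnivariateResult(col, float(norm_p), test, float(p)))
    results.sort(key=lambda r: r.p_value)
    return results


def fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticModel:
    """Maximum-likelihood single-feature logistic fit.

    Uses iteratively reweighted least squares; standard errors come from
    the observed information and p-values from two-sided Wald tests.
    Perfect separation is detected and reported rather than returning a
    diverged fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise SingleClassError("outcomes are all identical")
    # perfect separation: some threshold on x splits the classes exactly
    if max(x[y == 0].max(), -np.inf) < min(x[y == 1].min(), np.inf) or \
       max(x[y == 1].max(), -np.inf) < min(x[y == 0].min(), np.inf):
        raise SeparationError("perfect separation: logistic MLE does not exist")
    X = sm.add_constant(x)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise SeparationError("logistic fit diverged")
    return LogisticModel(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        se0=float(res.bse[0]), se1=float(res.bse[1]),
        p0=float(res.pvalues[0]), p1=float(res.pvalues[1]),
    )


@dataclass
class RocAnalysis:
    """AUC with bootstrap CI and the Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    best_threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    n_boot: int

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "best_threshold": self.best_threshold, "youden_j": self.youden_j,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "n_boot": self.n_boot,
        }


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic; ties count one half."""
    ranks = sps.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _youden_point(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """Maximize J = sens + spec - 1 over observed thresholds.

    A prediction is positive when score >= threshold. Ties in J are
    broken toward higher specificity (the higher threshold).
    """
    thresholds = np.unique(scores)
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    best = (-np.inf, -np.inf, 0.0, 0.0, 0.0)  # (J, spec, thr, sens, spec)
    for thr in thresholds:
        pred = scores >= thr
        sens = float((pred & pos).sum() / n1)
        spec = float((~pred & ~pos).sum() / n0)
        j = sens + spec - 1.0
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, float(thr), sens, spec)
    return best[2], best[0], best[3], best[4]


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> RocAnalysis:
    """AUC with class-stratified percentile-bootstrap 95% CI and Youden cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("ROC needs both outcome classes")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    auc = _auc_mann_whitney(scores, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        s1 = rng.choice(idx1, size=len(idx1), replace=True)
        s0 = rng.choice(idx0, size=len(idx0), replace=True)
        idx = np.concatenate([s1, s0])
        boot[b] = _auc_mann_whitney(scores[idx], labels[idx])
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    thr, j, sens, spec = _youden_point(scores, labels)
    return RocAnalysis(
        auc=auc, ci_low=float(min(ci_low, auc)), ci_high=float(max(ci_high, auc)),
        best_threshold=thr, youden_j=j, sensitivity=sens, specificity=spec,
        n_boot=n_boot,
    )


@dataclass
class CvResult:
    """Fold AUCs of repeated stratified k-fold cross-validation."""

    fold_aucs: list[float]
    k: int
    iterations: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def to_dict(self) -> dict:
        return {
            "fold_aucs": self.fold_aucs, "k": self.k,
            "iterations": self.iterations,
            "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
        }


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    iterations: int = 5,
    seed: int = 0,
) -> CvResult:
    """Repeated stratified k-fold CV of the single-feature logistic model.

    Each iteration reshuffles the stratified folds; the model is fitted
    on k-1 folds and scored by AUC on the held-out fold, giving
    k * iterations fold AUCs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise InsufficientDataError(f"each class needs >= k={k} members, got {counts.tolist()}")
    rng = np.random.default_rng(seed)
    fold_aucs: list[float] = []
    for _ in range(iterations):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in skf.split(x.reshape(-1, 1), y):
            try:
                model = fit_logistic(x[train], y[train])
                scores = np.asarray(predict_prob(model, x[test]))
            except SeparationError:
                # separable training fold: the MLE diverges but the ranking
                # is still defined; score by x oriented from training means
                sign = 1.0 if x[train][y[train] == 1].mean() >= x[train][y[train] == 0].mean() else -1.0
                scores = sign * x[test]
            fold_aucs.append(_auc_mann_whitney(scores, y[test]))
    return CvResult(fold_aucs=fold_aucs, k=k, iterations=iterations)
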