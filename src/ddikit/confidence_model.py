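"""Logistic confidence model for DDI-type approval.

The curated benchmark labels each DDI type ``approved`` or ``nonapproved``.
A binary logistic regression on interface features predicts the approval
probability of the thousands of uncurated types:

    logit P(approved) = beta_0 + sum_i beta_i x_i

Coefficients are maximum-likelihood estimates via iteratively reweighted
least squares; ``exp(beta_i)`` is the odds ratio per unit of feature ``i``.
Model variants are compared with likelihood-ratio chi-square tests and with
leave-one-out cross-validated ROC curves (each row scored by a model fit on
the other n-1 rows); calibration is checked with Hosmer-Lemeshow and decile
plots.  The fitted minimal model (z-score only) is invertible, turning a
desired approval probability into a 3did z-score cutoff for screening.

The estimator :class:`LogisticApprovalModel` follows the scikit-learn
fit/predict contract; the module-level functions mirror it for
DataFrame-centric pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .errors import (
    CollinearityError,
    DegenerateDataError,
    FoldError,
    StateError,
)

__all__ = [
    "LogisticFit",
    "ROCCurve",
    "ModelComparison",
    "LogisticApprovalModel",
    "label_vector",
    "complete_rows",
    "fit_logistic",
    "odds_ratios",
    "stepwise_reduce",
    "loocv_scores",
    "loocv_roc",
    "compare_nested",
    "hosmer_lemeshow",
    "decile_calibration",
    "zscore_probability_map",
    "bootstrap_auc_compare",
]

LOGIT_CLIP = 36.0  # |logit| bound before exponentiation, guards overflow only


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: variables, estimates and diagnostics."""

    variables: tuple[str, ...]  # includes "intercept" first
    params: np.ndarray  # log-odds scale, aligned to variables
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float
    n_obs: int
    converged: bool
    separation_warning: bool
    row_index: tuple  # table index labels of the rows actually fit

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.llf

    def coefficient(self, name: str) -> float:
        return float(self.params[self.variables.index(name)])

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(table, [v for v in self.variables if v != "intercept"])
        eta = np.clip(X @ self.params, -LOGIT_CLIP, LOGIT_CLIP)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ROCCurve:
    """ROC over out-of-fold probabilities with the Youden optimum."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    probabilities: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of two nested logistic fits."""

    statistic: float
    df: int
    p_value: float


def label_vector(table: pd.DataFrame) -> pd.Series:
    """0/1 approval outcomes from the ``label`` column, unlabeled rows dropped."""
    labeled = table[table["label"].isin(["approved", "nonapproved"])]
    return (labeled["label"] == "approved").astype(int)


def complete_rows(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Labeled rows with no missing value in any requested variable."""
    labeled = table[table["label"].isin(["approved", "nonapproved"])]
    return labeled.dropna(subset=list(variables))


def _design_matrix(table: pd.DataFrame, variables: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for v in variables:
        cols.append(table[v].to_numpy(dtype=float))
    return np.column_stack(cols)


def _check_collinearity(X: np.ndarray, variables: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # pivoted QR exposes which trailing columns are linear combinations
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    names = ["intercept"] + list(variables)
    offending = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    offending += [names[p] for p in piv[len(diag):]]
    raise CollinearityError(offending or names)


class LogisticApprovalModel(BaseEstimator, ClassifierMixin):
    """Scikit-learn style logistic approval classifier.

    Parameters
    ----------
    variables :
        Column names used as predictors when ``fit`` receives a DataFrame;
        with a plain array, all columns are used and named ``x0, x1, ...``.

    Attributes (after ``fit``)
    --------------------------
    intercept_, coef_ : maximum-likelihood estimates on the log-odds scale
    se_, pvalues_ : Wald standard errors and two-sided p-values (incl. intercept)
    llf_ : model log-likelihood
    converged_, separation_warning_ : IRLS diagnostics
    result_ : the full :class:`LogisticFit`
    """

    def __init__(self, variables: Sequence[str] | None = None):
        self.variables = variables

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = (
                list(self.variables) if self.variables is not None else list(X.columns)
            )
            frame = X[names]
            row_index = tuple(X.index)
            mat = frame.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            names = (
                list(self.variables)
                if self.variables
                else [f"x{i}" for i in range(mat.shape[1])]
            )
            row_index = tuple(range(len(mat)))
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = (y == "approved").astype(int)
        y = y.astype(float)
        if np.isnan(mat).any():
            raise ValueError("design matrix contains missing values; "
                             "restrict to complete rows first")
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateDataError(
                "labels contain a single class; the model is not identified"
            )
        design = np.column_stack([np.ones(len(mat)), mat])
        _check_collinearity(design, names)

        separation = False
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
            elif issubclass(w.category, ConvergenceWarning):
                converged = False
        converged = converged and bool(getattr(res, "converged", True))
        fitted = np.asarray(res.fittedvalues)
        if not separation and np.all(np.abs(fitted - y) < 1e-8):
            separation = True

        self.variables_ = tuple(["intercept"] + names)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.se_ = np.asarray(res.bse, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.llf_ = float(res.llf)
        self.n_obs_ = len(y)
        self.converged_ = converged
        self.separation_warning_ = separation
        self.classes_ = np.array([0, 1])
        self.result_ = LogisticFit(
            variables=self.variables_,
            params=np.asarray(res.params, dtype=float),
            bse=self.se_,
            pvalues=self.pvalues_,
            llf=self.llf_,
            n_obs=self.n_obs_,
            converged=converged,
            separation_warning=separation,
            row_index=row_index,
        )
        return self

    def decision_function(self, X):
        if isinstance(X, pd.DataFrame):
            names = [v for v in self.variables_ if v != "intercept"]
            mat = X[names].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
        return np.clip(
            self.intercept_ + mat @ self.coef_, -LOGIT_CLIP, LOGIT_CLIP
        )

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_logistic(table: pd.DataFrame, variables: Sequence[str]) -> LogisticFit:
    """Fit the approval model on the labeled, listwise-complete rows of ``table``."""
    rows = complete_rows(table, variables)
    if not len(rows):
        raise DegenerateDataError("no labeled complete rows to fit on")
    y = label_vector(rows).to_numpy()
    est = LogisticApprovalModel(variables=list(variables)).fit(rows, y)
    return est.result_


def odds_ratios(fit: LogisticFit) -> dict[str, float]:
    """exp(coefficient) per variable; the intercept is not reported."""
    if not fit.converged:
        raise StateError("odds ratios requested from a non-converged fit")
    return {
        v: float(np.exp(c))
        for v, c in zip(fit.variables, fit.params)
        if v != "intercept"
    }


def stepwise_reduce(
    table: pd.DataFrame,
    variables: Sequence[str],
    criterion: str = "aic",
) -> tuple[list[str], LogisticFit]:
    """Backwards stepwise elimination under AIC.

    At each step the variable whose removal lowers AIC most is dropped;
    elimination stops when no removal improves the criterion.  All candidate
    fits use the complete-row set of the *current* variable pool so
    successive AICs are comparable.  Deterministic: ties keep the earlier
    variable list order.
    """
    if criterion != "aic":
        raise ValueError(f"unsupported stepwise criterion {criterion!r}")
    current = list(variables)
    fit = fit_logistic(table, current)
    while len(current) > 1:
        # refit the incumbent and all drop-one candidates on the complete-row
        # set of the current pool so every AIC in this step is comparable
        rows = complete_rows(table, current)
        fit = fit_logistic(rows, current)
        candidates: list[tuple[float, list[str], LogisticFit]] = []
        for v in current:
            reduced = [w for w in current if w != v]
            cand = fit_logistic(rows, reduced)
            candidates.append((cand.aic, reduced, cand))
        best_aic, best_vars, best_fit = min(candidates, key=lambda c: c[0])
        if best_aic < fit.aic:
            current, fit = best_vars, best_fit
        else:
            break
    return current, fit


def loocv_scores(
    table: pd.DataFrame, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list]:
    """Out-of-fold approval probabilities by leave-one-out cross-validation.

    Deterministic: folds are the rows themselves, in table order.
    """
    rows = complete_rows(table, variables)
    y = label_vector(rows).to_numpy()
    probs = np.empty(len(rows))
    ids = list(rows.index)
    for k in range(len(rows)):
        train = rows.drop(index=ids[k])
        try:
            fit = fit_logistic(train, variables)
        except Exception as exc:  # noqa: BLE001 - reported per fold
            raise FoldError(ids[k], str(exc)) from exc
        probs[k] = fit.predict_proba(rows.iloc[[k]])[0]
    return probs, y, ids


def _roc_from_scores(y: np.ndarray, probs: np.ndarray) -> ROCCurve:
    fpr, tpr, thresholds = roc_curve(y, probs)
    sens, spec = tpr, 1 - fpr
    auc = float(roc_auc_score(y, probs))
    j = sens + spec - 1
    # maximize J; ties broken toward higher specificity
    order = np.lexsort((-spec, -j))
    best = order[0]
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thresholds[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
        probabilities=probs,
        labels=y,
    )


def loocv_roc(table: pd.DataFrame, variables: Sequence[str]) -> ROCCurve:
    """ROC/AUC over leave-one-out out-of-fold probabilities."""
    probs, y, _ = loocv_scores(table, variables)
    return _roc_from_scores(y, probs)


def compare_nested(fit_small: LogisticFit, fit_big: LogisticFit) -> ModelComparison:
    """Likelihood-ratio chi-square test of nested fits on identical rows."""
    small_vars = set(fit_small.variables)
    big_vars = set(fit_big.variables)
    if not small_vars <= big_vars:
        raise StateError(
            f"models are not nested: {sorted(small_vars - big_vars)} "
            "missing from the larger model"
        )
    if set(fit_small.row_index) != set(fit_big.row_index):
        raise StateError(
            "nested comparison requires both fits on the identical row set "
            "(refit on the intersection of complete rows)"
        )
    df = len(fit_big.params) - len(fit_small.params)
    stat = max(0.0, 2.0 * (fit_big.llf - fit_small.llf))
    if df == 0:
        return ModelComparison(statistic=stat, df=0, p_value=1.0)
    return ModelComparison(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df))
    )


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    n_groups: int
    merged_groups: int  # groups merged due to zero expected counts / ties
    table: pd.DataFrame = field(repr=False, default=None)


def hosmer_lemeshow(
    fit: LogisticFit, table: pd.DataFrame, groups: int = 10
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness of fit over predicted-probability deciles."""
    variables = [v for v in fit.variables if v != "intercept"]
    rows = complete_rows(table, variables)
    if len(rows) < groups:
        raise StateError(f"need at least {groups} rows for {groups} groups")
    y = label_vector(rows).to_numpy().astype(float)
    p = fit.predict_proba(rows)
    order = np.argsort(p, kind="mergesort")
    bins = np.array_split(order, groups)
    merged = 0
    # merge bins whose expected counts are degenerate into the neighbour
    stat_rows = []
    pending_idx: np.ndarray | None = None
    for b in bins:
        idx = b if pending_idx is None else np.concatenate([pending_idx, b])
        e1 = p[idx].sum()
        e0 = (1 - p[idx]).sum()
        if e1 <= 0 or e0 <= 0:
            pending_idx = idx
            merged += 1
            continue
        pending_idx = None
        stat_rows.append((idx, e1, e0))
    if pending_idx is not None and stat_rows:
        idx, e1, e0 = stat_rows.pop()
        idx = np.concatenate([idx, pending_idx])
        stat_rows.append((idx, p[idx].sum(), (1 - p[idx]).sum()))
        merged += 1
    statistic = 0.0
    summary = []
    for idx, e1, e0 in stat_rows:
        o1 = y[idx].sum()
        o0 = len(idx) - o1
        statistic += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        summary.append(
            {"n": len(idx), "observed": o1, "expected": e1,
             "mean_predicted": p[idx].mean()}
        )
    df = max(1, len(stat_rows) - 2)
    return HosmerLemeshowResult(
        statistic=float(statistic),
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        n_groups=len(stat_rows),
        merged_groups=merged,
        table=pd.DataFrame(summary),
    )


def decile_calibration(fit: LogisticFit, table: pd.DataFrame) -> pd.DataFrame:
    """Observed approval fraction per decile of predicted probability.

    Constant predictions collapse into a single occupied bin; empty bins are
    kept in the output with ``n = 0`` so the degeneracy is visible.
    """
    variables = [v for v in fit.variables if v != "intercept"]
    rows = complete_rows(table, variables)
    if len(rows) < 10:
        raise StateError("need at least 10 rows for decile calibration")
    y = label_vector(rows).to_numpy().astype(float)
    p = fit.predict_proba(rows)
    quantiles = np.quantile(p, np.linspace(0, 1, 11))
    edges = np.unique(quantiles)
    if len(edges) < 2:  # constant predictions
        assignment = np.zeros(len(p), dtype=int)
        n_bins = 10
    else:
        assignment = np.clip(
            np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2
        )
        n_bins = len(edges) - 1
    records = []
    for b in range(n_bins):
        mask = assignment == b
        records.append(
            {
                "decile": b + 1,
                "n": int(mask.sum()),
                "mean_predicted": float(p[mask].mean()) if mask.any() else np.nan,
                "observed_fraction": float(y[mask].mean()) if mask.any() else np.nan,
            }
        )
    # pad to 10 bins when quantile edges collapsed
    for b in range(n_bins, 10):
        records.append(
            {"decile": b + 1, "n": 0, "mean_predicted": np.nan,
             "observed_fraction": np.nan}
        )
    return pd.DataFrame(records)


def zscore_probability_map(
    fit_minimal: LogisticFit, direction: str, value: float
) -> float:
    """Translate between a z-score cutoff and an approval probability.

    ``forward``: p(z) = 1 / (1 + exp(-(b0 + b1 z))).
    ``inverse``: z(p) = (logit(p) - b0) / b1, the z-score cutoff at which the
    expected approval probability reaches ``p``.
    """
    if len(fit_minimal.params) != 2:
        raise StateError(
            "z-score/probability mapping needs a minimal model: "
            "intercept plus a single z-score coefficient"
        )
    b0, b1 = float(fit_minimal.params[0]), float(fit_minimal.params[1])
    if direction == "forward":
        eta = np.clip(b0 + b1 * value, -LOGIT_CLIP, LOGIT_CLIP)
        return float(1.0 / (1.0 + np.exp(-eta)))
    if direction == "inverse":
        if not 0.0 < value < 1.0:
            raise ValueError("probability must lie strictly inside (0, 1)")
        if b1 == 0:
            raise StateError("z-score coefficient is zero; mapping not invertible")
        return float((np.log(value / (1.0 - value)) - b0) / b1)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def bootstrap_auc_compare(
    table: pd.DataFrame,
    variables_a: Sequence[str],
    variables_b: Sequence[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Paired bootstrap test for a difference in LOOCV AUC between two models.

    Both models are scored on the intersection of their complete rows; the
    two out-of-fold probability vectors are resampled jointly (paired over
    rows), and the two-sided p-value is taken from the normal approximation
    to the bootstrap distribution of the AUC difference.  A model compared
    with itself gives p = 1.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    joint = list(dict.fromkeys(list(variables_a) + list(variables_b)))
    rows = complete_rows(table, joint)
    pa, y, _ = loocv_scores(rows, variables_a)
    pb, _, _ = loocv_scores(rows, variables_b)
    observed = roc_auc_score(y, pa) - roc_auc_score(y, pb)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
        diffs[b] = roc_auc_score(y[idx], pa[idx]) - roc_auc_score(y[idx], pb[idx])
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if observed == 0 else 0.0
    z = observed / sd
    return float(2 * stats.norm.sf(abs(z)))
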