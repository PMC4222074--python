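"""Histology-predictive validation: AUC, L1 signatures, Monte-Carlo nulls.

Predictive value of single features and multi-gene signatures is measured by
the rank-based AUC (Mann-Whitney U scaled to [0,1], ties counted 0.5).
Multi-gene signatures come from L1-penalized logistic regression with the
regularization strength chosen so the active set has the requested size; the
reported AUC pools out-of-fold scores across stratified cross-validation
folds.  Significance is assessed against Monte-Carlo nulls built from random
feature draws with the add-one rule, so a p-value is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import (ConfigurationError, InsufficientDataError,
                         UndefinedAUCError)

__all__ = [
    "ClassifierResult",
    "MonteCarloNull",
    "auc",
    "l1_signature",
    "monte_carlo_signature_pvalue",
    "single_feature_auc_test",
    "regional_amplification_test",
]


def _binarize(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise UndefinedAUCError(
            f"AUC needs exactly two classes, got {classes.size}")
    return (y == classes[-1]).astype(int)


def auc(scores, labels) -> float:
    """Rank-based AUC: Mann-Whitney U / (n1*n0), ties counted 0.5.

    The positive class is the larger of the two label values.  Raises
    :class:`UndefinedAUCError` for single-class labels.
    """
    y = _binarize(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ConfigurationError("scores and labels must align")
    if not np.isfinite(s).all():
        raise InsufficientDataError("scores must be finite")
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _l1_logistic(C: float) -> LogisticRegression:
    """Lasso-penalized logistic regression across sklearn API generations."""
    import sklearn

    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return LogisticRegression(solver="liblinear", C=C, l1_ratio=1.0,
                                  max_iter=2000, tol=1e-8, random_state=0)
    return LogisticRegression(penalty="l1", solver="liblinear", C=C,
                              max_iter=2000, tol=1e-8, random_state=0)


@dataclass
class ClassifierResult:
    """An L1-penalized signature with its pooled cross-validated AUC."""

    signature: list
    cv_auc: float
    fold_assignments: pd.Series
    seed: int
    requested_size: int
    size_attained: bool = True


def _fit_l1_at_size(X: np.ndarray, y: np.ndarray, size: int
                    ) -> tuple[LogisticRegression, bool]:
    """Fit L1 logistic regression with ~``size`` nonzero coefficients.

    Scans a log-spaced C path and bisects to the requested active-set size;
    when the path jumps over the exact size, the nearest attainable size is
    used and flagged.
    """
    def fit(C):
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        m = _l1_logistic(C)
        with warnings.catch_warnings():
            # near-separable folds at weak penalty stop on max_iter; the
            # decision scores are already stable there
            warnings.simplefilter("ignore", ConvergenceWarning)
            m.fit(X, y)
        return m

    size = min(size, X.shape[1])
    if X.shape[1] <= size:
        # no selection needed: effectively unpenalized fit
        return fit(1e4), True

    def nnz(m):
        return int(np.sum(m.coef_ != 0))

    lo, hi = 1e-4, 1e4
    m_lo, m_hi = fit(lo), fit(hi)
    if nnz(m_hi) <= size:
        return m_hi, nnz(m_hi) == size
    if nnz(m_lo) >= size:
        return m_lo, nnz(m_lo) == size
    best, best_gap = m_lo, abs(nnz(m_lo) - size)
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        m_mid = fit(mid)
        k = nnz(m_mid)
        if abs(k - size) < best_gap:
            best, best_gap = m_mid, abs(k - size)
        if k == size:
            return m_mid, True
        if k < size:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0001:
            break
    return best, best_gap == 0


def _standardize_train_test(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _cv_scores(X: np.ndarray, y: np.ndarray, size: int, cv_folds: int,
               seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold decision scores; returns (scores, fold ids).

    The fold count is clamped to the minority-class size so every fold
    keeps both classes.
    """
    n_minority = int(min(np.bincount(y)))
    cv_folds = min(cv_folds, n_minority)
    if cv_folds < 2:
        raise InsufficientDataError(
            "need at least two subjects per class for cross-validation")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    folds = np.empty(y.size, dtype=int)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = _standardize_train_test(X[tr], X[te])
        model, _ = _fit_l1_at_size(Xtr, y[tr], size)
        scores[te] = model.decision_function(Xte)
        folds[te] = k
    return scores, folds


def l1_signature(expr: pd.DataFrame, labels: pd.Series,
                 signature_size: int = 15, cv_folds: int = 10,
                 seed: int = 0) -> ClassifierResult:
    """An L1-penalized logistic signature of ``signature_size`` features.

    ``expr`` is features x subjects; ``labels`` a two-class series over the
    same subjects.  Per training fold the L1 path is tuned so the active set
    has the requested size; the reported ``cv_auc`` is the AUC of out-of-fold
    scores pooled across stratified folds.  The returned signature comes from
    a full-data fit at the matched size, ordered by decreasing |coefficient|;
    if the exact size is unattainable on the path the nearest size is
    returned with ``size_attained=False``.  Deterministic given ``seed``.
    """
    labels = labels.loc[expr.columns]
    y = _binarize(labels)
    X = expr.to_numpy(float).T
    scores, folds = _cv_scores(X, y, signature_size, cv_folds, seed)
    cv_auc = auc(scores, y)
    Xs, _ = _standardize_train_test(X, X)
    model, attained = _fit_l1_at_size(Xs, y, signature_size)
    coefs = model.coef_.ravel()
    order = np.argsort(-np.abs(coefs))
    sig = [expr.index[i] for i in order if coefs[i] != 0]
    return ClassifierResult(
        signature=sig, cv_auc=cv_auc,
        fold_assignments=pd.Series(folds, index=expr.columns, name="fold"),
        seed=seed, requested_size=signature_size,
        size_attained=attained and len(sig) == min(signature_size,
                                                   expr.shape[0]))


@dataclass
class MonteCarloNull:
    """A Monte-Carlo null: observed statistic, null draws, add-one p-value."""

    observed_auc: float
    null_aucs: np.ndarray
    p_value: float
    n_draws: int

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_aucs))


def monte_carlo_signature_pvalue(expr: pd.DataFrame, labels: pd.Series,
                                 signature_size: int = 15,
                                 n_draws: int = 1000, seed: int = 0,
                                 observed_auc: float | None = None,
                                 cv_folds: int = 10) -> MonteCarloNull:
    """Significance of a signature's AUC against random same-size signatures.

    Each draw samples ``signature_size`` features uniformly without
    replacement and scores subjects with the same cross-validated classifier
    protocol as :func:`l1_signature` restricted to the drawn features.  The
    p-value uses the add-one rule ``(1 + #{null >= observed}) / (n_draws+1)``.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be at least 1")
    if expr.shape[0] <= signature_size:
        raise ConfigurationError(
            "expr must have more features than signature_size")
    labels = labels.loc[expr.columns]
    y = _binarize(labels)
    if observed_auc is None:
        observed_auc = l1_signature(expr, labels, signature_size, cv_folds,
                                    seed).cv_auc
    rng = np.random.default_rng(seed)
    n_features = expr.shape[0]
    null = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(n_features, size=signature_size, replace=False)
        X = expr.iloc[idx].to_numpy(float).T
        scores, _ = _cv_scores(X, y, signature_size, cv_folds, seed)
        null[d] = auc(scores, y)
    p = (1 + int(np.sum(null >= observed_auc))) / (n_draws + 1)
    return MonteCarloNull(observed_auc=float(observed_auc), null_aucs=null,
                          p_value=p, n_draws=n_draws)


def single_feature_auc_test(expr: pd.DataFrame, feature, labels: pd.Series,
                            n_draws: int = 1000, seed: int = 0,
                            folded: bool = True) -> tuple[float, float]:
    """AUC of one feature with a random-feature Monte-Carlo p-value.

    The null draws ``n_draws`` random features from the same matrix and
    records their AUCs.  With ``folded=True`` (default) an AUC of a and 1-a
    are equivalent departures from 0.5; ``folded=False`` gives the one-sided
    upper test.  A constant feature has no ranking and raises
    :class:`UndefinedAUCError`.
    """
    labels = labels.loc[expr.columns]
    y = _binarize(labels)
    row = expr.loc[feature].to_numpy(float)
    if np.ptp(row) == 0:
        raise UndefinedAUCError(f"feature {feature!r} is constant")
    observed = auc(row, y)
    rng = np.random.default_rng(seed)
    n_features = expr.shape[0]
    idx = rng.choice(n_features, size=n_draws,
                     replace=n_draws > n_features)
    M = expr.iloc[idx].to_numpy(float)
    null = np.array([auc(M[i], y) for i in range(n_draws)])
    if folded:
        d_obs = max(observed, 1 - observed)
        d_null = np.maximum(null, 1 - null)
    else:
        d_obs, d_null = observed, null
    p = (1 + int(np.sum(d_null >= d_obs))) / (n_draws + 1)
    return float(observed), float(p)


def regional_amplification_test(probe_intensities, global_mean: float = 0.0,
                                alpha: float = 0.05
                                ) -> tuple[float, float, bool]:
    """Regional amplification call in the style of an external-cohort check.

    One-sided one-sample t test of the window's probe intensities against the
    standardized global mean (zero after within-sample standardization); the
    region is amplified when p falls below ``alpha``.  Requires at least two
    probes.
    """
    x = np.asarray(probe_intensities, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least two probes in the window")
    mean = float(x.mean())
    if np.ptp(x) == 0:
        if mean > global_mean:
            p = 0.0
        elif mean < global_mean:
            p = 1.0
        else:
            p = 0.5
    else:
        p = float(stats.ttest_1samp(x, global_mean,
                                    alternative="greater").pvalue)
    return mean, p, p < alpha
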