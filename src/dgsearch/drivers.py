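"""Candidate-driver filtering, correlation modules and sparse CCA refinement.

The driver search proceeds in three steps once recurrent CNA regions are
known: (1) genes/miRNAs inside pure-polarity recurrent regions become
candidate drivers and are filtered on expression variability, one-sided
Welch tests against copy-neutral subjects, fold change and sign consistency;
(2) every remaining (target) feature is grouped with the most correlated
significantly associated candidate driver (initial modules); (3) each module
is refined by rank-1 sparse canonical correlation analysis, dropping targets
whose canonical weight is thresholded to zero.  Final drivers pass stricter
fold-change/p thresholds and are ranked by module size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ConvergenceError

__all__ = [
    "DriverCandidate",
    "DriverModule",
    "SccaResult",
    "filter_variable_features",
    "cna_expression_filter",
    "pairwise_driver_correlation",
    "initial_modules",
    "refine_module_scca",
    "refine_modules",
    "choose_scca_penalty",
    "rank_and_select_drivers",
    "target_count_curve",
]


def filter_variable_features(expr: pd.DataFrame,
                             sd_threshold: float = 0.25) -> pd.Index:
    """Features whose sample SD across subjects is at least ``sd_threshold``.

    The exclusion rule is "standard deviation < 0.25"; the kept set is its
    strict complement (SD exactly at the threshold is kept).
    """
    if expr.shape[1] < 2:
        raise ConfigurationError("need at least two subjects")
    sd = expr.std(axis=1, ddof=1)
    return expr.index[sd >= sd_threshold]


@dataclass
class DriverCandidate:
    """One candidate driver and its CNA-expression filter outcome.

    ``fold_change`` is the linear-scale ratio of altered to copy-neutral
    means, ``2**(mean_alt - mean_neut)``; for deletions the filter is applied
    to its reciprocal (see :attr:`effect_fold_change`).
    """

    feature: str
    region_index: int
    polarity: str                       # "amp_only" | "del_only"
    fold_change: float = float("nan")
    welch_p: float = float("nan")
    consistency_fraction: float = float("nan")
    n_altered: int = 0
    retained: bool = False
    reason: str | None = None

    @property
    def effect_fold_change(self) -> float:
        """Fold change in the direction of the region's polarity (>= 1 for a
        concordant effect)."""
        if self.polarity == "del_only":
            return 1.0 / self.fold_change
        return self.fold_change


def cna_expression_filter(expr_row: pd.Series, altered_subjects,
                          polarity: str, p_max: float = 0.05,
                          min_fold_change: float | None = 2.0,
                          min_consistency: float = 0.9,
                          feature: str | None = None,
                          region_index: int = -1) -> DriverCandidate:
    """CNA-expression consistency filter for one candidate driver.

    One-sided Welch t test of the altered subjects' expression against the
    copy-neutral rest, in the direction of the polarity (up for
    amplifications, down for deletions); fold change on the linear scale;
    consistency = fraction of altered subjects whose log2(T/N) expression
    matches the polarity's sign.  Retained iff p < ``p_max`` AND the fold
    change exceeds ``min_fold_change`` in the polarity direction (skipped
    when None, the miRNA rule) AND consistency >= ``min_consistency``.

    An altered or neutral group smaller than two subjects yields a
    non-retained candidate with reason ``"insufficient_data"``.
    """
    if polarity not in ("amp_only", "del_only"):
        raise ConfigurationError(f"polarity must be pure, got {polarity!r}")
    name = feature if feature is not None else str(expr_row.name)
    altered = [s for s in altered_subjects if s in expr_row.index]
    neutral = expr_row.index.difference(altered)
    cand = DriverCandidate(feature=name, region_index=region_index,
                           polarity=polarity, n_altered=len(altered))
    if len(altered) < 2 or len(neutral) < 2:
        cand.reason = "insufficient_data"
        return cand

    alt = expr_row.loc[altered].to_numpy(float)
    neu = expr_row.loc[neutral].to_numpy(float)
    alternative = "greater" if polarity == "amp_only" else "less"
    welch = stats.ttest_ind(alt, neu, equal_var=False,
                            alternative=alternative)
    cand.welch_p = float(welch.pvalue)
    cand.fold_change = float(2.0 ** (alt.mean() - neu.mean()))
    sign_ok = alt > 0 if polarity == "amp_only" else alt < 0
    cand.consistency_fraction = float(sign_ok.mean())

    reasons = []
    if not cand.welch_p < p_max:
        reasons.append("welch_p")
    if min_fold_change is not None and \
            not cand.effect_fold_change > min_fold_change:
        reasons.append("fold_change")
    if not cand.consistency_fraction >= min_consistency:
        reasons.append("consistency")
    cand.retained = not reasons
    cand.reason = ",".join(reasons) if reasons else None
    return cand


def pairwise_driver_correlation(expr: pd.DataFrame, drivers: Sequence[str],
                                targets: Sequence[str],
                                method: str = "pearson"
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Driver x target correlation and two-sided p-value matrices.

    Pearson by default (Spearman via ``method``); p-values from the t
    transform with n-2 degrees of freedom.  Zero-variance features give
    missing correlations.
    """
    n = expr.shape[1]
    if n < 4:
        raise ConfigurationError("need at least four subjects")
    D = expr.loc[list(drivers)].to_numpy(float)
    T = expr.loc[list(targets)].to_numpy(float)
    if method == "spearman":
        D = np.apply_along_axis(stats.rankdata, 1, D)
        T = np.apply_along_axis(stats.rankdata, 1, T)
    elif method != "pearson":
        raise ConfigurationError(f"unknown correlation method {method!r}")

    def _standardize(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (M - mu) / sd
        Z[~np.isfinite(Z)] = np.nan
        return Z

    Zd, Zt = _standardize(D), _standardize(T)
    r = Zd @ Zt.T / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    rdf = pd.DataFrame(r, index=list(drivers), columns=list(targets))
    pdf = pd.DataFrame(p, index=list(drivers), columns=list(targets))
    return rdf, pdf


def initial_modules(corr: pd.DataFrame, pvals: pd.DataFrame,
                    p_threshold: float = 0.001) -> dict[str, list]:
    """Group each target with its most correlated significant driver.

    A target with at least one driver at p < ``p_threshold`` is assigned to
    the significant driver with the largest |r|; exact ties break to the
    lexicographically first driver id.  Targets with no significant driver
    stay unassigned.  Assigned targets form a partition.
    """
    modules: dict[str, list] = {d: [] for d in corr.index}
    drivers_sorted = sorted(corr.index)
    for tgt in corr.columns:
        p_col = pvals[tgt]
        sig = [d for d in drivers_sorted
               if np.isfinite(p_col[d]) and p_col[d] < p_threshold]
        if not sig:
            continue
        absr = corr.loc[sig, tgt].abs()
        # tie-break: lexicographically first driver among the |r| maxima
        best_val = absr.max()
        winner = next(d for d in drivers_sorted
                      if d in absr.index and absr[d] == best_val)
        modules[winner].append(tgt)
    return modules


@dataclass
class SccaResult:
    """Rank-1 sparse CCA fit: unit-norm weights and their canonical correlation."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    corr: float
    n_iter: int


def _soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_project(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-l2 vector proportional to a soft-thresholded ``a`` with l1 <= c."""
    norm = np.linalg.norm(a)
    if norm == 0:
        return a
    u = a / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(80):
        mid = (lo + hi) / 2
        su = _soft_threshold(a, mid)
        nrm = np.linalg.norm(su)
        if nrm == 0:
            hi = mid
            continue
        if np.abs(su / nrm).sum() > c:
            lo = mid
        else:
            hi = mid
    su = _soft_threshold(a, hi)
    nrm = np.linalg.norm(su)
    return su / nrm if nrm > 0 else su


def refine_module_scca(X, Y, penalty_x: float | None = None,
                       penalty_y: float | None = None,
                       standardize: bool = True, max_iter: int = 2000,
                       tol: float = 1e-12) -> SccaResult:
    """Rank-1 sparse canonical correlation between two feature blocks.

    ``X`` (subjects x drivers) and ``Y`` (subjects x targets).  Penalties are
    fractions of sqrt(block size) bounding the l1 norm of the unit-l2 weight
    vector (the penalized-matrix-decomposition formulation); ``None`` leaves
    that side unpenalized.  With both penalties ``None`` the iteration runs
    on the whitened cross-covariance, so the result is classical CCA; with a
    penalty, covariance within each block is treated as diagonal and weights
    are soft-thresholded each half-step.  Deterministic: initialisation is
    the column of the cross-covariance with the largest norm.

    Raises :class:`ConvergenceError` (carrying the last iterate and delta)
    if ``max_iter`` alternations do not converge.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ConfigurationError("X and Y must share the subject dimension")
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ConfigurationError("need more than two subjects")
    if p == 0 or q == 0:
        raise ConfigurationError("empty module")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if standardize:
        def _scale(M):
            sd = M.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            return M / sd
        Xc, Yc = _scale(Xc), _scale(Yc)

    whiten = penalty_x is None and penalty_y is None
    C = Xc.T @ Yc / (n - 1)
    if whiten:
        Cxx = Xc.T @ Xc / (n - 1)
        Cyy = Yc.T @ Yc / (n - 1)
        ridge_x = 1e-12 * max(np.trace(Cxx) / p, 1.0)
        ridge_y = 1e-12 * max(np.trace(Cyy) / q, 1.0)
        Lx = np.linalg.cholesky(Cxx + ridge_x * np.eye(p))
        Ly = np.linalg.cholesky(Cyy + ridge_y * np.eye(q))
        # K = Lx^{-1} Cxy Ly^{-T}
        K = np.linalg.solve(Lx, C)
        K = np.linalg.solve(Ly, K.T).T
    else:
        K = C

    cx = None if penalty_x is None else max(1.0, penalty_x * np.sqrt(p))
    cy = None if penalty_y is None else max(1.0, penalty_y * np.sqrt(q))

    col_norms = np.linalg.norm(K, axis=0)
    v = np.zeros(q)
    v[int(np.argmax(col_norms))] = 1.0
    u = np.zeros(p)
    delta = np.inf
    for it in range(1, max_iter + 1):
        u_new = K @ v
        if cx is None:
            nrm = np.linalg.norm(u_new)
            u_new = u_new / nrm if nrm > 0 else u_new
        else:
            u_new = _l1_project(u_new, cx)
        v_new = K.T @ u_new
        if cy is None:
            nrm = np.linalg.norm(v_new)
            v_new = v_new / nrm if nrm > 0 else v_new
        else:
            v_new = _l1_project(v_new, cy)
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"sparse CCA did not converge in {max_iter} iterations",
            last_iterate=(u, v), delta=delta)

    if whiten:
        a = np.linalg.solve(Lx.T, u)
        b = np.linalg.solve(Ly.T, v)
    else:
        a, b = u, v
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    a = a / na if na > 0 else a
    b = b / nb if nb > 0 else b

    xs = Xc @ a
    ys = Yc @ b
    if xs.std() == 0 or ys.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(xs, ys)[0, 1])
    return SccaResult(x_weights=a, y_weights=b, corr=corr, n_iter=it)


@dataclass
class DriverModule:
    """A candidate driver with its refined target set and sparse weights."""

    driver: str
    targets: list
    target_corr: dict = field(default_factory=dict)
    x_weights: np.ndarray | None = None
    y_weights: np.ndarray | None = None
    canonical_corr: float = float("nan")

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def choose_scca_penalty(X, Y, grid=(0.1, 0.2, 0.3, 0.5, 0.7, 0.9),
                        n_perm: int = 5, seed: int = 0) -> float:
    """Pick the target-side penalty maximising the real-vs-permuted gap.

    For each penalty on the grid, fit the sparse CCA on the real pairing and
    on ``n_perm`` subject-permuted pairings; the chosen penalty maximises
    canonical correlation minus the mean permuted canonical correlation.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    perms = [rng.permutation(X.shape[0]) for _ in range(n_perm)]
    best_gap, best_pen = -np.inf, grid[0]
    for pen in grid:
        real = refine_module_scca(X, Y, penalty_x=None, penalty_y=pen).corr
        null = np.mean([refine_module_scca(X[perm], Y, penalty_x=None,
                                           penalty_y=pen).corr
                        for perm in perms])
        gap = real - null
        if gap > best_gap:
            best_gap, best_pen = gap, pen
    return best_pen


def refine_modules(expr: pd.DataFrame, modules: Mapping[str, Sequence[str]],
                   corr: pd.DataFrame | None = None,
                   penalty_y: float | str = "auto",
                   seed: int = 0) -> dict[str, DriverModule]:
    """Refine every initial module by sparse CCA, dropping zero-weight targets.

    ``expr`` is features x subjects.  The driver side holds the module's
    driver (unpenalized); the target side is penalized, either with a fixed
    fraction or, with ``penalty_y="auto"``, a per-module permutation-selected
    penalty from :func:`choose_scca_penalty`.
    """
    refined: dict[str, DriverModule] = {}
    for driver, targets in modules.items():
        targets = list(targets)
        if not targets:
            refined[driver] = DriverModule(driver=driver, targets=[])
            continue
        X = expr.loc[[driver]].to_numpy(float).T
        Y = expr.loc[targets].to_numpy(float).T
        pen = penalty_y
        if penalty_y == "auto":
            pen = choose_scca_penalty(X, Y, seed=seed)
        res = refine_module_scca(X, Y, penalty_x=None, penalty_y=pen)
        keep = np.abs(res.y_weights) > 0
        kept = [t for t, k in zip(targets, keep) if k]
        tcorr = {}
        if corr is not None and driver in corr.index:
            tcorr = {t: float(corr.at[driver, t]) for t in kept
                     if t in corr.columns}
        refined[driver] = DriverModule(
            driver=driver, targets=kept, target_corr=tcorr,
            x_weights=res.x_weights, y_weights=res.y_weights[keep],
            canonical_corr=res.corr)
    return refined


def rank_and_select_drivers(candidates: Sequence[DriverCandidate],
                            modules: Mapping[str, DriverModule],
                            fc_final: float = 4.0,
                            p_final: float = 0.001
                            ) -> list[DriverCandidate]:
    """Final driver list: stricter thresholds, ranked by module size.

    Keeps retained candidates with fold change > ``fc_final`` (in the
    polarity direction) and Welch p < ``p_final``; orders by descending
    number of refined targets, ties by descending fold change, then feature
    id for full determinism.
    """
    final = [c for c in candidates
             if c.retained and c.effect_fold_change > fc_final
             and c.welch_p < p_final]

    def key(c: DriverCandidate):
        m = modules.get(c.feature)
        n_targets = m.n_targets if m is not None else 0
        return (-n_targets, -c.effect_fold_change, c.feature)

    return sorted(final, key=key)


def target_count_curve(module: DriverModule, thresholds: Sequence[float],
                       desired_size: int | None = None):
    """Target counts at increasing |correlation| cutoffs.

    Returns ``(counts, cutoff)`` where ``counts`` maps each threshold to the
    number of targets with |r| >= threshold (non-increasing in the
    threshold), and ``cutoff`` is the smallest threshold whose count is at
    most ``desired_size`` (None when no ``desired_size`` given or no
    threshold qualifies).
    """
    absr = np.abs(np.array([module.target_corr.get(t, np.nan)
                            for t in module.targets], dtype=float))
    counts = {}
    for thr in thresholds:
        counts[thr] = int(np.sum(absr >= thr)) if thr > 0 else len(absr)
    cutoff = None
    if desired_size is not None:
        for thr in sorted(thresholds):
            if counts[thr] <= desired_size:
                cutoff = thr
                break
    return counts, cutoff
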