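"""PLSR-based inference on functional connectivity and activation.

SIMPLS partial least squares with BIC-adjusted cross-validated component
selection, trimmed-score-regression (TSR) imputation of missing pupil
samples, conversion of loadings to original-unit "change in correlation"
slopes, residual-passing categorical (behavior-period) regressions,
permutation + FDR significance, and the activation-vs-FC relation test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SIMPLS core

def _simpls(X: np.ndarray, Y: np.ndarray, n_components: int) -> dict:
    """SIMPLS with unit-norm score convention.

    X, Y are centered internally.  Scores t_a are unit-norm, so the
    loading product XL @ YL.T reconstructs X'Y and, divided by n - 1,
    the cross-covariance of the (already normalized) inputs.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, m = X.shape
    p = Y.shape[1]
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("Y has no variance")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    c = min(n_components, n - 1, m)
    S = Xc.T @ Yc
    R = np.zeros((m, c))
    T = np.zeros((n, c))
    P = np.zeros((m, c))
    Q = np.zeros((p, c))
    V = np.zeros((m, c))
    for a in range(c):
        u, sv, vt = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = Xc @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt <= 1e-12:
            c = a
            R, T, P, Q, V = R[:, :a], T[:, :a], P[:, :a], Q[:, :a], V[:, :a]
            break
        t /= normt
        r /= normt
        pa = Xc.T @ t
        qa = Yc.T @ t
        va = pa.copy()
        if a > 0:
            va -= V[:, :a] @ (V[:, :a].T @ pa)
        va /= np.linalg.norm(va)
        S = S - np.outer(va, va @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, pa, qa, va
    beta = R @ Q.T
    return {
        "x_weights": R, "x_scores": T, "x_loadings": P, "y_loadings": Q,
        "beta": beta, "x_mean": X.mean(axis=0), "y_mean": Y.mean(axis=0),
        "n_components": c, "x_residuals": Xc - T @ P.T,
    }


class SIMPLSRegression(BaseEstimator, RegressorMixin):
    """Partial least squares regression in the SIMPLS convention.

    Fits latent components of X maximizing covariance with Y; scores are
    unit-norm so ``x_loadings_ @ y_loadings_.T / (n - 1)`` reconstructs
    the X-Y cross-covariance at full rank.

    Attributes
    ----------
    x_loadings_ : (m, c); y_loadings_ : (p, c)
    coef_ : (m, p) slopes relating centered X to centered Y
    x_residuals_ : (n, m) X-block reconstruction residuals
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SIMPLSRegression":
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.shape[0] == 1 and np.asarray(X).shape[0] != 1:
            Y = Y.T
        f = _simpls(X, Y, self.n_components)
        self.x_weights_ = f["x_weights"]
        self.x_scores_ = f["x_scores"]
        self.x_loadings_ = f["x_loadings"]
        self.y_loadings_ = f["y_loadings"]
        self.coef_ = f["beta"]
        self.intercept_ = f["y_mean"] - f["x_mean"] @ f["beta"]
        self.x_mean_ = f["x_mean"]
        self.x_residuals_ = f["x_residuals"]
        self.n_components_ = f["n_components"]
        self.n_samples_ = np.asarray(X).shape[0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef_ + self.intercept_


def plsr_fit(X0: np.ndarray, Y0: np.ndarray, n_components: int) -> SIMPLSRegression:
    """Functional wrapper over :class:`SIMPLSRegression`."""
    return SIMPLSRegression(n_components).fit(X0, Y0)


def delta_r(xl: np.ndarray, yl: np.ndarray, n: int, sigma_x: np.ndarray,
            sigma_y: np.ndarray) -> np.ndarray:
    """Original-unit change matrix from PLSR loadings.

    delta_r[m, p] = (XL @ YL.T)[m, p] / (n - 1) * sigma_x[m] / sigma_y[p]:
    the expected change of variable m (correlation or dF/F%) per unit of
    parameter p, PLSR-denoised.  At full rank with a single y this equals
    the OLS slope of each raw x on raw y.
    """
    sigma_y = np.asarray(sigma_y, float)
    if np.any(sigma_y <= 0):
        raise ValueError("sigma_y must be positive for every retained parameter")
    core = xl @ yl.T / (n - 1)
    return core * np.asarray(sigma_x, float)[:, None] / sigma_y[None, :]


# ---------------------------------------------------------------------------
# normalization and TSR imputation

def zscore_columns(A: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores ignoring NaNs; zero-variance columns become 0."""
    A = np.asarray(A, float)
    mean = np.nanmean(A, axis=0)
    sd = np.nanstd(A, axis=0, ddof=ddof)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (A - mean) / sd_safe, mean, sd


def tsr_impute(M: np.ndarray, var_target: float = 0.85, max_pcs: int = 10,
               tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, dict]:
    """Trimmed score regression imputation of missing (NaN) entries.

    Missing values start at column means; then, iteratively, PCA is run
    on the completed matrix with the smallest number of components
    explaining ``var_target`` of its variance (capped at ``max_pcs``),
    the full-data scores are regressed on the scores computed from each
    row's observed columns only (the trimmed scores), and missing entries
    are refilled from that regression's reconstruction.  Observed entries
    are never modified.  Preserves the correlation structure of the data.
    """
    M = np.asarray(M, float).copy()
    missing = ~np.isfinite(M)
    info = {"converged": True, "n_iter": 0, "n_pcs": 0}
    if not missing.any():
        return M, info
    if np.any(missing.all(axis=0)):
        raise ValueError("a column is entirely missing")
    col_means = np.nanmean(np.where(missing, np.nan, M), axis=0)
    M[missing] = np.broadcast_to(col_means, M.shape)[missing]

    patterns: dict[bytes, np.ndarray] = {}
    for i in np.where(missing.any(axis=1))[0]:
        key = missing[i].tobytes()
        patterns.setdefault(key, []).append(i)

    converged = False
    for it in range(1, max_iter + 1):
        mu = M.mean(axis=0)
        Mc = M - mu
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        var = s**2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, var_target) + 1)
        k = min(k, max_pcs, len(s))
        P = Vt[:k].T  # (d, k)
        T_full = Mc @ P
        max_change = 0.0
        for key, rows in patterns.items():
            rows = np.asarray(rows)
            miss_cols = np.frombuffer(key, dtype=bool)
            obs = ~miss_cols
            T_trim = Mc[np.ix_(rows, np.where(obs)[0])] @ P[obs]
            B, *_ = np.linalg.lstsq(T_trim, T_full[rows], rcond=None)
            recon = (T_trim @ B) @ P.T + mu
            new_vals = recon[:, miss_cols]
            old_vals = M[np.ix_(rows, np.where(miss_cols)[0])]
            max_change = max(max_change, float(np.abs(new_vals - old_vals).max()))
            M[np.ix_(rows, np.where(miss_cols)[0])] = new_vals
        info["n_iter"] = it
        info["n_pcs"] = k
        if max_change < tol:
            converged = True
            break
    if not converged:
        info["converged"] = False
        warnings.warn(f"TSR imputation did not converge in {max_iter} iterations")
    return M, info


# ---------------------------------------------------------------------------
# component selection

def _contiguous_folds(n: int, folds: int, rng: np.random.Generator,
                      labels: np.ndarray | None = None) -> list[np.ndarray]:
    """Contiguous equal blocks of the time-ordered observations with a
    random circular offset; stratified mode blocks each label separately
    so per-fold label ratios stay within one observation of global."""
    if labels is None:
        offset = int(rng.integers(0, n))
        order = np.roll(np.arange(n), -offset)
        return [np.sort(chunk) for chunk in np.array_split(order, folds)]
    parts = [[] for _ in range(folds)]
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]  # time-ordered within label
        offset = int(rng.integers(0, len(idx)))
        order = np.roll(idx, -offset)
        for f, chunk in enumerate(np.array_split(order, folds)):
            parts[f].append(chunk)
    return [np.sort(np.concatenate(p)) for p in parts]


def select_ncomp(X0: np.ndarray, Y0: np.ndarray, folds: int = 10, mc_reps: int = 10,
                 c_max: int = 10, stratify_labels: np.ndarray | None = None,
                 seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Number of PLSR components by BIC-adjusted cross-validated MSE.

    Every candidate count 1..c_max is scored by 10-fold cross-validation
    on contiguous time blocks (division points circularly offset at
    random, 10 Monte Carlo repetitions); the count minimizing
    ``n * ln(MSE_cv) + c * ln(n)`` wins.  Categorical regressions use
    stratified contiguous folds.
    """
    X0 = np.asarray(X0, float)
    Y0 = np.atleast_2d(np.asarray(Y0, float))
    if Y0.shape[0] == 1 and X0.shape[0] != 1:
        Y0 = Y0.T
    n = X0.shape[0]
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} observations for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    c_max = int(min(c_max, X0.shape[1], n - max(2, n // folds) - 1))
    c_max = max(c_max, 1)
    sse = np.zeros(c_max)
    count = 0
    for _ in range(mc_reps):
        fold_sets = _contiguous_folds(n, folds, rng, stratify_labels)
        for test_idx in fold_sets:
            if len(test_idx) == 0:
                continue
            train = np.setdiff1d(np.arange(n), test_idx)
            f = _simpls(X0[train], Y0[train], c_max)
            R, Q = f["x_weights"], f["y_loadings"]
            Tt = (X0[test_idx] - f["x_mean"]) @ R
            pred = np.tile(f["y_mean"], (len(test_idx), 1))
            for c in range(c_max):
                if c < R.shape[1]:
                    pred = pred + np.outer(Tt[:, c], Q[:, c])
                sse[c] += float(((Y0[test_idx] - pred) ** 2).sum())
            count += len(test_idx) * Y0.shape[1]
    mse = sse / count
    bic = n * np.log(mse) + (np.arange(1, c_max + 1)) * np.log(n)
    best = int(np.argmin(bic)) + 1
    table = pd.DataFrame({"n_components": np.arange(1, c_max + 1),
                          "mse_cv": mse, "bic": bic})
    return best, table


# ---------------------------------------------------------------------------
# regression drivers

@dataclass
class PlsrResult:
    """Fitted PLSR with original-unit slopes for one mouse/comparison."""

    b_pls: np.ndarray  # (m, p) normalized slopes
    x_loadings: np.ndarray  # (m, c)
    y_loadings: np.ndarray  # (p, c)
    n_components: int
    delta_r: np.ndarray  # (m, p) original units
    x_residuals: np.ndarray  # (n, m) original-unit X-block residuals
    cv_table: pd.DataFrame
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    n: int
    param_names: list[str]
    dropped_params: list[str] = field(default_factory=list)
    contrast: np.ndarray | None = None  # categorical: delta_r B minus A
    X0: np.ndarray | None = None  # normalized design kept for permutations
    Y0: np.ndarray | None = None


class BehaviorPLSR(BaseEstimator, RegressorMixin):
    """Behavior-parameter PLSR pipeline for one mouse and behavior period.

    normalize -> TSR-impute missing pupil -> select components by
    CV+BIC -> SIMPLS -> original-unit slope matrix.  ``X`` is the window
    observation matrix (Fisher-z edges, or node dF/F% for the
    fluorescence analogue); ``Y`` the behavior parameters.  Parameters
    constant within the period are dropped with a log entry.  An
    intercept column of ones is appended to the normalized X.
    """

    def __init__(self, c_max: int = 10, folds: int = 10, mc_reps: int = 10,
                 var_target: float = 0.85, max_pcs: int = 10, tsr_tol: float = 1e-10,
                 tsr_max_iter: int = 1000, seed: int = 0):
        self.c_max = c_max
        self.folds = folds
        self.mc_reps = mc_reps
        self.var_target = var_target
        self.max_pcs = max_pcs
        self.tsr_tol = tsr_tol
        self.tsr_max_iter = tsr_max_iter
        self.seed = seed

    def fit(self, X: np.ndarray, Y: np.ndarray, param_names: list[str] | None = None,
            stratify_labels: np.ndarray | None = None) -> "BehaviorPLSR":
        X = np.asarray(X, float)
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.shape[0] == 1 and X.shape[0] != 1:
            Y = Y.T
        names = list(param_names) if param_names else [f"y{i}" for i in range(Y.shape[1])]

        # row-complete requirement on X; missingness in Y handled by TSR
        keep_rows = np.isfinite(X).all(axis=1)
        if not keep_rows.all():
            logger.info("dropping %d windows with missing edges", int((~keep_rows).sum()))
            X, Y = X[keep_rows], Y[keep_rows]
            if stratify_labels is not None:
                stratify_labels = np.asarray(stratify_labels)[keep_rows]

        n_distinct = [len(np.unique(Y[np.isfinite(Y[:, j]), j])) for j in range(Y.shape[1])]
        keep = [j for j, d in enumerate(n_distinct) if d >= 2]
        self.dropped_params_ = [names[j] for j in range(Y.shape[1]) if j not in keep]
        if self.dropped_params_:
            logger.info("dropping constant parameters: %s", self.dropped_params_)
        if not keep:
            raise ValueError("every parameter is constant within this period")
        Y = Y[:, keep]
        self.param_names_ = [names[j] for j in keep]

        X0, x_mean, sigma_x = zscore_columns(X)
        self.x_mean_raw_ = x_mean
        Y0, _, sigma_y = zscore_columns(Y)
        if np.isnan(Y0).any():
            M = np.hstack([X0, Y0])
            M, self.tsr_info_ = tsr_impute(M, self.var_target, self.max_pcs,
                                           self.tsr_tol, self.tsr_max_iter)
            X0, Y0 = M[:, :X0.shape[1]], M[:, X0.shape[1]:]
        X0i = np.hstack([X0, np.ones((X0.shape[0], 1))])

        c, cv_table = select_ncomp(X0i, Y0, self.folds, self.mc_reps, self.c_max,
                                   stratify_labels, self.seed)
        core = SIMPLSRegression(c).fit(X0i, Y0)
        m = X.shape[1]
        dr = delta_r(core.x_loadings_[:m], core.y_loadings_, X0.shape[0],
                     sigma_x, sigma_y)
        self.n_components_ = core.n_components_
        self.core_ = core
        self.sigma_x_, self.sigma_y_ = sigma_x, sigma_y
        self.delta_r_ = dr
        self.cv_table_ = cv_table
        # original-unit confound-removed observations: the within-period
        # component structure is subtracted but the period's mean level is
        # kept, so across-period contrasts remain measurable downstream
        self.x_residuals_ = core.x_residuals_[:, :m] * sigma_x[None, :] + x_mean[None, :]
        self.X0_, self.Y0_ = X0i, Y0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X0 = (np.asarray(X, float) - self.x_mean_raw_) / np.where(
            self.sigma_x_ > 0, self.sigma_x_, 1.0)
        X0i = np.hstack([X0, np.ones((X0.shape[0], 1))])
        return self.core_.predict(X0i)

    def result(self) -> PlsrResult:
        m = len(self.sigma_x_)
        return PlsrResult(
            b_pls=self.core_.coef_[:m], x_loadings=self.core_.x_loadings_[:m],
            y_loadings=self.core_.y_loadings_, n_components=self.n_components_,
            delta_r=self.delta_r_, x_residuals=self.x_residuals_,
            cv_table=self.cv_table_, sigma_x=self.sigma_x_, sigma_y=self.sigma_y_,
            n=self.X0_.shape[0], param_names=self.param_names_,
            dropped_params=self.dropped_params_, X0=self.X0_, Y0=self.Y0_,
        )


CONTINUOUS_PARAMS = ("speed", "accel", "duration", "pupil")
_PARAM_COLUMNS = {"speed": "mean_speed", "accel": "mean_abs_accel",
                  "duration": "duration", "pupil": "mean_pupil"}


def continuous_regression(X: np.ndarray, meta: pd.DataFrame,
                          parameters=CONTINUOUS_PARAMS, **plsr_kwargs) -> PlsrResult:
    """Regress behavior parameters against FC (or dF/F%) in one period.

    ``X``: window observations (edges or nodes); ``meta``: the window
    table carrying mean_speed, mean_abs_accel, duration, mean_pupil.
    The X-block residuals in the result are the parameter-removed
    correlations kept for the categorical stage.
    """
    if not parameters:
        raise ValueError("parameter set is empty")
    Y = np.column_stack([meta[_PARAM_COLUMNS[p]].to_numpy(float) for p in parameters])
    est = BehaviorPLSR(**plsr_kwargs).fit(X, Y, list(parameters))
    return est.result()


def categorical_regression(resid_a: np.ndarray, resid_b: np.ndarray,
                           seed: int = 0, **plsr_kwargs) -> PlsrResult:
    """Dummy-coded period-A-vs-period-B regression on residual FC.

    Stacks the two periods' parameter-removed observations, codes each
    row as (1, 0) or (0, 1), normalizes the dummies by column, and fits
    with stratified contiguous cross-validation.  ``contrast`` is
    delta_r(B) - delta_r(A) per edge: positive means higher in B.
    """
    resid_a, resid_b = np.asarray(resid_a, float), np.asarray(resid_b, float)
    if len(resid_a) == 0 or len(resid_b) == 0:
        raise ValueError("both periods must contribute observations")
    X = np.vstack([resid_a, resid_b])
    labels = np.r_[np.zeros(len(resid_a), int), np.ones(len(resid_b), int)]
    Y = np.column_stack([(labels == 0).astype(float), (labels == 1).astype(float)])
    est = BehaviorPLSR(seed=seed, **plsr_kwargs).fit(X, Y, ["period_a", "period_b"],
                                                     stratify_labels=labels)
    res = est.result()
    res.contrast = res.delta_r[:, 1] - res.delta_r[:, 0]
    return res


def fluorescence_regression(mean_dff: np.ndarray, meta: pd.DataFrame,
                            parameters=CONTINUOUS_PARAMS, **plsr_kwargs) -> PlsrResult:
    """Continuous PLSR on per-node mean dF/F% instead of edges; slopes are
    reported as change in fluorescence as a percent of the mean."""
    return continuous_regression(mean_dff, meta, parameters, **plsr_kwargs)


# ---------------------------------------------------------------------------
# permutation significance

@dataclass
class SignificanceResult:
    observed: np.ndarray  # mouse-averaged delta_r (m,) or (m, p)
    null_mean: np.ndarray
    null_sd: np.ndarray
    p_values: np.ndarray
    fdr_mask: np.ndarray
    n_permutations: int
    flagged: np.ndarray | None = None  # entries with null sd = 0


def _refit_stat(X0, Y0, c, sigma_x, sigma_y, contrast: bool):
    f = _simpls(X0, Y0, c)
    m = len(sigma_x)
    dr = delta_r(f["x_loadings"][:m], f["y_loadings"], X0.shape[0], sigma_x, sigma_y)
    if contrast:
        return dr[:, 1] - dr[:, 0]
    return dr


def permutation_significance(mouse_fits: list[PlsrResult], n_perm: int = 1000,
                             seed: int = 0, alpha: float = 0.05,
                             contrast: bool = False) -> SignificanceResult:
    """Permutation + FDR significance of the mouse-averaged slopes.

    Per mouse and permutation, the rows of Y are circularly shifted
    against X by a random offset and the PLSR refit at that mouse's
    selected component count; null slope matrices are averaged across
    mice at matched permutation index so the null matches the observed
    across-mouse mean.  The rotation scheme (rather than a full row
    shuffle) preserves the serial dependence of the overlapping sliding
    windows, keeping the null spread honest for autocorrelated
    observations.  P-values come from a two-tailed z-test against the
    averaged null, corrected by Benjamini-Hochberg across edges (or
    nodes).
    """
    if not mouse_fits:
        raise ValueError("no fitted mice")
    stat = (lambda r: r.contrast) if contrast else (lambda r: r.delta_r)
    observed = np.mean([stat(r) for r in mouse_fits], axis=0)
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(len(mouse_fits))]
    null = np.zeros((n_perm,) + observed.shape)
    for mi, res in enumerate(mouse_fits):
        if res.X0 is None or res.Y0 is None:
            raise ValueError("PlsrResult must retain X0/Y0 for permutation")
        n_rows = res.Y0.shape[0]
        for k in range(n_perm):
            offset = int(rngs[mi].integers(1, n_rows))
            null[k] += _refit_stat(res.X0, np.roll(res.Y0, offset, axis=0),
                                   res.n_components, res.sigma_x, res.sigma_y, contrast)
    null /= len(mouse_fits)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    flagged = null_sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / np.where(flagged, 1.0, null_sd)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(flagged, 1.0, p)
    rej, *_ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")[:1]
    return SignificanceResult(observed, null_mean, null_sd, p,
                              rej.reshape(p.shape), n_perm, flagged)


# ---------------------------------------------------------------------------
# activation vs FC relation

def node_total_connectivity(delta_r_edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Per-node total connectivity change: mean slope over the node's edges."""
    iu = np.triu_indices(n_nodes, k=1)
    out = np.zeros(n_nodes)
    counts = np.zeros(n_nodes)
    for e, (i, j) in enumerate(zip(*iu)):
        out[i] += delta_r_edges[e]
        out[j] += delta_r_edges[e]
        counts[i] += 1
        counts[j] += 1
    return out / counts


def activation_fc_relation(per_mouse: list[dict], homolog_pairs: list[tuple[int, int]],
                           alpha: float = 0.05, min_comparisons: int = 3) -> pd.DataFrame:
    """Correlate activation changes with total-FC changes per homolog pair.

    ``per_mouse[mi]`` maps family name (across-periods, speed, accel,
    duration, pupil) to a list of comparisons, each a dict with
    ``dfluor`` (n_nodes,) and ``dconn`` (n_nodes,).  For each homolog
    pair and family, the pair-averaged values are correlated across the
    family's comparisons, one r per mouse, then tested across mice with
    a two-tailed one-sample t-test (df = n_mice - 1) and BH-FDR over all
    pair x family relationships.  Families with fewer than 3 comparisons
    are skipped.
    """
    families = sorted({fam for m in per_mouse for fam in m})
    rows = []
    for fam in families:
        n_comp = min(len(m.get(fam, [])) for m in per_mouse)
        if n_comp < min_comparisons:
            logger.info("family %s skipped (<%d comparisons)", fam, min_comparisons)
            continue
        for pair_idx, (lid, rid) in enumerate(homolog_pairs, start=1):
            rs = []
            for m in per_mouse:
                comps = m[fam]
                df = np.array([(c["dfluor"][lid - 1] + c["dfluor"][rid - 1]) / 2 for c in comps])
                dc = np.array([(c["dconn"][lid - 1] + c["dconn"][rid - 1]) / 2 for c in comps])
                if df.std() == 0 or dc.std() == 0:
                    rs.append(0.0)
                else:
                    rs.append(float(np.corrcoef(df, dc)[0, 1]))
            rs = np.asarray(rs)
            if len(rs) > 1 and rs.std(ddof=1) > 0:
                t, p = stats.ttest_1samp(rs, 0.0)
            else:
                t, p = (np.inf if abs(rs.mean()) > 0 else 0.0), (0.0 if abs(rs.mean()) > 0 else 1.0)
            rows.append({"family": fam, "homolog_id": pair_idx, "mean_r": rs.mean(),
                         "t_stat": float(t), "df": len(rs) - 1, "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = multipletests(out["p"], alpha=alpha, method="fdr_bh")[0]
    return out
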