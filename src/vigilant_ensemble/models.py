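"""The three component predictors and their equal-weight ensemble.

For participant *i* at time *t* the outcome (LRM-50) is modelled three ways:

* **Linear mixed effects (LME)** —
  ``y_it = β0 + X_it β + b_i + ε_it`` with a person-specific random
  intercept ``b_i ~ N(0, σ_b²)`` and residuals following a lag-one
  autoregressive (AR1) correlation structure within person,
  ``corr(ε_ij, ε_ik) = ρ^|j−k|`` indexed by observation order.  Fit by
  (restricted) maximum likelihood: β is profiled out by generalized least
  squares at each variance-parameter evaluation and (σ_b, ρ, σ) are
  optimized numerically.

* **Random forest** — a seeded regression forest (no closed form; captures
  non-linearities and interactions), via scikit-learn.

* **Functional concurrent model (FCM)** —
  ``y_ij = β0 + Σ_p f_p(X_ij^(p), t_ij) + b_i(t_ij) + ε_ij`` where each
  ``f_p`` is a smooth surface over (covariate value, mission fraction) and
  ``b_i(t)`` are smooth person-level random curves.  Surfaces are
  tensor-product penalized B-splines (second-order difference penalties,
  which leave bilinear surfaces — hence purely linear, time-constant
  effects — unpenalized); random curves are ridge-penalized per-person
  splines that shrink to zero for unseen participants.  Smoothing is chosen
  by generalized cross-validation.

The ensemble prediction is the arithmetic mean of the three components'
predictions (equal weights by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "LMEFit",
    "RFFit",
    "FCMFit",
    "EnsembleFit",
    "fit_lme",
    "fit_rf",
    "fit_fcm",
    "fit_ensemble",
    "predict_ensemble",
    "effect_heatmap",
]

logger = logging.getLogger(__name__)


def _design(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    X = df[list(covariates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in covariates if df[c].isna().any()]
        raise ValueError(f"covariates contain missing values: {bad}")
    return X


# ==========================================================================
# linear mixed effects with AR(1) residuals
# ==========================================================================


@dataclass
class LMEFit:
    """Random-intercept LME with AR(1) residual correlation."""

    covariates: list[str]
    beta0: float
    beta: pd.Series
    beta_se: pd.Series
    sigma_person: float
    rho: float
    sigma: float  # marginal residual sd
    ranef: dict[str, float]
    loglik: float
    reml: bool
    converged: bool
    outcome: str = "lrm50"
    group: str = "participant"

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.covariates)
        yhat = self.beta0 + X @ self.beta.to_numpy()
        # unseen participants: random effect 0 (group-average prediction)
        b = df[self.group].map(self.ranef).fillna(0.0).to_numpy()
        return yhat + b


def _lme_neg_loglik(theta, X, y, group_slices, reml):
    log_sb, z_rho, log_se = theta
    sb2 = np.exp(2.0 * log_sb)
    rho = np.tanh(z_rho)
    se2 = np.exp(2.0 * log_se)
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    chols = []
    for lo, hi in group_slices:
        n_g = hi - lo
        idx = np.arange(n_g)
        R = rho ** np.abs(idx[:, None] - idx[None, :])
        V = sb2 + se2 * R  # sb2 * ones + se2 * AR1
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None, None, None
        chols.append((c, low))
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        Xg, yg = X[lo:hi], y[lo:hi]
        Vi_X = linalg.cho_solve((c, low), Xg, check_finite=False)
        XtVX += Xg.T @ Vi_X
        XtVy += Vi_X.T @ yg
    try:
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf, None, None, None
    quad = 0.0
    for (lo, hi), (c, low) in zip(group_slices, chols):
        r = y[lo:hi] - X[lo:hi] @ beta
        quad += r @ linalg.cho_solve((c, low), r, check_finite=False)
    n = len(y)
    nll = 0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        nll += 0.5 * ld - 0.5 * p * np.log(2.0 * np.pi)
    return nll, beta, XtVX, (sb2, rho, se2)


def fit_lme(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    group: str = "participant",
    reml: bool = True,
    drop_collinear: bool = False,
) -> LMEFit:
    """Fit the random-intercept AR(1) LME by (RE)ML.

    Rows must be ordered by observation sequence within participant (the
    AR(1) index is within-person observation order).  Raises on
    rank-deficient designs, naming the collinear covariates; with
    ``drop_collinear`` the offending columns are dropped with a log entry
    instead (useful inside resampling loops where rare binary flags can go
    constant in a training subset).
    """
    df = df.sort_values([group, "timestamp"]) if "timestamp" in df.columns else df
    df = df.reset_index(drop=True)
    groups = df[group].to_numpy()
    ids, counts = np.unique(groups, return_counts=True)
    if len(ids) < 2:
        raise ValueError("need at least 2 participants")
    if (counts < 3).any():
        small = ids[counts < 3].tolist()
        logger.warning("participants with <3 observations: %s", small)
    X1 = _design(df, covariates)
    X = np.column_stack([np.ones(len(df)), X1])
    # scale-free rank check (binary flags vs large-scale columns)
    sds = X1.std(axis=0)
    Z = np.column_stack(
        [np.ones(len(df)), (X1 - X1.mean(axis=0)) / np.where(sds > 0, sds, 1.0)]
    )
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns greedily
        bad = []
        keep = [0]
        for j in range(1, Z.shape[1]):
            if np.linalg.matrix_rank(Z[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(covariates[j - 1])
        if not drop_collinear:
            raise ValueError(f"rank-deficient design; collinear covariates: {bad}")
        logger.info("dropping collinear covariates: %s", bad)
        covariates = [c for c in covariates if c not in bad]
        X1 = _design(df, covariates)
        X = np.column_stack([np.ones(len(df)), X1])
    y = df[outcome].to_numpy(dtype=float)

    slices = []
    lo = 0
    for pid in pd.unique(groups):
        n_g = int((groups == pid).sum())
        slices.append((lo, lo + n_g))
        lo += n_g

    # starting values from a pooled OLS decomposition
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    means = np.array([resid[a:b].mean() for a, b in slices])
    sb0 = max(means.std(), 1e-2)
    se0 = max(np.std(resid - np.repeat(means, [b - a for a, b in slices])), 1e-2)
    theta0 = np.array([np.log(sb0), np.arctanh(0.2), np.log(se0)])

    def obj(theta):
        return _lme_neg_loglik(theta, X, y, slices, reml)[0]

    res = optimize.minimize(obj, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 1000})
    nll, beta, XtVX, (sb2, rho, se2) = _lme_neg_loglik(res.x, X, y, slices, reml)
    se_beta = np.sqrt(np.diag(np.linalg.inv(XtVX)))

    # BLUPs of the random intercepts
    ranef = {}
    for (a, b_), pid in zip(slices, pd.unique(groups)):
        n_g = b_ - a
        idx = np.arange(n_g)
        V = sb2 + se2 * (rho ** np.abs(idx[:, None] - idx[None, :]))
        r = y[a:b_] - X[a:b_] @ beta
        ranef[pid] = float(sb2 * np.sum(linalg.solve(V, r, assume_a="pos")))

    return LMEFit(
        covariates=list(covariates),
        beta0=float(beta[0]),
        beta=pd.Series(beta[1:], index=list(covariates)),
        beta_se=pd.Series(se_beta[1:], index=list(covariates)),
        sigma_person=float(np.sqrt(sb2)),
        rho=float(rho),
        sigma=float(np.sqrt(se2)),
        ranef=ranef,
        loglik=float(-nll),
        reml=reml,
        converged=bool(res.success),
        outcome=outcome,
        group=group,
    )


# ==========================================================================
# random forest
# ==========================================================================


@dataclass
class RFFit:
    covariates: list[str]
    forest: RandomForestRegressor
    oob_score: float | None
    seed: int
    outcome: str = "lrm50"

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(_design(df, self.covariates))


def fit_rf(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int = 0,
) -> RFFit:
    """Seeded regression forest; regression-convention defaults
    (mtry = ⌊p/3⌋, minimum leaf 5), out-of-bag error recorded."""
    X = _design(df, covariates)
    y = df[outcome].to_numpy(dtype=float)
    p = len(covariates)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry or max(1, p // 3),
        min_samples_leaf=min_leaf,
        oob_score=len(df) >= 15,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    oob = float(forest.oob_score_) if hasattr(forest, "oob_score_") and forest.oob_score else None
    return RFFit(covariates=list(covariates), forest=forest, oob_score=oob,
                 seed=seed, outcome=outcome)


# ==========================================================================
# functional concurrent model
# ==========================================================================


def _bspline_basis(x: np.ndarray, lo: float, hi: float, n_basis: int, degree: int = 3):
    """Clamped cubic B-spline design matrix with quantile-free uniform
    interior knots on [lo, hi]; evaluation clamps x into the support."""
    from scipy.interpolate import BSpline

    if hi <= lo:
        hi = lo + 1.0
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


def _diff_penalty(n: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n), n=order, axis=0)
    return D.T @ D


@dataclass
class _FCMTerm:
    name: str
    kind: str  # "tensor" | "varying" | "linear"
    x_range: tuple[float, float]
    col_means: np.ndarray
    n_cols: int


@dataclass
class FCMFit:
    """Penalized-spline functional concurrent fit."""

    covariates: list[str]
    terms: list[_FCMTerm]
    coef: np.ndarray
    intercept_idx: int
    term_slices: dict[str, slice]
    re_slices: dict[str, slice]  # per-participant random-curve blocks
    t_range: tuple[float, float]
    k_x: int
    k_t: int
    k_re: int
    lam_f: float
    lam_b: float
    gcv: float
    outcome: str = "lrm50"
    group: str = "participant"
    time_col: str = "mission_frac"

    def _build_design(self, df: pd.DataFrame, with_re: bool = True) -> np.ndarray:
        n = len(df)
        t = df[self.time_col].to_numpy(dtype=float)
        Bt = _bspline_basis(t, *self.t_range, self.k_t)
        blocks = [np.ones((n, 1))]
        for term in self.terms:
            x = df[term.name].to_numpy(dtype=float)
            if term.kind == "tensor":
                Bx = _bspline_basis(x, *term.x_range, self.k_x)
                Z = (Bx[:, :, None] * Bt[:, None, :]).reshape(n, -1)
            elif term.kind == "varying":
                Z = x[:, None] * Bt
            else:  # linear
                Z = x[:, None]
            blocks.append(Z - term.col_means)
        if with_re:
            Bre = _bspline_basis(t, *self.t_range, self.k_re)
            for pid, sl in self.re_slices.items():
                Z = np.zeros((n, self.k_re))
                mask = (df[self.group] == pid).to_numpy()
                Z[mask] = Bre[mask]
                blocks.append(Z)
        return np.column_stack(blocks)

    def predict(self, df: pd.DataFrame, *, population: bool = False) -> np.ndarray:
        _design(df, self.covariates)  # validates presence/NaN
        Z = self._build_design(df, with_re=not population)
        coef = self.coef if not population else self.coef[: self.re_start]
        return Z[:, : len(coef)] @ coef

    @property
    def re_start(self) -> int:
        if not self.re_slices:
            return len(self.coef)
        return min(sl.start for sl in self.re_slices.values())


def fit_fcm(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    group: str = "participant",
    time_col: str = "mission_frac",
    k_x: int = 5,
    k_t: int = 5,
    k_re: int = 5,
    modes: dict[str, str] | None = None,
    lam_f_grid: np.ndarray | None = None,
    lam_b_grid: np.ndarray | None = None,
) -> FCMFit:
    """Fit the functional concurrent model by penalized least squares with
    GCV-selected smoothing.

    Covariates with ≥ 6 distinct values get a full (value × time) tensor
    surface; discrete/binary ones get a time-varying coefficient
    (x · spline(t)); ``modes`` overrides per covariate
    ("tensor" | "varying" | "linear").
    """
    if time_col not in df.columns:
        raise ValueError(f"time column {time_col!r} required")
    t = df[time_col].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time values")
    X = _design(df, covariates)
    y = df[outcome].to_numpy(dtype=float)
    n = len(df)
    t_range = (float(t.min()), float(t.max()))

    modes = modes or {}
    terms: list[_FCMTerm] = []
    blocks = [np.ones((n, 1))]
    pen_diag_f = [np.zeros((1, 1))]
    Bt = _bspline_basis(t, *t_range, k_t)
    Pt = _diff_penalty(k_t)
    Px = _diff_penalty(k_x)
    for j, name in enumerate(covariates):
        x = X[:, j]
        uniq = len(np.unique(x))
        kind = modes.get(name, "tensor" if uniq >= 6 else "varying")
        x_range = (float(x.min()), float(x.max()))
        if kind == "tensor":
            Bx = _bspline_basis(x, *x_range, k_x)
            Z = (Bx[:, :, None] * Bt[:, None, :]).reshape(n, -1)
            P = np.kron(Px, np.eye(k_t)) + np.kron(np.eye(k_x), Pt)
        elif kind == "varying":
            Z = x[:, None] * Bt
            P = Pt
        elif kind == "linear":
            Z = x[:, None]
            P = np.zeros((1, 1))
        else:
            raise ValueError(f"unknown FCM mode {kind!r} for {name!r}")
        mu = Z.mean(axis=0, keepdims=True)
        blocks.append(Z - mu)
        pen_diag_f.append(P)
        terms.append(
            _FCMTerm(name=name, kind=kind, x_range=x_range, col_means=mu,
                     n_cols=Z.shape[1])
        )

    # per-participant random curves (ridge penalty -> shrink to 0)
    pids = list(pd.unique(df[group])) if group in df.columns else []
    Bre = _bspline_basis(t, *t_range, k_re)
    re_blocks = []
    for pid in pids:
        Z = np.zeros((n, k_re))
        mask = (df[group] == pid).to_numpy()
        Z[mask] = Bre[mask]
        re_blocks.append(Z)

    Zf = np.column_stack(blocks)
    m_f = Zf.shape[1]
    Zall = np.column_stack([Zf] + re_blocks) if re_blocks else Zf
    m = Zall.shape[1]

    Pf = linalg.block_diag(*pen_diag_f)
    Pf_full = np.zeros((m, m))
    Pf_full[:m_f, :m_f] = Pf
    Pb_full = np.zeros((m, m))
    Pb_full[m_f:, m_f:] = np.eye(m - m_f)

    ZtZ = Zall.T @ Zall
    Zty = Zall.T @ y
    lam_f_grid = np.asarray(
        [1e-2, 1e-1, 1.0, 1e1, 1e2] if lam_f_grid is None else lam_f_grid
    )
    lam_b_grid = np.asarray([1e-1, 1.0, 1e1] if lam_b_grid is None else lam_b_grid)
    ridge = 1e-7 * (np.trace(ZtZ) / m) * np.eye(m)

    best = None
    for lf in lam_f_grid:
        for lb in lam_b_grid:
            A = ZtZ + lf * Pf_full + lb * Pb_full + ridge
            try:
                c, low = linalg.cho_factor(A)
            except linalg.LinAlgError:
                continue
            coef = linalg.cho_solve((c, low), Zty)
            edf = float(np.trace(linalg.cho_solve((c, low), ZtZ)))
            rss = float(np.sum((y - Zall @ coef) ** 2))
            denom = max(n - edf, 1e-6)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lf, lb, coef)
    if best is None:
        raise RuntimeError("FCM smoothing selection failed for every grid point")
    gcv, lam_f, lam_b, coef = best

    term_slices = {}
    pos = 1
    for term in terms:
        term_slices[term.name] = slice(pos, pos + term.n_cols)
        pos += term.n_cols
    re_slices = {}
    for pid in pids:
        re_slices[pid] = slice(pos, pos + k_re)
        pos += k_re

    return FCMFit(
        covariates=list(covariates),
        terms=terms,
        coef=coef,
        intercept_idx=0,
        term_slices=term_slices,
        re_slices=re_slices,
        t_range=t_range,
        k_x=k_x,
        k_t=k_t,
        k_re=k_re,
        lam_f=float(lam_f),
        lam_b=float(lam_b),
        gcv=float(gcv),
        outcome=outcome,
        group=group,
        time_col=time_col,
    )


def effect_heatmap(
    fcm: FCMFit,
    covariate: str,
    data: pd.DataFrame,
    *,
    x_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted-outcome surface over (covariate value, mission fraction).

    All other covariates are held at their average (continuous) or reference
    value (binary → modal value) computed from ``data``; the random curve is
    omitted (population-level surface).  Returns ``(matrix, x_grid,
    t_grid)`` with ``matrix[a, b]`` the prediction at ``(x_grid[a],
    t_grid[b])``.
    """
    if covariate not in fcm.covariates:
        raise ValueError(f"{covariate!r} is not a model covariate")
    x_obs = data[covariate].to_numpy(dtype=float)
    if x_grid is None:
        x_grid = np.linspace(x_obs.min(), x_obs.max(), 40)
    if t_grid is None:
        t_grid = np.linspace(fcm.t_range[0], fcm.t_range[1], 40)
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    rows = []
    for other in fcm.covariates:
        col = data[other].to_numpy(dtype=float)
        if len(np.unique(col)) <= 2:  # categorical/binary -> reference level
            vals, counts = np.unique(col, return_counts=True)
            rows.append(vals[np.argmax(counts)])
        else:
            rows.append(float(col.mean()))
    base = dict(zip(fcm.covariates, rows))
    grid_rows = []
    for xv in x_grid:
        for tv in t_grid:
            r = dict(base)
            r[covariate] = xv
            r[fcm.time_col] = tv
            r[fcm.group] = "__new__"
            grid_rows.append(r)
    gdf = pd.DataFrame(grid_rows)
    preds = fcm.predict(gdf, population=True)
    return preds.reshape(len(x_grid), len(t_grid)), x_grid, t_grid


# ==========================================================================
# ensemble
# ==========================================================================


@dataclass
class EnsembleFit:
    lme: LMEFit
    rf: RFFit
    fcm: FCMFit
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")
        if not self.covariates:
            self.covariates = list(self.lme.covariates)

    def component_predictions(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lme": self.lme.predict(df),
                "rf": self.rf.predict(df),
                "fcm": self.fcm.predict(df),
            },
            index=df.index,
        )

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        comp = self.component_predictions(df)
        w = np.asarray(self.weights)
        return comp.to_numpy() @ w


def fit_ensemble(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    seed: int = 0,
    rf_kwargs: dict | None = None,
    fcm_kwargs: dict | None = None,
    lme_kwargs: dict | None = None,
) -> EnsembleFit:
    """Fit all three components on the same rows.

    The internal LME drops collinear covariates (with a log entry) instead
    of raising, so a rare binary flag going constant in a resampled
    training set degrades gracefully; pass ``lme_kwargs`` to override.
    """
    lme = fit_lme(df, covariates, outcome,
                  **{"drop_collinear": True, **(lme_kwargs or {})})
    rf = fit_rf(df, covariates, outcome, seed=seed, **(rf_kwargs or {}))
    fcm = fit_fcm(df, covariates, outcome, **(fcm_kwargs or {}))
    return EnsembleFit(lme=lme, rf=rf, fcm=fcm, covariates=list(covariates))


def predict_ensemble(fit: EnsembleFit, df: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of the three component predictions."""
    return fit.predict(df)
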