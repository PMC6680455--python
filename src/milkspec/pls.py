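"""PLS1 regression with leave-one-out cross-validation and latent-variable selection.

Implements mean-centred single-response partial least squares (NIPALS), the
PRESS / RMSE_CV / R²_CV / RPD_CV fit statistics used throughout the package,
and a randomization test in the spirit of van der Voet (1994) for choosing
the number of latent variables: the smallest model whose out-of-fold squared
residuals are not significantly worse (p > 0.10) than those of the
PRESS-minimising model.

No autoscaling is applied: absorbance variables share one unit, so the
predictors are only centred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "loocv", "select_n_lv"]

#: Relative threshold below which an X-weight norm is treated as rank exhaustion.
_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted mean-centred PLS1 model.

    Attributes
    ----------
    x_weights, x_loadings : (n_variables, n_lv) arrays
        NIPALS weight and loading vectors per component.
    y_loadings : (n_lv,) array
        Regression of the (deflated) response on each score vector.
    coef : (n_variables,) array
        Regression coefficients on the original (uncentred) variable scale.
    x_mean, y_mean : centring offsets.
    n_lv : number of latent variables actually extracted (may be fewer than
        requested when the rank of X is exhausted).
    """

    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    n_lv: int

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary for one trait.

    Invariants (asserted at construction): RMSE_CV = sqrt(PRESS / n),
    RPD_CV = SD / RMSE_CV and R²_CV = 1 - PRESS / TSS, where SD is the
    n-1-denominator standard deviation of the reference values and TSS the
    total sum of squares about the full-sample mean.
    """

    press: float
    rmse_cv: float
    r2_cv: float
    rpd_cv: float
    n_lv: int
    predictions: np.ndarray = field(repr=False)
    sd: float = 0.0

    def __post_init__(self) -> None:
        n = self.predictions.size
        if not np.isclose(self.rmse_cv, np.sqrt(self.press / n), rtol=1e-10):
            raise ValueError("RMSE_CV inconsistent with PRESS")
        if self.rmse_cv > 0 and not np.isclose(
            self.rpd_cv, self.sd / self.rmse_cv, rtol=1e-10
        ):
            raise ValueError("RPD_CV inconsistent with SD and RMSE_CV")

    @classmethod
    def from_predictions(cls, y: np.ndarray, predictions: np.ndarray, n_lv: int) -> "CVResult":
        y = np.asarray(y, dtype=float)
        predictions = np.asarray(predictions, dtype=float)
        n = y.size
        press = float(np.sum((y - predictions) ** 2))
        rmse = float(np.sqrt(press / n))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - press / tss if tss > 0 else np.nan
        sd = float(np.std(y, ddof=1))
        rpd = sd / rmse if rmse > 0 else np.inf
        return cls(press=press, rmse_cv=rmse, r2_cv=r2, rpd_cv=rpd,
                   n_lv=n_lv, predictions=predictions, sd=sd)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} values")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite with no missing values")
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a mean-centred PLS1 model by NIPALS.

    Parameters
    ----------
    X : (n_samples, n_variables)
    y : (n_samples,)
    n_lv : requested number of latent variables (>= 1). If the rank of the
        centred X is exhausted earlier, the model is truncated with a warning.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n < 2:
        raise ValueError("at least 2 samples are required")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    max_rank = min(n - 1, p)
    if n_lv > max_rank:
        warnings.warn(
            f"n_lv={n_lv} exceeds max rank {max_rank}; reduced", stacklevel=2
        )
        n_lv = max_rank

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc) + 1.0

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    a_done = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _RANK_TOL * scale:
            warnings.warn(
                f"rank exhausted after {a} components; n_lv reduced", stacklevel=2
            )
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        pl = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc -= np.outer(t, pl)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pl, qa
        a_done = a + 1

    W, P, q = W[:, :a_done], P[:, :a_done], q[:a_done]
    # B = W (PᵀW)⁻¹ q maps original centred X to the component-space fit.
    coef = W @ np.linalg.solve(P.T @ W, q) if a_done else np.zeros(p)
    return PLSModel(x_weights=W, x_loadings=P, y_loadings=q, coef=coef,
                    x_mean=x_mean, y_mean=y_mean, n_lv=a_done)


def _loocv_predictions(
    X: np.ndarray, y: np.ndarray, max_lv: int, gram: np.ndarray | None = None
) -> np.ndarray:
    """Out-of-fold predictions for every model size 1..max_lv.

    Each of the n folds refits PLS1 on the other n-1 samples, re-centring
    inside the fold (no information leak), and predicts the held-out sample
    after each component. The folds are advanced in lockstep in
    cross-product form (kernel PLS with deflation carried on XᵀY only, per
    Dayal & MacGregor 1997, algebraically identical to NIPALS): each fold's
    centred XᵀX and XᵀY are rank-one downdates of the full-data
    cross-products, so the per-component cost collapses to a single matrix
    product shared by all folds.

    ``gram`` optionally supplies the precomputed full-data XᵀX (uncentred);
    callers scoring many column subsets of one matrix can pass a gathered
    submatrix of one precomputed Gram.

    Returns an (n, max_lv_effective) array; column a-1 holds the a-component
    predictions. Components past the within-fold rank leave the prediction
    unchanged.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise ValueError("LOOCV requires at least 3 samples")
    max_lv = min(max_lv, n - 2, p)
    if max_lv < 1:
        raise ValueError("max_lv must allow at least one component")

    G = X.T @ X if gram is None else np.asarray(gram, dtype=float)
    g = X.T @ y
    s = X.sum(axis=0)
    sy = float(y.sum())
    n1 = n - 1
    M = (s[None, :] - X) / n1            # per-fold training mean rows (n, p)
    ybar = (sy - y) / n1                 # per-fold training y means (n,)

    # Centred per-fold cross-products, columns = folds (p, n):
    #   XcᵀYc_i = g − y_i x_i − (Σy − y_i) m_i
    gc = (g[None, :] - y[:, None] * X - (sy - y)[:, None] * M).T.copy()
    Xt = X.T.copy()                      # (p, n), column i = x_i
    Mt = M.T.copy()
    xt_c = Xt - Mt                       # centred held-out samples
    scale = np.max(np.linalg.norm(gc, axis=0)) + 1.0

    preds = np.empty((n, max_lv))
    beta = np.zeros((p, n))
    Rs: list[np.ndarray] = []
    Ps: list[np.ndarray] = []
    for a in range(max_lv):
        nw = np.linalg.norm(gc, axis=0)
        live = nw > _RANK_TOL * scale
        w = np.where(live, gc / np.where(live, nw, 1.0), 0.0)
        r = w.copy()
        for rj, pj in zip(Rs, Ps):       # project to undeflated coordinates
            r -= rj * np.einsum("pn,pn->n", pj, w)
        # u_i = (XcᵀXc)_i r_i = G r_i − x_i (x_iᵀ r_i) − (n−1) m_i (m_iᵀ r_i)
        u = G @ r
        u -= Xt * np.einsum("pn,pn->n", Xt, r)
        u -= n1 * Mt * np.einsum("pn,pn->n", Mt, r)
        tt = np.einsum("pn,pn->n", r, u)
        tt_safe = np.where(tt > 0, tt, 1.0)
        ph = u / tt_safe
        qh = np.einsum("pn,pn->n", r, gc) / tt_safe
        gc -= ph * (tt * qh)
        beta += r * qh
        Rs.append(r)
        Ps.append(ph)
        preds[:, a] = ybar + np.einsum("pn,pn->n", xt_c, beta)
    return preds


def loocv(X: np.ndarray, y: np.ndarray, n_lv: int) -> CVResult:
    """Leave-one-out cross-validation of a PLS1 model with ``n_lv`` components.

    PRESS is the sum of squared out-of-fold residuals; RMSE_CV, R²_CV and
    RPD_CV follow from it (see :class:`CVResult`).
    """
    X, y = _validate_xy(X, y)
    n_lv_eff = min(n_lv, X.shape[0] - 2, X.shape[1])
    preds = _loocv_predictions(X, y, n_lv_eff)[:, -1]
    return CVResult.from_predictions(y, preds, n_lv_eff)


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    p_threshold: float = 0.10,
    n_randomizations: int = 1999,
    rng: np.random.Generator | int | None = None,
    gram: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the number of latent variables by PRESS plus a randomization test.

    LOOCV PRESS is computed for 1..max_lv components. Among models no larger
    than the global PRESS minimiser, the smallest one whose paired squared
    out-of-fold residuals are not significantly worse than the minimiser's
    (sign-randomization p-value > ``p_threshold``) is returned.

    The p-value for candidate model m versus the minimiser is the fraction of
    ``n_randomizations`` random sign assignments s of the paired differences
    d_i = e²_{i,m} - e²_{i,min} for which Σ s_i d_i >= Σ d_i. A non-positive
    observed difference gives p = 1. ``p_threshold <= 0`` degenerates to
    returning the PRESS-minimising model.

    Returns
    -------
    (chosen_lv, press) where press is the PRESS value per model size actually
    evaluated (length min(max_lv, n-2, p)).
    """
    X, y = _validate_xy(X, y)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    rng = np.random.default_rng(rng)
    preds = _loocv_predictions(X, y, max_lv, gram=gram)
    sq = (y[:, None] - preds) ** 2                 # (n, n_lv_evaluated)
    press = sq.sum(axis=0)
    lv_star = int(np.argmin(press)) + 1
    if p_threshold <= 0 or lv_star == 1:
        return lv_star, press

    n = y.size
    signs = rng.integers(0, 2, size=(n_randomizations, n)) * 2 - 1
    for lv in range(1, lv_star):
        d = sq[:, lv - 1] - sq[:, lv_star - 1]
        t_obs = d.sum()
        if t_obs <= 0:
            return lv, press
        p_val = float(np.mean(signs @ d >= t_obs))
        if p_val > p_threshold:
            return lv, press
    return lv_star, press
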