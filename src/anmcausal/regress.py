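"""One-dimensional nonparametric regression for ANM fitting.

Three methods are provided:

``spline``
    Penalized cubic B-spline (P-spline): equally spaced knots, a
    second-order difference penalty on the coefficients, and the
    penalty weight selected by generalized cross-validation (GCV)
    via the Demmler-Reinsch orthogonalization.  This is the default
    and the method used by the simulation studies.
``loess``
    Local polynomial regression (statsmodels lowess) with a fixed
    span of 0.75; predictions interpolate the fitted curve.
``bspline``
    Unpenalized least-squares cubic B-spline with the number of
    interior knots selected by GCV.

All methods standardize x and y internally (zero mean, unit variance)
and return predictions on the original scale, so fits are invariant to
affine rescaling of either variable.  Outside the training range the
curve is continued linearly from the boundary value and slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["RegressionFit", "fit_nonparametric", "residuals"]

_METHODS = ("spline", "loess", "bspline")

# upper end gives ~2 effective degrees of freedom (a straight line) at the
# sample sizes in use while keeping the penalized system well conditioned
_LAMBDA_GRID = np.logspace(-6, 5, 45)


@dataclass
class RegressionFit:
    """A fitted 1-D regression curve with linear extrapolation.

    ``_predict_std`` maps standardized x to standardized y inside the
    training range; the public :meth:`predict` handles de/standardization
    and linear continuation beyond ``training_range``.
    """

    method: str
    training_range: tuple[float, float]
    predictor_mean: float
    predictor_sd: float
    response_mean: float
    response_sd: float
    _predict_std: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _boundary: tuple[float, float, float, float] = field(repr=False)  # f(lo), f'(lo), f(hi), f'(hi)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x - self.predictor_mean) / self.predictor_sd
        lo, hi = self.training_range
        zlo = (lo - self.predictor_mean) / self.predictor_sd
        zhi = (hi - self.predictor_mean) / self.predictor_sd
        out = np.empty_like(z)
        inside = (z >= zlo) & (z <= zhi)
        if inside.any():
            out[inside] = self._predict_std(z[inside])
        flo, slo, fhi, shi = self._boundary
        below = z < zlo
        above = z > zhi
        if below.any():
            out[below] = flo + slo * (z[below] - zlo)
        if above.any():
            out[above] = fhi + shi * (z[above] - zhi)
        return out * self.response_sd + self.response_mean


def _pspline_std(z: np.ndarray, w: np.ndarray, nbasis: int = 20):
    """P-spline on standardized data; returns (callable, boundary tuple)."""
    order = 3
    zlo, zhi = float(z.min()), float(z.max())
    # uniform extended knot grid: with equal spacing everywhere the
    # difference penalty's null space is exactly the linear functions
    nseg = nbasis - order
    h = (zhi - zlo) / nseg
    knots = zlo + h * np.arange(-order, nseg + order + 1)
    # clip so design_matrix never sees out-of-range values from rounding
    zlo, zhi = knots[order], knots[-order - 1]
    B = BSpline.design_matrix(np.clip(z, zlo, zhi), knots, order).toarray()
    n, K = B.shape
    D = np.diff(np.eye(K), 2, axis=0)
    S = D.T @ D
    BtB = B.T @ B
    # tiny ridge keeps the Cholesky well posed when basis columns are empty
    R = np.linalg.cholesky(BtB + 1e-8 * np.eye(K)).T
    Rinv = np.linalg.inv(R)
    d, U = np.linalg.eigh(Rinv.T @ S @ Rinv)
    d = np.clip(d, 0.0, None)
    zc = U.T @ (Rinv.T @ (B.T @ w))
    wtw = float(w @ w)
    best_gcv, best_lam = np.inf, _LAMBDA_GRID[0]
    for lam in _LAMBDA_GRID:
        shrink = 1.0 / (1.0 + lam * d)
        coef_rot = zc * shrink
        rss = wtw - 2.0 * (zc @ coef_rot) + coef_rot @ coef_rot
        edf = float(shrink.sum())
        gcv = n * max(rss, 0.0) / (n - edf) ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    beta = Rinv @ (U @ (zc / (1.0 + best_lam * d)))
    spl = BSpline(knots, beta, order, extrapolate=False)
    dspl = spl.derivative()
    boundary = (float(spl(zlo)), float(dspl(zlo)), float(spl(zhi)), float(dspl(zhi)))

    def predict(q: np.ndarray) -> np.ndarray:
        return spl(np.clip(q, zlo, zhi))

    return predict, boundary


def _lsq_bspline_std(z: np.ndarray, w: np.ndarray):
    """Least-squares B-spline; interior-knot count chosen by GCV."""
    order = 3
    zlo, zhi = float(z.min()), float(z.max())
    n = z.size
    best = None
    for n_interior in (0, 1, 2, 4, 6, 8, 12, 16):
        interior = np.linspace(zlo, zhi, n_interior + 2)
        knots = np.r_[[zlo] * order, interior, [zhi] * order]
        B = BSpline.design_matrix(np.clip(z, zlo, zhi), knots, order).toarray()
        K = B.shape[1]
        if K >= n:
            break
        beta, *_ = np.linalg.lstsq(B + 0.0, w, rcond=None)
        rss = float(np.sum((B @ beta - w) ** 2))
        gcv = n * rss / (n - K) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, knots, beta)
    assert best is not None
    _, knots, beta = best
    spl = BSpline(knots, beta, order, extrapolate=False)
    dspl = spl.derivative()
    boundary = (float(spl(zlo)), float(dspl(zlo)), float(spl(zhi)), float(dspl(zhi)))

    def predict(q: np.ndarray) -> np.ndarray:
        return spl(np.clip(q, zlo, zhi))

    return predict, boundary


def _loess_std(z: np.ndarray, w: np.ndarray, frac: float = 0.75):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(w, z, frac=frac, return_sorted=True)
    zs, ws = fitted[:, 0], fitted[:, 1]
    zs, idx = np.unique(zs, return_index=True)
    ws = ws[idx]
    if zs.size < 2:
        raise ValueError("loess needs at least two distinct predictor values")
    slo = (ws[1] - ws[0]) / (zs[1] - zs[0])
    shi = (ws[-1] - ws[-2]) / (zs[-1] - zs[-2])
    boundary = (float(ws[0]), float(slo), float(ws[-1]), float(shi))

    def predict(q: np.ndarray) -> np.ndarray:
        return np.interp(q, zs, ws)

    return predict, boundary


def fit_nonparametric(
    x_train: np.ndarray, y_train: np.ndarray, method: str = "spline"
) -> RegressionFit:
    """Fit y on x with the chosen smoother.

    Requires n >= 10 and a non-constant predictor.  Smoothing strength
    (penalty weight or knot count) is selected by GCV for the spline
    methods; loess uses a fixed span of 0.75.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    x = np.asarray(x_train, dtype=float).ravel()
    y = np.asarray(y_train, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x_train and y_train must have equal length")
    if x.size < 10:
        raise ValueError(f"need at least 10 training points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("training data contain non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression is degenerate")

    mx, sx = float(x.mean()), float(x.std())
    my, sy = float(y.mean()), float(y.std())
    if sx == 0:  # unreachable given the ptp check, kept for safety
        sx = 1.0
    if sy == 0:
        sy = 1.0
    z = (x - mx) / sx
    w = (y - my) / sy

    if method == "spline":
        nbasis = min(20, max(6, x.size // 2))
        predict_std, boundary = _pspline_std(z, w, nbasis=nbasis)
    elif method == "bspline":
        predict_std, boundary = _lsq_bspline_std(z, w)
    else:
        predict_std, boundary = _loess_std(z, w)

    return RegressionFit(
        method=method,
        training_range=(float(x.min()), float(x.max())),
        predictor_mean=mx,
        predictor_sd=sx,
        response_mean=my,
        response_sd=sy,
        _predict_std=predict_std,
        _boundary=boundary,
    )


def residuals(fit: RegressionFit, x_test: np.ndarray, y_test: np.ndarray) -> np.ndarray:
    """Out-of-sample residuals y_test - fitted_curve(x_test)."""
    x = np.asarray(x_test, dtype=float).ravel()
    y = np.asarray(y_test, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x_test and y_test must have equal length")
    if x.size < 2:
        raise ValueError("need at least two test points")
    return y - fit.predict(x)
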