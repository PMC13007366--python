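"""Penalized B-spline (P-spline) smoothing of binomial event probabilities.

Eilers–Marx style smoother: equally spaced B-spline basis on an extended
uniform knot grid, difference penalty on adjacent coefficients, fitted by
penalized IRLS on the logit scale.  The smoothing parameter is chosen by
generalized cross-validation over a log-spaced grid, which is cheap enough
to re-select inside every bootstrap replicate.

With a second-order penalty the null space of the penalty is the set of
coefficient sequences affine in the basis index; on the uniform extended
knot grid the Greville abscissae are equally spaced, so the heavy-penalty
limit of the fitted logit curve is exactly a straight line in age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

_ETA_CLIP = 30.0
_RIDGE = 1e-9


def bspline_design(x, domain, n_basis: int, degree: int = 3) -> np.ndarray:
    """Design matrix of ``n_basis`` uniform B-splines covering ``domain``.

    Knots extend ``degree`` segments beyond each end of the domain
    (unclamped), so the basis reproduces polynomials up to ``degree`` with
    coefficients polynomial in the equally spaced Greville abscissae.
    """
    lo, hi = float(domain[0]), float(domain[1])
    n_seg = n_basis - degree
    if n_seg < 1:
        raise ValueError("n_basis must exceed the spline degree")
    h = (hi - lo) / n_seg
    knots = lo + h * np.arange(-degree, n_seg + degree + 1)
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


@dataclass
class PSplineFit:
    """Fitted penalized binomial spline on the logit scale."""

    coef: np.ndarray
    lam: float
    edf: float
    deviance: float
    gcv: float
    domain: tuple[float, float]
    n_basis: int
    degree: int
    converged: bool = True
    gcv_path: dict[float, float] = field(default_factory=dict)

    def linear_predictor(self, x) -> np.ndarray:
        b = bspline_design(x, self.domain, self.n_basis, self.degree)
        return b @ self.coef

    def predict(self, x) -> np.ndarray:
        """Fitted event probability at ages ``x``."""
        eta = np.clip(self.linear_predictor(x), -_ETA_CLIP, _ETA_CLIP)
        return 1.0 / (1.0 + np.exp(-eta))


def _binomial_deviance(y, n, mu) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def fit_binomial_pspline(
    x,
    y,
    n,
    domain,
    n_basis: int = 15,
    degree: int = 3,
    penalty_order: int = 2,
    lambdas=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> PSplineFit:
    """Fit event counts ``y`` out of ``n`` trials at ages ``x``.

    Observations with ``n == 0`` are dropped.  Returns the fit minimising
    GCV over ``lambdas`` (default ``10^-2 .. 10^6``, 9 points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    x, y, n = x[keep], y[keep], n[keep]
    if lambdas is None:
        lambdas = np.logspace(-2, 6, 9)
    m = len(x)
    if m == 0:
        raise ValueError("no observations with positive trial count")

    if y.sum() == 0:
        # no events anywhere: fitted probability is numerically zero
        coef = np.full(n_basis, -_ETA_CLIP)
        return PSplineFit(coef, float(lambdas[-1]), 0.0, 0.0, 0.0,
                          (float(domain[0]), float(domain[1])), n_basis, degree)

    b = bspline_design(x, domain, n_basis, degree)
    pen = difference_penalty(n_basis, penalty_order)
    eye = np.eye(n_basis)

    p_bar = min(max(y.sum() / n.sum(), 1e-10), 1 - 1e-10)
    eta0 = np.full(m, np.log(p_bar / (1 - p_bar)))

    best: PSplineFit | None = None
    gcv_path: dict[float, float] = {}
    # every lambda starts from the constant-logit fit: warm-starting across
    # lambdas can propagate a diverged nearly-unpenalized fit
    coef0 = np.full(n_basis, eta0[0])
    for lam in np.sort(np.asarray(lambdas, dtype=float)):
        c = coef0.copy()
        converged = False
        for _ in range(max_iter):
            eta = np.clip(b @ c, -_ETA_CLIP, _ETA_CLIP)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = n * mu * (1 - mu) + 1e-12
            z = eta + (y - n * mu) / w
            bw = b * w[:, None]
            lhs = b.T @ bw + lam * pen + _RIDGE * eye
            rhs = b.T @ (w * z)
            c_new = np.linalg.solve(lhs, rhs)
            step = np.max(np.abs(c_new - c))
            c = c_new
            if step < tol * (1 + np.max(np.abs(c))):
                converged = True
                break
        eta = np.clip(b @ c, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu) + 1e-12
        lhs = b.T @ (b * w[:, None]) + lam * pen + _RIDGE * eye
        edf = float(np.trace(np.linalg.solve(lhs, b.T @ (b * w[:, None]))))
        dev = _binomial_deviance(y, n, mu)
        denom = max(m - edf, 1e-6)
        gcv = m * dev / denom**2
        gcv_path[float(lam)] = gcv
        if best is None or gcv < best.gcv:
            best = PSplineFit(
                c.copy(), float(lam), edf, dev, gcv,
                (float(domain[0]), float(domain[1])), n_basis, degree,
                converged=converged,
            )
    assert best is not None
    best.gcv_path = gcv_path
    return best
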