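"""Penalized cubic-spline additive models with REML smoothness selection.

This is the numerical engine behind the per-region age-trajectory fits and
the covariate-association models.  The model is Gaussian and additive,

    y = beta0 + beta_sex * sex + f1(x1) [+ f2(x2)] + eps,

where each ``f`` is a cubic B-spline with a modest basis dimension (default
10) and a wiggliness penalty ``lambda * integral f''(x)^2 dx``.  The penalty
null space is exactly the linear functions, so a truly linear relationship
shrinks to one effective degree of freedom.  ``lambda`` is chosen by
restricted maximum likelihood (REML), i.e. the spline is treated as a mixed
model with the penalized directions as random effects.

Two entry points are provided:

* :class:`SmoothDesign` — a single smooth plus linear covariates, with the
  expensive design decomposition done once and shared across many response
  vectors (the per-ROI mass-fitting case).
* :class:`AdditiveGAM` — one or two smooths with independent smoothing
  parameters and an optional wiggliness multiplier ``gamma`` (the
  association-model case).

Significance of a smooth is assessed with an exact F test on the
*unpenalized* spline basis (nested ordinary least squares).  Conditional-
on-lambda tests based on effective degrees of freedom are anti-conservative
under the null; the unpenalized F statistic has an exact null distribution
for Gaussian errors and is what :meth:`SmoothDesign.smooth_test` returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = ["SmoothDesign", "AdditiveGAM", "SmoothFit", "bspline_design"]


def bspline_design(x, xmin, xmax, k=10, degree=3):
    """Cubic B-spline design matrix with ``k`` basis functions.

    Interior knots are equally spaced on ``[xmin, xmax]``; evaluation points
    outside the range are clamped to the boundary (constant extrapolation of
    the basis), which only matters when predicting outside the fitted range.

    Returns ``(B, knots)`` with ``B`` of shape ``(len(x), k)``.
    """
    x = np.asarray(x, dtype=float)
    n_inner = k - degree - 1
    if n_inner < 0:
        raise ValueError(f"basis dimension k={k} too small for degree {degree}")
    if not np.isfinite([xmin, xmax]).all() or xmax <= xmin:
        raise ValueError("need xmin < xmax with finite bounds")
    inner = np.linspace(xmin, xmax, n_inner + 2)[1:-1]
    knots = np.r_[[xmin] * (degree + 1), inner, [xmax] * (degree + 1)]
    B = BSpline.design_matrix(np.clip(x, xmin, xmax), knots, degree).toarray()
    return B, knots


def second_derivative_penalty(knots, k, degree=3):
    """Exact Gram matrix ``S_ij = integral B_i''(x) B_j''(x) dx``.

    For cubic splines the second derivatives are piecewise linear, so
    two-point Gauss–Legendre quadrature per inter-knot interval is exact.
    The null space of ``S`` is exactly {constant, linear}.
    """
    uk = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    S = np.zeros((k, k))
    coef = np.eye(k)
    splines = [BSpline(knots, coef[i], degree).derivative(2) for i in range(k)]
    for a, b in zip(uk[:-1], uk[1:]):
        xs = (a + b) / 2 + (b - a) / 2 * gauss
        D2 = np.column_stack([s(xs) for s in splines])
        S += (b - a) / 2 * (D2.T @ D2)
    return S


class _Smooth:
    """One constrained smooth term: basis, centering constraint, penalty."""

    def __init__(self, x, k, xmin=None, xmax=None, degree=3):
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("smooth covariate is constant; design is rank-deficient")
        self.xmin = float(np.min(x)) if xmin is None else float(xmin)
        self.xmax = float(np.max(x)) if xmax is None else float(xmax)
        self.k = int(k)
        self.degree = degree
        B, self.knots = bspline_design(x, self.xmin, self.xmax, self.k, degree)
        S0 = second_derivative_penalty(self.knots, self.k, degree)
        # absorb the sum-to-zero identifiability constraint 1'B c = 0
        C = B.sum(axis=0)[None, :]
        _, _, Vt = np.linalg.svd(C, full_matrices=True)
        self.Zc = Vt[1:].T                      # k x (k-1)
        self.X = B @ self.Zc                    # constrained design
        self.S = self.Zc.T @ S0 @ self.Zc       # constrained penalty

    def basis_at(self, xnew):
        B, _ = bspline_design(xnew, self.xmin, self.xmax, self.k, self.degree)
        return B @ self.Zc


@dataclass
class SmoothFit:
    """Result of a penalized fit for one response vector."""

    lam: float
    coef: np.ndarray
    fitted: np.ndarray
    rss: float
    sigma2: float
    edf_smooth: float
    edf_total: float
    intercept: float
    sex_coef: float
    n: int


class SmoothDesign:
    """Shared design for ``y ~ intercept + sex + s(x)`` across many ``y``.

    The fixed-effect projection and the singular value decomposition of the
    penalized directions depend only on ``(x, sex, k)`` and are computed
    once; each :meth:`fit` is then a couple of matrix–vector products plus a
    one-dimensional REML search.
    """

    def __init__(self, x, sex, k=10, xmin=None, xmax=None):
        x = np.asarray(x, dtype=float)
        sex = np.asarray(sex, dtype=float)
        if x.ndim != 1 or x.shape != sex.shape:
            raise ValueError("x and sex must be 1-D arrays of equal length")
        if np.isnan(x).any():
            raise ValueError("missing values in the smooth covariate")
        n = len(x)
        self.n = n
        self.x = x
        self.sex = sex
        self.smooth = _Smooth(x, k, xmin=xmin, xmax=xmax)
        # split the constrained smooth into penalty null space (linear trend)
        # and penalized directions scaled so the penalty becomes lam*||u||^2
        s, V = np.linalg.eigh(self.smooth.S)
        tol = s.max() * 1e-9
        pen = s > tol
        self._Vnull = V[:, ~pen]
        self._Vpen = V[:, pen] / np.sqrt(s[pen])
        self._spen = s[pen]
        Xf = np.column_stack([np.ones(n), sex, self.smooth.X @ self._Vnull])
        G = self.smooth.X @ self._Vpen
        self.Xf, self.G = Xf, G
        self.Mf = Xf.shape[1]
        Qfull, _ = np.linalg.qr(Xf, mode="complete")
        self._Q = Qfull[:, self.Mf:]            # residual-space basis
        U, d, _ = np.linalg.svd(self._Q.T @ G, full_matrices=False)
        self._U = U
        self._d2 = d**2
        # unpenalized designs for the exact F/t tests
        self._W = np.column_stack([Xf, G])
        self._X0 = np.column_stack([np.ones(n), sex])

    # -- penalized fit -----------------------------------------------------

    def fit(self, y, gamma=1.0):
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length does not match the design")
        n, Mf = self.n, self.Mf
        yt = self._Q.T @ y
        z = self._U.T @ yt
        ss_rest = float(yt @ yt - z @ z)
        d2 = self._d2
        neff = n / float(gamma)

        def reml(logk):
            kap = np.exp(logk)
            q = 1.0 + kap * d2
            return (neff - Mf) * np.log(z @ (z / q) + ss_rest) + np.sum(np.log(q))

        res = optimize.minimize_scalar(reml, bounds=(-25.0, 25.0), method="bounded")
        lam = float(np.exp(-res.x))
        W = self._W
        p = W.shape[1]
        M = W.T @ W
        M[Mf:, Mf:] += lam * np.eye(p - Mf)
        coef = np.linalg.solve(M, W.T @ y)
        fitted = W @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf_total = float(np.trace(np.linalg.solve(M, W.T @ W)))
        edf_smooth = edf_total - 2.0            # minus intercept and sex
        sigma2 = rss / max(n - edf_total, 1.0)
        return SmoothFit(
            lam=lam, coef=coef, fitted=fitted, rss=rss, sigma2=sigma2,
            edf_smooth=edf_smooth, edf_total=edf_total,
            intercept=float(coef[0]), sex_coef=float(coef[1]), n=n,
        )

    def curve(self, fit, grid, sex_value=None):
        """Population-average fitted curve evaluated at ``grid`` ages.

        ``sex_value`` defaults to the sample mean of the sex indicator, i.e.
        the curve for an average-composition cohort.
        """
        grid = np.asarray(grid, dtype=float)
        if sex_value is None:
            sex_value = float(self.sex.mean())
        BZ = self.smooth.basis_at(grid)
        Mf = self.Mf
        f = (BZ @ self._Vnull) @ fit.coef[2:Mf] + (BZ @ self._Vpen) @ fit.coef[Mf:]
        return fit.intercept + fit.sex_coef * sex_value + f

    # -- exact tests on the unpenalized basis ------------------------------

    def smooth_test(self, y):
        """Exact F test of any age dependence (unpenalized spline vs none)."""
        y = np.asarray(y, dtype=float)
        b0, *_ = np.linalg.lstsq(self._X0, y, rcond=None)
        rss0 = float(np.sum((y - self._X0 @ b0) ** 2))
        b1, *_ = np.linalg.lstsq(self._W, y, rcond=None)
        rss1 = float(np.sum((y - self._W @ b1) ** 2))
        df1 = self._W.shape[1] - self._X0.shape[1]
        df2 = self.n - self._W.shape[1]
        F = max(rss0 - rss1, 0.0) / df1 / (rss1 / df2)
        return float(F), float(stats.f.sf(F, df1, df2))

    def intercept_test(self, y):
        """Exact t test of a nonzero model intercept (unpenalized basis)."""
        y = np.asarray(y, dtype=float)
        W = self._W
        WtW_inv = np.linalg.pinv(W.T @ W)
        beta = WtW_inv @ (W.T @ y)
        resid = y - W @ beta
        df = self.n - np.linalg.matrix_rank(W)
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 * WtW_inv[0, 0])
        t = float(beta[0] / se)
        return t, float(2 * stats.t.sf(abs(t), df))


class AdditiveGAM:
    """``y ~ intercept + linear covariates + sum of smooths`` with per-smooth
    REML-selected penalties.

    Used for the association models ``score ~ s(age) + s(covariate) + sex``.
    ``gamma`` is a wiggliness multiplier (values above 1 force smoother
    fits) applied by dividing the effective sample size in the REML
    criterion, mirroring how heavier penalization is conventionally exposed
    in penalized-regression software.
    """

    def __init__(self, y, smooth_vars, linear_vars=None, k=10, gamma=1.0):
        y = np.asarray(y, dtype=float)
        n = len(y)
        self.y = y
        self.n = n
        self.gamma = float(gamma)
        if linear_vars is None:
            linear_vars = []
        lin = [np.asarray(v, dtype=float) for v in linear_vars]
        self.smooths = [_Smooth(np.asarray(x, dtype=float), k) for x in smooth_vars]
        blocks = [np.ones((n, 1))] + [v[:, None] for v in lin]
        self._n_fixed = len(blocks)
        self._slices = []
        col = sum(b.shape[1] for b in blocks)
        for sm in self.smooths:
            self._slices.append(slice(col, col + sm.X.shape[1]))
            blocks.append(sm.X)
            col += sm.X.shape[1]
        self.W = np.column_stack(blocks)
        self.p = self.W.shape[1]
        self._Slist = []
        for sm, sl in zip(self.smooths, self._slices):
            Sfull = np.zeros((self.p, self.p))
            Sfull[sl, sl] = sm.S
            self._Slist.append(Sfull)
        self._fit_reml()

    def _penalized_quantities(self, loglams):
        lams = np.exp(loglams)
        H = self.W.T @ self.W
        M = H + sum(l * S for l, S in zip(lams, self._Slist))
        return lams, H, M

    def _reml_criterion(self, loglams):
        lams, H, M = self._penalized_quantities(loglams)
        from scipy.linalg import cho_solve
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf
        b = self.W.T @ self.y
        delta = cho_solve((L, True), b)
        rss = float(self.y @ self.y - 2 * delta @ b + delta @ H @ delta)
        pen = sum(l * float(delta @ S @ delta) for l, S in zip(lams, self._Slist))
        D = max(rss + pen, np.finfo(float).tiny)
        logdet_M = 2 * float(np.sum(np.log(np.diag(L))))
        logdet_S = 0.0
        Mp = self.p
        for l, sm in zip(lams, self.smooths):
            s = np.linalg.eigvalsh(sm.S)
            s = s[s > s.max() * 1e-9]
            logdet_S += float(np.sum(np.log(l * s)))
            Mp -= len(s)
        neff = self.n / self.gamma
        return (neff - Mp) * np.log(D) + logdet_M - logdet_S

    def _fit_reml(self):
        m = len(self.smooths)
        x0 = np.zeros(m)
        if m == 1:
            res = optimize.minimize_scalar(
                lambda v: self._reml_criterion(np.array([v])),
                bounds=(-18.0, 22.0), method="bounded")
            loglams = np.array([res.x])
        else:
            with np.errstate(invalid="ignore"):   # inf-inf in degenerate fits
                res = optimize.minimize(
                    self._reml_criterion, x0, method="Nelder-Mead",
                    options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400})
            loglams = res.x
        self.loglams = loglams
        lams, H, M = self._penalized_quantities(loglams)
        self.lams = lams
        try:
            self.coef = np.linalg.solve(M, self.W.T @ self.y)
            edf_mat = np.linalg.solve(M, H)
        except np.linalg.LinAlgError:
            # fully collinear smooths (e.g. covariate identical to age):
            # fall back to the minimum-norm penalized solution
            Minv = np.linalg.pinv(M)
            self.coef = Minv @ (self.W.T @ self.y)
            edf_mat = Minv @ H
        self.fitted = self.W @ self.coef
        self.rss = float(np.sum((self.y - self.fitted) ** 2))
        self.edf_total = float(np.trace(edf_mat))
        self.edf_smooth = [float(np.trace(edf_mat[sl, sl])) for sl in self._slices]

    def partial_curve(self, which, grid):
        """Centered contribution of smooth ``which`` evaluated at ``grid``."""
        sm = self.smooths[which]
        return sm.basis_at(np.asarray(grid, dtype=float)) @ self.coef[self._slices[which]]

    def smooth_test(self, which):
        """Exact F test of smooth ``which`` via nested unpenalized OLS.

        Rank-deficient designs (e.g. the covariate is a copy of another
        smooth's variable) are handled with pseudoinverse fits; if the
        tested smooth adds no column rank the test degenerates to F=0, p=1.
        """
        keep = np.ones(self.p, dtype=bool)
        keep[self._slices[which]] = False
        W_full, W_red = self.W, self.W[:, keep]
        r_full = np.linalg.matrix_rank(W_full)
        r_red = np.linalg.matrix_rank(W_red)
        df1 = r_full - r_red
        df2 = self.n - r_full
        if df1 <= 0 or df2 <= 0:
            return 0.0, 1.0
        bf, *_ = np.linalg.lstsq(W_full, self.y, rcond=None)
        br, *_ = np.linalg.lstsq(W_red, self.y, rcond=None)
        rss_f = float(np.sum((self.y - W_full @ bf) ** 2))
        rss_r = float(np.sum((self.y - W_red @ br) ** 2))
        F = max(rss_r - rss_f, 0.0) / df1 / (rss_f / df2)
        return float(F), float(stats.f.sf(F, df1, df2))
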