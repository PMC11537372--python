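"""Gaussian additive models with penalized B-spline smooths.

The regression engine used throughout the model search and the spatial-trend
analyses.  Smooth terms are low-rank penalized regression splines in the
P-spline tradition: a cubic B-spline basis on equally spaced knots with a
second-order difference penalty on the coefficients.  Tensor-product smooths
of two covariates carry one penalty (and one smoothing parameter) per margin.
Identifiability is enforced by absorbing a sum-to-zero constraint into each
smooth's basis, so every smooth is centered over the observed data and the
model keeps an explicit intercept.

Smoothing parameters are chosen automatically by minimizing either the
generalized cross-validation score (default)

    GCV(lambda) = n * RSS / (n - edf)^2

or the (negative) Gaussian restricted likelihood.  The GCV denominator uses
an inflated degrees-of-freedom cost (``gamma`` = 1.4 by default), the
standard guard against the well-known tendency of plain GCV to undersmooth.
The effective degrees of freedom ``edf`` is the trace of the hat matrix; as a penalty tends to
infinity a 1-d smooth collapses onto the straight line in its covariate
(the null space of the difference penalty), so heavily penalized fits
reproduce ordinary linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space

_DEGREE = 3
_LOGLAM_BOUNDS = (-5.0, 12.0)
_GCV_GAMMA = 1.4  # edf-cost inflation guarding against GCV undersmoothing


def _bspline_knots(x: np.ndarray, n_basis: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("covariate is constant; cannot build a spline basis")
    inner = np.linspace(lo, hi, n_basis - _DEGREE + 1)
    return np.concatenate([[lo] * _DEGREE, inner, [hi] * _DEGREE])


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[_DEGREE], knots[-_DEGREE - 1]
    xc = np.clip(x, lo, hi)  # evaluate at the boundary outside the data range
    return BSpline.design_matrix(xc, knots, _DEGREE).toarray()


def _greville(knots: np.ndarray) -> np.ndarray:
    """Greville abscissae: knot averages at which B-splines have linear precision."""
    nb = knots.size - _DEGREE - 1
    return np.array([knots[i + 1 : i + _DEGREE + 1].mean() for i in range(nb)])


def _difference_penalty(knots: np.ndarray) -> np.ndarray:
    """Second divided-difference penalty with an exactly affine null space.

    Coefficient sequences linear in the Greville abscissae reproduce affine
    functions of x, so an infinitely penalized smooth collapses onto the
    ordinary straight-line fit.
    """
    g = _greville(knots)
    nb = g.size
    D = np.zeros((nb - 2, nb))
    for i in range(nb - 2):
        h1 = g[i + 1] - g[i]
        h2 = g[i + 2] - g[i + 1]
        D[i, i] = 1.0 / h1
        D[i, i + 1] = -(1.0 / h1 + 1.0 / h2)
        D[i, i + 2] = 1.0 / h2
    # scale to be comparable with a unit-spaced difference penalty
    D *= np.mean(np.diff(g))
    return D.T @ D


def _effective_basis_dim(k: int, n: int) -> int:
    return max(4, min(k, n - 2))


@dataclass
class Smooth1D:
    """A univariate penalized spline smooth ``s(x)``."""

    name: str
    k: int = 10

    def build(self, x: np.ndarray):
        nb = _effective_basis_dim(self.k, x.size)
        knots = _bspline_knots(x, nb)
        B = _bspline_design(x, knots)
        S = _difference_penalty(knots)
        self._knots = knots
        return B, [S]

    def basis(self, x: np.ndarray) -> np.ndarray:
        return _bspline_design(np.asarray(x, dtype=float), self._knots)

    @property
    def n_lambdas(self) -> int:
        return 1


@dataclass
class TensorSmooth:
    """A 2-d tensor-product smooth ``te(x1, x2)`` with per-margin penalties."""

    name: str  # "var1:var2"
    k: int = 5  # basis dimension per margin

    def build(self, x: np.ndarray):
        # x has two columns
        nb1 = _effective_basis_dim(self.k, x.shape[0])
        nb2 = nb1
        self._knots1 = _bspline_knots(x[:, 0], nb1)
        self._knots2 = _bspline_knots(x[:, 1], nb2)
        B1 = _bspline_design(x[:, 0], self._knots1)
        B2 = _bspline_design(x[:, 1], self._knots2)
        T = (B1[:, :, None] * B2[:, None, :]).reshape(x.shape[0], nb1 * nb2)
        S1 = np.kron(_difference_penalty(self._knots1), np.eye(nb2))
        S2 = np.kron(np.eye(nb1), _difference_penalty(self._knots2))
        return T, [S1, S2]

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        B1 = _bspline_design(x[:, 0], self._knots1)
        B2 = _bspline_design(x[:, 1], self._knots2)
        return (B1[:, :, None] * B2[:, None, :]).reshape(x.shape[0], -1)

    @property
    def n_lambdas(self) -> int:
        return 2


@dataclass
class _SmoothBlock:
    term: object
    Z: np.ndarray                 # constraint-absorbing reparameterization
    cols: slice                   # columns in the full design
    penalties: list[np.ndarray]   # constrained penalty matrices
    lambda_idx: list[int]
    edf: float = float("nan")


@dataclass
class GAMFit:
    """A fitted Gaussian additive model."""

    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    edf: float
    n: int
    lambdas: np.ndarray
    scale: float                  # RSS / (n - edf)
    gcv: float
    method: str
    cov: np.ndarray = field(repr=False, default=None)
    _blocks: list = field(repr=False, default=None)
    _n_parametric: int = 0

    @property
    def loglik(self) -> float:
        """Gaussian ML log-likelihood at the MLE variance RSS/n."""
        sigma2 = self.rss / self.n
        return -0.5 * self.n * (np.log(2.0 * np.pi * sigma2) + 1.0)

    def smooth_estimate(self, name: str, x: np.ndarray):
        """Evaluate a fitted (centered) smooth with pointwise SEs."""
        for block in self._blocks:
            if block.term.name == name:
                Xg = block.term.basis(x) @ block.Z
                est = Xg @ self.coef[block.cols]
                Vb = self.cov[block.cols, block.cols.start : block.cols.stop]
                se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Vb, Xg), 0.0))
                return est, se
        raise KeyError(f"no smooth named {name!r}")

    def smooth_edf(self, name: str) -> float:
        for block in self._blocks:
            if block.term.name == name:
                return block.edf
        raise KeyError(f"no smooth named {name!r}")


def _assemble(X_par: np.ndarray, smooths: list) -> tuple[np.ndarray, list[_SmoothBlock], int]:
    n = X_par.shape[0]
    blocks: list[_SmoothBlock] = []
    cols = [X_par]
    start = X_par.shape[1]
    lam_count = 0
    for term in smooths:
        x = term._x
        B, penalties = term.build(x)
        c = B.sum(axis=0)[:, None]  # sum-to-zero constraint over the data
        Z = null_space(c.T)
        Bz = B @ Z
        Sz = [Z.T @ S @ Z for S in penalties]
        idx = list(range(lam_count, lam_count + term.n_lambdas))
        lam_count += term.n_lambdas
        blocks.append(_SmoothBlock(term, Z, slice(start, start + Bz.shape[1]), Sz, idx))
        cols.append(Bz)
        start += Bz.shape[1]
    return np.hstack(cols), blocks, lam_count


def _penalty_matrix(p: int, blocks: list[_SmoothBlock], lambdas: np.ndarray) -> np.ndarray:
    S = np.zeros((p, p))
    for block in blocks:
        sl = block.cols
        for Sj, li in zip(block.penalties, block.lambda_idx):
            S[sl, sl.start : sl.stop] += lambdas[li] * Sj
    return S


def _solve(X, y, XtX, Xty, blocks, lambdas):
    p = X.shape[1]
    A = XtX + _penalty_matrix(p, blocks, lambdas)
    jitter = 1e-10 * (np.trace(XtX) / p + 1.0)
    try:
        cf = cho_factor(A + jitter * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("penalized normal equations not positive definite") from exc
    beta = cho_solve(cf, Xty)
    H_trace_mat = cho_solve(cf, XtX)  # A^{-1} X'X ; trace = edf
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    edf = float(np.trace(H_trace_mat))
    return beta, fitted, resid, rss, edf, cf, H_trace_mat


def _reml_criterion(y, X, blocks, lambdas, beta, rss, cf, n_unpenalized):
    """Negative Gaussian restricted likelihood, profiled over the variance."""
    n = y.size
    p = X.shape[1]
    S_lam = _penalty_matrix(p, blocks, lambdas)
    pen = float(beta @ S_lam @ beta)
    rss_p = rss + pen
    # pseudo log-determinant of the penalty over its range space
    logdet_S = 0.0
    rank_S = 0
    for block in blocks:
        St = sum(
            lambdas[li] * Sj for Sj, li in zip(block.penalties, block.lambda_idx)
        )
        ev = np.linalg.eigvalsh(St)
        tol = max(ev.max(), 0.0) * 1e-10 if ev.size else 0.0
        pos = ev[ev > tol]
        logdet_S += float(np.sum(np.log(pos)))
        rank_S += pos.size
    mp = n_unpenalized + (p - n_unpenalized - rank_S)  # dim of unpenalized space
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    nm = n - mp
    sigma2 = rss_p / nm
    reml = -0.5 * (
        nm * np.log(2.0 * np.pi * sigma2)
        + nm
        + logdet_A
        - logdet_S
    )
    return -reml


def fit_gam(
    y: np.ndarray,
    X_parametric: np.ndarray | None,
    smooths: list,
    smooth_data: dict[str, np.ndarray],
    method: str = "GCV",
    fixed_lambdas: np.ndarray | None = None,
    gamma: float = _GCV_GAMMA,
) -> GAMFit:
    """Fit a Gaussian additive model.

    Parameters
    ----------
    y : response vector.
    X_parametric : parametric design columns *including the intercept*;
        pass None for an intercept-only parametric part.
    smooths : list of :class:`Smooth1D` / :class:`TensorSmooth` terms.
    smooth_data : mapping from term name to covariate array (1-d for
        ``Smooth1D``, (n, 2) for ``TensorSmooth``).
    method : ``"GCV"`` (default) or ``"REML"`` smoothness selection.
    fixed_lambdas : bypass selection and fit at these smoothing parameters.
    gamma : effective-degrees-of-freedom cost inflation in the GCV score.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X_parametric is None:
        X_parametric = np.ones((n, 1))
    X_parametric = np.asarray(X_parametric, dtype=float)
    if method not in ("GCV", "REML"):
        raise ValueError(f"unknown smoothing-selection method {method!r}")

    for term in smooths:
        x = np.asarray(smooth_data[term.name], dtype=float)
        term._x = x if x.ndim > 1 else x.ravel()

    X, blocks, n_lam = _assemble(X_parametric, smooths)
    XtX = X.T @ X
    Xty = X.T @ y
    n_par = X_parametric.shape[1]

    if n_lam == 0:
        beta, fitted, resid, rss, edf, cf, _ = _solve(X, y, XtX, Xty, blocks, np.zeros(0))
        lambdas = np.zeros(0)
    else:
        def criterion(log10_lam: np.ndarray) -> float:
            lam = 10.0 ** np.clip(np.atleast_1d(log10_lam), *_LOGLAM_BOUNDS)
            try:
                beta, _, _, rss, edf, cf, _ = _solve(X, y, XtX, Xty, blocks, lam)
            except np.linalg.LinAlgError:
                return np.inf
            if method == "GCV":
                denom = max(n - gamma * edf, 1e-8)
                return n * rss / denom**2
            return _reml_criterion(y, X, blocks, lam, beta, rss, cf, n_par)

        if fixed_lambdas is not None:
            lambdas = np.asarray(fixed_lambdas, dtype=float)
        elif n_lam == 1:
            res = optimize.minimize_scalar(
                lambda u: criterion(np.array([u])), bounds=_LOGLAM_BOUNDS, method="bounded",
                options={"xatol": 1e-3},
            )
            lambdas = 10.0 ** np.array([np.clip(res.x, *_LOGLAM_BOUNDS)])
        else:
            best = None
            for start in (0.0, 3.0):
                res = optimize.minimize(
                    criterion, np.full(n_lam, start), method="Nelder-Mead",
                    options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200 * n_lam},
                )
                if best is None or res.fun < best.fun:
                    best = res
            lambdas = 10.0 ** np.clip(best.x, *_LOGLAM_BOUNDS)
        beta, fitted, resid, rss, edf, cf, _ = _solve(X, y, XtX, Xty, blocks, lambdas)

    scale = rss / max(n - edf, 1e-8)
    cov = cho_solve(cf, np.eye(X.shape[1])) * scale  # Bayesian posterior covariance

    # per-smooth edf: block-diagonal share of tr(A^{-1} X'X)
    Hdiag = np.diag(cho_solve(cf, XtX))
    for block in blocks:
        block.edf = float(np.sum(Hdiag[block.cols]))

    gcv = n * rss / max(n - edf, 1e-8) ** 2
    return GAMFit(
        coef=beta,
        fitted=fitted,
        residuals=resid,
        rss=rss,
        edf=edf,
        n=n,
        lambdas=lambdas,
        scale=scale,
        gcv=gcv,
        method=method,
        cov=cov,
        _blocks=blocks,
        _n_parametric=n_par,
    )
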