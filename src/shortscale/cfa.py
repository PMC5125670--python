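"""One-factor measurement model for dichotomous items.

The pipeline is the classic categorical-SEM route: estimate pairwise
tetrachoric correlations under the bivariate-normal liability model, smooth
the matrix to positive semidefiniteness, then fit a single-factor model
(rank-one-plus-diagonal structure) to the correlation matrix by unweighted
least squares.  Fit is summarized by the chi-square statistic T = (n-1) * f_min
together with CFI and RMSEA against the mutual-independence baseline, and
reliability by McDonald's omega (factor saturation of a tau-congeneric model).

The estimator is deliberately *not* WLSMV: the mean-and-variance adjusted
weight matrix needs the full asymptotic covariance of the thresholds and
polychorics, which buys nothing for ranking candidate item subsets.  The
least-squares fit satisfies the same structural contracts (df, CFI/RMSEA
conventions, Heywood bounding) and orders subsets consistently; see
docs/methods.md for the full discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io import ItemResponseMatrix

__all__ = [
    "CorrelationMatrix",
    "CFAFit",
    "tetrachoric_matrix",
    "fit_one_factor",
    "mcdonald_omega",
]

#: clamp for boundary 2x2 tables (a zero concordant or discordant diagonal)
R_MAX = 0.999

# ---------------------------------------------------------------------------
# bivariate-normal rectangle probabilities (vectorized)
# ---------------------------------------------------------------------------

# Gauss-Legendre nodes/weights on (0, 1); 96 nodes keep the upper-orthant
# probability accurate to ~1e-9 for |r| <= 0.999 at the thresholds that occur
# in practice, which is far below the sampling noise of any tetrachoric.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(96)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _bvn_upper(tau1, tau2, r):
    """P(Z1 > tau1, Z2 > tau2) for standard bivariate normal with correlation r.

    Uses the conditional-probit representation
    ``integral over u in (Phi(tau1), 1) of Phi((r*PhiInv(u) - tau2)/sqrt(1-r^2))``
    evaluated on fixed Gauss-Legendre nodes, fully vectorized over inputs.
    """
    tau1, tau2, r = np.broadcast_arrays(
        np.atleast_1d(np.asarray(tau1, float)),
        np.atleast_1d(np.asarray(tau2, float)),
        np.atleast_1d(np.asarray(r, float)),
    )
    p1 = stats.norm.sf(tau1)  # mass of the integration interval
    # nodes in u-space: u = Phi(tau1) + p1 * x  -> x on (0,1)
    u = stats.norm.cdf(tau1)[..., None] + p1[..., None] * _GL_X
    x = stats.norm.ppf(np.clip(u, 1e-16, 1 - 1e-16))
    s = np.sqrt(np.clip(1.0 - r**2, 1e-12, None))[..., None]
    integrand = stats.norm.cdf((r[..., None] * x - tau2[..., None]) / s)
    return p1 * (integrand * _GL_W).sum(axis=-1)


def _solve_tetrachoric(tau1, tau2, p11):
    """Vectorized bisection for r with P(Z1>tau1, Z2>tau2; r) = p11."""
    tau1 = np.atleast_1d(np.asarray(tau1, float))
    tau2 = np.atleast_1d(np.asarray(tau2, float))
    p11 = np.atleast_1d(np.asarray(p11, float))
    lo = np.full_like(p11, -R_MAX)
    hi = np.full_like(p11, R_MAX)
    # p11 is strictly increasing in r; clamp targets outside the attainable range
    p_lo = _bvn_upper(tau1, tau2, lo)
    p_hi = _bvn_upper(tau1, tau2, hi)
    r = np.zeros_like(p11)
    below = p11 <= p_lo
    above = p11 >= p_hi
    r[below] = -R_MAX
    r[above] = R_MAX
    active = ~(below | above)
    for _ in range(52):
        mid = 0.5 * (lo + hi)
        p_mid = _bvn_upper(tau1, tau2, mid)
        go_up = p_mid < p11
        lo = np.where(active & go_up, mid, lo)
        hi = np.where(active & ~go_up, mid, hi)
    r[active] = (0.5 * (lo + hi))[active]
    return r


# ---------------------------------------------------------------------------
# tetrachoric correlation matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationMatrix:
    """Item x item correlation matrix with provenance.

    ``values`` is PSD-smoothed (ready for fitting); ``raw_values`` keeps the
    pre-smoothing pairwise estimates so that sub-matrices can be re-smoothed
    consistently when evaluating item subsets.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    n_persons: int
    raw_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric to 1e-12")
        if np.abs(v).max() > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have a unit diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "item_ids", tuple(map(str, self.item_ids)))

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: Sequence[int]) -> "CorrelationMatrix":
        """Sub-matrix for an item subset, re-smoothed from the raw estimates."""
        idx = list(indices)
        raw = self.raw_values if self.raw_values is not None else self.values
        sub = raw[np.ix_(idx, idx)]
        return CorrelationMatrix(
            smooth_psd(sub),
            tuple(self.item_ids[i] for i in idx),
            self.n_persons,
            raw_values=sub,
        )


def smooth_psd(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and re-normalize the diagonal to 1."""
    corr = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(corr)
    if w[0] >= 0:
        return corr
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return 0.5 * (fixed + fixed.T)


def tetrachoric_pair(n11: float, n10: float, n01: float, n00: float) -> float:
    """Tetrachoric correlation from a single 2x2 table of counts.

    Cells follow (item1, item2) = (1,1), (1,0), (0,1), (0,0).  Thresholds are
    the ML estimates from the margins; r maximizes the bivariate-normal
    likelihood given those thresholds.  Boundary tables (both discordant or
    both concordant cells empty) are mapped to +/-R_MAX; a single empty cell
    receives a 0.5 continuity correction before estimation.
    """
    if n10 == 0 and n01 == 0:
        return R_MAX
    if n11 == 0 and n00 == 0:
        return -R_MAX
    cells = np.array([n11, n10, n01, n00], float)
    if (cells == 0).any():
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    n = cells.sum()
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("constant margin: tetrachoric threshold undefined")
    tau1 = stats.norm.isf(p1)
    tau2 = stats.norm.isf(p2)
    return float(_solve_tetrachoric(tau1, tau2, n11 / n)[0])


def tetrachoric_matrix(data: ItemResponseMatrix) -> CorrelationMatrix:
    """All pairwise tetrachoric correlations of a binary response matrix.

    Raises
    ------
    ValueError
        If any item column is constant (its threshold is undefined).
    """
    if data.n_items < 2:
        raise ValueError("need at least 2 items")
    x = data.values.astype(np.float64)
    n, m = x.shape
    p = x.mean(axis=0)
    constant = np.flatnonzero((p == 0) | (p == 1))
    if constant.size:
        names = [data.item_ids[i] for i in constant]
        raise ValueError(f"constant item column(s): {names}")

    n11 = x.T @ x
    ones = n * np.ones((m, m))
    n1 = n * p
    n10 = n1[:, None] - n11
    n01 = n1[None, :] - n11
    n00 = ones - n11 - n10 - n01

    iu = np.triu_indices(m, k=1)
    c11, c10, c01, c00 = (a[iu] for a in (n11, n10, n01, n00))

    r = np.zeros(len(c11))
    pos_bound = (c10 == 0) & (c01 == 0)
    neg_bound = (c11 == 0) & (c00 == 0)
    r[pos_bound] = R_MAX
    r[neg_bound] = -R_MAX
    rest = ~(pos_bound | neg_bound)
    if rest.any():
        cells = np.stack([c11, c10, c01, c00], axis=-1)[rest]
        zero = (cells == 0).any(axis=-1)
        cells = cells + 0.5 * zero[:, None]
        tot = cells.sum(axis=-1)
        p1 = (cells[:, 0] + cells[:, 1]) / tot
        p2 = (cells[:, 0] + cells[:, 2]) / tot
        r[rest] = _solve_tetrachoric(
            stats.norm.isf(p1), stats.norm.isf(p2), cells[:, 0] / tot
        )

    raw = np.eye(m)
    raw[iu] = r
    raw.T[iu] = r
    return CorrelationMatrix(
        smooth_psd(raw), data.item_ids, n, raw_values=raw
    )


# ---------------------------------------------------------------------------
# one-factor fit
# ---------------------------------------------------------------------------

LOADING_BOUND = 0.999  # Heywood guard
MAX_ITER = 500
F_TOL = 1e-8


@dataclass(frozen=True)
class CFAFit:
    """Result of a one-factor least-squares fit to a correlation matrix."""

    loadings: np.ndarray
    item_ids: tuple[str, ...]
    f_min: float
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    cfi: float
    rmsea: float
    n_persons: int
    converged: bool

    @property
    def omega(self) -> float:
        return mcdonald_omega(self.loadings)


def _discrepancy_and_grad(lam: np.ndarray, corr: np.ndarray):
    resid = corr - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    f = 0.5 * float(np.sum(resid**2))  # sum over i<j of squared residuals
    grad = -2.0 * resid @ lam
    return f, grad


def _start_loadings(corr: np.ndarray) -> np.ndarray:
    # first principal component scaled by sqrt(eig1 - 1): approximately the
    # loadings for a one-factor structure and exactly zero for a diagonal
    # matrix (whose global minimum is the null loading vector)
    w, v = np.linalg.eigh(corr)
    lam = v[:, -1] * np.sqrt(max(w[-1] - 1.0, 0.0))
    if lam.sum() < 0:
        lam = -lam
    return np.clip(lam, -0.9, 0.9)


def fit_one_factor(corr: CorrelationMatrix, n_persons: int | None = None) -> CFAFit:
    """Fit lambda in ``R ~ Lambda Lambda' + diag(1 - lambda^2)`` by least squares.

    The discrepancy is ``f = sum_{i<j} (r_ij - lambda_i lambda_j)^2``, minimized
    by L-BFGS-B with analytic gradient from first principal-component starting
    values, loadings bounded to (-0.999, 0.999).  T = (n-1) * f_min; CFI uses
    the mutual-independence baseline; RMSEA follows the usual
    ``sqrt(max(T - df, 0) / (df (n-1)))`` with the df = 0 saturated case
    defined as 0.
    """
    m = corr.n_items
    if m < 3:
        raise ValueError("one-factor model needs at least 3 items")
    n = int(n_persons if n_persons is not None else corr.n_persons)
    R = corr.values

    res = optimize.minimize(
        _discrepancy_and_grad,
        _start_loadings(R),
        args=(R,),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-LOADING_BOUND, LOADING_BOUND)] * m,
        options={"maxiter": MAX_ITER, "ftol": F_TOL * 1e-4, "gtol": 1e-10},
    )
    lam = res.x if res.x.sum() >= 0 else -res.x
    f_min = float(res.fun)

    df = m * (m - 1) // 2 - m
    df = max(df, 0)
    baseline_df = m * (m - 1) // 2
    off = R[np.triu_indices(m, k=1)]
    f_base = float(np.sum(off**2))
    T = max((n - 1) * f_min, 0.0)
    T_base = max((n - 1) * f_base, 0.0)

    denom = max(T - df, T_base - baseline_df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    rmsea = 0.0 if df == 0 else float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    if f_min <= 1e-12:
        cfi, rmsea = 1.0, 0.0

    return CFAFit(
        loadings=lam,
        item_ids=corr.item_ids,
        f_min=f_min,
        chi_square=T,
        df=df,
        baseline_chi_square=T_base,
        baseline_df=baseline_df,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        rmsea=rmsea,
        n_persons=n,
        converged=bool(res.success),
    )


def mcdonald_omega(loadings) -> float:
    """McDonald's omega: ``(sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2))``.

    Factor-saturation reliability of a tau-congeneric one-factor model.
    """
    lam = np.asarray(loadings, float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("all |loadings| must be < 1 for omega")
    s2 = lam.sum() ** 2
    resid = np.sum(1.0 - lam**2)
    if s2 == 0:
        return 0.0
    return float(s2 / (s2 + resid))
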