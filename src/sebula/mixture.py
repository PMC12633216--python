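"""Mixture density estimation for transformed HCLC values.

The per-cell high-coverage locus counts are truncated at a threshold
``x_min``, mapped to a continuous scale with a rank-preserving Box-Cox
transform (lambda chosen by profile maximum likelihood), binned into K
equal-width bins, and the histogram counts are smoothed by a Poisson GLM
with a log link on a natural cubic spline basis (Lindsey's method).  The
exponentiated linear predictor is the mixture density estimate f-hat; its
normalized cumulative bin masses give the CDF F-hat by linear
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from scipy.special import boxcox as _boxcox_transform
from scipy.stats import boxcox_llf

__all__ = [
    "DEFAULT_BINS",
    "DEFAULT_SPLINE_DF",
    "NaturalSplineBasis",
    "BoxCoxTransform",
    "SplineDensityFit",
    "truncate",
    "fit_boxcox",
    "bin_histogram",
    "fit_poisson_spline",
    "evaluate_density",
]

DEFAULT_BINS = 120
DEFAULT_SPLINE_DF = 7
LAMBDA_RANGE = (-2.0, 2.0)
LAMBDA_TOL = 1e-4
GLM_MAX_ITER = 100
GLM_TOL = 1e-8


# ---------------------------------------------------------------------------
# natural cubic spline basis (linear beyond the boundary knots)
# ---------------------------------------------------------------------------

def _bspline_design(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Dense cubic B-spline design matrix (or its derivative) at ``x``."""
    n_basis = len(knots) - 4
    out = np.empty((len(x), n_basis))
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        b = BSpline(knots, c, 3, extrapolate=True)
        out[:, i] = (b.derivative(deriv) if deriv else b)(x)
    return out


class NaturalSplineBasis:
    """Natural cubic spline basis with ``df`` functions, no intercept column.

    Cubic B-splines on the given knots are projected onto the null space of
    the second-derivative constraints at the two boundary knots, so the
    fitted curve is linear beyond the boundaries; evaluation outside the
    boundary knots extends each basis function linearly (value plus first
    derivative at the boundary), matching that constraint.
    """

    def __init__(self, interior_knots: np.ndarray, boundary_knots: tuple[float, float]):
        lo, hi = boundary_knots
        interior_knots = np.asarray(interior_knots, dtype=float)
        if np.any(interior_knots <= lo) or np.any(interior_knots >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        self.lo, self.hi = float(lo), float(hi)
        self.knots = np.r_[[lo] * 4, np.sort(interior_knots), [hi] * 4]
        # drop the leading B-spline column (absorbed by the GLM intercept)
        const = _bspline_design(np.array([lo, hi]), self.knots, deriv=2)[:, 1:]
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._null = q[:, 2:]  # (n_bspline-1) x df
        self.df = self._null.shape[1]
        b = np.array([self.lo, self.hi])
        self._boundary_val = _bspline_design(b, self.knots)[:, 1:] @ self._null
        self._boundary_der = _bspline_design(b, self.knots, deriv=1)[:, 1:] @ self._null

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        inside = np.clip(x, self.lo, self.hi)
        out = _bspline_design(inside, self.knots)[:, 1:] @ self._null
        below = x < self.lo
        above = x > self.hi
        if np.any(below):
            out[below] = self._boundary_val[0] + np.outer(x[below] - self.lo, self._boundary_der[0])
        if np.any(above):
            out[above] = self._boundary_val[1] + np.outer(x[above] - self.hi, self._boundary_der[1])
        return out


# ---------------------------------------------------------------------------
# truncation and Box-Cox transform
# ---------------------------------------------------------------------------

def truncate(
    hclc: np.ndarray, x_min: int, inclusive: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Drop low-count cells; return (retained values, retained indices).

    With ``inclusive`` (the default) cells with ``hclc >= x_min`` are kept;
    the classification pipeline instead keeps ``hclc > x_min`` so that
    boundary cells, which receive posterior 0, are excluded from fitting.
    """
    hclc = np.asarray(hclc)
    if np.any(hclc < 0):
        raise ValueError("HCLC values must be nonnegative")
    mask = hclc >= x_min if inclusive else hclc > x_min
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("truncation removed all cells")
    return hclc[idx], idx


@dataclass
class BoxCoxTransform:
    """Fitted Box-Cox power transform z = (x^lambda - 1) / lambda."""

    lam: float
    z_values: np.ndarray
    n_retained: int
    n_total: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("Box-Cox transform requires strictly positive values")
        return _boxcox_transform(x, self.lam)


def fit_boxcox(values: np.ndarray, n_total: int | None = None) -> BoxCoxTransform:
    """Maximum-likelihood Box-Cox transform of strictly positive counts.

    lambda maximizes the standard profile log-likelihood over [-2, 2]
    (bounded scalar search, tolerance 1e-4); lambda = 0 is the log limit.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values to transform")
    if np.any(x <= 0):
        raise ValueError(
            "Box-Cox transform requires positive values; raise x_min to at least 1 "
            "or shift the counts"
        )
    res = minimize_scalar(
        lambda lmb: -boxcox_llf(lmb, x),
        bounds=LAMBDA_RANGE,
        method="bounded",
        options={"xatol": LAMBDA_TOL},
    )
    lam = float(res.x)
    z = _boxcox_transform(x, lam)
    return BoxCoxTransform(lam, z, n_retained=x.size, n_total=n_total or x.size)


# ---------------------------------------------------------------------------
# histogram + Poisson spline smoothing
# ---------------------------------------------------------------------------

def bin_histogram(z_values: np.ndarray, n_bins: int = DEFAULT_BINS) -> tuple[np.ndarray, np.ndarray]:
    """K equal-width bins spanning the data range; returns (centers, counts)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty sample")
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    zmin, zmax = float(z.min()), float(z.max())
    if zmax == zmin:
        raise ValueError("degenerate sample: all transformed values equal")
    counts, edges = np.histogram(z, bins=n_bins, range=(zmin, zmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(np.int64)


@dataclass
class SplineDensityFit:
    """Poisson-spline smoothed histogram: density and CDF of the mixture."""

    bin_centers: np.ndarray
    bin_counts: np.ndarray
    coefficients: np.ndarray  # intercept followed by spline coefficients
    basis: NaturalSplineBasis
    n_retained: int
    fitted_counts: np.ndarray = field(init=False)
    rho: np.ndarray = field(init=False)  # per-bin probability mass f_i / N_T
    bin_width: float = field(init=False)
    _cdf_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bin_width = float(self.bin_centers[1] - self.bin_centers[0])
        self.fitted_counts = np.exp(self.linear_predictor(self.bin_centers))
        self.rho = self.fitted_counts / self.n_retained
        cum = np.cumsum(self.rho)
        self._cdf_grid = cum / cum[-1]  # renormalized so F(c_K) = 1 exactly

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def linear_predictor(self, z: np.ndarray) -> np.ndarray:
        X = self.basis.transform(np.atleast_1d(z))
        return self.coefficients[0] + X @ self.coefficients[1:]

    def density(self, z: np.ndarray) -> np.ndarray:
        """Continuous mixture density f-hat(z), per unit of z."""
        return np.exp(self.linear_predictor(z)) / (self.n_retained * self.bin_width)

    def cdf(self, t: np.ndarray) -> np.ndarray:
        """F-hat by linear interpolation of cumulative bin masses."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.interp(t, self.bin_centers, self._cdf_grid, left=0.0, right=1.0)


def fit_poisson_spline(
    bin_centers: np.ndarray,
    bin_counts: np.ndarray,
    df: int = DEFAULT_SPLINE_DF,
) -> SplineDensityFit:
    """Fit log f(z) = b0 + sum_k b_k ns_k(z) to histogram counts.

    Bin counts are treated as independent Poisson observations and the GLM
    is fit by IRLS.  Interior knots sit at equally spaced quantiles of the
    bin centers (so effectively uniformly over the data range, as in
    Lindsey-method density estimation); boundary knots at the data range.
    Count-weighted knot placement was tried and rejected: it clusters the
    knots in the central mass and makes the local log-density curvature,
    which central matching differentiates, unstable.
    """
    centers = np.asarray(bin_centers, dtype=float)
    counts = np.asarray(bin_counts, dtype=float)
    if df >= len(centers):
        raise ValueError(f"spline df ({df}) must be smaller than the number of bins ({len(centers)})")
    if np.any(counts < 0):
        raise ValueError("bin counts must be nonnegative")

    n_interior = df - 1
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(centers, probs)
    lo, hi = float(centers.min()), float(centers.max())
    eps = 1e-9 * max(1.0, hi - lo)
    interior = np.clip(interior, lo + eps, hi - eps)
    # knots must be distinct for a well-conditioned basis
    interior = np.unique(interior)
    basis = NaturalSplineBasis(interior, (lo, hi))

    X = sm.add_constant(basis.transform(centers), has_constant="add")
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    result = model.fit(maxiter=GLM_MAX_ITER, tol=GLM_TOL)
    if not result.converged:
        raise RuntimeError(
            f"Poisson spline GLM did not converge in {GLM_MAX_ITER} IRLS iterations "
            f"(deviance {result.deviance:.4g})"
        )
    return SplineDensityFit(
        bin_centers=centers,
        bin_counts=np.asarray(bin_counts),
        coefficients=np.asarray(result.params),
        basis=basis,
        n_retained=int(round(counts.sum())),
    )


def evaluate_density(fit: SplineDensityFit, z: np.ndarray) -> np.ndarray:
    """Continuous density f-hat(z); log-linear tails beyond the fitted range."""
    return fit.density(z)
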