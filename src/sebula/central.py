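"""Singlet density estimation by central matching.

Under the zero assumption, transformed HCLC values near the mode of the
mixture density are overwhelmingly singlets, so the singlet component
pi0 * f0(z) can be fit locally: the log of the spline-smoothed density is
regressed on a quadratic in (z - c_max) over a central percentile window,
and the quadratic coefficients induce the singlet normal parameters
(delta0, sigma0) and, by normalizing the implied singlet bin counts against
the fitted mixture counts, the singlet proportion pi0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .mixture import SplineDensityFit

__all__ = [
    "CentralWindow",
    "SingletFit",
    "locate_mode",
    "central_window_bins",
    "fit_quadratic",
    "derive_singlet_params",
    "estimate_pi0",
    "library_pi0",
    "fit_central_matching",
]

DEFAULT_LOWER_PCT = 20.0
DEFAULT_UPPER_PCT = 60.0
MIN_WINDOW_BINS = 4


@dataclass(frozen=True)
class CentralWindow:
    """Percentile window of the transformed sample used for the local fit."""

    lower_pct: float = DEFAULT_LOWER_PCT
    upper_pct: float = DEFAULT_UPPER_PCT

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError("require 0 <= lower_pct < upper_pct <= 100")


@dataclass
class SingletFit:
    """Singlet normal component and proportions from central matching."""

    c_max: float
    beta0: float
    beta1: float
    beta2: float
    delta0: float
    sigma0: float
    pi0_truncated: float
    pi0_library: float
    singlet_bin_counts: np.ndarray

    def f0(self, z: np.ndarray) -> np.ndarray:
        """Singlet density N(delta0, sigma0^2) at z."""
        return norm.pdf(np.asarray(z, dtype=float), loc=self.delta0, scale=self.sigma0)

    def F0(self, t: np.ndarray) -> np.ndarray:
        """Singlet CDF at t."""
        return norm.cdf(np.asarray(t, dtype=float), loc=self.delta0, scale=self.sigma0)


def locate_mode(fit: SplineDensityFit) -> float:
    """Center of the bin where the fitted mixture density is largest.

    Ties break toward the smaller bin index (np.argmax convention).
    """
    return float(fit.bin_centers[int(np.argmax(fit.fitted_counts))])


def central_window_bins(
    fit: SplineDensityFit, z_values: np.ndarray, window: CentralWindow
) -> np.ndarray:
    """Indices of bins whose centers fall inside the percentile window of Z_T."""
    lo, hi = np.percentile(np.asarray(z_values, dtype=float), [window.lower_pct, window.upper_pct])
    members = np.flatnonzero((fit.bin_centers >= lo) & (fit.bin_centers <= hi))
    if members.size < MIN_WINDOW_BINS:
        raise ValueError(
            f"central window contains {members.size} bins; at least {MIN_WINDOW_BINS} "
            "are required for the quadratic fit (widen the window or increase K)"
        )
    return members


def fit_quadratic(
    fit: SplineDensityFit, member_bins: np.ndarray, c_max: float
) -> tuple[float, float, float]:
    """OLS of log f-hat_i on (c_i - c_max) and (c_i - c_max)^2 over the window."""
    c = fit.bin_centers[member_bins] - c_max
    y = np.log(fit.fitted_counts[member_bins])
    X = np.column_stack([np.ones_like(c), c, c * c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta0, beta1, beta2 = map(float, beta)
    if beta2 >= 0:
        raise ValueError(
            "no concave central fit (beta2 >= 0); widen the window or adjust x_min"
        )
    return beta0, beta1, beta2


def derive_singlet_params(beta1: float, beta2: float, c_max: float) -> tuple[float, float]:
    """delta0 = c_max - beta1/(2 beta2); sigma0 = (-2 beta2)^(-1/2)."""
    if beta2 >= 0:
        raise ValueError("singlet parameters require beta2 < 0")
    delta0 = c_max - beta1 / (2.0 * beta2)
    sigma0 = (-2.0 * beta2) ** -0.5
    return float(delta0), float(sigma0)


def estimate_pi0(
    fit: SplineDensityFit, betas: tuple[float, float, float], c_max: float
) -> tuple[float, np.ndarray]:
    """Singlet proportion among retained cells: sum(f-tilde) / sum(f-hat).

    f-tilde extrapolates the central quadratic over all K bins; the ratio is
    capped at 1 (sampling noise can push it above).
    """
    beta0, beta1, beta2 = betas
    d = fit.bin_centers - c_max
    singlet_counts = np.exp(beta0 + beta1 * d + beta2 * d * d)
    pi0 = float(singlet_counts.sum() / fit.fitted_counts.sum())
    if pi0 > 1.0:
        warnings.warn(f"pi0 estimate {pi0:.4f} exceeds 1; capping at 1", stacklevel=2)
        pi0 = 1.0
    return pi0, singlet_counts


def library_pi0(pi0_truncated: float, n_retained: int, n_total: int) -> float:
    """Singlet proportion in the whole library: 1 - (N_T/N)(1 - pi0)."""
    if not (0 < n_retained <= n_total):
        raise ValueError("require 0 < n_retained <= n_total")
    return 1.0 - (n_retained / n_total) * (1.0 - pi0_truncated)


def fit_central_matching(
    fit: SplineDensityFit,
    z_values: np.ndarray,
    n_total: int,
    window: CentralWindow | None = None,
) -> SingletFit:
    """Run the full central-matching chain on a fitted mixture density."""
    window = window or CentralWindow()
    c_max = locate_mode(fit)
    members = central_window_bins(fit, z_values, window)
    lo, hi = fit.bin_centers[members[0]], fit.bin_centers[members[-1]]
    if not (lo <= c_max <= hi):
        warnings.warn(
            f"mixture mode {c_max:.3g} lies outside the central window "
            f"[{lo:.3g}, {hi:.3g}]; the quadratic remains anchored at the mode",
            stacklevel=2,
        )
    betas = fit_quadratic(fit, members, c_max)
    delta0, sigma0 = derive_singlet_params(betas[1], betas[2], c_max)
    pi0_t, singlet_counts = estimate_pi0(fit, betas, c_max)
    pi0_lib = library_pi0(pi0_t, fit.n_retained, n_total)
    return SingletFit(
        c_max=c_max,
        beta0=betas[0],
        beta1=betas[1],
        beta2=betas[2],
        delta0=delta0,
        sigma0=sigma0,
        pi0_truncated=pi0_t,
        pi0_library=pi0_lib,
        singlet_bin_counts=singlet_counts,
    )
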