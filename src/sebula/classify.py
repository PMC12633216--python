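"""Posterior multiplet probabilities and FDR-controlled calls.

Each retained cell gets the two-group posterior
``p_j = 1 - pi0 * f0(z_j) / f(z_j)`` (0 for cells at or below the
truncation threshold).  Calls are made either at a posterior cutoff
(p_j > 0.8, i.e. a 20% local FDR) or by the right-sided Bayesian FDR rule,
which thresholds the transformed value z at the smallest cutoff t whose
estimated tail FDR ``pi0 (1 - F0(t)) / (1 - F(t))`` is at or below the
nominal level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pipeline import SebulaFit

__all__ = [
    "DEFAULT_POSTERIOR_THRESHOLD",
    "DEFAULT_FDR_LEVEL",
    "posterior_multiplet",
    "call_by_local_fdr",
    "bayesian_fdr",
    "call_by_bayesian_fdr",
    "make_calls",
]

DEFAULT_POSTERIOR_THRESHOLD = 0.8
DEFAULT_FDR_LEVEL = 0.2


def posterior_multiplet(hclc: np.ndarray, fit: SebulaFit) -> np.ndarray:
    """Per-cell posterior probability of being a multiplet.

    Cells with HCLC at or below x_min get probability 0; for the rest the
    singlet normal density and the spline mixture density are both
    evaluated as continuous densities on the z scale, so their ratio is
    scale-free.  The result is clipped to [0, 1].
    """
    x = np.asarray(hclc)
    p = np.zeros(x.shape, dtype=float)
    active = x > fit.x_min
    if np.any(active):
        z = fit.transform(x[active].astype(float))
        f = fit.density.density(z)
        if np.any(f <= 0):
            raise FloatingPointError("mixture density vanished at an observed point")
        p[active] = 1.0 - fit.singlet.pi0_truncated * fit.singlet.f0(z) / f
    return np.clip(p, 0.0, 1.0)


def call_by_local_fdr(
    posteriors: np.ndarray, threshold: float = DEFAULT_POSTERIOR_THRESHOLD
) -> np.ndarray:
    """Multiplet calls at a posterior cutoff: p_j > threshold.

    The default 0.8 corresponds to a 20% local false discovery rate
    (1 - p_j) among calls.
    """
    if not (0 < threshold < 1):
        raise ValueError("posterior threshold must lie in (0, 1)")
    return np.asarray(posteriors) > threshold


def bayesian_fdr(t: np.ndarray, fit: SebulaFit) -> np.ndarray:
    """Estimated tail FDR of the rule 'call multiplet when z >= t'."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pi0 = fit.singlet.pi0_truncated
    num = pi0 * (1.0 - fit.singlet.F0(t))
    den = 1.0 - fit.density.cdf(t)
    out = np.empty_like(num)
    beyond = den <= 0
    if np.any(beyond):
        warnings.warn("cutoff beyond the data range: tail FDR reported as 0", stacklevel=2)
    out[beyond] = 0.0
    out[~beyond] = np.clip(num[~beyond] / den[~beyond], 0.0, 1.0)
    return out


def call_by_bayesian_fdr(
    z: np.ndarray, fit: SebulaFit, level: float = DEFAULT_FDR_LEVEL
) -> tuple[np.ndarray, float]:
    """Right-sided Bayesian FDR calls at a nominal level.

    The cutoff grid is the histogram bin centers augmented with the
    observed z values; t* is the smallest grid point whose estimated FDR is
    at or below ``level``, and cells with z >= t* are called.  Returns
    (calls, t*); when no grid point satisfies the level no cell is called
    and t* is NaN.
    """
    if not (0 < level <= 1):
        raise ValueError("FDR level must lie in (0, 1]")
    z = np.asarray(z, dtype=float)
    grid = np.unique(np.concatenate([fit.density.bin_centers, z]))
    # cutoffs at or beyond the last bin center have no estimated tail mass
    # (F-hat = 1) and cannot define a meaningful rule
    grid = grid[grid < fit.density.bin_centers[-1]]
    if grid.size == 0:
        warnings.warn("no usable cutoff grid; zero cells called", stacklevel=2)
        return np.zeros(z.shape, dtype=bool), float("nan")
    fdr = bayesian_fdr(grid, fit)
    ok = np.flatnonzero(fdr <= level)
    if ok.size == 0:
        warnings.warn(f"no cutoff achieves FDR <= {level}; zero cells called", stacklevel=2)
        return np.zeros(z.shape, dtype=bool), float("nan")
    t_star = float(grid[ok[0]])
    return z >= t_star, t_star


def make_calls(
    hclc: pd.Series | np.ndarray,
    fit: SebulaFit,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    fdr_level: float = DEFAULT_FDR_LEVEL,
) -> pd.DataFrame:
    """Per-cell call table: posterior, local-FDR call and Bayesian-FDR call.

    All barcodes are kept in the output; cells excluded by truncation carry
    posterior 0, a NaN z value and a ``retained`` flag of False.
    """
    if isinstance(hclc, pd.Series):
        barcodes = hclc.index.to_numpy()
        x = hclc.to_numpy()
    else:
        x = np.asarray(hclc)
        barcodes = np.arange(x.size)
    active = x > fit.x_min
    z = np.full(x.shape, np.nan)
    z[active] = fit.transform(x[active].astype(float))
    p = posterior_multiplet(x, fit)
    call_local = call_by_local_fdr(p, posterior_threshold)
    call_bfdr = np.zeros(x.shape, dtype=bool)
    t_star = float("nan")
    if np.any(active):
        call_bfdr[active], t_star = call_by_bayesian_fdr(z[active], fit, level=fdr_level)
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "hclc": x,
            "z": z,
            "retained": active,
            "posterior_multiplet": p,
            "local_fdr": 1.0 - p,
            "call_local": call_local,
            "call_bfdr": call_bfdr,
        }
    )
    df.attrs["t_star"] = t_star
    df.attrs["fdr_level"] = fdr_level
    df.attrs["posterior_threshold"] = posterior_threshold
    return df
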