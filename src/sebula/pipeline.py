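"""End-to-end model fit: truncation -> Box-Cox -> density -> central matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .central import CentralWindow, SingletFit, fit_central_matching
from .mixture import (
    DEFAULT_BINS,
    DEFAULT_SPLINE_DF,
    BoxCoxTransform,
    SplineDensityFit,
    bin_histogram,
    fit_boxcox,
    fit_poisson_spline,
    truncate,
)

__all__ = ["SebulaFit", "fit_sebula"]


@dataclass
class SebulaFit:
    """Everything the classifier needs: transform, mixture and singlet fits.

    Cells with HCLC <= x_min are excluded from fitting and later receive
    posterior multiplet probability 0; N is the full library size and N_T
    the number of retained (fitted) cells.
    """

    x_min: int
    transform: BoxCoxTransform
    density: SplineDensityFit
    singlet: SingletFit
    n_total: int
    retained_index: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.transform.n_retained

    def summary(self) -> dict:
        s = self.singlet
        return {
            "x_min": self.x_min,
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "lambda": self.transform.lam,
            "n_bins": self.density.n_bins,
            "spline_df": self.density.basis.df,
            "spline_coefficients": self.density.coefficients.tolist(),
            "c_max": s.c_max,
            "delta0": s.delta0,
            "sigma0": s.sigma0,
            "pi0_truncated": s.pi0_truncated,
            "pi0_library": s.pi0_library,
            "multiplet_prevalence": 1.0 - s.pi0_library,
        }


def fit_sebula(
    hclc: np.ndarray | pd.Series,
    x_min: int = 0,
    n_bins: int = DEFAULT_BINS,
    spline_df: int = DEFAULT_SPLINE_DF,
    window: CentralWindow | None = None,
) -> SebulaFit:
    """Fit the semi-parametric mixture model to a vector of HCLC counts.

    Only cells with HCLC strictly greater than ``x_min`` enter the fit
    (zeros are therefore always excluded, as the Box-Cox transform needs
    positive support); they are Box-Cox transformed, binned, smoothed with
    the Poisson spline, and the singlet component is recovered by central
    matching.
    """
    values = np.asarray(hclc.values if isinstance(hclc, pd.Series) else hclc)
    retained, idx = truncate(values, x_min, inclusive=False)
    transform = fit_boxcox(retained, n_total=values.size)
    centers, counts = bin_histogram(transform.z_values, n_bins=n_bins)
    density = fit_poisson_spline(centers, counts, df=spline_df)
    singlet = fit_central_matching(density, transform.z_values, n_total=values.size, window=window)
    return SebulaFit(
        x_min=int(x_min),
        transform=transform,
        density=density,
        singlet=singlet,
        n_total=int(values.size),
        retained_index=idx,
    )
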