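"""Shared fixtures: closed-form oracles and reusable simulated datasets."""

import numpy as np
import pytest

from sebula import SimulationConfig, simulate_dataset
from sebula.central import fit_central_matching
from sebula.mixture import BoxCoxTransform, bin_histogram, fit_poisson_spline
from sebula.pipeline import SebulaFit

TWO_NORMAL_PI0 = 0.9
TWO_NORMAL_MU1 = 4.0
TWO_NORMAL_N = 20_000


def build_fit_from_z(z: np.ndarray, n_total: int | None = None) -> SebulaFit:
    """Assemble a SebulaFit directly from continuous z values.

    Skips truncation and Box-Cox (identity transform with lambda = 1 keeps
    z unchanged up to a shift, and the stored z_values are used as-is), so
    closed-form mixtures can exercise the density / central-matching /
    classification chain without count-data preprocessing.
    """
    z = np.asarray(z, dtype=float)
    n_total = n_total if n_total is not None else z.size
    centers, counts = bin_histogram(z)
    density = fit_poisson_spline(centers, counts)
    singlet = fit_central_matching(density, z, n_total=n_total)
    transform = BoxCoxTransform(lam=1.0, z_values=z, n_retained=z.size, n_total=n_total)
    return SebulaFit(
        x_min=0,
        transform=transform,
        density=density,
        singlet=singlet,
        n_total=n_total,
        retained_index=np.arange(z.size),
    )


@pytest.fixture(scope="session")
def two_normal_sample() -> tuple[np.ndarray, np.ndarray]:
    """0.9 N(0,1) + 0.1 N(4,1), 20,000 draws, with component labels."""
    rng = np.random.default_rng(20_240_101)
    is_alt = rng.random(TWO_NORMAL_N) < (1 - TWO_NORMAL_PI0)
    z = rng.standard_normal(TWO_NORMAL_N) + np.where(is_alt, TWO_NORMAL_MU1, 0.0)
    return z, is_alt


@pytest.fixture(scope="session")
def two_normal_fit(two_normal_sample) -> SebulaFit:
    z, _ = two_normal_sample
    return build_fit_from_z(z)


@pytest.fixture(scope="session")
def small_dataset():
    """One small clean labeled dataset for fast integration-style tests."""
    cfg = SimulationConfig(n_cells=4_000, n_loci=1_500, doublet_proportion=0.10, seed=11)
    return simulate_dataset(cfg)
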