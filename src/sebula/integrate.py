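"""Probabilistic integration of HCLC evidence with external callers.

The HCLC posterior p_j and the library singlet proportion pi0-tilde define
a per-cell Bayes factor BF_j = posterior odds / prior odds of the
multiplet class.  Treating an external caller's multiplet probability
(e.g. an RNA-modality detector) as the prior, a naive-Bayes update yields
the combined posterior P(multiplet | x, y) = prior*BF / (prior*BF + 1 - prior),
assuming the two evidence sources are conditionally independent given the
cell's class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["bayes_factor", "combine", "integrate_tables"]

_CLIP = 1e-10


def bayes_factor(p_j: np.ndarray, pi0_library: float) -> np.ndarray:
    """BF_j = [p_j / (1 - p_j)] / [(1 - pi0) / pi0].

    Posteriors within 1e-10 of 1 are clipped first so the odds stay
    finite; a degenerate library prior (pi0 of exactly 0 or 1) leaves the
    prior odds undefined and raises.
    """
    if not (0.0 < pi0_library < 1.0):
        raise ValueError("degenerate prior; integration undefined for pi0_library in {0, 1}")
    p = np.clip(np.asarray(p_j, dtype=float), 0.0, 1.0 - _CLIP)
    prior_odds = (1.0 - pi0_library) / pi0_library
    return (p / (1.0 - p)) / prior_odds


def combine(prior_prob: np.ndarray, bf: np.ndarray) -> np.ndarray:
    """Posterior-odds update: prior*BF / (prior*BF + (1 - prior))."""
    prior = np.asarray(prior_prob, dtype=float)
    bf = np.asarray(bf, dtype=float)
    if np.any((prior < 0) | (prior > 1)) or np.any(bf < 0):
        raise ValueError("prior probabilities must lie in [0, 1] and Bayes factors be nonnegative")
    num = prior * bf
    den = num + (1.0 - prior)
    if np.any(den == 0):
        raise ValueError("contradictory certainties: prior*BF and (1 - prior) both zero")
    return num / den


def integrate_tables(
    calls: pd.DataFrame,
    external: pd.DataFrame,
    pi0_library: float,
    join: str = "left",
) -> pd.DataFrame:
    """Join HCLC calls with an external probability table and combine.

    ``calls`` needs columns ``barcode`` and ``posterior_multiplet``;
    ``external`` needs ``barcode`` and a probability column (the second
    column, whatever its name).  Under a left join, cells missing external
    evidence keep the HCLC posterior; under an inner join, only shared
    barcodes survive (zero overlap raises).  External probabilities of
    exactly 0 or 1 are nudged by 1e-10.
    """
    if join not in ("left", "inner"):
        raise ValueError("join must be 'left' or 'inner'")
    ext = external.rename(columns={external.columns[1]: "prior_prob"})[["barcode", "prior_prob"]]
    merged = calls.merge(ext, on="barcode", how=join)
    if merged.empty:
        raise ValueError("zero overlapping barcodes between call table and external table")

    prior = merged["prior_prob"].to_numpy(dtype=float)
    missing_ext = np.isnan(prior)
    boundary = (~missing_ext) & ((prior <= 0.0) | (prior >= 1.0))
    if np.any(boundary):
        warnings.warn(
            f"{int(boundary.sum())} external probabilities at exactly 0 or 1 nudged by {_CLIP}",
            stacklevel=2,
        )
        prior[boundary] = np.clip(prior[boundary], _CLIP, 1.0 - _CLIP)

    p = merged["posterior_multiplet"].to_numpy(dtype=float)
    bf = bayes_factor(p, pi0_library)
    combined = np.where(missing_ext, p, combine(np.nan_to_num(prior, nan=0.5), bf))

    out = merged.copy()
    out["bayes_factor"] = bf
    out["combined_posterior"] = combined
    out["external_missing"] = missing_ext
    return out
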