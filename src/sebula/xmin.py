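"""Data-driven selection of the truncation point x_min.

For each candidate threshold the full model is refit and the goodness of
fit of the singlet normal is scored by the cross-entropy of the fitted
N(delta0, sigma0^2) over the transformed values within one sigma of
delta0.  Lower cross-entropy means the central-matching assumption holds
better; the chosen threshold is the elbow of the cross-entropy trace,
balancing fit quality against the number of retained cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .central import CentralWindow
from .mixture import DEFAULT_BINS, DEFAULT_SPLINE_DF
from .pipeline import SebulaFit, fit_sebula

__all__ = ["XminTrace", "cross_entropy", "trace_xmin", "select_elbow", "auto_xmin"]


def cross_entropy(fit: SebulaFit) -> float:
    """Mean negative log singlet density over S = {z : |z - delta0| <= sigma0}."""
    s = fit.singlet
    z = fit.transform.z_values
    members = z[(z >= s.delta0 - s.sigma0) & (z <= s.delta0 + s.sigma0)]
    if members.size == 0:
        raise ValueError("no transformed values within one sigma of delta0; CE undefined")
    return float(-np.mean(norm.logpdf(members, loc=s.delta0, scale=s.sigma0)))


@dataclass
class XminTrace:
    """Cross-entropy trace over candidate truncation points."""

    candidates: np.ndarray
    cross_entropies: np.ndarray  # NaN for failed candidates
    n_retained: np.ndarray
    window_sizes: np.ndarray
    failures: dict[int, str] = field(default_factory=dict)
    chosen: int | None = None

    @property
    def ok(self) -> np.ndarray:
        return ~np.isnan(self.cross_entropies)

    def to_frame(self) -> pd.DataFrame:
        status = np.where(self.ok, "ok", "failed")
        return pd.DataFrame(
            {
                "x_min": self.candidates,
                "n_retained": self.n_retained,
                "cross_entropy": self.cross_entropies,
                "window_size": self.window_sizes,
                "status": status,
            }
        )


def trace_xmin(
    hclc: np.ndarray | pd.Series,
    candidates: np.ndarray | None = None,
    n_bins: int = DEFAULT_BINS,
    spline_df: int = DEFAULT_SPLINE_DF,
    window: CentralWindow | None = None,
    stride: int = 1,
) -> XminTrace:
    """Refit the model over a grid of x_min values and record CE(x_min).

    The default grid is every ``stride``-th integer from 0 to the first
    quartile Q1 of the HCLC vector (inclusive).  Candidates for which the
    fit fails (non-concave central window, empty one-sigma set, ...) are
    recorded with the failure reason and excluded from elbow selection.
    """
    values = np.asarray(hclc.values if isinstance(hclc, pd.Series) else hclc)
    q1 = int(np.percentile(values, 25))
    if candidates is None:
        candidates = np.arange(0, q1 + 1, max(1, stride))
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("empty candidate grid")
    if np.any(candidates < 0) or np.any(candidates > q1):
        raise ValueError(f"candidates must lie within [0, Q1] = [0, {q1}]")

    ce = np.full(candidates.size, np.nan)
    n_ret = np.zeros(candidates.size, dtype=int)
    wsize = np.zeros(candidates.size, dtype=int)
    failures: dict[int, str] = {}
    for i, xm in enumerate(candidates):
        try:
            fit = fit_sebula(values, x_min=int(xm), n_bins=n_bins, spline_df=spline_df, window=window)
            n_ret[i] = fit.n_retained
            s = fit.singlet
            z = fit.transform.z_values
            wsize[i] = int(np.count_nonzero((z >= s.delta0 - s.sigma0) & (z <= s.delta0 + s.sigma0)))
            ce[i] = cross_entropy(fit)
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            failures[int(xm)] = str(exc)
    if not np.any(~np.isnan(ce)):
        raise RuntimeError("model fit failed for every candidate x_min")
    trace = XminTrace(candidates, ce, n_ret, wsize, failures)
    trace.chosen = select_elbow(trace)
    return trace


def select_elbow(trace: XminTrace) -> int:
    """Elbow of the CE trace: maximal distance to the first-last chord.

    Both axes are min-max normalized before computing each point's
    perpendicular distance to the chord joining the first and last
    successful candidates; ties break toward the smaller x_min.  With
    fewer than three successful candidates the CE minimizer is returned.
    """
    ok = trace.ok
    xs = trace.candidates[ok].astype(float)
    ys = trace.cross_entropies[ok]
    if xs.size == 1:
        return int(xs[0])
    if xs.size == 2:
        return int(xs[int(np.argmin(ys))])

    def norm01(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    x, y = norm01(xs), norm01(ys)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    chord = np.hypot(dx, dy)
    if chord == 0:
        return int(xs[0])
    dist = np.abs(dx * (y[0] - y) - (x[0] - x) * dy) / chord
    return int(xs[int(np.argmax(dist))])


def auto_xmin(hclc: np.ndarray | pd.Series, **kwargs) -> tuple[int, XminTrace]:
    """Convenience wrapper: run the trace and return (chosen x_min, trace)."""
    trace = trace_xmin(hclc, **kwargs)
    assert trace.chosen is not None
    return trace.chosen, trace
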