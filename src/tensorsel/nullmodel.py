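"""Gaussian null with optimized standard deviation for component scores.

A feature's score is its entry in the chosen feature-mode singular vector.
Under the null the scores are taken as N(0, sigma^2); the P-value is the
chi-squared (1 d.o.f.) upper tail of the squared standardized score,

    P_i = Pr[ chi2_1 > (u_i / sigma)^2 ],

i.e. the two-sided standard-normal tail.  sigma is not estimated from the
raw spread (which signal features would inflate) but optimized so the
P-values of the null bulk look uniform: histogram 1 - P into B equal-width
bins on [0, 1], drop the bins nearest 1 (where true signal concentrates),
and minimize the standard deviation of the remaining bin counts.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import NullFit

__all__ = [
    "compute_pvalues",
    "optimize_sd",
    "bh_adjust",
    "select_features",
    "fit_null",
    "GaussianNullSelector",
]

DEFAULT_BINS = 100
DEFAULT_TAIL_FRACTION = 0.1
DEFAULT_SIGMA_BRACKET = (0.01, 10.0)
DEFAULT_THRESHOLD = 0.01
_GRID_POINTS = 64


def compute_pvalues(scores, sigma: float) -> np.ndarray:
    """Chi-squared (1 dof) upper-tail P-values of ``(scores / sigma)**2``."""
    if not np.isscalar(sigma) or not sigma > 0:
        raise ValueError(f"sigma must be a positive scalar, got {sigma!r}")
    u = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("scores contain non-finite values")
    return stats.chi2.sf((u / sigma) ** 2, df=1)


def _flatness_objective(u: np.ndarray, sigma: float, bins: int, tail_fraction: float) -> float:
    """Coefficient of variation of the kept (non-tail) histogram bin counts.

    The raw SD of the counts has a degenerate optimum: shrinking sigma
    pushes every score into the excluded tail, emptying the kept bins and
    driving their SD to zero.  Dividing by the mean kept count removes
    that optimum (emptying the bins now blows the objective up) while
    preserving the flat-histogram principle: the minimum is still where
    the null P-values are uniform.
    """
    p = stats.chi2.sf((u / sigma) ** 2, df=1)
    counts, _ = np.histogram(1.0 - p, bins=bins, range=(0.0, 1.0))
    n_excluded = int(round(bins * tail_fraction))
    kept = counts[: bins - n_excluded] if n_excluded > 0 else counts
    mean = kept.mean()
    if mean == 0:
        return float("inf")
    return float(np.std(kept) / mean)


def optimize_sd(
    scores,
    bins: int = DEFAULT_BINS,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    sigma_bracket: Sequence[float] = DEFAULT_SIGMA_BRACKET,
    return_objective: bool = False,
):
    """Optimize the null standard deviation by the flat-histogram criterion.

    The search bracket is ``sigma_bracket`` (relative multipliers) times the
    sample SD of the scores, scanned on a 64-point geometric grid and then
    refined by bounded scalar minimization (relative tolerance 1e-4), which
    makes the estimate exactly equivariant under rescaling of the scores.
    """
    u = np.asarray(scores, dtype=float).ravel()
    if u.size == 0 or not np.all(np.isfinite(u)):
        raise ValueError("scores must be a non-empty finite vector")
    sd = float(np.std(u))
    if sd == 0.0:
        raise ValueError("scores are constant (all equal); sigma cannot be optimized")
    lo, hi = (float(sigma_bracket[0]) * sd, float(sigma_bracket[1]) * sd)
    if not (0 < lo < hi):
        raise ValueError(
            f"invalid sigma search bracket [{lo:.4g}, {hi:.4g}] "
            f"(multipliers {tuple(sigma_bracket)}, sample SD {sd:.4g})"
        )
    if u.size < 100:
        warnings.warn(
            f"optimizing sigma from only {u.size} scores; the flat-histogram "
            "objective is unreliable below ~100 scores",
            stacklevel=2,
        )
    grid = np.geomspace(lo, hi, _GRID_POINTS)
    vals = np.array([_flatness_objective(u, s, bins, tail_fraction) for s in grid])
    best = int(np.argmin(vals))
    lo_ref = grid[max(best - 1, 0)]
    hi_ref = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda s: _flatness_objective(u, s, bins, tail_fraction),
        bounds=(lo_ref, hi_ref),
        method="bounded",
        options={"xatol": 1e-4 * grid[best]},
    )
    sigma = float(res.x) if res.fun <= vals[best] else float(grid[best])
    obj = float(min(res.fun, vals[best]))
    if return_objective:
        return sigma, obj
    return sigma


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted P-values,
    capped at 1 and mapped back to the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    # mathematically adjusted >= raw; guard the 1-ulp dip of (p*m)/m rounding
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(m)
    out[order] = adjusted
    return out


def fit_null(
    scores,
    threshold: float = DEFAULT_THRESHOLD,
    bins: int = DEFAULT_BINS,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    sigma_bracket: Sequence[float] = DEFAULT_SIGMA_BRACKET,
    sigma: Optional[float] = None,
) -> NullFit:
    """Optimize sigma (unless given), compute raw and BH-adjusted P, threshold."""
    u = np.asarray(scores, dtype=float).ravel()
    if sigma is None:
        sigma, obj = optimize_sd(
            u, bins=bins, tail_fraction=tail_fraction,
            sigma_bracket=sigma_bracket, return_objective=True,
        )
    else:
        obj = _flatness_objective(u, sigma, bins, tail_fraction)
    p = compute_pvalues(u, sigma)
    adj = bh_adjust(p)
    counts, edges = np.histogram(1.0 - p, bins=bins, range=(0.0, 1.0))
    return NullFit(
        sigma=sigma,
        p_values=p,
        adjusted_p=adj,
        selected=adj < threshold,
        threshold=threshold,
        histogram=(edges, counts),
        objective_value=obj,
    )


def _feature_table(feature_ids, u, fit: NullFit) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "feature_id": [str(f) for f in feature_ids],
            "score_u": u,
            "p_value": fit.p_values,
            "adjusted_p": fit.adjusted_p,
            "selected": fit.selected,
        }
    )
    table["_absu"] = np.abs(table["score_u"])
    table = table.sort_values(
        ["adjusted_p", "_absu"], ascending=[True, False], kind="stable"
    ).drop(columns="_absu")
    return table.reset_index(drop=True)


def select_features(
    scores,
    feature_ids,
    threshold: float = DEFAULT_THRESHOLD,
    **null_kwargs,
) -> pd.DataFrame:
    """Full per-feature selection: sigma optimization, P-values, BH, threshold.

    Returns a table (feature_id, score_u, p_value, adjusted_p, selected)
    sorted by adjusted P then |score| descending.
    """
    u = np.asarray(scores, dtype=float).ravel()
    feature_ids = list(feature_ids)
    if len(feature_ids) != u.size:
        raise ValueError(
            f"{len(feature_ids)} feature ids for {u.size} scores"
        )
    if u.size == 1 and u[0] == 0.0:
        # degenerate single zero score: P = 1 by definition, nothing selected
        fit = NullFit(
            sigma=1.0, p_values=np.array([1.0]), adjusted_p=np.array([1.0]),
            selected=np.array([False]), threshold=threshold,
            histogram=(np.linspace(0, 1, 2), np.array([1])), objective_value=0.0,
        )
        return _feature_table(feature_ids, u, fit)
    fit = fit_null(u, threshold=threshold, **null_kwargs)
    return _feature_table(feature_ids, u, fit)


class GaussianNullSelector:
    """Feature selector under the SD-optimized Gaussian null (sklearn-style).

    Parameters
    ----------
    threshold : BH-adjusted P-value cutoff (default 0.01).
    bins, tail_fraction : flat-histogram objective configuration.
    sigma_bracket : relative (low, high) multipliers of the sample SD
        bounding the sigma search.
    sigma : fix the null SD instead of optimizing it.

    Attributes (after :meth:`fit`)
    ------------------------------
    sigma_, p_values_, adjusted_p_, selected_ (input order),
    feature_table_ (sorted), objective_value_.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        bins: int = DEFAULT_BINS,
        tail_fraction: float = DEFAULT_TAIL_FRACTION,
        sigma_bracket: Sequence[float] = DEFAULT_SIGMA_BRACKET,
        sigma: Optional[float] = None,
    ):
        self.threshold = threshold
        self.bins = bins
        self.tail_fraction = tail_fraction
        self.sigma_bracket = sigma_bracket
        self.sigma = sigma

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "bins": self.bins,
            "tail_fraction": self.tail_fraction,
            "sigma_bracket": self.sigma_bracket,
            "sigma": self.sigma,
        }

    def set_params(self, **params) -> "GaussianNullSelector":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, scores, feature_ids=None) -> "GaussianNullSelector":
        u = np.asarray(scores, dtype=float).ravel()
        if feature_ids is None:
            feature_ids = [f"feature_{i}" for i in range(u.size)]
        fit = fit_null(
            u,
            threshold=self.threshold,
            bins=self.bins,
            tail_fraction=self.tail_fraction,
            sigma_bracket=self.sigma_bracket,
            sigma=self.sigma,
        )
        self.null_fit_ = fit
        self.sigma_ = fit.sigma
        self.p_values_ = fit.p_values
        self.adjusted_p_ = fit.adjusted_p
        self.selected_ = fit.selected
        self.objective_value_ = fit.objective_value
        self.feature_table_ = _feature_table(feature_ids, u, fit)
        return self

    def get_support(self) -> np.ndarray:
        if not hasattr(self, "selected_"):
            raise AttributeError("GaussianNullSelector instance is not fitted yet")
        return self.selected_
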