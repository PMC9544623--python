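"""Multilevel heterogeneity statistics: I², typical sampling variance, marginal R².

I² partitions the total variability of the effect sizes into the share due
to between-study heterogeneity (per random level) versus sampling error,
using a "typical" within-study sampling variance in place of the per-row
variances. Marginal R² is the share of heterogeneity explained by the fixed
moderators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelFit


@dataclass(frozen=True)
class HeterogeneityStats:
    typical_v: float
    i2_by_level: dict
    i2_total: float
    r2_marginal: float | None = None

    def to_dict(self) -> dict:
        d = {
            "typical_v": float(self.typical_v),
            "i2_by_level": {k: float(v) for k, v in self.i2_by_level.items()},
            "i2_total": float(self.i2_total),
        }
        if self.r2_marginal is not None:
            d["r2_marginal"] = float(self.r2_marginal)
        return d


def typical_sampling_variance(v, estimator: str = "higgins-thompson") -> float:
    """Representative within-study sampling variance.

    The default is the Higgins-Thompson form built from inverse-variance
    weights w_i = 1/v_i:

        typical_v = (k - 1) * sum(w) / (sum(w)^2 - sum(w^2))

    ``estimator="mean"`` returns the plain average of the sampling variances
    (exposed for sensitivity checks).
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        raise ValueError("typical sampling variance needs at least 2 effects")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    if estimator == "mean":
        return float(np.mean(v))
    if estimator != "higgins-thompson":
        raise ValueError(f"unknown estimator {estimator!r}")
    w = 1.0 / v
    sw, sw2 = float(np.sum(w)), float(np.sum(w**2))
    return float((len(v) - 1) * sw / (sw**2 - sw2))


def i_squared(fit: ModelFit, typical_v: float) -> HeterogeneityStats:
    """Per-level and total I² (percent) for a fitted multilevel model."""
    if not fit.converged:
        raise ValueError("model did not converge")
    total_s2 = fit.total_sigma2
    denom = total_s2 + typical_v
    by_level = {name: 100.0 * s2 / denom if denom > 0 else 0.0
                for name, s2 in fit.variance_components.items()}
    i2_total = 100.0 * total_s2 / denom if denom > 0 else 0.0
    return HeterogeneityStats(typical_v=float(typical_v),
                              i2_by_level=by_level, i2_total=float(i2_total))


def r2_marginal(mod_fit: ModelFit, null_fit: ModelFit | None = None) -> float:
    """Percent of heterogeneity explained by the moderators (marginal R²).

    R² = 100 * var(X beta) / (var(X beta) + sum(sigma2)) for the moderator
    model, clipped to [0, 100]. ``null_fit``, when given, is only checked
    for having the same data and random structure.
    """
    if null_fit is not None:
        if null_fit.n_effects != mod_fit.n_effects:
            raise ValueError("null and moderator fits are not on the same data")
        if set(null_fit.variance_components) != set(mod_fit.variance_components):
            raise ValueError("null and moderator fits have different random structures")
    fitted = mod_fit.fitted_values()
    s2_fixed = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    denom = s2_fixed + mod_fit.total_sigma2
    if denom <= 0:
        return 0.0
    return float(np.clip(100.0 * s2_fixed / denom, 0.0, 100.0))
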