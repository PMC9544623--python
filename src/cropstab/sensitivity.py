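"""Sensitivity analyses: leave-one-out, subsampling, time-lag and Egger tests.

All procedures refit the random-effects-only (null) multilevel model of the
requested effect size; stochastic procedures are seeded and reproduce
exactly under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import model, pipeline
from .data import Dataset
from .model import ModelSpec


@dataclass
class SensitivityReport:
    kind: str
    iterations: pd.DataFrame  # label, estimate, ci_low, ci_high
    summary: dict
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "iterations": [
                {k: (float(v) if isinstance(v, (int, float, np.floating)) else str(v))
                 for k, v in row.items()}
                for row in self.iterations.to_dict("records")
            ],
            "summary": {k: float(v) for k, v in self.summary.items()},
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _null_fit(ds: Dataset, spec: ModelSpec, ci_level: float = 0.95):
    cfg = pipeline.SuiteConfig()
    y, S, levels, _ = pipeline._contrast_inputs(ds, spec.response_type, cfg)
    X = pd.DataFrame({"intercept": np.ones(len(y))})
    fr = model.fit(y, X, S, levels, method=spec.method)
    wald = model.wald_summary(fr, level=ci_level)
    return fr, wald


def _covariate_fit(ds: Dataset, spec: ModelSpec, covariate, cov_name: str,
                   ci_level: float = 0.95) -> pd.DataFrame:
    cfg = pipeline.SuiteConfig()
    y, S, levels, _ = pipeline._contrast_inputs(ds, spec.response_type, cfg)
    X = pd.DataFrame({"intercept": np.ones(len(y)),
                      cov_name: np.asarray(covariate, dtype=float)})
    fr = model.fit(y, X, S, levels, method=spec.method)
    return model.wald_summary(fr, level=ci_level)


def leave_one_publication_out(ds: Dataset, spec: Optional[ModelSpec] = None,
                              ci_level: float = 0.95) -> SensitivityReport:
    """Refit the null model once per publication left out."""
    spec = spec or ModelSpec()
    pubs = ds.frame["publication_id"].astype(str).unique()
    if len(pubs) < 2:
        raise ValueError("leave-one-out needs at least 2 publications")
    _, full_wald = _null_fit(ds, spec, ci_level)
    rows = []
    for pub in pubs:
        mask = ds.frame["publication_id"].astype(str) != pub
        _, wald = _null_fit(ds.subset(mask), spec, ci_level)
        rows.append({"left_out": pub,
                     "estimate": float(wald.loc["intercept", "estimate"]),
                     "ci_low": float(wald.loc["intercept", "ci_low"]),
                     "ci_high": float(wald.loc["intercept", "ci_high"])})
    it = pd.DataFrame(rows)
    return SensitivityReport(
        kind="leave_one_publication_out", iterations=it,
        summary={"full_estimate": float(full_wald.loc["intercept", "estimate"]),
                 "min": float(it["estimate"].min()),
                 "max": float(it["estimate"].max())},
    )


def one_effect_per_comparison(ds: Dataset, spec: Optional[ModelSpec] = None,
                              replicates: int = 100, seed: int = 0,
                              ci_level: float = 0.95) -> SensitivityReport:
    """Refit keeping one uniformly chosen effect per experimental comparison."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = spec or ModelSpec()
    f = ds.frame
    comp = f["publication_id"].astype(str) + ":" + f["comparison_id"].astype(str)
    groups = {c: np.flatnonzero(comp.to_numpy() == c) for c in comp.unique()}
    _, full_wald = _null_fit(ds, spec, ci_level)
    rows = []
    rng = np.random.default_rng(seed)
    for r in range(replicates):
        keep = np.sort([rng.choice(idx) for idx in groups.values()])
        mask = pd.Series(False, index=f.index)
        mask.iloc[keep] = True
        _, wald = _null_fit(ds.subset(mask), spec, ci_level)
        rows.append({"replicate": r,
                     "estimate": float(wald.loc["intercept", "estimate"]),
                     "ci_low": float(wald.loc["intercept", "ci_low"]),
                     "ci_high": float(wald.loc["intercept", "ci_high"])})
    it = pd.DataFrame(rows)
    return SensitivityReport(
        kind="one_effect_per_comparison", iterations=it,
        summary={"full_estimate": float(full_wald.loc["intercept", "estimate"]),
                 "mean": float(it["estimate"].mean()),
                 "sd": float(it["estimate"].std(ddof=1)) if len(it) > 1 else 0.0,
                 "min": float(it["estimate"].min()),
                 "max": float(it["estimate"].max())},
        seed=seed,
    )


def time_lag_test(ds: Dataset, spec: Optional[ModelSpec] = None,
                  ci_level: float = 0.95) -> pd.DataFrame:
    """Publication year (mean-centred) as a continuous moderator."""
    spec = spec or ModelSpec()
    year = ds.frame["year"].astype(float)
    if year.nunique() < 2:
        raise ValueError("time-lag test needs more than one distinct year")
    return _covariate_fit(ds, spec, (year - year.mean()).to_numpy(), "year_centred",
                          ci_level)


def effective_n(n_t, n_c, variant: str = "harmonic"):
    """Effective sample size of a two-arm comparison.

    ``harmonic``: ñ = n_T n_C / (n_T + n_C); ``hedges``: 4 n_T n_C / (n_T + n_C).
    """
    n_t = np.asarray(n_t, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    base = n_t * n_c / (n_t + n_c)
    if variant == "harmonic":
        return base
    if variant == "hedges":
        return 4.0 * base
    raise ValueError(f"unknown effective-n variant {variant!r}")


def egger_effective_n(ds: Dataset, spec: Optional[ModelSpec] = None,
                      variant: str = "harmonic",
                      ci_level: float = 0.95) -> pd.DataFrame:
    """Egger-type small-study regression with sqrt(1/ñ) as the moderator.

    Run on the lnRR analysis (mean effects); a slope CI excluding zero
    signals funnel asymmetry consistent with publication bias.
    """
    spec = spec or ModelSpec(response_type="lnRR")
    f = ds.frame
    if f[["n_t", "n_c"]].isna().any().any():
        raise ValueError("arm sample sizes are required for the Egger test")
    ntilde = effective_n(f["n_t"], f["n_c"], variant=variant)
    return _covariate_fit(ds, spec, np.sqrt(1.0 / ntilde), "sqrt_inv_n", ci_level)
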