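"""The full model suite: null, moderator, covariate and arm-based analyses.

Model names follow the suite layout: CVR* are contrast-based lnCVR models,
SD* are arm-based ln(SD) models, RR*/VR0 are lnRR/lnVR models. Contrast
models use the shared-control sampling VCV; arm-based models use a diagonal
sampling variance with cluster-robust (CR2) inference clustered on the
experimental comparison. Every model is fitted by ML (for likelihood-ratio
moderator tests) and re-fitted by REML (for the reported estimates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import effects, heterogeneity, model
from .data import Dataset


# ---------------------------------------------------------------------------
# covariates and scale conversions

def z_standardise(ds: Dataset, arm: str = "treatment") -> pd.Series:
    """Z-score arm mean yields within crop x response_measure x scale groups.

    Groups with fewer than 2 members (or zero spread) give NaN; models using
    the covariate drop those rows. The group SD uses the n-1 denominator.
    """
    col = {"treatment": "mean_t", "control": "mean_c"}[arm]
    f = ds.frame
    x = f[col].astype(float)
    out = pd.Series(np.nan, index=f.index, name=f"z_{arm}")
    for _, idx in f.groupby(["crop", "response_measure", "scale"]).groups.items():
        vals = x.loc[idx]
        if len(vals) < 2:
            continue
        sd = vals.std(ddof=1)
        if not sd > 0:
            continue
        out.loc[idx] = (vals - vals.mean()) / sd
    return out


def percent_change(estimate: float, mode: str) -> float:
    """Convert a log-ratio to the percent scale.

    ``stability`` (negative log-ratio means more stable): (1 - exp(b)) * 100.
    ``yield`` / ``variance``: (exp(b) - 1) * 100.
    """
    if mode == "stability":
        return float((1.0 - np.exp(estimate)) * 100.0)
    if mode in {"yield", "variance"}:
        return float((np.exp(estimate) - 1.0) * 100.0)
    raise ValueError(f"unknown percent mode {mode!r}")


_PERCENT_MODE = {"lnCVR": "stability", "lnSD": "stability",
                 "lnRR": "yield", "lnVR": "variance"}


# ---------------------------------------------------------------------------
# model containers

@dataclass
class ModelResult:
    name: str
    response: str
    fit_reml: Optional[model.ModelFit] = None
    fit_ml: Optional[model.ModelFit] = None
    wald: Optional[pd.DataFrame] = None
    het: Optional[heterogeneity.HeterogeneityStats] = None
    percent: Optional[pd.DataFrame] = None
    prediction_intervals: Optional[dict] = None
    robust: bool = False
    skipped: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        if self.skipped is not None:
            return {"name": self.name, "skipped": self.skipped}
        d = {
            "name": self.name,
            "response": self.response,
            "reml": self.fit_reml.to_dict(),
            "ml_log_likelihood": float(self.fit_ml.log_likelihood),
            "wald": {str(k): {c: float(v) for c, v in row.items()}
                     for k, row in self.wald.to_dict("index").items()},
            "robust": self.robust,
        }
        if self.het is not None:
            d["heterogeneity"] = self.het.to_dict()
        if self.percent is not None:
            d["percent"] = {str(k): {c: float(v) for c, v in row.items()}
                            for k, row in self.percent.to_dict("index").items()}
        if self.prediction_intervals is not None:
            d["prediction_intervals"] = {
                k: [float(a), float(b)] for k, (a, b) in self.prediction_intervals.items()}
        d.update({k: v for k, v in self.extra.items()})
        return d


@dataclass
class SuiteConfig:
    models: Sequence[str] = ("CVR0", "SD0", "RR0", "VR0", "CVR1", "SD1",
                             "CVR2", "SD2", "CVR3", "CVR4", "RR1",
                             "CVR5", "CVR6", "CVR7")
    ci_level: float = 0.95
    lncvr_variance_mean_terms: bool = True
    merge_plot_cohort: bool = True  # plot and cohort are one scale level
    seed: int = 0

    ALL = ("CVR0", "SD0", "RR0", "VR0", "CVR1", "SD1", "CVR2", "SD2",
           "CVR3", "CVR4", "RR1", "CVR5", "CVR6", "CVR7")


@dataclass
class SuiteResult:
    results: dict
    lrt_table: pd.DataFrame
    config: SuiteConfig
    counts: dict

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "models": {k: v.to_dict() for k, v in sorted(self.results.items())},
            "lrt": {f"{r.model} vs {r.null}": {"statistic": float(r.statistic),
                                               "df": int(r.df), "p": float(r.p)}
                    for r in self.lrt_table.itertuples(index=False)},
            "ci_level": self.config.ci_level,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# fitting helpers

def _levels_for(f: pd.DataFrame) -> dict:
    """Nested random levels with compound comparison keys."""
    return {
        "publication_id": f["publication_id"].astype(str).to_numpy(),
        "comparison_id": (f["publication_id"].astype(str) + ":"
                          + f["comparison_id"].astype(str)).to_numpy(),
        "effect_id": f["effect_id"].astype(str).to_numpy(),
    }


def _contrast_inputs(ds: Dataset, response: str, cfg: SuiteConfig):
    kw = {}
    if response == "lnCVR":
        kw["variance_mean_terms"] = cfg.lncvr_variance_mean_terms
    tab, S = effects.vcv_from_dataset(ds, response, **kw)
    y = tab["estimate"].to_numpy()
    return y, S, _levels_for(ds.frame), tab


def _fit_both(y, X, S, levels, ci_level, cluster=None):
    """REML fit for reported estimates, ML for likelihood comparisons."""
    f_reml = model.fit(y, X, S, levels, method="REML")
    f_ml = model.fit(y, X, S, levels, method="ML")
    if cluster is not None:
        wald = model.robust_wald_summary(f_reml, cluster, level=ci_level)
    else:
        wald = model.wald_summary(f_reml, level=ci_level)
    return f_reml, f_ml, wald


def _percent_table(wald: pd.DataFrame, mode: str, rows=None) -> pd.DataFrame:
    rows = list(wald.index) if rows is None else rows
    out = {}
    for name in rows:
        est = percent_change(wald.loc[name, "estimate"], mode)
        lo = percent_change(wald.loc[name, "ci_low"], mode)
        hi = percent_change(wald.loc[name, "ci_high"], mode)
        if mode == "stability":  # negative log-ratio maps to the upper percent
            lo, hi = hi, lo
        out[name] = {"estimate": est, "ci_low": min(lo, hi), "ci_high": max(lo, hi)}
    return pd.DataFrame(out).T


def _cellmeans(f: pd.DataFrame, col: str, prefix: str | None = None) -> pd.DataFrame:
    d = pd.get_dummies(f[col].astype(str), dtype=float)
    d.columns = [f"{prefix or col}:{c}" for c in d.columns]
    return d.reset_index(drop=True)


def _reference(f: pd.DataFrame, col: str) -> pd.DataFrame:
    d = pd.get_dummies(f[col].astype(str), dtype=float, drop_first=True)
    d.columns = [f"{col}[{c}]" for c in d.columns]
    X = pd.concat([pd.Series(1.0, index=d.index, name="intercept"),
                   d.reset_index(drop=True)], axis=1)
    return X


def _scale_column(ds: Dataset, cfg: SuiteConfig) -> pd.Series:
    s = ds.frame["scale"].astype(str)
    if not cfg.merge_plot_cohort:
        return s
    return s.replace({"plot": "plot_or_cohort", "cohort": "plot_or_cohort"})


# ---------------------------------------------------------------------------
# the suite

def run_suite(ds: Dataset, cfg: Optional[SuiteConfig] = None) -> SuiteResult:
    """Run the configured model suite and collect results and LRTs."""
    cfg = cfg or SuiteConfig()
    results: dict[str, ModelResult] = {}
    lrt_rows = []
    ci = cfg.ci_level
    f = ds.frame

    def categorical_contrast(name, response, col_series, label):
        """Contrast-based model with a categorical moderator in cell-means
        coding (reported) plus its reference-coded ML twin (for the LRT)."""
        y, S, levels, _ = _contrast_inputs(ds, response, cfg)
        frame = f.assign(_mod=col_series.to_numpy())
        Xcm = _cellmeans(frame, "_mod", prefix=label)
        fr, fm, wald = _fit_both(y, Xcm, S, levels, ci)
        Xref = _reference(frame, "_mod")
        fm_ref = model.fit(y, Xref, S, levels, method="ML")
        typical = heterogeneity.typical_sampling_variance(np.diag(S))
        het = heterogeneity.i_squared(fr, typical)
        het = heterogeneity.HeterogeneityStats(
            typical_v=het.typical_v, i2_by_level=het.i2_by_level,
            i2_total=het.i2_total, r2_marginal=heterogeneity.r2_marginal(fr))
        res = ModelResult(
            name=name, response=response, fit_reml=fr, fit_ml=fm, wald=wald,
            het=het,
            percent=_percent_table(wald, _PERCENT_MODE[response]),
            prediction_intervals={c: model.prediction_interval(fr, c, ci)
                                  for c in wald.index},
            extra={"ml_log_likelihood_reference_coding": float(fm_ref.log_likelihood)},
        )
        results[name] = res
        return res

    def null_contrast(name, response):
        y, S, levels, _ = _contrast_inputs(ds, response, cfg)
        X = pd.DataFrame({"intercept": np.ones(len(y))})
        fr, fm, wald = _fit_both(y, X, S, levels, ci)
        typical = heterogeneity.typical_sampling_variance(np.diag(S))
        res = ModelResult(
            name=name, response=response, fit_reml=fr, fit_ml=fm, wald=wald,
            het=heterogeneity.i_squared(fr, typical),
            percent=_percent_table(wald, _PERCENT_MODE[response]),
            prediction_intervals={"intercept": model.prediction_interval(fr, "intercept", ci)},
        )
        results[name] = res
        return res

    def covariate_contrast(name, response, covariate, cov_name, subset_mask=None):
        sub = ds if subset_mask is None else ds.subset(subset_mask)
        cov = covariate if subset_mask is None else covariate[subset_mask.to_numpy()]
        y, S, levels, _ = _contrast_inputs(sub, response, cfg)
        X = pd.DataFrame({"intercept": np.ones(len(y)), cov_name: np.asarray(cov, float)})
        fr, fm, wald = _fit_both(y, X, S, levels, ci)
        typical = heterogeneity.typical_sampling_variance(np.diag(S))
        het = heterogeneity.i_squared(fr, typical)
        het = heterogeneity.HeterogeneityStats(
            typical_v=het.typical_v, i2_by_level=het.i2_by_level,
            i2_total=het.i2_total, r2_marginal=heterogeneity.r2_marginal(fr))
        res = ModelResult(name=name, response=response, fit_reml=fr, fit_ml=fm,
                          wald=wald, het=het,
                          extra={"n_effects": int(len(y)),
                                 "counts": sub.counts()})
        results[name] = res
        return res

    def arm_based(name, by: str | None):
        """Arm-based ln(SD) model; ``by`` adds per-level condition effects."""
        arms = effects.make_arm_rows(ds)
        if by is not None:
            key = {"crop": f["crop"].astype(str),
                   "scale": _scale_column(ds, cfg)}[by]
            lut = dict(zip(f["effect_id"].astype(str), key))
            # control arms take the level of the first row using them
            ctl_lut = {}
            for eid, scid, lev in zip(f["effect_id"].astype(str),
                                      f["shared_control_id"].astype(str), key):
                ctl_lut.setdefault(f"c:{scid}", lev)
            lev = arms["arm_id"].map(lambda a: lut.get(a[2:], ctl_lut.get(a)) if a.startswith("t:")
                                     else ctl_lut[a])
            groups = _cellmeans(arms.assign(_lev=lev.to_numpy()), "_lev", prefix=by)
            cond = (arms["condition"] == "treated").astype(float)
            X = pd.concat(
                [groups] + [ (groups[c] * cond).rename(f"treated|{c}")
                             for c in groups.columns ], axis=1)
            X["ln_mean"] = arms["ln_mean"].to_numpy()
            cond_cols = [c for c in X.columns if c.startswith("treated|")]
        else:
            X = pd.DataFrame({
                "intercept": np.ones(len(arms)),
                "treated": (arms["condition"] == "treated").astype(float),
                "ln_mean": arms["ln_mean"].to_numpy(),
            })
            cond_cols = ["treated"]
        y = arms["ln_sd"].to_numpy()
        S = np.diag(arms["sampling_variance"].to_numpy())
        levels = {
            "publication_id": arms["publication_id"].to_numpy(),
            "comparison_id": arms["comparison_id"].to_numpy(),
            "effect_id": arms["arm_id"].to_numpy(),
        }
        cluster = arms["comparison_id"].to_numpy()
        fr, fm, wald = _fit_both(y, X, S, levels, ci, cluster=cluster)
        res = ModelResult(
            name=name, response="lnSD", fit_reml=fr, fit_ml=fm, wald=wald,
            percent=_percent_table(wald, "stability", rows=cond_cols),
            robust=True,
            extra={"condition_coefficients": cond_cols},
        )
        results[name] = res
        return res

    wanted = list(cfg.models)

    def want(name):
        return name in wanted

    missing_cols = [c for c in ("crop", "scale", "treatment_type", "intensity", "year")
                    if c not in f.columns]

    # --- null models
    if want("CVR0"):
        null_contrast("CVR0", "lnCVR")
    if want("RR0"):
        null_contrast("RR0", "lnRR")
    if want("VR0"):
        null_contrast("VR0", "lnVR")
    if want("SD0"):
        arm_based("SD0", by=None)

    # --- categorical moderators
    if want("CVR1"):
        categorical_contrast("CVR1", "lnCVR", f["crop"].astype(str), "crop")
    if want("SD1"):
        arm_based("SD1", by="crop")
    if want("CVR2"):
        categorical_contrast("CVR2", "lnCVR", _scale_column(ds, cfg), "scale")
    if want("SD2"):
        arm_based("SD2", by="scale")
    if want("CVR5"):
        categorical_contrast("CVR5", "lnCVR", f["treatment_type"].astype(str), "pollinator")
    if want("CVR6"):
        open_vs = f["treatment_type"].astype(str).map(
            lambda t: "open" if t == "open" else "other")
        categorical_contrast("CVR6", "lnCVR", open_vs, "pollinator2")

    # --- covariate models (covariates treated as fixed and error-free)
    if want("CVR3"):
        lnrr = effects.effect_table(ds, "lnRR")["estimate"].to_numpy()
        covariate_contrast("CVR3", "lnCVR", lnrr, "lnRR")
    if want("CVR4"):
        z_t = z_standardise(ds, "treatment")
        mask = z_t.notna()
        covariate_contrast("CVR4", "lnCVR", z_t.to_numpy(), "z_yield_treated",
                           subset_mask=mask)
    if want("RR1"):
        z_c = z_standardise(ds, "control")
        mask = z_c.notna()
        covariate_contrast("RR1", "lnRR", z_c.to_numpy(), "z_yield_control",
                           subset_mask=mask)

    # --- intensity subset
    if want("CVR7"):
        mask = f["intensity"].astype(str).isin(["high", "low"])
        if mask.sum() < 4 or f.loc[mask, "intensity"].nunique() < 2:
            results["CVR7"] = ModelResult(
                name="CVR7", response="lnCVR",
                skipped="no two-level pollination-intensity subset in this dataset")
        else:
            sub = ds.subset(mask)
            y, S, levels, _ = _contrast_inputs(sub, "lnCVR", cfg)
            Xcm = _cellmeans(sub.frame, "intensity", prefix="intensity")
            fr, fm, wald = _fit_both(y, Xcm, S, levels, ci)
            Xnull = pd.DataFrame({"intercept": np.ones(len(y))})
            fm_null = model.fit(y, Xnull, S, levels, method="ML")
            results["CVR7"] = ModelResult(
                name="CVR7", response="lnCVR", fit_reml=fr, fit_ml=fm, wald=wald,
                percent=_percent_table(wald, "stability"),
                extra={"counts": sub.counts(),
                       "null_ml_log_likelihood": float(fm_null.log_likelihood)},
            )
            stat, df, p = model.lrt(fm_null, fm)
            lrt_rows.append({"model": "CVR7", "null": "CVR7-null(subset)",
                             "statistic": stat, "df": df, "p": p})

    for name in wanted:
        if name not in results:
            reason = ("unknown model name" if name not in SuiteConfig.ALL
                      else f"missing moderator columns: {missing_cols}")
            results[name] = ModelResult(name=name, response="", skipped=reason)

    # --- moderator LRTs against the lnCVR null
    def add_lrt(alt, null):
        if alt in results and null in results and results[alt].skipped is None \
                and results[null].skipped is None:
            stat, df, p = model.lrt(results[null].fit_ml, results[alt].fit_ml)
            lrt_rows.append({"model": alt, "null": null,
                             "statistic": stat, "df": df, "p": p})

    add_lrt("CVR1", "CVR0")
    add_lrt("CVR2", "CVR0")
    add_lrt("CVR5", "CVR0")
    add_lrt("CVR6", "CVR0")
    if all(m in results and results[m].skipped is None for m in ("CVR5", "CVR6")):
        stat, df, p = model.lrt(results["CVR6"].fit_ml, results["CVR5"].fit_ml)
        lrt_rows.append({"model": "CVR5", "null": "CVR6",
                         "statistic": stat, "df": df, "p": p})

    lrt_table = pd.DataFrame(lrt_rows, columns=["model", "null", "statistic", "df", "p"])
    return SuiteResult(results=results, lrt_table=lrt_table, config=cfg,
                       counts=ds.counts())


def covariate_regression(ds: Dataset, response_type: str, covariate,
                         cov_name: str = "covariate",
                         ci_level: float = 0.95) -> pd.DataFrame:
    """Multilevel model of a contrast effect size on one error-free covariate.

    Returns the Wald summary; the ``cov_name`` row is the slope of interest.
    """
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(ds):
        raise ValueError("covariate length does not match the dataset")
    cfg = SuiteConfig()
    y, S, levels, _ = _contrast_inputs(ds, response_type, cfg)
    X = pd.DataFrame({"intercept": np.ones(len(y)), cov_name: cov})
    fr = model.fit(y, X, S, levels, method="REML")
    return model.wald_summary(fr, level=ci_level)


# ---------------------------------------------------------------------------
# plot-data exports

def figure_level_data(res: ModelResult) -> pd.DataFrame:
    """Point, CI and PI per coefficient level (forest-style plot data)."""
    if res.skipped is not None:
        raise ValueError(f"model {res.name} was skipped: {res.skipped}")
    rows = []
    for name in res.wald.index:
        row = {"level": name,
               "estimate": float(res.wald.loc[name, "estimate"]),
               "ci_low": float(res.wald.loc[name, "ci_low"]),
               "ci_high": float(res.wald.loc[name, "ci_high"])}
        if res.prediction_intervals and name in res.prediction_intervals:
            row["pi_low"], row["pi_high"] = map(float, res.prediction_intervals[name])
        rows.append(row)
    return pd.DataFrame(rows)


def figure_scatter_data(ds: Dataset, response_type: str, covariate,
                        cov_name: str = "covariate") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter of effect sizes against a covariate plus the fitted line."""
    tab = effects.effect_table(ds, response_type)
    cov = np.asarray(covariate, dtype=float)
    scatter = pd.DataFrame({cov_name: cov, response_type: tab["estimate"].to_numpy()})
    wald = covariate_regression(ds, response_type, cov, cov_name=cov_name)
    grid = np.linspace(np.nanmin(cov), np.nanmax(cov), 50)
    line = pd.DataFrame({
        cov_name: grid,
        "fitted": wald.loc["intercept", "estimate"] + wald.loc[cov_name, "estimate"] * grid,
    })
    return scatter, line
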