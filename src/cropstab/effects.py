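"""Ratio effect sizes for meta-analysis of yield means and variability.

Implements the small-sample bias-corrected log response ratio (lnRR), log
variability ratio (lnVR) and log coefficient-of-variation ratio (lnCVR),
their sampling variances, arm-level ln(SD) rows for arm-based modelling, and
the block sampling variance-covariance matrix induced by comparisons that
share a control group.

Notation: each arm has sample mean x̄, sample SD s and n experimental units;
CV = s / x̄. The delta-method variance of ln(x̄) is s²/(n x̄²) = CV²/n and the
(approximate) variance of ln(s) is 1/(2(n-1)); the small-sample corrections
added to the point estimates are half of (for means) or exactly (for log
SDs) these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ArmSummary, Dataset

EFFECT_TYPES = ("lnRR", "lnVR", "lnCVR")


@dataclass(frozen=True)
class EffectSize:
    effect_id: str
    type: str
    estimate: float
    sampling_variance: float
    shared_control_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate):
            raise ValueError(f"{self.effect_id}: non-finite estimate")
        if not self.sampling_variance > 0:
            raise ValueError(f"{self.effect_id}: sampling variance must be > 0")


@dataclass(frozen=True)
class ArmRow:
    """One experimental arm as a row for arm-based ln(SD) modelling."""

    arm_id: str
    condition: str  # "treated" or "control"
    ln_sd: float
    ln_mean: float
    sampling_variance: float
    publication_id: str
    comparison_id: str


def _check_ratio_arms(t: ArmSummary, c: ArmSummary, need_sd: bool) -> None:
    for label, a in (("treatment", t), ("control", c)):
        if a.mean <= 0:
            raise ValueError(f"{label} arm mean must be > 0 for ratio effect sizes")
        if a.n < 2:
            raise ValueError(f"{label} arm needs n >= 2")
        if need_sd and a.sd <= 0:
            raise ValueError(f"{label} arm sd must be > 0 (log of zero SD undefined)")


def compute_lnrr(t: ArmSummary, c: ArmSummary, effect_id: str = "",
                 shared_control_id: str = "") -> EffectSize:
    """Bias-corrected log response ratio ln(x̄_T / x̄_C).

    estimate = ln(x̄_T/x̄_C) + ½[CV_T²/n_T − CV_C²/n_C]
    variance = CV_T²/n_T + CV_C²/n_C
    """
    _check_ratio_arms(t, c, need_sd=False)
    mt, mc = t.cv**2 / t.n, c.cv**2 / c.n
    est = np.log(t.mean / c.mean) + 0.5 * (mt - mc)
    var = mt + mc
    if var <= 0:  # both SDs zero: no information about the mean's error
        raise ValueError("lnRR sampling variance is zero (both arm SDs are 0)")
    return EffectSize(effect_id, "lnRR", float(est), float(var), shared_control_id)


def compute_lnvr(t: ArmSummary, c: ArmSummary, effect_id: str = "",
                 shared_control_id: str = "") -> EffectSize:
    """Bias-corrected log variability (SD) ratio ln(s_T / s_C).

    estimate = ln(s_T/s_C) + 1/(2(n_T−1)) − 1/(2(n_C−1))
    variance = 1/(2(n_T−1)) + 1/(2(n_C−1))
    """
    _check_ratio_arms(t, c, need_sd=True)
    vt, vc = 1.0 / (2 * (t.n - 1)), 1.0 / (2 * (c.n - 1))
    est = np.log(t.sd / c.sd) + vt - vc
    return EffectSize(effect_id, "lnVR", float(est), float(vt + vc), shared_control_id)


def compute_lncvr(t: ArmSummary, c: ArmSummary, effect_id: str = "",
                  shared_control_id: str = "",
                  variance_mean_terms: bool = True,
                  mean_sd_correlation: float = 0.0) -> EffectSize:
    """Bias-corrected log coefficient-of-variation ratio ln(CV_T / CV_C).

    estimate = ln(CV_T/CV_C) + [1/(2(n_T−1)) − 1/(2(n_C−1))] − ½[CV_T²/n_T − CV_C²/n_C]
    variance = CV_T²/n_T + 1/(2(n_T−1)) + CV_C²/n_C + 1/(2(n_C−1))

    ``mean_sd_correlation`` (ρ) optionally adds the mean-variance correlation
    term of the full estimator, −2ρ·[CV_T/√(n_T) ... ], which needs a
    within-arm correlation the usual summary data do not report; it defaults
    to zero. ``variance_mean_terms=False`` drops the CV²/n terms from the
    sampling variance, leaving the pure log-SD-ratio variance — the weighting
    under which the contrast-based lnCVR model and the arm-based ln(SD) model
    are exactly equivalent.
    """
    _check_ratio_arms(t, c, need_sd=True)
    cvt, cvc = t.cv, c.cv
    vt, vc = 1.0 / (2 * (t.n - 1)), 1.0 / (2 * (c.n - 1))
    mt, mc = cvt**2 / t.n, cvc**2 / c.n
    est = np.log(cvt / cvc) + (vt - vc) - 0.5 * (mt - mc)
    var = vt + vc
    if variance_mean_terms:
        var = var + mt + mc
    if mean_sd_correlation:
        # full estimator's mean-variance correlation term; with arm summaries
        # only, approximated symmetrically as 2ρ(√(m_T v_T) + √(m_C v_C))
        var = vt + vc + mt + mc - 2.0 * mean_sd_correlation * (
            np.sqrt(mt * vt) + np.sqrt(mc * vc)
        )
    return EffectSize(effect_id, "lnCVR", float(est), float(var), shared_control_id)


_COMPUTE = {"lnRR": compute_lnrr, "lnVR": compute_lnvr, "lnCVR": compute_lncvr}


def compute_effect(type: str, t: ArmSummary, c: ArmSummary, **kw) -> EffectSize:
    return _COMPUTE[type](t, c, **kw)


def effect_table(ds: Dataset, type: str, **kw) -> pd.DataFrame:
    """Compute one effect size per dataset row.

    Returns a DataFrame indexed like the dataset with columns effect_id,
    type, estimate, sampling_variance, shared_control_id.
    """
    if type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {type!r}; expected one of {EFFECT_TYPES}")
    rows = []
    for rec in ds.records():
        es = compute_effect(type, rec.treatment, rec.control,
                            effect_id=rec.effect_id,
                            shared_control_id=rec.shared_control_id, **kw)
        rows.append({
            "effect_id": es.effect_id, "type": es.type,
            "estimate": es.estimate, "sampling_variance": es.sampling_variance,
            "shared_control_id": es.shared_control_id,
        })
    return pd.DataFrame(rows)


def make_arm_rows(ds: Dataset, bias_correct_log_mean: bool = False) -> pd.DataFrame:
    """Arm-level rows for the arm-based ln(SD) analysis.

    Each dataset row contributes its treatment arm; each distinct control
    group (by shared_control_id) contributes exactly one control row, so a
    control shared by several treatments is not duplicated.

    ln_sd = ln(s) + 1/(2(n−1))  (bias-corrected log SD)
    ln_mean = ln(x̄), or ln(x̄) + CV²/(2n) when ``bias_correct_log_mean`` —
    the correction that makes the treated-minus-control contrast of
    (ln_sd − ln_mean) reproduce the bias-corrected lnCVR exactly.
    sampling_variance = 1/(2(n−1))
    """
    rows = []
    seen_controls: set[str] = set()
    for rec in ds.records():
        for cond, arm, arm_id in (
            ("treated", rec.treatment, f"t:{rec.effect_id}"),
            ("control", rec.control, f"c:{rec.shared_control_id}"),
        ):
            if cond == "control":
                if rec.shared_control_id in seen_controls:
                    continue
                seen_controls.add(rec.shared_control_id)
            if arm.sd <= 0 or arm.mean <= 0 or arm.n < 2:
                raise ValueError(
                    f"arm {arm_id}: needs sd > 0, mean > 0 and n >= 2 for ln(SD) rows"
                )
            v = 1.0 / (2 * (arm.n - 1))
            ln_mean = np.log(arm.mean)
            if bias_correct_log_mean:
                ln_mean += arm.cv**2 / (2 * arm.n)
            rows.append({
                "arm_id": arm_id, "condition": cond,
                "ln_sd": float(np.log(arm.sd) + v), "ln_mean": float(ln_mean),
                "sampling_variance": v,
                "publication_id": rec.publication_id,
                "comparison_id": f"{rec.publication_id}:{rec.comparison_id}",
            })
    df = pd.DataFrame(rows)
    if df["arm_id"].duplicated().any():
        raise ValueError("duplicate arm rows produced; effect_ids are not unique")
    return df


def shared_control_covariance(a: EffectSize, b: EffectSize, c: ArmSummary) -> float:
    """Sampling covariance of two effect sizes sharing a control arm.

    The shared control contributes its full sampling-variance component to
    the covariance: CV_C²/n_C for lnRR, 1/(2(n_C−1)) for lnVR, and their sum
    for lnCVR.
    """
    if a.type != b.type:
        raise ValueError(f"cannot mix effect types {a.type} and {b.type}")
    if a.shared_control_id != b.shared_control_id:
        raise ValueError("effects do not share a control group")
    mean_term = c.cv**2 / c.n
    sd_term = 1.0 / (2 * (c.n - 1))
    if a.type == "lnRR":
        return float(mean_term)
    if a.type == "lnVR":
        return float(sd_term)
    return float(mean_term + sd_term)


def build_vcv(effects: Sequence[EffectSize],
              controls: Mapping[str, ArmSummary],
              repair_tol: float = 1e-10) -> np.ndarray:
    """Assemble the block sampling variance-covariance matrix.

    Diagonal holds each effect's sampling variance; off-diagonals within a
    shared-control block hold :func:`shared_control_covariance`; all other
    entries are zero. Symmetry holds by construction; positive
    semi-definiteness is verified via the smallest eigenvalue, and tiny
    rounding deficits (within ``repair_tol`` of the largest eigenvalue) are
    repaired by inflating the diagonal.
    """
    k = len(effects)
    V = np.zeros((k, k))
    if k == 0:
        return V
    types = {e.type for e in effects}
    if len(types) > 1:
        raise ValueError(f"cannot mix effect types in one VCV: {sorted(types)}")
    for i, e in enumerate(effects):
        V[i, i] = e.sampling_variance
    by_control: dict[str, list[int]] = {}
    for i, e in enumerate(effects):
        by_control.setdefault(e.shared_control_id, []).append(i)
    for scid, idx in by_control.items():
        if len(idx) < 2:
            continue
        c = controls[scid]
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                cov = shared_control_covariance(effects[i], effects[j], c)
                V[i, j] = V[j, i] = cov
    eig = np.linalg.eigvalsh(V)
    lo, hi = eig[0], eig[-1]
    if lo < -repair_tol * max(hi, 1.0):
        # identify an offending block for the error message
        for scid, idx in by_control.items():
            if len(idx) > 1 and np.linalg.eigvalsh(V[np.ix_(idx, idx)])[0] < -repair_tol * max(hi, 1.0):
                raise ValueError(f"sampling VCV block for shared control {scid!r} is not PSD")
        raise ValueError("assembled sampling VCV is not positive semi-definite")
    if lo < 0:
        V[np.diag_indices(k)] += -lo
    return V


def vcv_from_dataset(ds: Dataset, type: str, **effect_kw) -> tuple[pd.DataFrame, np.ndarray]:
    """Convenience: effect table plus its sampling VCV, in dataset row order."""
    tab = effect_table(ds, type, **effect_kw)
    effs = [
        EffectSize(r.effect_id, r.type, r.estimate, r.sampling_variance, r.shared_control_id)
        for r in tab.itertuples(index=False)
    ]
    V = build_vcv(effs, ds.control_map())
    return tab, V


def write_effect_table(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, index=False)


def write_vcv(V: np.ndarray, effect_ids: Iterable[str], path_mtx, path_index) -> None:
    """Write a sampling VCV as coordinate-sparse MTX plus an effect-id index."""
    scipy.io.mmwrite(str(path_mtx), scipy.sparse.coo_matrix(V))
    with open(path_index, "w", encoding="utf-8") as fh:
        for eid in effect_ids:
            fh.write(f"{eid}\n")
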