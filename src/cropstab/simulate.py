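"""Synthetic pollination-exclusion datasets.

Two generators:

* :func:`generate_summary_dataset` — a model-faithful simulator. Each effect
  row gets a true log-ratio (lnRR for means, lnCVR for coefficients of
  variation) built from a grand mean plus independent normal deviates at the
  publication, comparison and effect-size levels. Control-arm experimental
  units are drawn from a lognormal with a configured mean and CV; the
  treatment arm's lognormal realises the row's true ratios exactly at the
  distribution level, so sampling noise enters only through the finite
  number of units per arm. Several treatment arms can share one control
  draw, reproducing the shared-control sampling correlation.

* :func:`generate_ceiling_dataset` — a mechanistic resource-ceiling
  simulator. Unit yield is the minimum of a pre-ceiling yield and a
  unit-specific maximum potential yield; animal pollination multiplies the
  pre-ceiling yield. As the gain pushes yields into the ceiling, treated
  units cluster below it, compressing their relative variation — the
  mechanism that produces a negative association between lnCVR and lnRR.

Yields are lognormal throughout: yield responses are positive and
right-skewed, and multiplicative noise reproduces the strong mean-variance
relationship seen in pollination experiments.

Seeding: one master seed; every publication / comparison / arm derives its
own deterministic substream, so changing one count never reshuffles
previously generated rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import COLUMNS, Dataset, write_dataset

_CROPS = ("apple", "oilseed_rape", "faba_bean")
_CROP_P = (0.25, 0.42, 0.33)
_SCALES = ("flower", "plant", "plot_or_cohort", "site")
_SCALE_P = (0.04, 0.30, 0.38, 0.28)
_TREATMENTS = ("hand", "honeybee", "bumblebee", "hoverfly", "solitary", "open")
_MEASURES = {
    "apple": ["fruit_set", "seeds_per_fruit"],
    "oilseed_rape": ["yield_mass", "seed_number", "pod_number"],
    "faba_bean": ["yield_mass", "seed_number", "pod_number", "seeds_per_fruit"],
}
_MEASURE_SCALE = {"yield_mass": 1.0, "seed_number": 20.0, "pod_number": 5.0,
                  "fruit_set": 0.5, "seeds_per_fruit": 0.3}


@dataclass
class GeneratorConfig:
    """Configuration of the summary-level generator.

    Defaults emulate the structure of the pollination-stability evidence
    base: 47 publications with 3-6 experimental comparisons each and 1-4
    effect sizes (response measures) per comparison (~500 effects in
    total), two treatment arms per control group, a true stability ratio
    of lnCVR = ln(0.68) ≈ -0.386 and a true yield benefit of
    lnRR = ln(2.04) ≈ 0.713, with modest multilevel heterogeneity.
    """

    n_publications: int = 47
    comparisons_per_publication: tuple = (3, 6)
    effects_per_comparison: tuple = (1, 4)
    treatments_per_control: int = 2
    true_mu: dict = field(default_factory=lambda: {"lnCVR": -0.3857, "lnRR": 0.7129})
    sigma2: dict = field(default_factory=lambda: {
        "publication": 0.05, "comparison": 0.02, "effect": 0.01})
    sigma2_lnrr: dict = field(default_factory=lambda: {
        "publication": 0.20, "comparison": 0.05, "effect": 0.02})
    unit_n_range: tuple = (8, 40)
    control_cv: float = 0.3
    control_mean_median: float = 100.0
    control_mean_log_sd: float = 1.0
    crop_effects: Optional[dict] = None  # additive shift of true lnCVR per crop
    #: regression of true lnCVR deviations on true lnRR deviations, emulating
    #: the negative stability-benefit association of the evidence base
    lnrr_coupling: float = -0.28
    intensity_study_prob: float = 0.23
    seed: int = 0

    def validate(self) -> None:
        if self.n_publications < 1 or self.treatments_per_control < 1:
            raise ValueError("counts must be >= 1")
        for rng_ in (self.comparisons_per_publication, self.effects_per_comparison):
            if len(rng_) != 2 or rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid count range {rng_}")
        if self.unit_n_range[0] < 2:
            raise ValueError("unit_n_range minimum must be >= 2")
        if any(v < 0 for v in self.sigma2.values()) or any(v < 0 for v in self.sigma2_lnrr.values()):
            raise ValueError("sigma2 values must be >= 0")
        if not self.control_cv > 0:
            raise ValueError("control_cv must be > 0")


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _lognormal_units(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Draw n lognormal units with the given arithmetic mean and CV."""
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), size=n)


def generate_summary_dataset(cfg: GeneratorConfig) -> Dataset:
    """Generate a dataset of arm summaries with known true effects."""
    cfg.validate()
    seed = int(cfg.seed)
    rows = []
    for p in range(cfg.n_publications):
        pub = f"P{p + 1:03d}"
        prng = _rng(seed, 1, p)
        crop = str(prng.choice(_CROPS, p=_CROP_P))
        scale = str(prng.choice(_SCALES, p=_SCALE_P))
        country = f"country_{prng.integers(1, 21)}"
        year = int(prng.integers(1950, 2021))
        intensity_study = bool(prng.random() < cfg.intensity_study_prob)
        n_comp = int(prng.integers(cfg.comparisons_per_publication[0],
                                   cfg.comparisons_per_publication[1] + 1))
        b_pub = prng.normal(0.0, np.sqrt(cfg.sigma2["publication"]))
        b_pub_rr = prng.normal(0.0, np.sqrt(cfg.sigma2_lnrr["publication"]))
        measures = _MEASURES[crop]
        mu_cvr = cfg.true_mu["lnCVR"] + (cfg.crop_effects or {}).get(crop, 0.0)
        mu_rr = cfg.true_mu["lnRR"]

        # cache of shared control draws: (group, measure slot) -> summary
        controls: dict = {}
        for j in range(n_comp):
            comp = f"{pub}_c{j + 1}"
            group = j // cfg.treatments_per_control
            crng = _rng(seed, 2, p, j)
            b_comp = crng.normal(0.0, np.sqrt(cfg.sigma2["comparison"]))
            b_comp_rr = crng.normal(0.0, np.sqrt(cfg.sigma2_lnrr["comparison"]))
            treatment_type = str(crng.choice(_TREATMENTS))
            intensity = ("high" if j % 2 == 0 else "low") if intensity_study else "none"
            n_eff = int(crng.integers(cfg.effects_per_comparison[0],
                                      cfg.effects_per_comparison[1] + 1))
            for e in range(n_eff):
                slot = e % len(measures)
                measure = measures[slot]
                key = (group, slot)
                if key not in controls:
                    grng = _rng(seed, 3, p, group, slot)
                    m_c = (cfg.control_mean_median
                           * float(np.exp(grng.normal(0.0, cfg.control_mean_log_sd)))
                           * _MEASURE_SCALE[measure])
                    n_c = int(grng.integers(cfg.unit_n_range[0], cfg.unit_n_range[1] + 1))
                    units_c = _lognormal_units(grng, m_c, cfg.control_cv, n_c)
                    controls[key] = {
                        "true_mean": m_c,
                        "mean": float(np.mean(units_c)),
                        "sd": float(np.std(units_c, ddof=1)),
                        "n": n_c,
                        "id": f"{pub}_g{group + 1}_m{slot + 1}",
                    }
                ctl = controls[key]
                erng = _rng(seed, 4, p, j, e)
                b_eff = erng.normal(0.0, np.sqrt(cfg.sigma2["effect"]))
                b_eff_rr = erng.normal(0.0, np.sqrt(cfg.sigma2_lnrr["effect"]))
                rr_dev = b_pub_rr + b_comp_rr + b_eff_rr
                true_lncvr = mu_cvr + b_pub + b_comp + b_eff + cfg.lnrr_coupling * rr_dev
                true_lnrr = mu_rr + rr_dev
                m_t = ctl["true_mean"] * float(np.exp(true_lnrr))
                cv_t = cfg.control_cv * float(np.exp(true_lncvr))
                if not (m_t > 0 and cv_t > 0):
                    raise ValueError("implied treatment mean/CV not positive")
                n_t = int(erng.integers(cfg.unit_n_range[0], cfg.unit_n_range[1] + 1))
                units_t = _lognormal_units(erng, m_t, cv_t, n_t)
                rows.append({
                    "publication_id": pub, "comparison_id": comp,
                    "effect_id": f"{comp}_e{e + 1}",
                    "crop": crop, "country": country, "scale": scale,
                    "response_measure": measure, "treatment_type": treatment_type,
                    "intensity": intensity, "year": year,
                    "mean_t": float(np.mean(units_t)),
                    "disp_t": float(np.std(units_t, ddof=1)), "n_t": n_t,
                    "mean_c": ctl["mean"], "disp_c": ctl["sd"], "n_c": ctl["n"],
                    "dispersion_kind": "SD", "shared_control_id": ctl["id"],
                })
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return Dataset(frame, provenance=f"cropstab summary generator seed={seed}")


@dataclass
class CeilingConfig:
    """Configuration of the mechanistic resource-ceiling generator.

    ``ceiling_mean``/``ceiling_cv`` describe the distribution of each unit's
    maximum potential yield; ``baseline_*`` describe auto-pollinated
    pre-ceiling yield; ``pollination_gain`` multiplies pre-ceiling yield in
    the treated arm, evaluated over a grid of gains so the lnCVR-lnRR
    association can be fitted across comparisons.
    """

    ceiling_mean: float = 100.0
    ceiling_cv: float = 0.2
    pollination_gain: Sequence[float] = (1.0, 1.25, 1.5, 2.0, 3.0, 4.0)
    baseline_mean: float = 50.0
    baseline_cv: float = 0.3
    units_per_arm: int = 30
    comparisons_per_gain: int = 8
    seed: int = 0

    def validate(self) -> None:
        if not (self.ceiling_mean > 0 and self.baseline_mean > 0):
            raise ValueError("means must be > 0")
        if not (self.ceiling_cv > 0 and self.baseline_cv > 0):
            raise ValueError("cv values must be > 0")
        if self.units_per_arm < 2 or self.comparisons_per_gain < 1:
            raise ValueError("units_per_arm >= 2 and comparisons_per_gain >= 1 required")


def generate_ceiling_dataset(cfg: CeilingConfig) -> Dataset:
    """Generate unit-level ceiling-effect data, summarised per arm."""
    cfg.validate()
    seed = int(cfg.seed)
    rows = []
    for gi, gain in enumerate(cfg.pollination_gain):
        pub = f"G{gi + 1:02d}"
        for j in range(cfg.comparisons_per_gain):
            rng = _rng(seed, 11, gi, j)
            n = cfg.units_per_arm

            def arm_units(mult: float) -> np.ndarray:
                pre = _lognormal_units(rng, cfg.baseline_mean, cfg.baseline_cv, n) * mult
                ceiling = _lognormal_units(rng, cfg.ceiling_mean, cfg.ceiling_cv, n)
                return np.minimum(pre, ceiling)

            uc = arm_units(1.0)
            ut = arm_units(float(gain))
            comp = f"{pub}_c{j + 1}"
            rows.append({
                "publication_id": pub, "comparison_id": comp,
                "effect_id": f"{comp}_e1",
                "crop": "oilseed_rape", "country": "synthetic",
                "scale": "plot_or_cohort", "response_measure": "yield_mass",
                "treatment_type": "open", "intensity": "none",
                "year": 2020,
                "mean_t": float(np.mean(ut)), "disp_t": float(np.std(ut, ddof=1)),
                "n_t": n,
                "mean_c": float(np.mean(uc)), "disp_c": float(np.std(uc, ddof=1)),
                "n_c": n,
                "dispersion_kind": "SD", "shared_control_id": comp,
            })
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return Dataset(frame, provenance=f"cropstab ceiling generator seed={seed}")


def write_fixture(ds: Dataset, path) -> None:
    """Write generator output in the canonical CSV schema (round-trip safe)."""
    write_dataset(ds, path)


def small_fixture(seed: int = 20) -> Dataset:
    """A small fixed-structure dataset (5 publications x 3 comparisons x 2 effects)."""
    cfg = GeneratorConfig(
        n_publications=5, comparisons_per_publication=(3, 3),
        effects_per_comparison=(2, 2), seed=seed)
    return generate_summary_dataset(cfg)
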