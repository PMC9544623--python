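"""Leave-one-out, subsampling, time-lag and Egger publication-bias analyses."""

import numpy as np
import pandas as pd
import pytest

import cropstab as cs
from cropstab import sensitivity
from cropstab.model import ModelSpec


@pytest.fixture(scope="module")
def loo_ds():
    cfg = cs.GeneratorConfig(n_publications=6, comparisons_per_publication=(2, 3),
                             effects_per_comparison=(1, 2), seed=31)
    return cs.generate_summary_dataset(cfg)


class TestLeaveOneOut:
    def test_one_iteration_per_publication(self, loo_ds):
        rep = cs.leave_one_publication_out(loo_ds)
        assert len(rep.iterations) == loo_ds.counts()["publications"]
        assert rep.summary["min"] <= rep.summary["full_estimate"] <= rep.summary["max"] \
            or abs(rep.summary["full_estimate"] - rep.summary["min"]) < 0.5

    def test_planted_outlier_moves_estimate_most(self):
        # low natural heterogeneity so the +1 shift is a genuine outlier
        cfg = cs.GeneratorConfig(
            n_publications=6, comparisons_per_publication=(2, 3),
            effects_per_comparison=(1, 2), lnrr_coupling=0.0,
            sigma2={"publication": 0.005, "comparison": 0.005, "effect": 0.005},
            seed=31)
        loo_ds = cs.generate_summary_dataset(cfg)
        f = loo_ds.frame.copy()
        outlier = f["publication_id"].iloc[0]
        mask = f["publication_id"] == outlier
        f.loc[mask, "disp_t"] = f.loc[mask, "disp_t"] * np.e  # shifts lnCVR by +1
        ds = cs.Dataset(f)
        rep = cs.leave_one_publication_out(ds)
        full = rep.summary["full_estimate"]
        moves = rep.iterations.assign(
            move=(rep.iterations["estimate"] - full).abs())
        assert moves.loc[moves["move"].idxmax(), "left_out"] == outlier

    def test_single_publication_errors(self, loo_ds):
        one = loo_ds.subset(loo_ds.frame["publication_id"]
                            == loo_ds.frame["publication_id"].iloc[0])
        with pytest.raises(ValueError, match="2 publications"):
            cs.leave_one_publication_out(one)


class TestOneEffectPerComparison:
    def test_single_effect_comparisons_reproduce_full_fit(self):
        cfg = cs.GeneratorConfig(n_publications=5, comparisons_per_publication=(2, 2),
                                 effects_per_comparison=(1, 1), seed=13)
        ds = cs.generate_summary_dataset(cfg)
        rep = cs.one_effect_per_comparison(ds, replicates=3, seed=1)
        assert np.allclose(rep.iterations["estimate"],
                           rep.summary["full_estimate"], atol=1e-8)

    def test_seed_reproducibility(self, loo_ds):
        a = cs.one_effect_per_comparison(loo_ds, replicates=5, seed=42)
        b = cs.one_effect_per_comparison(loo_ds, replicates=5, seed=42)
        assert a.to_json() == b.to_json()

    def test_replicate_validation(self, loo_ds):
        with pytest.raises(ValueError):
            cs.one_effect_per_comparison(loo_ds, replicates=0)

    def test_spread_shrinks_with_within_comparison_correlation(self):
        """When effect-level heterogeneity vanishes, effects within a
        comparison are nearly interchangeable and subsampling barely moves
        the estimate."""
        spreads = []
        for eff_var in (0.3, 0.001):
            cfg = cs.GeneratorConfig(
                n_publications=8, comparisons_per_publication=(2, 3),
                effects_per_comparison=(2, 3), lnrr_coupling=0.0,
                sigma2={"publication": 0.02, "comparison": 0.01,
                        "effect": eff_var},
                seed=17)
            ds = cs.generate_summary_dataset(cfg)
            rep = cs.one_effect_per_comparison(ds, replicates=12, seed=3)
            spreads.append(rep.iterations["estimate"].std(ddof=1))
        assert spreads[1] < spreads[0]


class TestTimeLag:
    def test_single_year_is_rank_error(self, loo_ds):
        f = loo_ds.frame.copy()
        f["year"] = 2000
        with pytest.raises(ValueError, match="distinct year"):
            cs.time_lag_test(cs.Dataset(f))

    def test_null_data_slope_near_zero(self, loo_ds):
        w = cs.time_lag_test(loo_ds)
        assert w.loc["year_centred", "ci_low"] <= 0 <= w.loc["year_centred", "ci_high"]

    def test_planted_drift_detected(self):
        cfg = cs.GeneratorConfig(n_publications=30, comparisons_per_publication=(3, 4),
                                 effects_per_comparison=(2, 3), seed=23)
        ds = cs.generate_summary_dataset(cfg)
        f = ds.frame.copy()
        drift = 0.01 * (f["year"] - f["year"].min())
        f["disp_t"] = f["disp_t"] * np.exp(drift)  # lnCVR drifts +0.01/yr
        w = cs.time_lag_test(cs.Dataset(f))
        assert w.loc["year_centred", "estimate"] > 0
        assert w.loc["year_centred", "p"] < 0.05


class TestEgger:
    def test_effective_n_variants(self):
        assert sensitivity.effective_n(10, 10) == pytest.approx(5.0)
        assert np.sqrt(1 / sensitivity.effective_n(10, 10)) == pytest.approx(0.4472, abs=1e-4)
        assert sensitivity.effective_n(10, 10, variant="hedges") == pytest.approx(20.0)
        with pytest.raises(ValueError):
            sensitivity.effective_n(10, 10, variant="nope")

    def test_symmetric_data_slope_near_zero(self, loo_ds):
        w = cs.egger_effective_n(loo_ds)
        assert w.loc["sqrt_inv_n", "ci_low"] <= 0 <= w.loc["sqrt_inv_n", "ci_high"]

    def test_simulated_selection_gives_positive_slope(self):
        """Suppressing unfavourable small studies induces funnel asymmetry."""
        cfg = cs.GeneratorConfig(
            n_publications=25, comparisons_per_publication=(3, 4),
            effects_per_comparison=(1, 2), lnrr_coupling=0.0,
            true_mu={"lnCVR": 0.0, "lnRR": 0.0},
            unit_n_range=(4, 40), seed=29)
        ds = cs.generate_summary_dataset(cfg)
        lnrr = cs.effect_table(ds, "lnRR")["estimate"].to_numpy()
        ntilde = sensitivity.effective_n(ds.frame["n_t"], ds.frame["n_c"])
        small = ntilde < np.median(ntilde)
        keep = ~(small & (lnrr < 0))
        sel = ds.subset(pd.Series(keep, index=ds.frame.index))
        w = cs.egger_effective_n(sel, ModelSpec(response_type="lnRR"))
        assert w.loc["sqrt_inv_n", "estimate"] > 0

    def test_report_serialisation_roundtrip(self, loo_ds, tmp_path):
        rep = cs.leave_one_publication_out(loo_ds)
        p = tmp_path / "loo.json"
        text = rep.to_json(p)
        assert p.read_text() == text
        assert '"kind": "leave_one_publication_out"' in text
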