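"""REML/ML engine, Wald and prediction intervals, LRT, robust variance."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cropstab as cs
from cropstab import model, pipeline
from conftest import null_fit

ZERO3 = {"publication_id": 0.0, "comparison_id": 0.0, "effect_id": 0.0}


def _levels(n):
    ids = [f"e{i}" for i in range(n)]
    return {"publication_id": ids, "comparison_id": ids, "effect_id": ids}


def _intercept(n):
    return pd.DataFrame({"intercept": np.ones(n)})


class TestGls:
    def test_zero_responses_give_zero_mean(self):
        f = cs.fit([0.0, 0.0], _intercept(2), np.eye(2), _levels(2),
                   fixed_sigma2=ZERO3)
        assert f.coefficients["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_inverse_variance_weighted_mean(self):
        f = cs.fit([1.0, 3.0], _intercept(2), np.eye(2), _levels(2),
                   fixed_sigma2=ZERO3)
        assert f.coefficients["intercept"] == pytest.approx(2.0, rel=1e-10)
        assert f.se["intercept"] == pytest.approx(np.sqrt(0.5), rel=1e-10)

    def test_unequal_weights(self):
        # weights 1 and 1/4: mu = (1*1 + 0.25*5)/1.25 = 1.8
        f = cs.fit([1.0, 5.0], _intercept(2), np.diag([1.0, 4.0]), _levels(2),
                   fixed_sigma2=ZERO3)
        assert f.coefficients["intercept"] == pytest.approx(1.8, rel=1e-10)

    def test_rank_deficient_design_names_columns(self, tiny_ds):
        y, S, levels, _ = pipeline._contrast_inputs(tiny_ds, "lnCVR",
                                                    pipeline.SuiteConfig())
        X = pd.DataFrame({"intercept": np.ones(len(y)),
                          "dup": np.ones(len(y))})
        with pytest.raises(ValueError, match="rank deficient"):
            cs.fit(y, X, S, levels)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            cs.fit([1.0, 2.0], _intercept(2), np.eye(3), _levels(2))


class TestRemlEngine:
    def test_reml_matches_metafor_on_shared_control_data(self, small_ds):
        """Independent cross-check of estimates, SEs, variance components
        and log-likelihoods against metafor's rma.mv on the same inputs."""
        y, S, levels, _ = pipeline._contrast_inputs(small_ds, "lnCVR",
                                                    pipeline.SuiteConfig())
        ours = {
            m: cs.fit(y, _intercept(len(y)), S, levels, method=m)
            for m in ("REML", "ML")
        }
        import tempfile, os
        d = tempfile.mkdtemp()
        pd.DataFrame({"yi": y, "pub": levels["publication_id"],
                      "comp": levels["comparison_id"],
                      "eff": levels["effect_id"]}).to_csv(f"{d}/dat.csv", index=False)
        np.savetxt(f"{d}/V.csv", S, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            dat <- read.csv("{d}/dat.csv")
            V <- as.matrix(read.csv("{d}/V.csv", header=FALSE))
            for (m in c("REML", "ML")) {{
              r <- rma.mv(yi, V, random = ~1|pub/comp/eff, data=dat, method=m,
                          control=list(rel.tol=1e-10))
              cat(sprintf("%s %.8f %.8f %.8f %.8f %.8f %.8f\\n", m, coef(r),
                          r$se, logLik(r), r$sigma2[1], r$sigma2[2], r$sigma2[3]))
            }}
        """)
        with open(f"{d}/fit.R", "w") as fh:
            fh.write(script)
        out = subprocess.run(["Rscript", f"{d}/fit.R"], capture_output=True,
                             text=True, check=True).stdout
        for line in out.strip().splitlines():
            m, mu, se, ll, s1, s2, s3 = line.split()
            f = ours[m]
            assert f.coefficients["intercept"] == pytest.approx(float(mu), abs=2e-6)
            assert f.se["intercept"] == pytest.approx(float(se), abs=2e-6)
            assert f.log_likelihood == pytest.approx(float(ll), abs=1e-4)
            got = list(f.variance_components.values())
            assert got == pytest.approx([float(s1), float(s2), float(s3)], abs=2e-5)

    def test_adding_constant_shifts_only_intercept(self, tiny_ds):
        y, S, levels, _ = pipeline._contrast_inputs(tiny_ds, "lnCVR",
                                                    pipeline.SuiteConfig())
        X = _intercept(len(y))
        f0 = cs.fit(y, X, S, levels)
        f1 = cs.fit(y + 5.0, X, S, levels)
        assert f1.coefficients["intercept"] == pytest.approx(
            f0.coefficients["intercept"] + 5.0, abs=1e-6)
        for k in f0.variance_components:
            assert f1.variance_components[k] == pytest.approx(
                f0.variance_components[k], abs=1e-6)

    def test_variance_components_invariant_to_row_order(self, small_ds):
        y, S, levels, _ = pipeline._contrast_inputs(small_ds, "lnCVR",
                                                    pipeline.SuiteConfig())
        f0 = cs.fit(y, _intercept(len(y)), S, levels)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(y))
        f1 = cs.fit(y[perm], _intercept(len(y)), S[np.ix_(perm, perm)],
                    {k: np.asarray(v)[perm] for k, v in levels.items()})
        assert f1.coefficients["intercept"] == pytest.approx(
            f0.coefficients["intercept"], abs=1e-7)
        for k in f0.variance_components:
            assert f1.variance_components[k] == pytest.approx(
                f0.variance_components[k], abs=1e-6)

    def test_reml_and_ml_agree_when_components_fixed(self):
        y = np.array([0.3, -0.1, 0.2, 0.4])
        fixed = {"publication_id": 0.05, "comparison_id": 0.0, "effect_id": 0.02}
        fr = cs.fit(y, _intercept(4), np.eye(4) * 0.1, _levels(4),
                    method="REML", fixed_sigma2=fixed)
        fm = cs.fit(y, _intercept(4), np.eye(4) * 0.1, _levels(4),
                    method="ML", fixed_sigma2=fixed)
        assert fr.coefficients["intercept"] == pytest.approx(
            fm.coefficients["intercept"], rel=1e-10)


class TestWaldAndPrediction:
    def _stub(self, est, se, sigma2=None):
        names = ["intercept"]
        return model.ModelFit(
            coefficients=pd.Series([est], index=names),
            coef_vcov=pd.DataFrame([[se**2]], index=names, columns=names),
            variance_components=sigma2 or {}, log_likelihood=0.0, method="REML",
            n_effects=2, n_params=1, converged=True)

    def test_standard_normal_interval(self):
        w = cs.wald_summary(self._stub(0.0, 1.0), level=0.95)
        assert w.loc["intercept", "ci_low"] == pytest.approx(-1.959964, abs=1e-4)
        assert w.loc["intercept", "ci_high"] == pytest.approx(1.959964, abs=1e-4)

    def test_hand_evaluated_interval(self):
        w = cs.wald_summary(self._stub(-0.386, 0.05), level=0.95)
        assert w.loc["intercept", "ci_low"] == pytest.approx(-0.484, abs=5e-4)
        assert w.loc["intercept", "ci_high"] == pytest.approx(-0.288, abs=5e-4)

    def test_zero_level_degenerates_to_estimate(self):
        w = cs.wald_summary(self._stub(0.7, 0.1), level=0.0)
        assert w.loc["intercept", "ci_low"] == w.loc["intercept", "ci_high"] == 0.7

    def test_prediction_interval_half_width(self):
        f = self._stub(0.0, 0.1, sigma2={"publication_id": 0.02, "effect_id": 0.01})
        lo, hi = cs.prediction_interval(f, level=0.95)
        assert hi == pytest.approx(1.959964 * np.sqrt(0.04), abs=1e-4)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_prediction_contains_confidence(self, small_cvr0):
        w = cs.wald_summary(small_cvr0)
        lo, hi = cs.prediction_interval(small_cvr0)
        assert lo <= w.loc["intercept", "ci_low"]
        assert hi >= w.loc["intercept", "ci_high"]

    def test_zero_uncertainty_gives_point_interval(self):
        f = self._stub(0.3, 0.0)
        lo, hi = cs.prediction_interval(f, level=0.95)
        assert lo == hi == pytest.approx(0.3)


class TestLrt:
    def _fit_pair(self, ds):
        fm_null, _ = null_fit(ds, method="ML")
        cfg = pipeline.SuiteConfig()
        y, S, levels, _ = pipeline._contrast_inputs(ds, "lnCVR", cfg)
        X = pd.DataFrame({"intercept": np.ones(len(y)),
                          "crop_dummy": (ds.frame["crop"] == "apple").astype(float)})
        if X["crop_dummy"].nunique() < 2:
            X["crop_dummy"] = np.arange(len(y), dtype=float)
        fm_alt = cs.fit(y, X, S, levels, method="ML")
        return fm_null, fm_alt

    def test_identical_models_give_zero(self, tiny_ds):
        f, _ = null_fit(tiny_ds, method="ML")
        stat, df, p = cs.lrt(f, _copy_with(f, n_params=f.n_params + 1))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_reference(self, tiny_ds):
        f, _ = null_fit(tiny_ds, method="ML")
        null = _copy_with(f, log_likelihood=-10.0)
        alt = _copy_with(f, log_likelihood=-7.0, n_params=f.n_params + 2)
        stat, df, p = cs.lrt(null, alt)
        assert (stat, df) == (6.0, 2)
        assert p == pytest.approx(0.049787, abs=1e-5)

    def test_nested_moderator_increases_likelihood(self, tiny_ds):
        fm_null, fm_alt = self._fit_pair(tiny_ds)
        stat, df, p = cs.lrt(fm_null, fm_alt)
        assert stat >= 0 and df == 1 and 0 <= p <= 1

    def test_reml_fits_rejected(self, small_cvr0):
        with pytest.raises(ValueError, match="ML"):
            cs.lrt(small_cvr0, small_cvr0)

    def test_wrong_nesting_rejected(self, tiny_ds):
        f, _ = null_fit(tiny_ds, method="ML")
        with pytest.raises(ValueError, match="more parameters"):
            cs.lrt(f, _copy_with(f, n_params=f.n_params - 1))


def _copy_with(f, **kw):
    import dataclasses
    return dataclasses.replace(f, **kw)


class TestRobustVariance:
    def _sim_fit(self, seed, n_clusters=20, per=2, sigma2=0.04):
        rng = np.random.default_rng(seed)
        cl = np.repeat([f"c{i}" for i in range(n_clusters)], per)
        n = len(cl)
        v = np.full(n, 0.05)
        b = rng.normal(0, np.sqrt(sigma2), n_clusters)
        y = 0.3 + b[np.repeat(np.arange(n_clusters), per)] + rng.normal(0, np.sqrt(v))
        levels = {"comparison_id": cl, "effect_id": [f"e{i}" for i in range(n)]}
        f = cs.fit(y, pd.DataFrame({"intercept": np.ones(n)}), np.diag(v), levels,
                   fixed_sigma2={"comparison_id": sigma2, "effect_id": 0.0})
        return f, cl

    def test_single_cluster_rejected(self, tiny_ds):
        f, _ = null_fit(tiny_ds)
        with pytest.raises(ValueError, match="2 clusters"):
            cs.robust_se(f, ["same"] * f.n_effects)

    def test_two_clusters_df_at_most_one(self):
        f, cl = self._sim_fit(0, n_clusters=2, per=4)
        rr = cs.robust_se(f, cl)
        assert rr.df["intercept"] <= 1.0 + 1e-8

    def test_own_cluster_reduces_to_row_wise_form(self):
        """With every row its own cluster the CR2 meat collapses to a
        heteroscedasticity-robust form computable by hand."""
        y = np.array([0.1, -0.2, 0.4, 0.05])
        v = np.array([0.1, 0.2, 0.15, 0.05])
        n = 4
        levels = {"effect_id": [f"e{i}" for i in range(n)]}
        f = cs.fit(y, pd.DataFrame({"intercept": np.ones(n)}), np.diag(v), levels,
                   fixed_sigma2={"effect_id": 0.0})
        rr = cs.robust_se(f, [f"e{i}" for i in range(n)])
        # hand computation: w_i = 1/v_i; for the intercept-only GLS fit the
        # working variance of residual i is v_i - 1/sum(w), so the CR2
        # adjustment squared is A_i^2 = v_i / (v_i - 1/sum(w))
        w = 1.0 / v
        mu = float(np.sum(w * y) / np.sum(w))
        e = y - mu
        a2 = v / (v - 1.0 / np.sum(w))
        meat = np.sum(w**2 * a2 * e**2)
        expected = meat / np.sum(w) ** 2
        assert rr.coef_vcov.loc["intercept", "intercept"] == pytest.approx(
            expected, rel=1e-8)

    def test_robust_se_close_to_model_se_when_well_specified(self):
        """Balanced clusters, correctly specified covariance: the CR2 SE
        should track the model SE (within 25 percent on average)."""
        ratios = []
        for seed in range(200):
            f, cl = self._sim_fit(seed)
            rr = cs.robust_se(f, cl)
            ratios.append(rr.se["intercept"] / f.se["intercept"])
        ratios = np.asarray(ratios)
        assert abs(np.mean(ratios) - 1.0) < 0.25
        assert np.all(ratios > 0.4) and np.all(ratios < 2.5)

    def test_satterthwaite_df_bounded_by_clusters(self):
        f, cl = self._sim_fit(3)
        rr = cs.robust_se(f, cl)
        assert 1.0 <= rr.df["intercept"] <= len(np.unique(cl)) - 1 + 1e-8
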