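import numpy as np
import pandas as pd
import pytest

from lumpanel.errors import InestimableError, ValidationError
from lumpanel.rewb import (
    REWBResult,
    decompose_within_between,
    fit_rewb,
    rubin_pool,
    run_all_models,
)
from lumpanel.synthetic import (
    WorldConfig,
    generate_analytic_exposures,
    generate_panel,
)
from tests._oracles import between_means_slope, fe_within_slope, rubin_by_hand


def analytic_panel(seed=11, n=150, buffer_sizes=(1000.0,), **cfg_kw):
    cfg = WorldConfig(seed=seed, n_persons=n, missingness={}, **cfg_kw)
    expo = generate_analytic_exposures(
        cfg, np.random.default_rng(seed), buffer_sizes=buffer_sizes
    )
    panel, truth = generate_panel(cfg, expo)
    return panel.merge(expo, on=["person_id", "wave_id"]), truth


class TestDecomposition:
    def test_simple_sequence(self):
        df = pd.DataFrame({"person_id": ["a"] * 3, "lum_scaled": [1.0, 2.0, 3.0]})
        out = decompose_within_between(df)
        assert out["lum_scaled_bar"].tolist() == [2.0, 2.0, 2.0]
        assert out["lum_scaled_dev"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_exposure_has_zero_deviations(self):
        df = pd.DataFrame({"person_id": ["a"] * 3, "lum_scaled": [4.0] * 3})
        out = decompose_within_between(df)
        assert (out["lum_scaled_dev"] == 0.0).all()

    def test_identities_on_random_panels(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "person_id": np.repeat([f"p{i}" for i in range(n)], 3),
                "lum_scaled": rng.uniform(0, 10, 3 * n),
            }
        )
        out = decompose_within_between(df)
        # reconstruction is exact
        assert np.allclose(out["lum_scaled_dev"] + out["lum_scaled_bar"], out["lum_scaled"])
        # deviations sum to zero within every person
        sums = out.groupby("person_id")["lum_scaled_dev"].sum()
        assert np.abs(sums).max() < 1e-9


class TestFitREWB:
    def test_within_matches_fe_oracle_on_balanced_panel(self):
        df, _ = analytic_panel()
        df = decompose_within_between(df)
        res = fit_rewb(df, "walk_min_wk", covariates=())
        oracle = fe_within_slope(
            df["lum_scaled_dev"].to_numpy(),
            df["walk_min_wk"].to_numpy(),
            df["person_id"].to_numpy(),
        )
        assert res.params["lum_scaled_dev"] == pytest.approx(oracle, abs=1e-6)

    def test_between_matches_means_ols_oracle_on_balanced_panel(self):
        df, _ = analytic_panel()
        df = decompose_within_between(df)
        res = fit_rewb(df, "walk_min_wk", covariates=())
        oracle = between_means_slope(
            df["lum_scaled"].to_numpy(),
            df["walk_min_wk"].to_numpy(),
            df["person_id"].to_numpy(),
        )
        assert res.params["lum_scaled_bar"] == pytest.approx(oracle, abs=1e-6)

    def test_noiseless_limit_recovers_exactly(self):
        df, truth = analytic_panel(
            seed=5, n=60, var_v=0.0, var_eps=0.0, covariate_effects={}
        )
        df = decompose_within_between(df)
        res = fit_rewb(df, "walk_min_wk", covariates=())
        assert res.params["lum_scaled_dev"] == pytest.approx(truth["beta_within"], abs=1e-6)
        assert res.params["lum_scaled_bar"] == pytest.approx(truth["beta_between"], abs=1e-6)
        assert res.boundary_variance  # zero noise drives var_v to the boundary

    def test_person_constant_shift_leaves_within_unchanged(self):
        df, _ = analytic_panel(seed=13)
        df = decompose_within_between(df)
        base = fit_rewb(df, "walk_min_wk", covariates=())
        shifted = df.copy()
        rng = np.random.default_rng(0)
        offsets = {p: rng.uniform(-2, 2) for p in shifted["person_id"].unique()}
        shifted["lum_scaled"] = shifted["lum_scaled"] + shifted["person_id"].map(offsets)
        shifted = decompose_within_between(shifted.drop(columns=["lum_scaled_bar", "lum_scaled_dev"]))
        res = fit_rewb(shifted, "walk_min_wk", covariates=())
        assert np.allclose(shifted["lum_scaled_dev"], df["lum_scaled_dev"], atol=1e-9)
        assert res.params["lum_scaled_dev"] == pytest.approx(
            base.params["lum_scaled_dev"], abs=1e-6
        )

    def test_zero_within_variance_is_inestimable(self):
        df, _ = analytic_panel(seed=7, n=40, parcel_change_prob=0.0)
        df["lum_scaled"] = df.groupby("person_id")["lum_scaled"].transform("mean")
        df = decompose_within_between(df)
        with pytest.raises(InestimableError):
            fit_rewb(df, "walk_min_wk", covariates=())

    def test_rank_deficient_design_lists_aliased_terms(self):
        df, _ = analytic_panel(seed=9, n=60)
        df = decompose_within_between(df)
        df["dup"] = df["lum_scaled_bar"]
        with pytest.raises(ValidationError, match="dup"):
            fit_rewb(df, "walk_min_wk", covariates=("dup",))

    def test_missing_decomposition_rejected(self):
        df, _ = analytic_panel(seed=9, n=20)
        with pytest.raises(ValidationError):
            fit_rewb(df, "walk_min_wk")

    def test_ci_brackets_estimate(self):
        df, _ = analytic_panel(seed=15)
        df = decompose_within_between(df)
        res = fit_rewb(df, "walk_min_wk", covariates=())
        assert (res.ci_low < res.params).all()
        assert (res.params < res.ci_high).all()
        assert res.var_v >= 0 and res.var_eps > 0
        assert res.n_person_observations == len(df)


class TestRubinPooling:
    @staticmethod
    def _result(estimates, ses, spec=("y", ("a",))):
        idx = [f"t{i}" for i in range(len(estimates))]
        return REWBResult(
            params=pd.Series(estimates, index=idx),
            se=pd.Series(ses, index=idx),
            var_v=100.0,
            var_eps=900.0,
            n_persons=10,
            n_person_observations=30,
            spec_key=spec,
        )

    def test_hand_computed_two_imputation_example(self):
        # estimates {1, 3}, within-variances {1, 1}:
        # pooled = 2, total variance = 1 + 1.5 * 2 = 4
        pooled = rubin_pool([self._result([1.0], [1.0]), self._result([3.0], [1.0])])
        assert pooled.params["t0"] == pytest.approx(2.0)
        assert pooled.se["t0"] ** 2 == pytest.approx(4.0)
        q, t = rubin_by_hand([1.0, 3.0], [1.0, 1.0])
        assert (pooled.params["t0"], pooled.se["t0"] ** 2) == pytest.approx((q, t))

    def test_identical_imputations_collapse(self):
        results = [self._result([2.5, -1.0], [0.5, 0.2]) for _ in range(4)]
        pooled = rubin_pool(results)
        assert pooled.params.tolist() == pytest.approx([2.5, -1.0])
        # between-imputation variance is zero -> total = within
        assert pooled.se.tolist() == pytest.approx([0.5, 0.2])

    def test_single_result_warns_and_passes_through(self, caplog):
        r = self._result([1.0], [1.0])
        with caplog.at_level("WARNING"):
            pooled = rubin_pool([r])
        assert pooled is r
        assert any("single imputation" in rec.message for rec in caplog.records)

    def test_mismatched_specifications_rejected(self):
        a = self._result([1.0], [1.0], spec=("y", ("a",)))
        b = self._result([1.0], [1.0], spec=("y", ("b",)))
        with pytest.raises(ValidationError):
            rubin_pool([a, b])

    def test_matches_hand_formulas_on_random_draws(self, rng):
        ests = rng.normal(0, 1, 7)
        ses = rng.uniform(0.5, 2.0, 7)
        pooled = rubin_pool([self._result([e], [s]) for e, s in zip(ests, ses)])
        q, t = rubin_by_hand(list(ests), list(ses**2))
        assert pooled.params["t0"] == pytest.approx(q)
        assert pooled.se["t0"] ** 2 == pytest.approx(t)


class TestRunAllModels:
    def test_two_outcomes_three_buffers_gives_twelve_rows(self):
        df, _ = analytic_panel(seed=17, n=80, buffer_sizes=(500.0, 1000.0, 1600.0))
        df = df.drop(columns=["res_x", "res_y"], errors="ignore")
        results = run_all_models(df, covariates=("C(sex)", "age"))
        assert len(results) == 12
        assert (results["status"] != "").all()
        ok = results[results["status"] == "ok"]
        assert set(results["effect_type"]) == {"within", "between"}
        assert (ok["ci_low"] <= ok["beta"]).all() and (ok["beta"] <= ok["ci_high"]).all()

    def test_missing_buffer_size_marked_failed(self):
        df, _ = analytic_panel(seed=17, n=40, buffer_sizes=(1000.0,))
        results = run_all_models(df, covariates=())
        failed = results[results["buffer_size"] == 500.0]
        assert (failed["status"].str.startswith("failed")).all()
        assert results[results["buffer_size"] == 1000.0]["status"].eq("ok").all()

    def test_default_run_recovers_truth_pattern(self):
        df, truth = analytic_panel(seed=23, n=800)
        results = run_all_models(
            df, buffer_sizes=(1000.0,), covariates=("C(sex)", "age")
        )
        w = results[(results["outcome"] == "walk_min_wk") & (results["effect_type"] == "within")]
        b = results[(results["outcome"] == "walk_min_wk") & (results["effect_type"] == "between")]
        # sign and rough magnitude of the generating coefficients
        assert w["ci_low"].item() < truth["beta_within"] < w["ci_high"].item()
        assert b["ci_low"].item() < truth["beta_between"] < b["ci_high"].item()
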