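import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lumpanel.errors import ValidationError
from lumpanel.harmonize import (
    LapaqItem,
    SquashItem,
    enforce_time_invariant,
    filter_nonmovers,
    impute_missing,
    lapaq_minutes_per_week,
    pool_cohorts,
    squash_column,
    squash_minutes_per_week,
)


class TestSquash:
    @pytest.mark.parametrize(
        "days,minutes,median,expected",
        [
            (3, 30, None, 90.0),  # complete item
            (None, 45, None, 45.0),  # duration only: assume 1 active day
            (4, None, 30, 120.0),  # days only: median substitute
            (7, 60, None, 420.0),
            (0, 30, None, 0.0),
        ],
    )
    def test_harmonization_rules(self, days, minutes, median, expected):
        item = SquashItem(days_per_week=days, minutes_per_day=minutes)
        assert squash_minutes_per_week(item, median) == expected

    def test_direct_weekly_minutes_pass_through(self):
        item = SquashItem(minutes_per_week_direct=150.0)
        assert squash_minutes_per_week(item) == 150.0

    def test_all_missing_is_missing(self):
        assert np.isnan(squash_minutes_per_week(SquashItem()))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            squash_minutes_per_week(SquashItem(days_per_week=-1, minutes_per_day=30))

    def test_days_without_duration_needs_median(self):
        with pytest.raises(ValidationError):
            squash_minutes_per_week(SquashItem(days_per_week=3))

    def test_vectorized_matches_scalar(self):
        days = pd.Series([3.0, np.nan, 4.0, np.nan, 2.0])
        minutes = pd.Series([30.0, 45.0, np.nan, np.nan, 10.0])
        out = squash_column(days, minutes)
        median = minutes[days.notna() & minutes.notna()].median()  # 20.0
        expected = [90.0, 45.0, 4 * median, np.nan, 20.0]
        assert out.tolist() == pytest.approx(expected, nan_ok=True)

    @given(
        days=st.integers(0, 7),
        minutes=st.floats(0, 600, allow_nan=False),
        k=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_consistency(self, days, minutes, k):
        base = squash_minutes_per_week(SquashItem(days, minutes))
        scaled = squash_minutes_per_week(SquashItem(days, minutes * k))
        assert scaled == pytest.approx(base * k, rel=1e-9, abs=1e-9)


class TestLapaq:
    @pytest.mark.parametrize(
        "sessions,minutes,expected",
        [(4, 30, 60.0), (0, 30, 0.0), (7, 20, 70.0), (1, 45, 22.5)],
    )
    def test_two_week_recall_to_weekly_minutes(self, sessions, minutes, expected):
        assert lapaq_minutes_per_week(LapaqItem(sessions, minutes)) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            lapaq_minutes_per_week(LapaqItem(-1, 30))

    @given(
        sessions=st.integers(0, 28),
        minutes=st.floats(0, 300, allow_nan=False),
        k=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_consistency(self, sessions, minutes, k):
        base = lapaq_minutes_per_week(LapaqItem(sessions, minutes))
        scaled = lapaq_minutes_per_week(LapaqItem(sessions, minutes * k))
        assert scaled == pytest.approx(base * k, rel=1e-9, abs=1e-9)


def _panel(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "wave_id", "res_x", "res_y"]
    )


class TestFilterNonmovers:
    def test_stayer_kept_mover_and_dropout_removed(self):
        panel = _panel(
            [
                ("stay", 1, 0.0, 0.0), ("stay", 2, 0.0, 0.0), ("stay", 3, 0.5, 0.0),
                ("move", 1, 0.0, 0.0), ("move", 2, 0.0, 0.0), ("move", 3, 500.0, 0.0),
                ("drop", 1, 0.0, 0.0), ("drop", 2, 0.0, 0.0),
            ]
        )
        kept, counts = filter_nonmovers(panel)
        assert set(kept["person_id"]) == {"stay"}  # 0.5 m within jitter tolerance
        assert counts == {
            "persons_in": 3,
            "excluded_incomplete_followup": 1,
            "excluded_movers": 1,
            "persons_kept": 1,
        }

    def test_flow_accounting_balances(self):
        rng = np.random.default_rng(7)
        rows = []
        for p in range(40):
            waves = (1, 2, 3) if rng.random() < 0.8 else (1, 3)
            x = rng.uniform(0, 1000)
            for w in waves:
                xx = x + (200.0 if (rng.random() < 0.2 and w == 3) else 0.0)
                rows.append((f"p{p}", w, xx, 0.0))
        kept, c = filter_nonmovers(_panel(rows))
        assert c["persons_in"] == (
            c["excluded_incomplete_followup"] + c["excluded_movers"] + c["persons_kept"]
        )

    def test_idempotent(self):
        panel = _panel(
            [
                ("a", 1, 0, 0), ("a", 2, 0, 0), ("a", 3, 0, 0),
                ("b", 1, 0, 0), ("b", 2, 9, 0), ("b", 3, 9, 0),
            ]
        )
        once, _ = filter_nonmovers(panel)
        twice, counts = filter_nonmovers(once)
        pd.testing.assert_frame_equal(once, twice)
        assert counts["excluded_incomplete_followup"] == 0
        assert counts["excluded_movers"] == 0


class TestPoolCohorts:
    @staticmethod
    def _cohort(prefix, n=2, income_codes=(1, 2, 3, 4)):
        rng = np.random.default_rng(abs(hash(prefix)) % 2**31)
        return pd.DataFrame(
            {
                "person_id": [f"{prefix}{i}" for i in range(n)],
                "cohort_id": prefix,
                "wave_id": 1,
                "income": rng.choice(income_codes, size=n),
                "walk_min_wk": rng.uniform(0, 300, size=n),
            }
        )

    def test_concatenation_keeps_cohort_and_rows(self):
        a, b = self._cohort("A"), self._cohort("B")
        pooled = pool_cohorts(a, b)
        assert len(pooled) == 4
        assert set(pooled["cohort_id"]) == {"A", "B"}
        pd.testing.assert_frame_equal(pooled[pooled["cohort_id"] == "A"], a)

    def test_per_cohort_marginals_preserved(self):
        a, b = self._cohort("A", n=50), self._cohort("B", n=30)
        pooled = pool_cohorts(a, b)
        for df, label in ((a, "A"), (b, "B")):
            sub = pooled[pooled["cohort_id"] == label]
            assert sub["walk_min_wk"].mean() == pytest.approx(df["walk_min_wk"].mean())

    def test_schema_mismatch_lists_columns(self):
        a, b = self._cohort("A"), self._cohort("B").drop(columns="income")
        with pytest.raises(ValidationError, match="income"):
            pool_cohorts(a, b)

    def test_conflicting_income_coding_rejected(self):
        a = self._cohort("A")
        b = self._cohort("B")
        b["income"] = [5, 6]  # un-harmonized 6-level coding
        with pytest.raises(ValidationError, match="income"):
            pool_cohorts(a, b)

    def test_empty_second_panel_warns(self, caplog):
        a = self._cohort("A")
        with caplog.at_level("WARNING"):
            pooled = pool_cohorts(a, a.iloc[0:0])
        pd.testing.assert_frame_equal(pooled, a)


class TestTimeInvariance:
    def test_baseline_value_propagated(self):
        panel = pd.DataFrame(
            {
                "person_id": ["a"] * 3,
                "wave_id": [1, 2, 3],
                "sex": [1, 1, 0],
                "education": [2, 3, 2],
            }
        )
        fixed = enforce_time_invariant(panel)
        assert fixed["sex"].tolist() == [1, 1, 1]
        assert fixed["education"].tolist() == [2, 2, 2]


class TestImputation:
    @staticmethod
    def _panel_with_missing(n=600, miss=0.1, seed=3):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(n)],
                "sex": rng.integers(0, 2, n),
                "education": rng.choice([1, 2, 3, 4], n, p=[0.31, 0.18, 0.22, 0.29]),
                "age": rng.normal(60, 10, n),
                "marital_status": rng.choice([1, 2, 3, 4], n),
                "income": rng.choice([1.0, 2.0, 3.0, 4.0], n, p=[0.12, 0.27, 0.40, 0.21]),
                "employment": rng.integers(0, 2, n).astype(float),
                "self_rated_health": rng.choice([1, 2, 3, 4, 5], n),
                "smoking": rng.integers(0, 2, n),
                "bmi": rng.normal(26, 4, n),
            }
        )
        truth = df["income"].copy()
        df.loc[rng.random(n) < miss, "income"] = np.nan
        return df, truth

    def test_no_missingness_returns_identical_copies(self):
        df, _ = self._panel_with_missing(miss=0.0)
        out = impute_missing(df, m=3, seed=1)
        assert len(out) == 3
        for d in out:
            pd.testing.assert_frame_equal(d, df)

    def test_mcar_imputation_completes_all_datasets(self):
        df, _ = self._panel_with_missing()
        out = impute_missing(df, m=5, seed=1)
        assert len(out) == 5
        for d in out:
            assert not d["income"].isna().any()
            assert set(d["income"].unique()) <= {1.0, 2.0, 3.0, 4.0}
        # observed rows untouched
        obs = df["income"].notna()
        for d in out:
            assert (d.loc[obs, "income"] == df.loc[obs, "income"]).all()

    def test_mcar_category_frequencies_recovered(self):
        df, truth = self._panel_with_missing(n=2000, miss=0.1, seed=5)
        out = impute_missing(df, m=5, seed=11)
        imputed_all = pd.concat([d["income"] for d in out])
        freq_true = truth.value_counts(normalize=True).sort_index()
        freq_imp = imputed_all.value_counts(normalize=True).sort_index()
        # MCAR: imputed marginals match truth within Monte Carlo error
        assert np.abs(freq_true - freq_imp).max() < 0.04

    def test_seed_reproducibility(self):
        df, _ = self._panel_with_missing()
        a = impute_missing(df, m=3, seed=9)
        b = impute_missing(df, m=3, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_all_missing_variable_rejected(self):
        df, _ = self._panel_with_missing()
        df["employment"] = np.nan
        with pytest.raises(ValidationError):
            impute_missing(df, m=2, seed=1)

    def test_mostly_missing_variable_warns(self, caplog):
        df, _ = self._panel_with_missing(n=300, miss=0.7)
        with caplog.at_level("WARNING"):
            impute_missing(df, m=2, seed=1)
        assert any("missing" in r.message for r in caplog.records)
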