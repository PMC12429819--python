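import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohcasim import (
    AmputationSpec,
    ForestConfig,
    KnnConfig,
    ampute,
    impute_knn,
    impute_mean_mode,
    impute_missforest,
    impute_missingness_indicator,
)
from ohcasim import schema
from ohcasim.imputers import DEFAULT_PREDICTOR_VARIABLES, _mode_domain_order, gower_distance

from conftest import toy_table

ALL_IMPUTERS = [impute_mean_mode, impute_missingness_indicator, impute_knn, impute_missforest]


def brute_force_knn(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Independent exhaustive nearest-neighbour oracle for small tables."""
    out = table.copy()
    ages = table["age"].dropna()
    ranges = {"age": float(ages.max() - ages.min()) if len(ages) and ages.max() > ages.min() else 1.0}
    for target in schema.AMPUTABLE:
        gap_rows = np.flatnonzero(table[target].isna().to_numpy())
        donor_rows = np.flatnonzero(~table[target].isna().to_numpy())
        variables = tuple(v for v in DEFAULT_PREDICTOR_VARIABLES if v != target)
        for gi in gap_rows:
            scored = sorted(
                (
                    gower_distance(table.iloc[gi], table.iloc[dj], ranges, variables),
                    int(table["case_id"].iloc[dj]),
                    dj,
                )
                for dj in donor_rows
            )
            chosen = [dj for _, _, dj in scored[: min(k, len(scored))]]
            vals = table[target].to_numpy()[chosen]
            if target == "age":
                out.loc[gi, target] = float(np.median(vals.astype(float)))
            else:
                out.loc[gi, target] = _mode_domain_order(vals, schema.DOMAINS[target])
    return out


class TestMeanMode:
    def test_mean_fill(self):
        t = toy_table({"age": [19.0, 20.0, np.nan, 21.0]})
        out = impute_mean_mode(t).table
        assert out.loc[2, "age"] == 20.0

    def test_mode_fill(self):
        t = toy_table({"witness_type": ["family", "lay", "lay", None]})
        out = impute_mean_mode(t).table
        assert out.loc[3, "witness_type"] == "lay"

    def test_mode_tie_uses_domain_order(self):
        t = toy_table({"witness_type": ["family", "family", "lay", "lay", None]})
        out = impute_mean_mode(t).table
        assert out.loc[4, "witness_type"] == "family"

    def test_fully_missing_column_errors(self):
        t = toy_table({"age": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="age"):
            impute_mean_mode(t)

    def test_variance_shrinks(self, full_cohort):
        # the documented mean-imputation pathology
        amputed, _ = ampute(full_cohort, AmputationSpec(0.3), seed=1)
        out = impute_mean_mode(amputed).table
        assert out["age"].var() < full_cohort["age"].var()


class TestMissingnessIndicator:
    def test_age_fill_and_indicator(self):
        t = toy_table({"age": [30.0] * 7 + [np.nan] + [35.0] * 2})
        out = impute_missingness_indicator(t)
        assert out.table.loc[7, "age"] == 0.0
        assert out.table.loc[7, "age_missing"] == 1
        assert out.table["age_missing"].sum() == 1
        assert out.extra_terms == ["age_missing"]

    def test_no_missing_is_identity(self, small_cohort):
        out = impute_missingness_indicator(small_cohort)
        assert out.extra_terms == []
        pd.testing.assert_frame_equal(out.table, small_cohort)

    def test_categorical_missing_level_count(self, amputed_small):
        table, mask = amputed_small
        out = impute_missingness_indicator(table)
        n_wit = (mask["pattern"] == "witness_type").sum()
        assert (out.table["witness_type"] == schema.MISSING_LEVEL).sum() == n_wit


class TestGowerDistance:
    def test_identical_rows(self):
        t = toy_table({"age": [40.0, 40.0]})
        assert gower_distance(t.iloc[0], t.iloc[1], {"age": 80.0}) == 0.0

    def test_all_categorical_mismatch(self):
        a = {"gender": "female", "arrest_location": "home", "first_rhythm": "shockable"}
        b = {"gender": "male", "arrest_location": "public", "first_rhythm": "unknown"}
        d = gower_distance(a, b, {}, ("gender", "arrest_location", "first_rhythm"))
        assert d == 1.0

    def test_hand_example(self):
        # age 40 vs 60 over range 80, equal gender, differing location
        a = {"age": 40.0, "gender": "female", "arrest_location": "home"}
        b = {"age": 60.0, "gender": "female", "arrest_location": "public"}
        d = gower_distance(a, b, {"age": 80.0}, ("age", "gender", "arrest_location"))
        assert d == pytest.approx((0.25 + 0.0 + 1.0) / 3.0)

    def test_ordinal_call_time_scaled(self):
        a = {"call_time": "t00_05"}
        b = {"call_time": "t19_23"}
        c = {"call_time": "t06_18"}
        assert gower_distance(a, b, {}, ("call_time",)) == pytest.approx(1.0)
        assert gower_distance(a, c, {}, ("call_time",)) == pytest.approx(0.5)

    def test_no_shared_variable_errors(self):
        a = {"age": np.nan, "gender": "female"}
        b = {"age": 50.0, "gender": np.nan}
        with pytest.raises(ValueError, match="shared"):
            gower_distance(a, b, {"age": 10.0}, ("age", "gender"))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        def random_row():
            return {
                "age": float(rng.uniform(18, 110)),
                "gender": rng.choice(schema.DOMAINS["gender"]),
                "witness_type": rng.choice(schema.DOMAINS["witness_type"]),
                "arrest_location": rng.choice(schema.DOMAINS["arrest_location"]),
                "call_time": rng.choice(schema.DOMAINS["call_time"]),
                "first_rhythm": rng.choice(schema.DOMAINS["first_rhythm"]),
                "alert_issued": int(rng.integers(2)),
                "bcpr": int(rng.integers(2)),
            }
        a, b = random_row(), random_row()
        ranges = {"age": 92.0}
        d_ab = gower_distance(a, b, ranges)
        d_ba = gower_distance(b, a, ranges)
        assert d_ab == pytest.approx(d_ba)
        assert 0.0 <= d_ab <= 1.0


class TestKnn:
    def test_k1_copies_exact_match(self):
        t = toy_table(
            {
                "age": [30.0, 80.0, np.nan, 80.0],
                "gender": ["female", "male", "female", "male"],
                "arrest_location": ["home", "public", "home", "public"],
                "bcpr": [1, 0, 1, 0],
            }
        )
        out = impute_knn(t, KnnConfig(k=1)).table
        assert out.loc[2, "age"] == 30.0

    def test_k_exceeding_donors_degenerates_to_pooled_aggregate(self):
        t = toy_table({"age": [20.0, 30.0, 40.0, np.nan]})
        out = impute_knn(t, KnnConfig(k=50)).table
        assert out.loc[3, "age"] == 30.0  # median of all donors

    def test_deterministic_without_seed(self, amputed_small):
        table, _ = amputed_small
        a = impute_knn(table).table
        b = impute_knn(table).table
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_brute_force_on_small_tables(self, table1, seed, k):
        from ohcasim import generate_table_faithful

        cohort = generate_table_faithful(table1, scale=0.002, seed=seed)  # ~27 rows
        amputed, _ = ampute(cohort, AmputationSpec(0.35), seed=seed)
        fast = impute_knn(amputed, KnnConfig(k=k)).table
        slow = brute_force_knn(amputed, k=k)
        pd.testing.assert_frame_equal(fast, slow)

    def test_no_donor_for_variable_errors(self):
        t = toy_table({"age": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            impute_knn(t, KnnConfig(k=1))

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            KnnConfig(k=0)


def _planted_toy(n: int, seed: int, gap_rate: float = 0.2):
    """Cohort where witness_type is a deterministic function of location/gender,
    with MAR gaps in witness_type only."""
    rng = np.random.default_rng(seed)
    loc = rng.choice(schema.DOMAINS["arrest_location"], size=n)
    gender = rng.choice(schema.DOMAINS["gender"], size=n)
    planted = np.where(
        loc == "public",
        np.where(gender == "male", "lay", "healthcare"),
        np.where(gender == "male", "family", "not_witnessed"),
    )
    t = toy_table(
        {
            "age": rng.uniform(20, 100, size=n).round(1),
            "gender": list(gender),
            "arrest_location": list(loc),
            "witness_type": list(planted),
            "call_time": list(rng.choice(schema.DOMAINS["call_time"], size=n)),
            "first_rhythm": list(rng.choice(schema.DOMAINS["first_rhythm"], size=n)),
            "alert_issued": list(rng.integers(2, size=n)),
            "bcpr": list(rng.integers(2, size=n)),
        }
    )
    gaps = rng.random(n) < gap_rate
    amputed = t.copy()
    amputed.loc[gaps, "witness_type"] = None
    return t, amputed, gaps


class TestMissForest:
    def test_recovers_planted_relation(self):
        truth, amputed, gaps = _planted_toy(2000, seed=3)
        out = impute_missforest(amputed, ForestConfig(seed=3)).table
        agreement = (out.loc[gaps, "witness_type"] == truth.loc[gaps, "witness_type"]).mean()
        assert agreement >= 0.95

    def test_beats_mean_mode_on_planted_signal(self):
        mf_hits = mm_hits = total = 0
        for seed in range(20):
            truth, amputed, gaps = _planted_toy(400, seed=seed)
            mf = impute_missforest(amputed, ForestConfig(seed=seed)).table
            mm = impute_mean_mode(amputed).table
            planted = truth.loc[gaps, "witness_type"]
            mf_hits += (mf.loc[gaps, "witness_type"] == planted).sum()
            mm_hits += (mm.loc[gaps, "witness_type"] == planted).sum()
            total += int(gaps.sum())
        assert mf_hits > mm_hits
        assert mf_hits / total > 0.9

    def test_no_missing_returns_unchanged(self, small_cohort):
        out = impute_missforest(small_cohort, ForestConfig(seed=1))
        pd.testing.assert_frame_equal(out.table, small_cohort)

    def test_seeded_determinism(self, amputed_small):
        table, _ = amputed_small
        a = impute_missforest(table, ForestConfig(seed=9)).table
        b = impute_missforest(table, ForestConfig(seed=9)).table
        pd.testing.assert_frame_equal(a, b)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=0)
        with pytest.raises(ValueError):
            ForestConfig(max_iter=0)


class TestSharedInvariants:
    @pytest.mark.parametrize("imputer", ALL_IMPUTERS, ids=["mm", "mxi", "knn", "mf"])
    def test_observed_cells_untouched(self, amputed_small, imputer):
        table, _ = amputed_small
        out = imputer(table).table
        assert len(out) == len(table)
        assert (out["case_id"] == table["case_id"]).all()
        for col in schema.AMPUTABLE:
            observed = ~table[col].isna()
            assert (out.loc[observed, col] == table.loc[observed, col]).all()

    @pytest.mark.parametrize("imputer", ALL_IMPUTERS, ids=["mm", "mxi", "knn", "mf"])
    def test_no_missing_cells_after_imputation(self, amputed_small, imputer):
        table, _ = amputed_small
        out = imputer(table)
        assert not out.table[list(schema.COLUMNS)].isna().any().any()
        if out.method != "mxi":
            schema.validate_cohort(out.table)
        else:
            schema.validate_cohort(out.table, allow_missing_level=True)

    @pytest.mark.parametrize("imputer", ALL_IMPUTERS, ids=["mm", "mxi", "knn", "mf"])
    def test_mask_records_provenance(self, amputed_small, imputer):
        table, mask = amputed_small
        out = imputer(table)
        assert (out.mask["pattern"] == mask["pattern"]).all()
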