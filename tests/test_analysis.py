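"""Phase binning, table assembly, mixed models, and correlation tests."""

import numpy as np
import pandas as pd
import pytest

from circavol import (
    assign_phase,
    build_long_table,
    change_score_correlation,
    effect_size,
    fit_activity_model,
    fit_rhythm_model,
    fit_variability_model,
    fit_series_bundle,
    hourly_activity,
    simulate_trial,
    within_subject_correlation,
)
from circavol.analysis import PHASES
from conftest import coarse_filter_config, null_design


class TestPhase:
    @pytest.mark.parametrize(
        "day,expected",
        [(-14, "run-in"), (-3, "run-in"), (0, "run-in"), (1, "week1"), (7, "week1"),
         (8, "week2"), (14, "week2"), (15, "week3"), (21, "week3"), (22, "week4"),
         (28, "week4"), (29, None), (-15, None)],
    )
    def test_mapping(self, day, expected):
        assert assign_phase(day) == expected

    def test_partition_is_exact(self):
        seen = {}
        for day in range(-14, 29):
            ph = assign_phase(day)
            assert ph in PHASES
            seen.setdefault(ph, []).append(day)
        assert sorted(sum(seen.values(), [])) == list(range(-14, 29))
        assert len(seen["run-in"]) == 15
        assert all(len(seen[f"week{w}"]) == 7 for w in range(1, 5))


class TestEffectSize:
    def test_zero_t_gives_zero(self):
        assert effect_size(0.0, 0.0, 100) == 0.0

    def test_reported_pairing_scale(self):
        # 2*2.134/sqrt(1100) ~ 0.129: the d scale that pairs with this t
        assert effect_size(-8.368, -2.134, 1100) == pytest.approx(-0.129, abs=1e-3)

    def test_quadrupling_df_halves_d(self):
        assert effect_size(1.0, 2.0, 400) == pytest.approx(effect_size(1.0, 2.0, 100) / 2)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 1.0, 0.5)


@pytest.fixture(scope="module")
def trial_with_estimates():
    ds = simulate_trial(null_design(n_per_arm=3, missing_day_rate=0.25, seed=21))
    bundle = fit_series_bundle(ds, coarse_filter_config(n=8, cands=1))
    return ds, bundle


class TestLongTable:
    def test_row_counts_match_flags(self, trial_with_estimates):
        ds, bundle = trial_with_estimates
        table = build_long_table(ds, bundle)
        pid = int(ds.days["id"].iloc[0])
        n_valid = int(ds.days[(ds.days["id"] == pid) & ds.days["valid"]].shape[0])
        sub = table[table["id"] == pid]
        assert len(sub[(sub["role"] == "volatility") & (sub["source"] == "level")]) == 43 * 2
        assert len(sub[sub["role"] == "level"]) == n_valid * 2
        assert len(sub[sub["role"] == "noise"]) == 43 * 4  # level + onset tracks

    def test_without_estimates_only_observed_rows(self, trial_with_estimates):
        ds, _ = trial_with_estimates
        table = build_long_table(ds, None)
        assert set(table["role"]) == {"level", "onset"}
        assert table["pa_volatility"].isna().all()

    def test_deterministic_row_order(self, trial_with_estimates):
        ds, bundle = trial_with_estimates
        a = build_long_table(ds, bundle)
        b = build_long_table(ds, bundle)
        pd.testing.assert_frame_equal(a, b)


class TestMixedModels:
    def test_symmetric_effect_has_null_contrast(self):
        # apply the same level shift to BOTH arms: group x phase must vanish
        ds = simulate_trial(null_design(n_per_arm=10, missing_day_rate=0.1, seed=32))
        shift = ds.days["day"].between(15, 28) * 10.0
        ds.days["m10"] = ds.days["m10"] + shift
        fit = fit_activity_model(build_long_table(ds))
        for r in fit.contrasts.itertuples():
            assert abs(r.B) < 2 * r.se

    def test_injected_effect_recovered_with_sign(self):
        design = null_design(
            n_per_arm=12, missing_day_rate=0.1,
            effect_m10_by_week={3: -0.2, 4: -0.2}, seed=77,
        )
        fit = fit_activity_model(build_long_table(simulate_trial(design)))
        wk4 = fit.contrasts[fit.contrasts["term"] == "lithium:week4"].iloc[0]
        assert wk4["B"] < 0 and wk4["p"] < 0.05
        recs = fit.effect_estimates()
        assert len(recs) == 4 and all(np.sign(r.d) == np.sign(r.B) for r in recs)
        wk1 = fit.contrasts[fit.contrasts["term"] == "lithium:week1"].iloc[0]
        assert abs(wk1["B"]) < 3 * wk1["se"]

    def test_fit_invariant_to_row_shuffling(self):
        ds = simulate_trial(null_design(n_per_arm=5, missing_day_rate=0.0, seed=13))
        table = build_long_table(ds)
        a = fit_activity_model(table)
        b = fit_activity_model(table.sample(frac=1.0, random_state=0))
        assert np.allclose(a.contrasts["B"], b.contrasts["B"], atol=1e-8)

    def test_variability_recovery(self):
        # an injected log-volatility shift on the lithium arm is detected
        # with the right sign in the filter-derived variability model; the
        # shift must be large relative to the filter's estimation noise
        # because clustered inference draws power from participants, not days
        hits = 0
        reps = 10
        for rep in range(reps):
            design = null_design(
                n_per_arm=16, missing_day_rate=0.1,
                effect_volatility_by_week={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
                seed=950 + rep,
            )
            ds = simulate_trial(design)
            bundle = fit_series_bundle(
                ds, coarse_filter_config(n=20, cands=3), measures=("m10", "l5")
            )
            fit = fit_variability_model(build_long_table(ds, bundle))
            wk = fit.contrasts[fit.contrasts["term"] == "lithium:week4"].iloc[0]
            if wk["B"] > 0 and wk["p"] < 0.05:
                hits += 1
        assert hits >= int(0.8 * reps)

    def test_rhythm_model_single_period_rejected(self):
        ds = simulate_trial(null_design(n_per_arm=4, missing_day_rate=0.0, seed=3))
        rows = []
        for r in ds.participants.itertuples():
            rows.append({"id": r.id, "arm": r.arm, "phase": "run-in", "ra": 0.8,
                         "age": r.age, "sex": r.sex, "season_of_intake": r.season_of_intake})
        with pytest.raises(ValueError, match="single period"):
            fit_rhythm_model(pd.DataFrame(rows), "ra")

    def test_rhythm_is_effect_detected(self):
        hits = 0
        reps = 6
        for rep in range(reps):
            design = null_design(
                n_per_arm=12, missing_day_rate=0.1,
                effect_is_by_week={3: -0.8, 4: -0.8},  # calmer hours: higher IS
                seed=700 + rep,
            )
            ds = simulate_trial(design)
            hourly = hourly_activity(ds, seed=100 + rep)
            from circavol import metrics as cm

            rows = []
            for r in ds.participants.itertuples():
                sub = ds.days[(ds.days["id"] == r.id) & ds.days["valid"]]
                hp = hourly[hourly["id"] == r.id]
                for period in PHASES:
                    days = [
                        cm.CircadianDay(day=int(x.day), valid=True, m10_amount=x.m10,
                                        m10_onset=x.m10_onset, l5_amount=x.l5, l5_onset=x.l5_onset)
                        for x in sub.itertuples() if assign_phase(int(x.day)) == period
                    ]
                    hsub = hp[hp["day"].isin([d.day for d in days])].sort_values(["day", "hour"])
                    st = cm.summarize_period(days, period, hsub["activity"].to_numpy())
                    rows.append({"id": r.id, "arm": r.arm, "phase": period,
                                 "is_": st.interdaily_stability, "age": r.age,
                                 "sex": r.sex, "season_of_intake": r.season_of_intake})
            fit = fit_rhythm_model(pd.DataFrame(rows), "is")
            wk = fit.contrasts[fit.contrasts["term"] == "lithium:week4"].iloc[0]
            if wk["B"] > 0 and wk["p"] < 0.05:
                hits += 1
        assert hits >= int(0.8 * reps)


class TestCorrelations:
    def test_identical_variables_give_unit_beta(self):
        df = pd.DataFrame({"id": np.repeat([1, 2, 3], 10), "a": np.random.default_rng(0).normal(size=30)})
        df["b"] = df["a"]
        out = within_subject_correlation(df, "a", "b")
        assert out.beta == 1.0 and out.degenerate

    def test_independent_variables_give_null_beta(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            df = pd.DataFrame({
                "id": np.repeat(np.arange(20), 30),
                "a": rng.normal(size=600),
                "b": rng.normal(size=600),
            })
            out = within_subject_correlation(df, "a", "b")
            if abs(out.beta) < 2 * out.se:
                hits += 1
        assert hits >= 18  # ~95% coverage of a 2 SE band

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"id": [1, 1, 2, 2], "a": [1, 2, 3, 4], "b": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError):
            within_subject_correlation(df, "a", "b")


class TestChangeScores:
    @staticmethod
    def delta_table(deltas_a, deltas_b):
        rows = []
        for i, (da, db) in enumerate(zip(deltas_a, deltas_b)):
            for phase, off_a, off_b in (("run-in", 0.0, 0.0), ("week4", da, db)):
                for d in range(3):
                    rows.append({"id": i, "activity_type": "M10", "role": "level",
                                 "phase": phase, "value": 10.0 + off_a})
                    rows.append({"id": i, "activity_type": "M10", "role": "volatility",
                                 "phase": phase, "value": -1.0 + off_b})
        return pd.DataFrame(rows)

    def test_proportional_deltas_give_unit_r(self, rng):
        da = rng.normal(size=12)
        table = self.delta_table(da, 2 * da)
        out = change_score_correlation(table, "M10.level", "M10.volatility")
        assert out["r"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_residual_residual_brute_force(self, rng):
        n = 15
        da, db = rng.normal(size=n), rng.normal(size=n)
        cov = pd.DataFrame({"id": np.arange(n), "age": rng.normal(40, 10, n),
                            "sex": rng.choice(["F", "M"], n)})
        table = self.delta_table(da, db)
        out = change_score_correlation(table, "M10.level", "M10.volatility", cov)
        # oracle: correlate OLS residuals of each delta on the covariates
        X = np.column_stack([np.ones(n), cov["age"], (cov["sex"] == "M").astype(float)])
        ra = da - X @ np.linalg.lstsq(X, da, rcond=None)[0]
        rb = db - X @ np.linalg.lstsq(X, db, rcond=None)[0]
        expected = np.corrcoef(ra, rb)[0, 1]
        assert out["r"] == pytest.approx(expected, abs=1e-6)

    def test_too_few_participants_rejected(self, rng):
        table = self.delta_table(rng.normal(size=3), rng.normal(size=3))
        with pytest.raises(ValueError):
            change_score_correlation(table, "M10.level", "M10.volatility")
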