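"""Selection resolution, preference map, cost prediction, conflict split."""

import numpy as np
import pandas as pd
import pytest

from saccost import preference
from saccost.preference import (
    apply_curvature_exclusions,
    build_preference_map,
    min_angle_deg,
    predict_choice_by_cost,
    prediction_accuracy,
    resolve_selection,
    split_preferred_avoided,
)
from saccost.simulate import CostProfile, SimulationConfig, cost_map_truth


def target(d, ecc=10.0):
    th = np.deg2rad(d)
    return ecc * np.array([np.cos(th), np.sin(th)])


class TestResolveSelection:
    def test_gaze_on_target_selects_it(self):
        which, diff = resolve_selection(tuple(target(0)), target(0), target(90))
        assert which == "a" and diff >= 1.5

    def test_small_distance_difference_excluded(self):
        # d_A = 5, d_B = 6 -> difference 1 deg < 1.5 -> ambiguous
        a = np.array([5.0, 0.0])
        b = np.array([-6.0, 0.0])
        which, diff = resolve_selection((0.0, 0.0), a, b)
        assert which is None and diff == pytest.approx(1.0)

    def test_boundary_difference_kept(self):
        a = np.array([1.0, 0.0])
        b = np.array([-2.5, 0.0])
        which, diff = resolve_selection((0.0, 0.0), a, b)
        assert which == "a" and diff == pytest.approx(1.5)


def make_pref_trial(**overrides):
    row = dict(
        participant=1, session=1, trial=0, dir_a=0.0, dir_b=90.0, pair_angle=90.0,
        selected_deg=0.0, resolved=True, distance_diff=5.0,
        latency_ms=250.0, duration_ms=45.0, amplitude_deg=10.0, peak_velocity=400.0,
        peak_deviation=0.3, curve_class="away", has_saccade=True,
    )
    row.update(overrides)
    return row


class TestPreferenceMap:
    def test_ratio_arithmetic(self):
        rows = []
        for i in range(10):
            rows.append(
                make_pref_trial(trial=i, selected_deg=0.0 if i < 5 else 90.0)
            )
        pm = build_preference_map(pd.DataFrame(rows))
        assert pm.group.loc[0.0] == pytest.approx(0.5)
        assert pm.group.loc[90.0] == pytest.approx(0.5)

    def test_deterministic_choice_gives_one(self):
        rows = [make_pref_trial(trial=i, selected_deg=0.0) for i in range(6)]
        pm = build_preference_map(pd.DataFrame(rows))
        assert pm.group.loc[0.0] == 1.0
        assert pm.group.loc[90.0] == 0.0

    def test_selected_counts_conserved(self):
        rng = np.random.default_rng(2)
        rows = [
            make_pref_trial(
                trial=i,
                dir_a=float(rng.integers(36) * 10),
                dir_b=float(rng.integers(36) * 10),
            )
            for i in range(50)
        ]
        df = pd.DataFrame(rows)
        df = df[df.dir_a != df.dir_b].reset_index(drop=True)
        df["selected_deg"] = np.where(np.arange(len(df)) % 2 == 0, df.dir_a, df.dir_b)
        pm = build_preference_map(df)
        offered = pd.concat([df.groupby("dir_a").size(), df.groupby("dir_b").size()])
        offered = offered.groupby(level=0).sum()
        selected = (pm.per_participant.iloc[0] * offered.reindex(pm.per_participant.columns)).dropna()
        assert selected.sum() == pytest.approx(len(df))

    def test_softmax_session_matches_analytic_probabilities(self, profile):
        cfg = SimulationConfig(
            n_participants=1, n_sessions=1, trials_per_session=3000, seed=17
        )
        from saccost.simulate import simulate_preference_session

        _, _, truth = simulate_preference_session(cfg, profile, 1, 1)
        df = truth.rename(columns={"chosen_deg": "selected_deg"}).assign(resolved=True)
        pm = build_preference_map(df)
        # analytic per-direction expectation: average P(selected) over the
        # offered pairs that actually occurred
        for d in (0.0, 40.0, 90.0):
            mask_a = df.dir_a == d
            mask_b = df.dir_b == d
            p = np.concatenate(
                [df.loc[mask_a, "p_choose_a"], 1.0 - df.loc[mask_b, "p_choose_a"]]
            )
            n = len(p)
            se = np.sqrt((p * (1 - p)).sum()) / n
            assert abs(pm.group.loc[d] - p.mean()) <= 3.5 * se


class TestSplitPreferredAvoided:
    def test_simple_split(self):
        m = pd.Series({0.0: 0.6, 90.0: 0.4})
        pref, avoid = split_preferred_avoided(m)
        assert pref == [0.0] and avoid == [90.0]

    def test_exact_half_in_neither(self):
        m = pd.Series({0.0: 0.5, 90.0: 0.5})
        pref, avoid = split_preferred_avoided(m)
        assert pref == [] and avoid == []

    def test_preferred_cheaper_than_avoided_on_synthetic_map(self, profile):
        truth = cost_map_truth(profile)
        # construct a map that mirrors the softmax ordering
        m = pd.Series(0.5 - (truth - truth.mean()), index=truth.index)
        pref, avoid = split_preferred_avoided(m)
        assert truth.loc[pref].mean() < truth.loc[avoid].mean()


class TestPredictChoice:
    def test_lower_cost_option_predicted(self, profile):
        cmap = cost_map_truth(profile)
        row = {"dir_a": 0.0, "dir_b": 40.0}
        assert predict_choice_by_cost(row, cmap) == 0.0

    def test_antisymmetry_under_pair_swap(self, profile):
        cmap = cost_map_truth(profile)
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.choice(np.arange(0, 360, 10), 2, replace=False)
            row = {"dir_a": float(a), "dir_b": float(b)}
            swapped = {"dir_a": float(b), "dir_b": float(a)}
            assert predict_choice_by_cost(row, cmap) == predict_choice_by_cost(swapped, cmap)

    def test_missing_bin_and_tie_skipped(self):
        cmap = pd.Series({0.0: 0.1, 40.0: 0.1, 90.0: np.nan})
        assert predict_choice_by_cost({"dir_a": 0.0, "dir_b": 40.0}, cmap) is None
        assert predict_choice_by_cost({"dir_a": 0.0, "dir_b": 90.0}, cmap) is None

    def test_random_choices_hover_at_chance(self, profile):
        # near-infinite temperature: choices ignore cost
        cfg = SimulationConfig(
            n_participants=5, n_sessions=1, trials_per_session=200,
            choice_temperature=1e9, seed=23,
        )
        from saccost.simulate import simulate_preference_study

        frames = [t for _, _, t in simulate_preference_study(cfg, profile)]
        df = pd.concat(frames).rename(columns={"chosen_deg": "selected_deg"})
        df["resolved"] = True
        acc, test, counts = prediction_accuracy(df, cost_map_truth(profile))
        assert test.p > 0.01
        assert abs(acc.mean() - 0.5) < 0.05


class TestCurvatureExclusions:
    @pytest.mark.parametrize(
        "overrides, excluded",
        [
            ({"pair_angle": 160.0}, True),
            ({"pair_angle": 150.0}, False),
            ({"latency_ms": 160.0}, True),
            ({"amplitude_deg": 4.0}, True),
            ({"duration_ms": 5.0}, True),
            ({"duration_ms": 120.0}, True),
            ({"resolved": False, "selected_deg": np.nan}, True),
            ({}, False),
        ],
    )
    def test_criteria(self, overrides, excluded):
        out = apply_curvature_exclusions(pd.DataFrame([make_pref_trial(**overrides)]))
        assert bool(out["curvature_included"].iloc[0]) == (not excluded)

    def test_toy_counts_match_enumeration(self):
        rows = [
            make_pref_trial(trial=0),
            make_pref_trial(trial=1, latency_ms=100.0),
            make_pref_trial(trial=2, pair_angle=170.0),
            make_pref_trial(trial=3, amplitude_deg=2.0),
        ]
        out = apply_curvature_exclusions(pd.DataFrame(rows))
        assert out["curvature_included"].sum() == 1
        rep = out.attrs["curvature_report"]
        assert rep["fast_latency"] == 1
        assert rep["pair_angle"] == 1
        assert rep["small_amplitude"] == 1


@pytest.fixture(scope="module")
def study(profile):
    cfg = SimulationConfig(n_participants=6, n_sessions=1, trials_per_session=250, seed=31)
    return preference.run_preference_pipeline(cfg, profile)


class TestConflictAnalysis:
    def test_injected_deviation_slope_recovered(self, study, profile):
        res = preference.conflict_analysis(study, cost_map_truth(profile))
        assert res.model.beta("peak_dev") > 0
        assert res.model.p("peak_dev") < 0.001

    def test_mostly_away_curvature(self, study, profile):
        res = preference.conflict_analysis(study, cost_map_truth(profile))
        assert res.pct_away > 50.0

    def test_cost_independent_curvature_gives_null_slope(self, profile):
        # flat profile: |dcost| = 0 against the truth map is degenerate, so
        # instead decouple curvature from cost with zero curvature gain
        cfg = SimulationConfig(
            n_participants=6, n_sessions=1, trials_per_session=200,
            curvature_gain=0.0, seed=37,
        )
        trials = preference.run_preference_pipeline(cfg, profile)
        res = preference.conflict_analysis(trials, cost_map_truth(profile))
        assert res.model.p("peak_dev") > 0.01
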