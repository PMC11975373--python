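"""Exclusion cascade, cost window, cost map, direction-predictor model."""

import numpy as np
import pandas as pd
import pytest

from saccost import planning
from saccost.planning import (
    apply_planning_exclusions,
    build_cost_map,
    cost_window_mean,
    direction_predictors,
    extract_planning_trials,
    fit_planning_model,
)
from saccost.simulate import CostProfile, cost_map_truth, simulate_planning_session


def make_trial(**overrides):
    row = dict(
        participant=1, session=1, trial=0, cued_deg=0.0, is_practice=False,
        latency_ms=300.0, duration_ms=45.0, amplitude_deg=9.8,
        landing_error_deg=0.5, wrong_target=False, has_saccade=True,
        cost_raw=0.1, cost_window_ok=True, peak_velocity=400.0,
    )
    row.update(overrides)
    return row


class TestExclusions:
    @pytest.mark.parametrize(
        "overrides, reason",
        [
            ({"latency_ms": 600.0}, "slow_latency"),
            ({"latency_ms": 150.0}, "fast_latency"),
            ({"duration_ms": 5.0}, "short_duration"),
            ({"duration_ms": 120.0}, "long_duration"),
            ({"amplitude_deg": 4.0}, "small_amplitude"),
            ({"landing_error_deg": 2.5}, "landing_error"),
            ({"wrong_target": True}, "wrong_target"),
            ({"is_practice": True}, "practice"),
            ({}, ""),  # all bounds satisfied -> included
        ],
    )
    def test_single_criterion_attribution(self, overrides, reason):
        trials = pd.DataFrame([make_trial(**overrides)])
        out, report = apply_planning_exclusions(trials)
        assert out["included"].iloc[0] == (reason == "")
        assert out["exclusion_reason"].iloc[0] == reason

    def test_toy_set_report_sums(self):
        rows = [make_trial(trial=i) for i in range(8)]
        rows.append(make_trial(trial=8, latency_ms=600.0))
        rows.append(make_trial(trial=9, amplitude_deg=3.0))
        out, report = apply_planning_exclusions(pd.DataFrame(rows))
        assert report.attrs["n_excluded"] == 2
        assert report.attrs["pct_excluded_all"] == pytest.approx(20.0)
        assert report["n_excluded"].sum() == report.attrs["n_excluded"]

    def test_conservation(self):
        rows = [make_trial(trial=i, latency_ms=100.0 + 100 * i) for i in range(6)]
        out, report = apply_planning_exclusions(pd.DataFrame(rows))
        assert out["included"].sum() + report.attrs["n_excluded"] == len(out)

    def test_first_firing_criterion_wins(self):
        # fast latency is listed before small amplitude
        trials = pd.DataFrame([make_trial(latency_ms=100.0, amplitude_deg=3.0)])
        out, _ = apply_planning_exclusions(trials)
        assert out["exclusion_reason"].iloc[0] == "fast_latency"


class TestCostWindow:
    def test_constant_trace(self):
        t = np.arange(0, 2000, 10.0)
        assert cost_window_mean(t, np.full(len(t), 0.4), 1000.0) == pytest.approx(0.4)

    def test_linear_ramp_mean(self):
        t = np.arange(0, 2000, 10.0)
        # 0 at window start (850) to 0.32 at window end (1170)
        trace = (t - 850.0) / 320.0 * 0.32
        assert cost_window_mean(t, trace, 1000.0) == pytest.approx(0.155, abs=0.01)

    def test_equals_direct_summation_over_32_samples(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 2000, 10.0)
        trace = rng.normal(size=len(t))
        mask = (t >= 850.0) & (t < 1170.0)
        assert mask.sum() == 32
        assert cost_window_mean(t, trace, 1000.0) == pytest.approx(
            trace[mask].sum() / 32
        )

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            cost_window_mean(np.arange(0, 100, 10.0), np.ones(10), 1000.0)


class TestDirectionPredictors:
    @pytest.mark.parametrize(
        "direction, o, v, h",
        [
            (0, 0, 0.0, 1.0),
            (270, 0, -1.0, 0.0),
            (130, 4, np.sin(np.deg2rad(130)), np.cos(np.deg2rad(130))),
            (90, 0, 1.0, 0.0),
            (220, 4, np.sin(np.deg2rad(220)), np.cos(np.deg2rad(220))),
        ],
    )
    def test_values(self, direction, o, v, h):
        p = direction_predictors(direction)
        assert p.oblique == o
        assert p.vertical == pytest.approx(v, abs=1e-12)
        assert p.horizontal == pytest.approx(h, abs=1e-12)
        assert p.vertical**2 + p.horizontal**2 == pytest.approx(1.0)

    def test_non_bin_rejected(self):
        with pytest.raises(ValueError):
            direction_predictors(5)


def _included_trials(n_per_dir=4, participants=(1, 2), rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    rows = []
    for p in participants:
        for d in range(0, 360, 10):
            for k in range(n_per_dir):
                rows.append(
                    make_trial(
                        participant=p, session=1, trial=len(rows), cued_deg=float(d),
                        cost_raw=rng.normal(0.01 * d, 1.0),
                    )
                )
    t = pd.DataFrame(rows)
    t["included"] = True
    return t


class TestCostMap:
    def test_constant_cost_samples_rejected_as_zero_variance(self):
        t = _included_trials()
        t["cost_raw"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            build_cost_map(t)

    def test_antisymmetric_participants_cancel(self):
        t = _included_trials(participants=(1, 2))
        # force participant 2's z-map to be the negative of participant 1's
        sub = t[t.participant == 1]
        mirrored = sub.copy()
        mirrored["participant"] = 2
        mirrored["cost_raw"] = -sub["cost_raw"].to_numpy()
        t = pd.concat([sub, mirrored], ignore_index=True)
        cmap = build_cost_map(t)
        assert np.allclose(cmap.group.to_numpy(), 0.0, atol=1e-12)

    def test_invariant_to_trial_and_participant_order(self):
        t = _included_trials()
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = build_cost_map(t)
        b = build_cost_map(shuffled)
        pd.testing.assert_series_equal(a.group, b.group)

    def test_empty_bins_stay_missing(self):
        t = _included_trials()
        t = t[t.cued_deg != 90.0]
        cmap = build_cost_map(t)
        assert np.isnan(cmap.group.loc[90.0])
        assert cmap.group.drop(90.0).notna().all()


def test_cost_map_recovery_from_synthetic_session(profile):
    """A modest synthetic study recovers the ground-truth anisotropy."""
    from saccost.simulate import SimulationConfig

    cfg = SimulationConfig(n_participants=3, n_sessions=1, trials_per_session=180, seed=9)
    trials, report, cmap = planning.run_planning_pipeline(cfg, profile)
    truth = cost_map_truth(profile)
    r = np.corrcoef(cmap.group.reindex(truth.index), truth)[0, 1]
    assert r > 0.85


@pytest.fixture(scope="module")
def fitted(profile):
    from saccost.simulate import SimulationConfig

    cfg = SimulationConfig(n_participants=6, n_sessions=1, trials_per_session=144, seed=13)
    trials, _, _ = planning.run_planning_pipeline(cfg, profile)
    return fit_planning_model(trials)


class TestPlanningModel:
    def test_oblique_effect_recovered(self, fitted):
        assert fitted.beta("oblique") > 0
        assert fitted.p("oblique") < 0.001

    def test_vertical_and_horizontal_signs(self, fitted):
        # c_down > 0: cost falls with upward (sin) component
        assert fitted.beta("vertical") < 0
        # c_left > 0: cost falls with rightward (cos) component
        assert fitted.beta("horizontal") < 0

    def test_response_scaling_doubles_betas(self, profile):
        from saccost.simulate import SimulationConfig

        cfg = SimulationConfig(n_participants=2, n_sessions=1, trials_per_session=72, seed=21)
        trials, _, _ = planning.run_planning_pipeline(cfg, profile)
        inc = trials[trials.included].copy()
        from saccost.preprocess import zscore_by_group

        inc["cost_z"] = zscore_by_group(inc.cost_raw, [inc.participant, inc.session])
        doubled = inc.copy()
        doubled["cost_z"] = 2.0 * doubled["cost_z"]
        f1 = fit_planning_model(inc)
        f2 = fit_planning_model(doubled)
        # REML refits from scratch, so tolerance covers optimizer noise on
        # the well-conditioned direction terms
        for term in ("oblique", "vertical", "horizontal"):
            assert f2.beta(term) == pytest.approx(2.0 * f1.beta(term), rel=0.05)


def test_parameter_recovery_sign_across_replicates(profile):
    """The oblique weight's sign is recovered in (nearly) every replicate."""
    from saccost.simulate import SimulationConfig

    correct = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimulationConfig(
            n_participants=1, n_sessions=1, trials_per_session=72, seed=100 + rep
        )
        trials, _, cmap = planning.run_planning_pipeline(cfg, profile)
        m = cmap.group.dropna()
        obl = np.array([planning.direction_predictors(d).oblique for d in m.index])
        if np.corrcoef(m.to_numpy(), obl)[0, 1] > 0:
            correct += 1
    assert correct >= 19
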