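"""Binary-choice task: selection, preference map, prediction, conflict.

Which of the two offered targets was selected is resolved from the mean
gaze position over the last 50 ms of the trial: the nearer option wins,
and the trial is discarded when the two gaze-to-option distances differ
by less than 1.5 deg. The preference map divides per-direction selected
counts by offered counts. Trial-by-trial prediction takes the lower-cost
option from the planning-task group cost map and scores it against the
actual selection; the conflict analysis relates the absolute cost
difference to signed saccade curvature and latency and splits prediction
accuracy by curve direction (toward/away from the non-selected option).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oculomotor
from .planning import CostMap
from .recording import GazeRecording
from .stats import EffectReport, LmmFit, fit_lmm, one_sample_t, paired_t

MIN_DISTANCE_DIFF_DEG = 1.5  # selection-resolution rule
TERMINAL_WINDOW_MS = 50.0
MIN_PAIR_ANGLE_DEG = 20.0
MAX_PAIR_ANGLE_DEG = 150.0  # curvature-analysis exclusion

# shared with the planning cascade
CURV_LATENCY_FAST_MS = 175.0
CURV_MIN_AMPLITUDE_DEG = 5.0
CURV_DURATION_SHORT_MS = 10.0
CURV_DURATION_LONG_MS = 110.0


def min_angle_deg(a: float, b: float) -> float:
    """Minimal absolute angular difference on the circle, deg."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def resolve_selection(
    gaze_xy: tuple[float, float],
    option_a_xy: np.ndarray,
    option_b_xy: np.ndarray,
) -> tuple[str | None, float]:
    """Nearer option to the terminal gaze position, or None when ambiguous.

    Returns ``(selected, distance_difference)`` where ``selected`` is
    "a", "b", or None when |d_A - d_B| < 1.5 deg (a boundary difference
    of exactly 1.5 deg is kept, per the strict "<" rule).
    """
    g = np.asarray(gaze_xy, dtype=float)
    d_a = float(np.linalg.norm(g - option_a_xy))
    d_b = float(np.linalg.norm(g - option_b_xy))
    diff = abs(d_a - d_b)
    if diff < MIN_DISTANCE_DIFF_DEG:
        return None, diff
    return ("a" if d_a < d_b else "b"), diff


def extract_preference_trials(
    recording: GazeRecording,
    events: pd.DataFrame,
    eccentricity: float = 10.0,
) -> pd.DataFrame:
    """One session's recording + events -> per-trial preference table.

    Detects the primary saccade (first detection after target onset),
    resolves the selection from the terminal 50 ms of gaze, and computes
    signed curvature of the primary saccade relative to the non-selected
    option. Latency is referenced to target onset.
    """
    saccades = oculomotor.detect_saccades(recording)
    onsets = np.array([s.onset for s in saccades])
    wide = events.pivot_table(
        index=["participant", "session", "trial"], columns="event", values="t_ms", aggfunc="first"
    ).reset_index()
    payloads = events.set_index(["participant", "session", "trial", "event"])["payload"]

    def target_xy(d):
        th = np.deg2rad(d)
        return eccentricity * np.array([np.cos(th), np.sin(th)])

    rows = []
    for rec_tuple in wide.itertuples(index=False):
        row = rec_tuple._asdict()
        p, s, tr = row["participant"], row["session"], row["trial"]
        targets_on, trial_end = row["targets_on"], row["trial_end"]
        dir_a, dir_b = [float(v) for v in ast.literal_eval(str(payloads[(p, s, tr, "targets_on")]))]
        pos_a, pos_b = target_xy(dir_a), target_xy(dir_b)

        out = dict(participant=p, session=s, trial=tr, dir_a=dir_a, dir_b=dir_b,
                   pair_angle=min_angle_deg(dir_a, dir_b))
        # terminal gaze: mean over the last 50 ms before trial end
        lo = recording.index_at(trial_end - TERMINAL_WINDOW_MS)
        hi = recording.index_at(trial_end)
        if hi - lo < 2:
            out.update(selected_deg=np.nan, resolved=False, distance_diff=np.nan)
        else:
            gaze = (recording.x[lo:hi].mean(), recording.y[lo:hi].mean())
            which, diff = resolve_selection(gaze, pos_a, pos_b)
            out.update(
                selected_deg=(dir_a if which == "a" else dir_b) if which else np.nan,
                resolved=which is not None,
                distance_diff=diff,
            )
        k = np.searchsorted(onsets, targets_on)
        sac = saccades[k] if k < len(saccades) and onsets[k] < trial_end else None
        if sac is None:
            out.update(latency_ms=np.nan, duration_ms=np.nan, amplitude_deg=np.nan,
                       peak_velocity=np.nan, peak_deviation=np.nan, curve_class=None,
                       has_saccade=False)
        else:
            out.update(
                latency_ms=sac.onset - targets_on,
                duration_ms=sac.duration,
                amplitude_deg=sac.amplitude,
                peak_velocity=sac.peak_velocity,
                has_saccade=True,
            )
            nonselected = None
            if out["resolved"]:
                nonselected = pos_b if out["selected_deg"] == dir_a else pos_a
            if nonselected is not None and sac.trajectory.shape[0] >= 3 and sac.amplitude > 0:
                try:
                    curv = oculomotor.signed_curvature(sac, tuple(nonselected))
                    out.update(peak_deviation=curv.peak_deviation, curve_class=curv.direction_class)
                except ValueError:
                    out.update(peak_deviation=np.nan, curve_class=None)
            else:
                out.update(peak_deviation=np.nan, curve_class=None)
        rows.append(out)
    return pd.DataFrame(rows)


@dataclass
class PreferenceMap:
    """Per-direction selection proportion (selected / offered), in [0, 1]."""

    per_participant: pd.DataFrame  # participants x directions
    group: pd.Series  # unweighted mean over participants


def build_preference_map(trials: pd.DataFrame) -> PreferenceMap:
    """Resolved trials -> participant and group preference maps.

    Per participant and direction: times selected / times offered (each
    resolved trial offers two directions and selects one). The group map
    is the unweighted mean of participant maps; never-offered directions
    stay missing.
    """
    res = trials[trials["resolved"].astype(bool)]
    if res.empty:
        raise ValueError("no resolved trials")
    offered = pd.concat(
        [
            res[["participant", "dir_a"]].rename(columns={"dir_a": "direction"}),
            res[["participant", "dir_b"]].rename(columns={"dir_b": "direction"}),
        ]
    )
    n_offered = offered.groupby(["participant", "direction"]).size()
    n_selected = res.groupby(["participant", "selected_deg"]).size()
    n_selected.index = n_selected.index.set_names(["participant", "direction"])
    ratio = (n_selected.reindex(n_offered.index, fill_value=0) / n_offered).rename("preference")
    per = ratio.unstack("direction")
    per.columns.name = "direction_deg"
    group = per.mean(axis=0, skipna=True)
    group.name = "preference"
    return PreferenceMap(per_participant=per, group=group)


def split_preferred_avoided(group_map: pd.Series) -> tuple[list[float], list[float]]:
    """Strictly >50% chosen -> preferred; <50% -> avoided; 50% -> neither."""
    preferred = group_map.index[group_map > 0.5].tolist()
    avoided = group_map.index[group_map < 0.5].tolist()
    return preferred, avoided


def predict_choice_by_cost(trial_row, cost_map_group: pd.Series) -> float | None:
    """Lower-cost option per the group cost map; None on missing bin/tie."""
    c_a = cost_map_group.get(trial_row["dir_a"], np.nan)
    c_b = cost_map_group.get(trial_row["dir_b"], np.nan)
    if np.isnan(c_a) or np.isnan(c_b) or c_a == c_b:
        return None
    return trial_row["dir_a"] if c_a < c_b else trial_row["dir_b"]


def prediction_accuracy(
    trials: pd.DataFrame, cost_map: CostMap | pd.Series
) -> tuple[pd.Series, EffectReport, dict]:
    """Per-participant % of resolved trials where the lower-cost option won.

    Returns (per-participant accuracy, one-sample t vs chance 50%,
    bookkeeping counts). Trials with a missing cost bin or a cost tie
    are skipped and counted; accuracies are reported on the scored
    denominator (counts expose both denominators).
    """
    group_map = cost_map.group if isinstance(cost_map, CostMap) else cost_map
    res = trials[trials["resolved"].astype(bool)].copy()
    predicted = res.apply(lambda r: predict_choice_by_cost(r, group_map), axis=1)
    scored = predicted.notna()
    res["correct"] = predicted[scored] == res.loc[scored, "selected_deg"]
    acc = res.loc[scored].groupby("participant")["correct"].mean().astype(float)
    counts = {
        "n_resolved": int(len(res)),
        "n_scored": int(scored.sum()),
        "n_skipped_cost": int((~scored).sum()),
    }
    test = one_sample_t(acc.to_numpy(), 0.5, name="prediction_vs_chance")
    return acc, test, counts


def apply_curvature_exclusions(trials: pd.DataFrame) -> pd.DataFrame:
    """Any-criterion exclusion cascade for the curvature analyses.

    Excludes trials with latency < 175 ms, amplitude < 5 deg, duration
    outside [10, 110] ms, or a pair angle exceeding 150 deg; unresolved
    selections and ambiguous (exactly straight) trajectories cannot enter
    the toward/away split either. Adds ``curvature_included`` plus a
    per-criterion report in ``DataFrame.attrs['curvature_report']``.
    """
    t = trials.copy()
    criteria = {
        "fast_latency": t["latency_ms"] < CURV_LATENCY_FAST_MS,
        "small_amplitude": t["amplitude_deg"] < CURV_MIN_AMPLITUDE_DEG,
        "short_duration": t["duration_ms"] < CURV_DURATION_SHORT_MS,
        "long_duration": t["duration_ms"] > CURV_DURATION_LONG_MS,
        "pair_angle": t["pair_angle"] > MAX_PAIR_ANGLE_DEG,
        "unresolved": ~t["resolved"].astype(bool),
        "ambiguous_curvature": t["curve_class"].isna() & t["resolved"].astype(bool),
    }
    excluded = pd.Series(False, index=t.index)
    report = {}
    for name, fires in criteria.items():
        fires = fires.fillna(True) if name != "pair_angle" else fires.fillna(False)
        report[name] = int((fires & ~excluded).sum())
        excluded |= fires
    t["curvature_included"] = ~excluded
    t.attrs["curvature_report"] = report
    return t


@dataclass
class ConflictAnalysis:
    """Cost-difference model plus curvature-split prediction accuracies."""

    model: LmmFit
    accuracy_away: pd.Series
    accuracy_toward: pd.Series
    away_vs_toward: EffectReport
    pct_away: float  # % of included trials curving away, mean over participants


def conflict_analysis(trials: pd.DataFrame, cost_map: CostMap | pd.Series) -> ConflictAnalysis:
    """|cost difference| ~ peak deviation + latency, and the toward/away split.

    Fits the mixed model on curvature-included trials and computes
    cost-based prediction accuracy separately for away- and toward-
    curving saccades, compared across participants with a paired t-test
    (participants lacking one class are dropped from the paired test).
    """
    group_map = cost_map.group if isinstance(cost_map, CostMap) else cost_map
    inc = trials[trials["curvature_included"].astype(bool)].copy()
    if inc.empty:
        raise ValueError("no curvature-included trials")
    inc["abs_dcost"] = (
        inc["dir_a"].map(group_map).sub(inc["dir_b"].map(group_map)).abs()
    )
    inc = inc.dropna(subset=["abs_dcost", "peak_deviation", "latency_ms"])
    data = inc.rename(columns={"peak_deviation": "peak_dev", "latency_ms": "latency"})
    data["latency"] = (data["latency"] - data["latency"].mean()) / data["latency"].std(ddof=1)
    model = fit_lmm(
        "abs_dcost ~ peak_dev + latency", data, groups="participant", re_formula="~peak_dev"
    )

    accs = {}
    for cls in ("away", "toward"):
        sub = inc[inc["curve_class"] == cls]
        acc, _, _ = (
            prediction_accuracy(sub, group_map)
            if not sub.empty
            else (pd.Series(dtype=float), None, None)
        )
        accs[cls] = acc
    both = accs["away"].index.intersection(accs["toward"].index)
    if len(both) >= 2:
        test = paired_t(
            accs["away"].loc[both].to_numpy(),
            accs["toward"].loc[both].to_numpy(),
            name="away_vs_toward_accuracy",
        )
    else:
        raise ValueError("fewer than 2 participants have both curve classes")
    pct_away = (
        inc.assign(away=inc["curve_class"] == "away")
        .groupby("participant")["away"]
        .mean()
        .mul(100.0)
        .mean()
    )
    return ConflictAnalysis(
        model=model,
        accuracy_away=accs["away"],
        accuracy_toward=accs["toward"],
        away_vs_toward=test,
        pct_away=float(pct_away),
    )


def run_preference_pipeline(config, profile):
    """Simulate and analyze a full preference study; returns the trial table."""
    from .simulate import simulate_preference_study

    frames = []
    for rec, events, _truth in simulate_preference_study(config, profile):
        frames.append(extract_preference_trials(rec, events, eccentricity=config.eccentricity))
    trials = pd.concat(frames, ignore_index=True)
    return apply_curvature_exclusions(trials)
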