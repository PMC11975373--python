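"""Planning task: trial extraction, exclusions, cost map, direction model.

From raw session recordings to the 36-direction saccade-cost map: pupil
traces are blink-interpolated, downsampled to 100 Hz and baseline
corrected per trial (first 250 ms after cue onset); the cost sample is
the mean pupil from 150 ms before until 170 ms after cue offset, before
any saccade onset. Cost samples are z-transformed per participant within
session, averaged per cued direction per participant, and the group map
is the unweighted mean of the participant maps.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oculomotor, preprocess
from .recording import GazeRecording
from .simulate import DIRECTIONS, obliqueness

# Trial exclusion bounds. A trial is excluded when ANY criterion fires;
# the report attributes it to the first firing criterion in this order.
LATENCY_FAST_MS = 175.0
LATENCY_SLOW_MS = 550.0
DURATION_SHORT_MS = 10.0
DURATION_LONG_MS = 110.0
MIN_AMPLITUDE_DEG = 5.0
MAX_LANDING_DEG = 2.0

COST_WINDOW_PRE_MS = 150.0  # before cue offset
COST_WINDOW_POST_MS = 170.0  # after cue offset
BASELINE_MS = 250.0  # after cue onset
DOWNSAMPLE_HZ = 100.0

EXCLUSION_ORDER = [
    "fast_latency",
    "slow_latency",
    "short_duration",
    "long_duration",
    "small_amplitude",
    "landing_error",
    "wrong_target",
    "practice",
    "no_saccade",
]


@dataclass(frozen=True)
class DirectionPredictors:
    """Continuous direction predictors for the cost model.

    obliqueness: distance to the nearest cardinal axis in 10-deg steps
    (0-4); verticalness/horizontalness: unit-vector y/x components of the
    direction (positive = up / right), so V^2 + H^2 = 1.
    """

    oblique: float
    vertical: float
    horizontal: float


def direction_predictors(direction: float) -> DirectionPredictors:
    if direction % 10 != 0 or not (0 <= direction < 360):
        raise ValueError("direction must be a bin direction (multiple of 10)")
    theta = np.deg2rad(direction)
    return DirectionPredictors(
        oblique=obliqueness(direction),
        vertical=float(np.sin(theta)),
        horizontal=float(np.cos(theta)),
    )


def cost_window_mean(
    t: np.ndarray, pupil: np.ndarray, cue_offset: float
) -> float:
    """Mean baseline-corrected pupil over [cue_off - 150, cue_off + 170) ms.

    At 100 Hz this retains 32 samples. The caller must ensure the trace
    is baseline corrected and that the window precedes saccade onset.
    """
    t = np.asarray(t, dtype=float)
    pupil = np.asarray(pupil, dtype=float)
    mask = (t >= cue_offset - COST_WINDOW_PRE_MS) & (t < cue_offset + COST_WINDOW_POST_MS)
    window = pupil[mask]
    window = window[np.isfinite(window)]
    if window.size == 0:
        raise ValueError("cost window not covered by the trace")
    return float(window.mean())


def _trial_events(events: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long event log to one row per trial."""
    wide = events.pivot_table(
        index=["participant", "session", "trial"],
        columns="event",
        values="t_ms",
        aggfunc="first",
    ).reset_index()
    payloads = events.set_index(["participant", "session", "trial", "event"])["payload"]
    return wide, payloads


def extract_planning_trials(
    recording: GazeRecording,
    events: pd.DataFrame,
    eccentricity: float = 10.0,
    practice_trials: int = 0,
) -> pd.DataFrame:
    """One session's recording + event log -> per-trial measures table.

    Runs the full preprocessing chain (blink interpolation, 100 Hz
    downsampling, per-trial baseline correction) plus saccade detection,
    then assembles latency, kinematics, landing error, target identity
    and the raw (not yet z-scored) cost sample for every trial.
    """
    blinks = preprocess.detect_blinks(recording)
    clean = preprocess.interpolate_blinks(recording, blinks)
    low = preprocess.downsample(clean, DOWNSAMPLE_HZ)
    saccades = oculomotor.detect_saccades(clean)
    onsets = np.array([s.onset for s in saccades])

    wide, payloads = _trial_events(events)
    rows = []
    for rec_tuple in wide.itertuples(index=False):
        row = rec_tuple._asdict()
        p, s, tr = row["participant"], row["session"], row["trial"]
        cue_on, cue_off = row["cue_on"], row["cue_off"]
        trial_end = row["trial_end"]
        cued = float(ast.literal_eval(str(payloads[(p, s, tr, "cue_on")])))
        offered = [float(v) for v in ast.literal_eval(str(payloads[(p, s, tr, "targets_on")]))]

        out = dict(
            participant=p, session=s, trial=tr, cued_deg=cued,
            is_practice=tr < practice_trials,
        )
        # primary saccade: first detected saccade after targets onset
        k = np.searchsorted(onsets, row["targets_on"])
        sac = saccades[k] if k < len(saccades) and onsets[k] < trial_end else None
        if sac is None:
            out.update(
                latency_ms=np.nan, duration_ms=np.nan, amplitude_deg=np.nan,
                peak_velocity=np.nan, landing_error_deg=np.nan, wrong_target=False,
                onset_ms=np.nan, offset_ms=np.nan, has_saccade=False,
            )
        else:
            targets = {
                d: eccentricity * np.array([np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))])
                for d in offered
            }
            end = np.asarray(sac.end_xy)
            landing = float(np.linalg.norm(end - targets[cued]))
            nearest = min(targets, key=lambda d: np.linalg.norm(end - targets[d]))
            out.update(
                latency_ms=sac.onset - cue_off,
                duration_ms=sac.duration,
                amplitude_deg=sac.amplitude,
                peak_velocity=sac.peak_velocity,
                landing_error_deg=landing,
                wrong_target=nearest != cued,
                onset_ms=sac.onset,
                offset_ms=sac.offset,
                has_saccade=True,
            )
        # pupil cost sample on the baseline-corrected 100 Hz trace
        lo_i = low.index_at(row["trial_start"])
        hi_i = low.index_at(trial_end)
        t_tr = low.t[lo_i:hi_i]
        try:
            corrected = preprocess.baseline_correct(
                t_tr, low.pupil[lo_i:hi_i], cue_on, cue_on + BASELINE_MS
            )
            cost = cost_window_mean(t_tr, corrected, cue_off)
            window_ok = not (sac is not None and sac.onset < cue_off + COST_WINDOW_POST_MS)
        except ValueError:
            cost, window_ok = np.nan, False
        out.update(cost_raw=cost, cost_window_ok=window_ok)
        rows.append(out)
    return pd.DataFrame(rows)


def apply_planning_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag trials per the exclusion cascade; returns (trials, report).

    A trial is excluded if any criterion fires. The report counts
    exclusions per criterion (attributed to the first firing one, in the
    listed order) and gives the overall percentage on two denominators:
    all trials, and non-practice trials.
    """
    t = trials.copy()
    criteria = {
        "fast_latency": t["latency_ms"] < LATENCY_FAST_MS,
        "slow_latency": t["latency_ms"] > LATENCY_SLOW_MS,
        "short_duration": t["duration_ms"] < DURATION_SHORT_MS,
        "long_duration": t["duration_ms"] > DURATION_LONG_MS,
        "small_amplitude": t["amplitude_deg"] < MIN_AMPLITUDE_DEG,
        "landing_error": t["landing_error_deg"] > MAX_LANDING_DEG,
        "wrong_target": t["wrong_target"].astype(bool),
        "practice": t.get("is_practice", pd.Series(False, index=t.index)).astype(bool),
        "no_saccade": ~t.get("has_saccade", pd.Series(True, index=t.index)).astype(bool),
    }
    reason = pd.Series("", index=t.index, dtype=object)
    excluded = pd.Series(False, index=t.index)
    for name in EXCLUSION_ORDER:
        fires = criteria[name].fillna(False) & ~excluded
        reason[fires] = name
        excluded |= criteria[name].fillna(False)
    if "cost_window_ok" in t.columns:
        bad_window = ~t["cost_window_ok"].astype(bool) & ~excluded
        reason[bad_window] = "cost_window"
        excluded |= bad_window
    t["included"] = ~excluded
    t["exclusion_reason"] = reason

    counts = reason[excluded].value_counts()
    n_total = len(t)
    n_nonpractice = int((~t.get("is_practice", pd.Series(False, index=t.index))).sum())
    report = pd.DataFrame(
        {
            "criterion": counts.index,
            "n_excluded": counts.values,
            "pct_of_all": 100.0 * counts.values / n_total,
            "pct_of_nonpractice": 100.0 * counts.values / max(n_nonpractice, 1),
        }
    )
    report.attrs["n_total"] = n_total
    report.attrs["n_excluded"] = int(excluded.sum())
    report.attrs["pct_excluded_all"] = 100.0 * excluded.sum() / n_total
    report.attrs["pct_excluded_nonpractice"] = 100.0 * excluded.sum() / max(n_nonpractice, 1)
    return t, report


@dataclass
class CostMap:
    """Direction-binned mean z-scored pupil size during planning.

    ``per_participant``: participants x 36 directions (NaN where a
    participant has no trials in a bin). ``group``: unweighted mean over
    participants per bin; bins with no data anywhere stay missing, never
    zero-filled.
    """

    per_participant: pd.DataFrame
    group: pd.Series

    def to_frame(self) -> pd.DataFrame:
        long = (
            self.per_participant.stack()
            .rename("mean_z")
            .reset_index()
        )
        long["level"] = "participant"
        grp = self.group.rename("mean_z").reset_index()
        grp["participant"] = ""
        grp["level"] = "group"
        return pd.concat([long, grp], ignore_index=True)


def build_cost_map(trials: pd.DataFrame) -> CostMap:
    """Included trials -> participant and group cost maps.

    Cost samples are z-transformed per participant within session (using
    only included trials), then averaged within each cued-direction bin
    per participant; the group map averages participant maps per bin.
    """
    inc = trials[trials["included"]].copy()
    if inc.empty:
        raise ValueError("no included trials")
    inc["cost_z"] = preprocess.zscore_by_group(
        inc["cost_raw"], [inc["participant"], inc["session"]]
    )
    per = (
        inc.pivot_table(index="participant", columns="cued_deg", values="cost_z", aggfunc="mean")
        .reindex(columns=DIRECTIONS.astype(float))
    )
    per.columns.name = "direction_deg"
    group = per.mean(axis=0, skipna=True)
    group.name = "mean_z"
    return CostMap(per_participant=per, group=group)


def attach_predictors(trials: pd.DataFrame, direction_col: str = "cued_deg") -> pd.DataFrame:
    """Add oblique / vertical / horizontal predictor columns."""
    t = trials.copy()
    preds = t[direction_col].map(lambda d: direction_predictors(float(d)))
    t["oblique"] = [p.oblique for p in preds]
    t["vertical"] = [p.vertical for p in preds]
    t["horizontal"] = [p.horizontal for p in preds]
    return t


def _standardize(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def fit_planning_model(trials: pd.DataFrame):
    """Mixed-effects model of pupil size on direction predictors.

    pupil_z ~ oblique * duration + vertical + horizontal + amplitude +
    landing error + peak velocity, with by-participant random intercept
    and slopes for oblique and vertical. Saccade covariates are
    standardized before fitting. Returns an :class:`saccost.stats.LmmFit`.
    """
    from .stats import fit_lmm

    inc = trials[trials["included"]].copy()
    if inc["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if "cost_z" not in inc.columns:
        inc["cost_z"] = preprocess.zscore_by_group(
            inc["cost_raw"], [inc["participant"], inc["session"]]
        )
    inc = attach_predictors(inc)
    for col, name in [
        ("duration_ms", "duration"),
        ("amplitude_deg", "amplitude"),
        ("landing_error_deg", "landing_error"),
        ("peak_velocity", "peak_vel"),
    ]:
        inc[name] = _standardize(inc[col])
    formula = (
        "cost_z ~ oblique * duration + vertical + horizontal"
        " + amplitude + landing_error + peak_vel"
    )
    return fit_lmm(formula, inc, groups="participant", re_formula="~oblique + vertical")


def run_planning_pipeline(config, profile, practice_trials: int = 0):
    """Simulate and analyze a full planning study session by session.

    Returns (trials, report, cost_map). Sessions are processed one at a
    time so peak memory stays at a single 1000 Hz recording.
    """
    from .simulate import simulate_planning_study

    frames = []
    for rec, events, _truth in simulate_planning_study(config, profile):
        frames.append(
            extract_planning_trials(
                rec, events, eccentricity=config.eccentricity, practice_trials=practice_trials
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    trials, report = apply_planning_exclusions(trials)
    cost_map = build_cost_map(trials)
    return trials, report, cost_map
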