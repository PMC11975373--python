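"""Ground-truth-parameterized synthetic recordings for all three tasks.

The generator emulates the study conditions end to end so that every
downstream stage is testable without external recordings:

* **Planning task** — per trial, eight offered directions (of 36), one
  cued; the participant withholds the saccade until cue offset and then
  saccades to the cued target at 10 deg eccentricity. The pupil trace is
  a baseline plus white noise plus an effort dilation proportional to the
  ground-truth cost of the cued direction, convolved with (here: shaped
  by) a pupil impulse-response kernel locked to cue onset.
* **Preference task** — two offered directions at least 20 deg apart; the
  choice is sampled from a softmax on the ground-truth cost difference,
  and the executed saccade bows away from the non-selected option with a
  peak deviation proportional to |cost A - cost B| plus noise.
* **Natural-scene search** — free-viewing fixation sequences whose
  outgoing saccade directions are drawn proportional to exp(-kappa *
  cost), with a higher kappa and longer inter-saccade intervals in the
  dual-task condition, and per-fixation covariates (luminance, saliency,
  gaze position, durations).

Equal seeds give bit-identical output: every session derives its RNG from
``SeedSequence([seed, task, participant, session])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .recording import GazeRecording

__all__ = [
    "DIRECTIONS",
    "CostProfile",
    "SimulationConfig",
    "obliqueness",
    "ground_truth_cost",
    "cost_map_truth",
    "pupil_kernel",
    "saccade_duration_ms",
    "peak_velocity",
    "threshold_crossing_ms",
    "simulate_planning_session",
    "simulate_preference_session",
    "simulate_search_session",
    "simulate_planning_study",
    "simulate_preference_study",
    "simulate_search_study",
]

#: The 36 target directions (deg); bins are centered on these.
DIRECTIONS = np.arange(0, 360, 10)

_TASK_PLANNING, _TASK_PREFERENCE, _TASK_SEARCH = 1, 2, 3


@dataclass(frozen=True)
class CostProfile:
    """Direction-dependent saccade-cost anisotropies, in z-units.

    cost(theta) = c0 + c_obl * O(theta)/4 + c_down * (-sin theta)
                  + c_left * (-cos theta)

    where O(theta) is the angular distance to the nearest cardinal axis in
    10-deg steps (0-4). Positive ``c_down`` makes downward saccades
    costlier than upward; positive ``c_left`` makes leftward costlier.
    """

    c0: float = 0.0
    c_obl: float = 0.3
    c_down: float = 0.1
    c_left: float = 0.05

    def __post_init__(self) -> None:
        for name in ("c0", "c_obl", "c_down", "c_left"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters (defaults = the study conditions).

    The planning/preference scale (20 participants x 2 sessions x 360
    trials) matches the deposited study; search defaults emulate a
    desk-scale version of the 25-participant dual-task experiment.
    """

    n_participants: int = 20
    n_sessions: int = 2
    trials_per_session: int = 360
    sampling_rate: float = 1000.0  # Hz
    eccentricity: float = 10.0  # deg
    choice_temperature: float = 0.5  # z-units (softmax tau)
    pupil_gain: float = 1.0  # a.u. per z-unit of cost
    kernel_n: float = 10.1
    kernel_t_max: float = 930.0  # ms
    blink_rate: float = 5.0  # events/min
    noise_sd: float = 0.2  # a.u. (pupil); gaze jitter scales with this
    seed: int = 0
    baseline_pupil: float = 1000.0  # a.u.
    landing_sd: float = 0.5  # deg
    latency_mean: float = 280.0  # ms (planning, cue offset -> onset)
    latency_sd: float = 60.0
    latency_range: tuple[float, float] = (120.0, 650.0)
    pref_latency_mean: float = 230.0  # ms (preference, target onset -> onset)
    pref_latency_sd: float = 40.0
    pref_latency_range: tuple[float, float] = (120.0, 450.0)
    curvature_gain: float = 1.0  # deg of peak deviation per z-unit |dcost|
    curvature_sd: float = 0.25  # deg
    # natural-scene search
    kappa_single: float = 2.0
    kappa_dual: float = 3.0
    interval_single_ms: float = 300.0  # mean inter-saccade interval
    interval_dual_ms: float = 400.0
    search_trials: int = 20
    search_trial_duration_ms: float = 8000.0
    search_amplitude_mean: float = 5.0  # deg
    outlier_rate: float = 0.02
    display_bounds: tuple[float, float, float, float] = (-16.0, 16.0, -12.0, 12.0)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be positive")
        for name in ("n_participants", "n_sessions", "trials_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def total_trials(self) -> int:
        return self.n_participants * self.n_sessions * self.trials_per_session

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def obliqueness(direction: float) -> float:
    """Angular distance to the nearest cardinal axis in 10-deg steps (0-4)."""
    m = direction % 90.0
    return min(m, 90.0 - m) / 10.0


def _check_direction(direction: float) -> None:
    if direction % 10 != 0 or not (0 <= direction < 360):
        raise ValueError("direction must be a multiple of 10 deg in [0, 360)")


def ground_truth_cost(direction: float, profile: CostProfile) -> float:
    """Deterministic ground-truth cost (z-units) of a bin direction."""
    _check_direction(direction)
    theta = math.radians(direction)
    return (
        profile.c0
        + profile.c_obl * obliqueness(direction) / 4.0
        + profile.c_down * (-math.sin(theta))
        + profile.c_left * (-math.cos(theta))
    )


def cost_map_truth(profile: CostProfile) -> pd.Series:
    """Ground-truth cost over all 36 bin directions."""
    return pd.Series(
        [ground_truth_cost(d, profile) for d in DIRECTIONS],
        index=pd.Index(DIRECTIONS, name="direction_deg"),
        name="cost_true",
    )


# ---------------------------------------------------------------------------
# kinematic and pupillary primitives


def pupil_kernel(t_ms: np.ndarray, n: float = 10.1, t_max: float = 930.0) -> np.ndarray:
    """Erlang-family pupil impulse response, unit peak at ``t_max`` ms.

    h(t) = (t / t_max)^n * exp(n * (1 - t / t_max)) for t >= 0, else 0.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / t_max
    out[pos] = r**n * np.exp(n * (1.0 - r))
    return out


def saccade_duration_ms(amplitude: float) -> float:
    """Main-sequence duration: 2.2 ms/deg * amplitude + 21 ms."""
    return 2.2 * amplitude + 21.0


def peak_velocity(amplitude: float) -> float:
    """Peak velocity (deg/s) of the raised-cosine profile.

    The raised-cosine velocity profile integrates to the amplitude, which
    ties the peak to 2A/D with D from the main sequence; as a function of
    amplitude this saturates near 2/2.2 * 1000 ~ 909 deg/s.
    """
    return 2.0 * amplitude / (saccade_duration_ms(amplitude) / 1000.0)


def threshold_crossing_ms(amplitude: float, threshold: float = 75.0) -> float:
    """Time from movement start to the first analytic crossing of
    ``threshold`` deg/s on the raised-cosine speed profile.

    This is the *operational* saccade onset under the study's velocity
    criterion; truth tables record it as the injected onset.
    """
    d = saccade_duration_ms(amplitude)
    vp = peak_velocity(amplitude)
    if vp <= threshold:
        raise ValueError("saccade never reaches the onset threshold")
    return d / (2.0 * math.pi) * math.acos(1.0 - 2.0 * threshold / vp)


def _raised_cosine_progress(t_ms: np.ndarray, duration: float) -> np.ndarray:
    """Normalized displacement 0->1 whose derivative is a raised cosine."""
    u = np.clip(t_ms / duration, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _fixational_jitter(rng: np.random.Generator, n: int, dt_s: float, noise_sd: float) -> np.ndarray:
    """Slow mean-reverting drift (deg), one axis.

    Velocity is an OU process (sd ~ 1.25 * noise_sd deg/s, timescale
    100 ms) integrated into position with weak reversion (timescale 2 s),
    mimicking fixational drift. White positional noise is deliberately
    avoided: it does not occur in tracker gaze traces at this magnitude
    and would defeat any deg/s offset criterion.
    """
    if noise_sd == 0 or n == 0:
        return np.zeros(n)
    sigma_v = 1.25 * noise_sd  # deg/s
    alpha = math.exp(-dt_s / 0.1)
    v = lfilter([1.0], [1.0, -alpha], rng.normal(0.0, sigma_v * math.sqrt(1 - alpha**2), n))
    beta = 1.0 - dt_s / 2.0
    return lfilter([dt_s], [1.0, -beta], v)


def _insert_blinks(
    rng: np.random.Generator,
    pupil: np.ndarray,
    valid: np.ndarray,
    rate_hz: float,
    blink_rate_per_min: float,
) -> None:
    """Set pupil to vendor-style zero runs of 80-200 ms at the given rate."""
    if blink_rate_per_min <= 0:
        return
    n = len(pupil)
    minutes = n / rate_hz / 60.0
    n_blinks = rng.poisson(blink_rate_per_min * minutes)
    for _ in range(n_blinks):
        dur = int(round(rng.uniform(80, 200) * rate_hz / 1000.0))
        start = int(rng.integers(0, max(n - dur, 1)))
        pupil[start : start + dur] = 0.0
        valid[start : start + dur] = False


def _session_rng(config: SimulationConfig, task: int, participant: int, session: int):
    ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, task, participant, session])
    return np.random.default_rng(ss)


def _target_xy(direction: float, eccentricity: float) -> np.ndarray:
    theta = math.radians(direction)
    return np.array([eccentricity * math.cos(theta), eccentricity * math.sin(theta)])


def _offered_eight(rng: np.random.Generator, cued_idx: int) -> np.ndarray:
    """Eight (approximately) equally spaced bin indices including the cue."""
    offsets = np.round(np.arange(8) * 36 / 8).astype(int)
    slot = int(rng.integers(8))
    return (cued_idx - offsets[slot] + offsets) % 36


class _SessionBuilder:
    """Accumulates per-trial gaze/pupil segments into session arrays."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.dt = 1000.0 / config.sampling_rate
        self.segments_x: list[np.ndarray] = []
        self.segments_y: list[np.ndarray] = []
        self.costs: list[tuple[float, float]] = []  # (cue_on_abs, cost)
        self.t_cursor = 0.0

    def n_samples(self, duration_ms: float) -> int:
        return int(round(duration_ms / self.dt))

    def hold(self, xy: np.ndarray, duration_ms: float) -> None:
        n = self.n_samples(duration_ms)
        self.segments_x.append(np.full(n, xy[0]))
        self.segments_y.append(np.full(n, xy[1]))
        self.t_cursor += n * self.dt

    def saccade(self, p0: np.ndarray, p1: np.ndarray, duration_ms: float, bow: np.ndarray | None = None) -> None:
        """Append a movement segment from p0 to p1 (p0 sample excluded,
        p1 held at the final sample). ``bow`` is the quadratic-Bezier
        control-point offset from the chord midpoint (2x the peak
        deviation), or None for a straight saccade."""
        n = self.n_samples(duration_ms)
        t = (np.arange(1, n + 1)) * self.dt
        g = _raised_cosine_progress(t, duration_ms)
        if bow is None:
            seg = p0[None, :] + g[:, None] * (p1 - p0)[None, :]
        else:
            mid = 0.5 * (p0 + p1)
            ctrl = mid + bow
            u = g[:, None]
            seg = (1 - u) ** 2 * p0[None, :] + 2 * u * (1 - u) * ctrl[None, :] + u**2 * p1[None, :]
        self.segments_x.append(seg[:, 0])
        self.segments_y.append(seg[:, 1])
        self.t_cursor += n * self.dt

    def finish(self, participant: int, session: int) -> GazeRecording:
        cfg = self.cfg
        x = np.concatenate(self.segments_x)
        y = np.concatenate(self.segments_y)
        n = len(x)
        dt_s = self.dt / 1000.0
        x = x + _fixational_jitter(self.rng, n, dt_s, cfg.noise_sd)
        y = y + _fixational_jitter(self.rng, n, dt_s, cfg.noise_sd)
        t = np.arange(n) * self.dt
        pupil = np.full(n, cfg.baseline_pupil)
        if cfg.noise_sd > 0:
            pupil += self.rng.normal(0.0, cfg.noise_sd, n)
        for cue_on, cost in self.costs:
            i0 = int(round(cue_on / self.dt))
            # kernel support truncated at 4 * t_max: < 1e-4 of peak beyond
            i1 = min(n, i0 + self.n_samples(4 * cfg.kernel_t_max))
            rel_t = t[i0:i1] - cue_on
            pupil[i0:i1] += cfg.pupil_gain * cost * pupil_kernel(rel_t, cfg.kernel_n, cfg.kernel_t_max)
        valid = np.ones(n, dtype=bool)
        _insert_blinks(self.rng, pupil, valid, cfg.sampling_rate, cfg.blink_rate)
        return GazeRecording(
            participant=participant, session=session, rate=cfg.sampling_rate,
            t=t, x=x, y=y, pupil=pupil, valid=valid,
        )


_HOLD_MS = 300.0  # on-target hold before trial end
_RETURN_GAP_MS = 150.0  # trial end -> return-saccade motion start
_SETTLE_MS = 150.0  # after the return saccade, before the next trial


def _clipped_normal(rng, mean, sd, lo, hi, size):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def simulate_planning_session(
    config: SimulationConfig,
    profile: CostProfile,
    participant: int = 1,
    session: int = 1,
) -> tuple[GazeRecording, pd.DataFrame, pd.DataFrame]:
    """One planning-task session: (recording, event log, truth table).

    Per trial: 400 ms central fixation, targets onset (8 offered
    directions), cue onset 400 ms later (one cued direction), cue offset
    after 750-1250 ms, then a main-sequence saccade to the cued target.
    Cued directions are balanced across the 36 bins within the session.
    The truth table records the operational saccade onset (first analytic
    75 deg/s crossing), the kinematic motion start, and the trial's
    ground-truth cost.
    """
    rng = _session_rng(config, _TASK_PLANNING, participant, session)
    n_tr = config.trials_per_session
    reps = -(-n_tr // 36)
    cued_idx = np.tile(np.arange(36), reps)[:n_tr]
    rng.shuffle(cued_idx)
    cue_dur = rng.uniform(750.0, 1250.0, n_tr)
    lat = _clipped_normal(rng, config.latency_mean, config.latency_sd, *config.latency_range, n_tr)

    builder = _SessionBuilder(config, rng)
    events, truth = [], []
    center = np.zeros(2)
    for i in range(n_tr):
        cued = float(DIRECTIONS[cued_idx[i]])
        offered = [float(DIRECTIONS[j]) for j in _offered_eight(rng, cued_idx[i])]
        target = _target_xy(cued, config.eccentricity)
        end = target + rng.normal(0.0, config.landing_sd, 2)
        amp = float(np.hypot(*(end - center)))
        dur = saccade_duration_ms(amp)
        t_cross = threshold_crossing_ms(amp)
        cost = ground_truth_cost(cued, profile)

        t0 = builder.t_cursor
        trial_start = t0
        targets_on = t0 + 400.0
        cue_on = targets_on + 400.0
        cue_off = cue_on + cue_dur[i]
        onset = cue_off + lat[i]
        motion_on = onset - t_cross

        builder.hold(center, motion_on - t0)
        builder.saccade(center, end, dur)
        offset = motion_on + dur
        builder.hold(end, _HOLD_MS)
        trial_end = builder.t_cursor
        # inter-trial return saccade back to fixation
        builder.hold(end, _RETURN_GAP_MS)
        builder.saccade(end, center, saccade_duration_ms(amp))
        builder.hold(center, _SETTLE_MS)
        builder.costs.append((cue_on, cost))

        base = dict(participant=participant, session=session, trial=i)
        events.extend(
            [
                dict(base, event="trial_start", t_ms=trial_start, payload=""),
                dict(base, event="targets_on", t_ms=targets_on, payload=str(offered)),
                dict(base, event="cue_on", t_ms=cue_on, payload=str(cued)),
                dict(base, event="cue_off", t_ms=cue_off, payload=str(cued)),
                dict(base, event="trial_end", t_ms=trial_end, payload=""),
            ]
        )
        truth.append(
            dict(
                base,
                cued_deg=cued,
                cost_true=cost,
                cue_on_ms=cue_on,
                cue_off_ms=cue_off,
                onset_ms=onset,
                motion_onset_ms=motion_on,
                offset_ms=offset,
                latency_ms=lat[i],
                amplitude_deg=amp,
                duration_ms=dur,
                peak_velocity=peak_velocity(amp),
                end_x=end[0],
                end_y=end[1],
            )
        )
    rec = builder.finish(participant, session)
    return rec, pd.DataFrame(events), pd.DataFrame(truth)


def _min_angle(a: float, b: float) -> float:
    """Minimal absolute angular difference on the circle, deg."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def simulate_preference_session(
    config: SimulationConfig,
    profile: CostProfile,
    participant: int = 1,
    session: int = 1,
) -> tuple[GazeRecording, pd.DataFrame, pd.DataFrame]:
    """One binary-choice session: (recording, event log, truth table).

    Two offered directions >= 20 deg apart; choice sampled with
    P(A) = 1 / (1 + exp((cost_A - cost_B) / tau)); the saccade bows away
    from the non-selected option with injected peak deviation
    ``curvature_gain * |dcost| + N(0, curvature_sd)`` (negative draws bow
    toward it, so that toward-curving trials exist, preferentially at
    small cost differences).
    """
    rng = _session_rng(config, _TASK_PREFERENCE, participant, session)
    n_tr = config.trials_per_session
    fix_dur = rng.uniform(150.0, 400.0, n_tr)
    lat = _clipped_normal(
        rng, config.pref_latency_mean, config.pref_latency_sd, *config.pref_latency_range, n_tr
    )

    builder = _SessionBuilder(config, rng)
    events, truth = [], []
    center = np.zeros(2)
    for i in range(n_tr):
        idx_a = int(rng.integers(36))
        idx_b = (idx_a + int(rng.integers(2, 35))) % 36
        dir_a, dir_b = float(DIRECTIONS[idx_a]), float(DIRECTIONS[idx_b])
        assert _min_angle(dir_a, dir_b) >= 20.0
        cost_a = ground_truth_cost(dir_a, profile)
        cost_b = ground_truth_cost(dir_b, profile)
        p_a = 1.0 / (1.0 + math.exp((cost_a - cost_b) / config.choice_temperature))
        choose_a = rng.random() < p_a
        chosen, other = (dir_a, dir_b) if choose_a else (dir_b, dir_a)

        target = _target_xy(chosen, config.eccentricity)
        nonsel = _target_xy(other, config.eccentricity)
        end = target + rng.normal(0.0, config.landing_sd, 2)
        amp = float(np.hypot(*(end - center)))
        dur = saccade_duration_ms(amp)
        t_cross = threshold_crossing_ms(amp)

        dev = config.curvature_gain * abs(cost_a - cost_b) + rng.normal(0.0, config.curvature_sd)
        chord = end - center
        n_left = np.array([-chord[1], chord[0]]) / np.hypot(*chord)
        side_ns = math.copysign(1.0, chord[0] * nonsel[1] - chord[1] * nonsel[0])
        bow = (-side_ns * n_left) * (2.0 * dev)  # away side when dev > 0

        t0 = builder.t_cursor
        targets_on = t0 + fix_dur[i]
        onset = targets_on + lat[i]
        motion_on = onset - t_cross
        builder.hold(center, motion_on - t0)
        builder.saccade(center, end, dur, bow=bow)
        offset = motion_on + dur
        builder.hold(end, _HOLD_MS)
        trial_end = builder.t_cursor
        builder.hold(end, _RETURN_GAP_MS)
        builder.saccade(end, center, saccade_duration_ms(amp))
        builder.hold(center, _SETTLE_MS)

        base = dict(participant=participant, session=session, trial=i)
        events.extend(
            [
                dict(base, event="trial_start", t_ms=t0, payload=""),
                dict(base, event="targets_on", t_ms=targets_on, payload=str([dir_a, dir_b])),
                dict(base, event="trial_end", t_ms=trial_end, payload=""),
            ]
        )
        truth.append(
            dict(
                base,
                dir_a=dir_a,
                dir_b=dir_b,
                cost_a=cost_a,
                cost_b=cost_b,
                p_choose_a=p_a,
                chosen_deg=chosen,
                dev_injected=dev,
                targets_on_ms=targets_on,
                onset_ms=onset,
                motion_onset_ms=motion_on,
                offset_ms=offset,
                latency_ms=lat[i],
                amplitude_deg=amp,
                duration_ms=dur,
            )
        )
    rec = builder.finish(participant, session)
    return rec, pd.DataFrame(events), pd.DataFrame(truth)


def simulate_search_session(
    config: SimulationConfig,
    profile: CostProfile,
    condition: str,
    participant: int = 1,
) -> pd.DataFrame:
    """Free-viewing fixation/saccade table for one participant-condition.

    Outgoing saccade directions are drawn over the 36 bins with
    probability proportional to exp(-kappa_cond * cost); inter-saccade
    intervals are Gamma-distributed with the condition's mean. Each
    fixation carries covariates and a pupil value with an effort
    component proportional to the cost of its outgoing direction.
    Columns ``is_outlier`` and ``cost_true`` are generator bookkeeping,
    never consumed by the analysis.
    """
    if condition not in ("single", "dual"):
        raise ValueError("condition must be 'single' or 'dual'")
    rng = _session_rng(
        config, _TASK_SEARCH, participant, 1 if condition == "single" else 2
    )
    kappa = config.kappa_single if condition == "single" else config.kappa_dual
    mean_iv = config.interval_single_ms if condition == "single" else config.interval_dual_ms
    costs = cost_map_truth(profile).to_numpy()
    probs = np.exp(-kappa * costs)
    probs /= probs.sum()
    xmin, xmax, ymin, ymax = config.display_bounds
    # participant-level pupil baseline: stable across conditions so the
    # per-participant z-transform removes it
    p_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, _TASK_SEARCH, participant, 99])
    )
    p_offset = p_rng.normal(0.0, 0.5)

    rows = []
    for trial in range(config.search_trials):
        pos = np.zeros(2)
        t = 0.0
        fix_num = 0
        while t < config.search_trial_duration_ms:
            bin_idx = int(rng.choice(36, p=probs))
            direction = (DIRECTIONS[bin_idx] + rng.uniform(-5.0, 5.0)) % 360.0
            amp = rng.gamma(9.0, config.search_amplitude_mean / 9.0)
            # main-sequence scatter so duration is not an exact linear
            # function of amplitude (which would make covariate fits singular)
            sdur = saccade_duration_ms(amp) + rng.normal(0.0, 3.0)
            interval = rng.gamma(10.0, mean_iv / 10.0)
            fixdur = max(interval - sdur, 50.0)
            lum = rng.normal()
            sal = rng.normal()
            cost = costs[bin_idx]
            pupil = (
                p_offset
                + config.pupil_gain * cost
                - 0.1 * lum
                + 0.05 * sal
                + rng.normal(0.0, config.noise_sd)
            )
            is_outlier = 0
            x, y = pos
            if rng.random() < config.outlier_rate:
                if rng.random() < 0.5:
                    pupil += math.copysign(4.0 + rng.uniform(0, 1), rng.random() - 0.5)
                    is_outlier = 1
                else:
                    x = xmax + rng.uniform(1.0, 3.0)
                    is_outlier = 2
            rows.append(
                dict(
                    participant=participant,
                    condition=condition,
                    trial=trial,
                    fixation_number=fix_num,
                    x_deg=x,
                    y_deg=y,
                    fixation_duration_ms=fixdur,
                    mean_pupil=pupil,
                    direction_deg=direction,
                    saccade_amplitude_deg=amp,
                    saccade_duration_ms=sdur,
                    luminance=lum,
                    saliency=sal,
                    trial_duration_ms=config.search_trial_duration_ms,
                    is_outlier=is_outlier,
                    cost_true=cost,
                )
            )
            theta = math.radians(direction)
            pos = np.clip(
                pos + amp * np.array([math.cos(theta), math.sin(theta)]),
                [xmin, ymin],
                [xmax, ymax],
            )
            t += fixdur + sdur
            fix_num += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-level iterators


def simulate_planning_study(config: SimulationConfig, profile: CostProfile):
    """Yield (recording, events, truth) for every participant x session."""
    for p in range(1, config.n_participants + 1):
        for s in range(1, config.n_sessions + 1):
            yield simulate_planning_session(config, profile, p, s)


def simulate_preference_study(config: SimulationConfig, profile: CostProfile):
    for p in range(1, config.n_participants + 1):
        for s in range(1, config.n_sessions + 1):
            yield simulate_preference_session(config, profile, p, s)


def simulate_search_study(config: SimulationConfig, profile: CostProfile, conditions=("single", "dual")) -> pd.DataFrame:
    """Concatenated fixation table over participants and conditions."""
    frames = [
        simulate_search_session(config, profile, cond, participant=p)
        for p in range(1, config.n_participants + 1)
        for cond in conditions
    ]
    return pd.concat(frames, ignore_index=True)
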