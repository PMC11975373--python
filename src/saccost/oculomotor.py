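"""Saccade/fixation detection and trajectory curvature.

Saccades are detected from 2D gaze speed with an onset threshold of
75 deg/s and an offset threshold of 1 deg/s (offset must persist for a
few samples to avoid splitting a saccade on velocity ripples). Fixations
are the complement intervals. Curvature is the peak perpendicular
deviation of the trajectory from the straight onset-to-offset chord,
signed positive when the saccade bows away from the non-selected option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import GazeRecording

ONSET_THRESHOLD = 75.0  # deg/s
OFFSET_THRESHOLD = 1.0  # deg/s
OFFSET_PERSIST = 3  # samples the speed must stay below OFFSET_THRESHOLD
MIN_INTERSACCADE_MS = 20.0
MIN_FIXATION_MS = 40.0


@dataclass
class Saccade:
    """One detected saccade with kinematics and its raw trajectory."""

    onset: float  # ms
    offset: float  # ms
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude: float  # deg, Euclidean start->end
    duration: float  # ms
    peak_velocity: float  # deg/s
    i_onset: int
    i_offset: int
    trajectory: np.ndarray = field(repr=False)  # (n, 2) gaze samples
    latency: float | None = None  # ms relative to a task reference event
    landing_error: float | None = None  # deg, end to target


@dataclass
class Fixation:
    start: float  # ms
    end: float  # ms
    centroid_xy: tuple[float, float]
    duration: float  # ms
    mean_pupil: float


@dataclass
class CurvatureResult:
    """Signed peak deviation; positive = away from the non-selected option."""

    peak_deviation: float  # deg
    direction_class: str | None  # "toward" | "away" | None when ambiguous


def compute_speed(recording: GazeRecording) -> np.ndarray:
    """2D gaze speed (deg/s) via central differences over a 5-sample window.

    Interior samples use ``(g[i+2] - g[i-2]) / (4 dt)``, which averages the
    instantaneous velocity over +-2 samples; the 4 edge samples fall back to
    one-sided differences and should not be trusted for threshold work.
    """
    if len(recording) < 5:
        raise ValueError("need at least 5 samples to estimate speed")
    dt_s = recording.dt / 1000.0
    vx = np.empty(len(recording))
    vy = np.empty(len(recording))
    for g, out in ((recording.x, vx), (recording.y, vy)):
        out[2:-2] = (g[4:] - g[:-4]) / (4.0 * dt_s)
        out[0] = (g[1] - g[0]) / dt_s
        out[1] = (g[2] - g[0]) / (2 * dt_s)
        out[-2] = (g[-1] - g[-3]) / (2 * dt_s)
        out[-1] = (g[-1] - g[-2]) / dt_s
    return np.hypot(vx, vy)


def detect_saccades(
    recording: GazeRecording,
    onset_threshold: float = ONSET_THRESHOLD,
    offset_threshold: float = OFFSET_THRESHOLD,
    offset_persist: int = OFFSET_PERSIST,
    min_intersaccade: float = MIN_INTERSACCADE_MS,
    speed: np.ndarray | None = None,
) -> list[Saccade]:
    """Threshold-scan the speed trace for saccades, in temporal order.

    A saccade opens at the first sample with speed >= ``onset_threshold``
    (outside any open saccade) and closes at the first subsequent sample
    where speed <= ``offset_threshold`` for ``offset_persist`` consecutive
    samples. A saccade still open at the end of the recording is dropped.
    The next onset is searched no earlier than ``min_intersaccade`` ms
    after the previous offset.
    """
    if speed is None:
        speed = compute_speed(recording)
    n = len(speed)
    below = speed <= offset_threshold
    if offset_persist > 1:
        sustained = below.copy()
        for k in range(1, offset_persist):
            sustained[: n - k] &= below[k:]
            sustained[n - k :] = False
    else:
        sustained = below
    above_idx = np.flatnonzero(speed >= onset_threshold)
    sustained_idx = np.flatnonzero(sustained)
    gap = int(round(min_intersaccade * recording.rate / 1000.0))

    saccades: list[Saccade] = []
    cursor = 0
    while True:
        j = np.searchsorted(above_idx, cursor)
        if j >= len(above_idx):
            break
        i_on = int(above_idx[j])
        k = np.searchsorted(sustained_idx, i_on)
        if k >= len(sustained_idx):
            break  # saccade open at end of recording: dropped
        i_off = int(sustained_idx[k])
        traj = np.column_stack((recording.x[i_on : i_off + 1], recording.y[i_on : i_off + 1]))
        start = (recording.x[i_on], recording.y[i_on])
        end = (recording.x[i_off], recording.y[i_off])
        saccades.append(
            Saccade(
                onset=float(recording.t[i_on]),
                offset=float(recording.t[i_off]),
                start_xy=start,
                end_xy=end,
                amplitude=float(np.hypot(end[0] - start[0], end[1] - start[1])),
                duration=float(recording.t[i_off] - recording.t[i_on]),
                peak_velocity=float(speed[i_on : i_off + 1].max()),
                i_onset=i_on,
                i_offset=i_off,
                trajectory=traj,
            )
        )
        cursor = i_off + max(gap, 1)
    return saccades


def detect_fixations(
    recording: GazeRecording,
    saccades: list[Saccade],
    min_duration: float = MIN_FIXATION_MS,
) -> list[Fixation]:
    """Complement intervals between saccades (and the recording bounds).

    With k saccades this yields at most k+1 fixations; intervals shorter
    than ``min_duration`` ms are discarded. Fixations and saccades jointly
    tile the recording up to those short gaps.
    """
    bounds = [0]
    for sac in saccades:
        bounds.extend([sac.i_onset, sac.i_offset + 1])
    bounds.append(len(recording))
    fixations = []
    for lo, hi in zip(bounds[0::2], bounds[1::2]):
        if hi <= lo:
            continue
        dur = recording.t[hi - 1] - recording.t[lo]
        if dur < min_duration:
            continue
        pupil = recording.pupil[lo:hi]
        pupil = pupil[np.isfinite(pupil)]
        fixations.append(
            Fixation(
                start=float(recording.t[lo]),
                end=float(recording.t[hi - 1]),
                centroid_xy=(float(recording.x[lo:hi].mean()), float(recording.y[lo:hi].mean())),
                duration=float(dur),
                mean_pupil=float(pupil.mean()) if pupil.size else np.nan,
            )
        )
    return fixations


def signed_curvature(saccade: Saccade, nonselected_xy: tuple[float, float]) -> CurvatureResult:
    """Peak deviation of the trajectory from the onset->offset chord.

    The extremal perpendicular distance is signed positive when it lies on
    the opposite side of the chord from ``nonselected_xy`` (the saccade
    curved *away* from the non-selected option). A trajectory exactly on
    the chord gets class ``None``: such trials are ambiguous and excluded
    from toward/away splits rather than counted as "toward".
    """
    traj = saccade.trajectory
    if traj.shape[0] < 3:
        raise ValueError("trajectory needs at least 3 samples")
    p0 = np.asarray(saccade.start_xy, dtype=float)
    p1 = np.asarray(saccade.end_xy, dtype=float)
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        raise ValueError("zero-length chord")
    rel = traj - p0
    dist = (chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm  # signed, left positive
    extremal = dist[np.argmax(np.abs(dist))]
    ns = np.asarray(nonselected_xy, dtype=float) - p0
    side_ns = np.sign(chord[0] * ns[1] - chord[1] * ns[0])
    if side_ns == 0:
        raise ValueError("non-selected option lies on the chord line")
    peak = -float(extremal) * float(side_ns)
    if peak > 0:
        cls = "away"
    elif peak < 0:
        cls = "toward"
    else:
        cls = None
    return CurvatureResult(peak_deviation=peak, direction_class=cls)
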