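"""Pupil-trace conditioning.

The pupillometric pipeline applied before any cost analysis:

1. blink detection (missing/zero pupil runs, padded and merged) and
   linear interpolation across each blink,
2. downsampling of the 1000 Hz stream to 100 Hz by block means,
3. subtractive baseline correction per trial (mean of the first 250 ms
   after cue onset),
4. z-transformation of per-trial measures per participant within session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import GazeRecording

#: Blink criterion defaults: pupil missing or <=0 for at least MIN_BLINK_MS,
#: each run extended by PAD_MS on both sides before merging.
MIN_BLINK_MS = 20.0
PAD_MS = 100.0


@dataclass(frozen=True)
class Blink:
    """Half-open sample-index interval [start, end) of one padded blink."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("blink start must precede end")


def _missing_mask(recording: GazeRecording) -> np.ndarray:
    p = recording.pupil
    return ~np.isfinite(p) | (p <= 0) | ~recording.valid


def detect_blinks(
    recording: GazeRecording,
    pad: float = PAD_MS,
    min_duration: float = MIN_BLINK_MS,
) -> list[Blink]:
    """Find maximal runs of missing/zero pupil, padded by ``pad`` ms.

    Runs shorter than ``min_duration`` ms are ignored (tracker glitches,
    not blinks). Padded intervals are clipped to the recording and merged
    when they overlap or touch.
    """
    missing = _missing_mask(recording)
    if not missing.any():
        return []
    n = len(recording)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]
    pad_n = int(round(pad * recording.rate / 1000.0))
    min_n = int(np.ceil(min_duration * recording.rate / 1000.0))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if e - s < min_n:
            continue
        s, e = max(0, s - pad_n), min(n, e + pad_n)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Blink(s, e) for s, e in merged]


def interpolate_blinks(recording: GazeRecording, blinks: list[Blink]) -> GazeRecording:
    """Linearly interpolate pupil across each blink; gaze is untouched.

    The pupil is interpolated between the last sample before and the first
    sample after each padded blink. A blink touching a recording boundary
    is filled with the nearest available value; such samples stay flagged
    invalid, as do all interpolated samples.
    """
    pupil = recording.pupil.copy()
    valid = recording.valid.copy()
    n = len(recording)
    for blink in blinks:
        if not (0 <= blink.start and blink.end <= n):
            raise ValueError("blink indices out of range")
        lo, hi = blink.start - 1, blink.end
        if lo >= 0 and hi < n:
            span = np.arange(lo, hi + 1)
            pupil[lo : hi + 1] = np.interp(span, [lo, hi], [pupil[lo], pupil[hi]])
        elif lo < 0 and hi < n:  # starts at recording onset
            pupil[: blink.end] = pupil[hi]
        elif lo >= 0 and hi >= n:  # runs to recording end
            pupil[blink.start :] = pupil[lo]
        else:  # whole recording missing: nothing to anchor on
            raise ValueError("cannot interpolate a blink spanning the whole recording")
        valid[blink.start : blink.end] = False
    return GazeRecording(
        participant=recording.participant,
        session=recording.session,
        rate=recording.rate,
        t=recording.t,
        x=recording.x,
        y=recording.y,
        pupil=pupil,
        valid=valid,
    )


def downsample(recording: GazeRecording, target_rate: float) -> GazeRecording:
    """Downsample by block means (not decimation).

    Each output sample is the mean of ``rate / target_rate`` consecutive
    input samples; the output carries the time stamp of the first sample
    of its block and is valid only when the whole block is valid. Output
    length is ``floor(n * target_rate / rate)``; trailing samples that do
    not fill a block are dropped.
    """
    ratio = recording.rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("rate must be an integer multiple of target_rate")
    k = int(round(ratio))
    n_out = len(recording) // k
    if n_out == 0:
        raise ValueError("recording shorter than one output block")

    def block_mean(a: np.ndarray) -> np.ndarray:
        return a[: n_out * k].reshape(n_out, k).mean(axis=1)

    return GazeRecording(
        participant=recording.participant,
        session=recording.session,
        rate=target_rate,
        t=recording.t[: n_out * k : k],
        x=block_mean(recording.x),
        y=block_mean(recording.y),
        pupil=block_mean(recording.pupil),
        valid=recording.valid[: n_out * k].reshape(n_out, k).all(axis=1),
    )


def baseline_correct(
    t: np.ndarray,
    pupil: np.ndarray,
    window_start: float,
    window_end: float,
) -> np.ndarray:
    """Subtract the mean pupil over ``[window_start, window_end)`` ms.

    Raises ``ValueError`` when the trace does not cover the window (the
    caller flags such trials excluded). The corrected trace has zero mean
    over the baseline window by construction.
    """
    t = np.asarray(t, dtype=float)
    pupil = np.asarray(pupil, dtype=float)
    in_window = (t >= window_start) & (t < window_end)
    window = pupil[in_window]
    window = window[np.isfinite(window)]
    if window.size == 0:
        raise ValueError("baseline window not covered by the trace")
    return pupil - window.mean()


def zscore_by_group(values: pd.Series, grouping) -> pd.Series:
    """Standardize within groups (mean 0, sample SD 1 per group).

    ``grouping`` is anything accepted by ``Series.groupby`` — typically
    ``[participant, session]`` columns. A group with fewer than two values
    or zero spread is rejected with its identifier, since a z-score is
    undefined there.
    """
    values = pd.Series(values, dtype=float)
    grouped = values.groupby(grouping)
    sizes = grouped.size()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 values: {bad}")
    sds = grouped.std(ddof=1)
    if (sds == 0).any() or sds.isna().any():
        bad = sds.index[(sds == 0) | sds.isna()].tolist()
        raise ValueError(f"zero-variance groups: {bad}")
    return grouped.transform(lambda v: (v - v.mean()) / v.std(ddof=1))
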