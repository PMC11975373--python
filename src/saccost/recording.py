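"""Gaze/pupil recording container.

A :class:`GazeRecording` holds one uniformly sampled monocular stream of
gaze position (degrees of visual angle) and pupil size (arbitrary tracker
units) for a single participant/session. Angle convention throughout the
package: 0 deg = rightward, counterclockwise positive, 90 deg = upward.
Screen-native y-down coordinates must be flipped at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["participant", "session", "t_ms", "x_deg", "y_deg", "pupil", "valid"]


@dataclass
class GazeRecording:
    """Uniformly sampled time/x/y/pupil stream with validity flags.

    Parameters
    ----------
    participant, session
        Identifiers; carried through to all derived tables.
    rate
        Sampling rate in Hz. Sample times must be uniformly spaced at
        ``1000 / rate`` ms.
    t, x, y, pupil
        Per-sample time (ms), horizontal/vertical gaze (deg) and pupil
        size (a.u.). ``pupil`` may contain NaN or zeros during blinks.
    valid
        Boolean flag per sample; False marks samples that were missing in
        the source (or, after blink interpolation, filled in).
    """

    participant: int
    session: int
    rate: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pupil) & (self.pupil > 0)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.pupil) == len(self.valid) == n):
            raise ValueError("all sample arrays must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.rate, atol=1e-6):
                raise ValueError("sample times must be uniformly spaced at 1000/rate ms")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return 1000.0 / self.rate

    def index_at(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(np.searchsorted(self.t, t_ms, side="left"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "session": self.session,
                "t_ms": self.t,
                "x_deg": self.x,
                "y_deg": self.y,
                "pupil": self.pupil,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float) -> "GazeRecording":
        """Build a recording from one participant/session slice of the
        ``samples.csv`` dialect."""
        participants = df["participant"].unique()
        sessions = df["session"].unique()
        if len(participants) != 1 or len(sessions) != 1:
            raise ValueError("frame must contain exactly one participant/session")
        df = df.sort_values("t_ms")
        return cls(
            participant=participants[0],
            session=sessions[0],
            rate=rate,
            t=df["t_ms"].to_numpy(dtype=float),
            x=df["x_deg"].to_numpy(dtype=float),
            y=df["y_deg"].to_numpy(dtype=float),
            pupil=df["pupil"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=bool),
        )


def iter_recordings(samples: pd.DataFrame, rate: float):
    """Yield one :class:`GazeRecording` per (participant, session) group."""
    for _, group in samples.groupby(["participant", "session"], sort=True):
        yield GazeRecording.from_frame(group, rate=rate)
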