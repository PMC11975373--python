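"""CSV/YAML dialects used by the pipeline.

``samples.csv``: participant, session, t_ms, x_deg, y_deg, pupil, valid
``events.csv``:  participant, session, trial, event, t_ms, payload (JSON)
``truth.csv``:   generator ground truth, one row per trial (or fixation)

All files are plain uncompressed CSV so that sessions written by the
simulator round-trip exactly through the analysis entry points.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

EVENT_COLUMNS = ["participant", "session", "trial", "event", "t_ms", "payload"]


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def payload(value) -> str:
    """Serialize an event payload (lists/scalars) to the JSON column."""
    return json.dumps(value)


def parse_payload(cell: str):
    if cell in ("", None):
        return None
    return json.loads(cell)


def load_config(path: str | Path) -> dict:
    """Read a YAML config file; returns an empty dict for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
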