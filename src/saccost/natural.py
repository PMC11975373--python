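"""Free-viewing search: outlier exclusion, direction maps, dual-task effects.

Fixation-wise pupil size is z-transformed per participant; fixations with
|z| > 3 or a gaze position off the display are excluded. Saccade
directions (of the saccade leaving each fixation) are classified into 36
half-open 10-deg sectors centered on multiples of 10 deg; per-participant
percentages are averaged into a group preference map. The adjustment map
is the entrywise dual-minus-single difference in percentage points.
Fixation-by-fixation mixed models relate pupil size to the map value of
the outgoing direction while controlling for luminance, saliency, gaze
position, durations, amplitude, and fixation/trial number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DIRECTIONS
from .stats import EffectReport, LmmFit, fit_lmm, paired_t

OUTLIER_SD = 3.0
DEFAULT_BOUNDS = (-16.0, 16.0, -12.0, 12.0)  # deg: xmin, xmax, ymin, ymax

MODEL_COVARIATES = [
    "luminance",
    "saliency",
    "fixation_number",
    "trial",
    "x_deg",
    "y_deg",
    "saccade_duration_ms",
    "fixation_duration_ms",
    "saccade_amplitude_deg",
]


def exclude_fixation_outliers(
    records: pd.DataFrame,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
) -> tuple[pd.DataFrame, dict]:
    """Drop off-display fixations and |z| > 3 pupil outliers.

    Pupil is z-transformed per participant (sample SD over all of a
    participant's fixations) before thresholding; the returned table
    carries the ``pupil_z`` column. The report gives the percentage
    excluded and the surviving fixation count.
    """
    r = records.copy()
    grouped = r.groupby("participant")["mean_pupil"]
    r["pupil_z"] = (r["mean_pupil"] - grouped.transform("mean")) / grouped.transform("std")
    xmin, xmax, ymin, ymax = bounds
    off_screen = ~r["x_deg"].between(xmin, xmax) | ~r["y_deg"].between(ymin, ymax)
    outlier_pupil = r["pupil_z"].abs() > OUTLIER_SD
    drop = off_screen | outlier_pupil
    report = {
        "n_total": int(len(r)),
        "n_excluded": int(drop.sum()),
        "n_retained": int((~drop).sum()),
        "pct_excluded": 100.0 * float(drop.mean()),
        "n_off_screen": int(off_screen.sum()),
        "n_pupil_outlier": int((outlier_pupil & ~off_screen).sum()),
    }
    kept = r[~drop].copy()
    # recompute z on the surviving fixations so downstream models use a
    # standardization untainted by the outliers themselves
    grouped = kept.groupby("participant")["mean_pupil"]
    kept["pupil_z"] = (kept["mean_pupil"] - grouped.transform("mean")) / grouped.transform("std")
    return kept, report


def direction_bin(direction) -> np.ndarray:
    """Half-open 10-deg sector centered on the nearest multiple of 10.

    4.999 deg -> bin 0; 5.0 deg -> bin 10; 355 deg -> bin 0.
    """
    d = np.asarray(direction, dtype=float) % 360.0
    return (np.floor((d + 5.0) / 10.0).astype(int) % 36) * 10


def bin_directions(records: pd.DataFrame, direction_col: str = "direction_deg") -> pd.DataFrame:
    """Per-participant percentage of saccades in each of the 36 bins.

    Returns participants x 36 directions; rows sum to 100 over the
    non-missing bins. Use ``.mean(axis=0)`` for the group map.
    """
    r = records.copy()
    r["bin"] = direction_bin(r[direction_col])
    counts = (
        r.groupby(["participant", "bin"]).size().unstack("bin")
        .reindex(columns=DIRECTIONS, fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns.name = "direction_deg"
    return pct


def build_adjustment_map(single_map: pd.Series, dual_map: pd.Series) -> pd.Series:
    """Entrywise dual - single group maps, in percentage points.

    Bins missing in either map are missing in the output. When both maps
    cover all 36 bins the entries sum to exactly zero.
    """
    single_map, dual_map = single_map.align(dual_map, join="outer")
    return (dual_map - single_map).rename("adjustment_pp")


def saccade_frequency(records: pd.DataFrame) -> pd.DataFrame:
    """Saccades per second per participant-condition.

    Counts outgoing saccades (one per fixation row) and divides by the
    summed viewing time of that participant-condition's trials.
    """
    viewing = (
        records.groupby(["participant", "condition", "trial"])["trial_duration_ms"]
        .first()
        .groupby(["participant", "condition"])
        .sum()
    )
    counts = records.groupby(["participant", "condition"]).size()
    freq = (counts / (viewing / 1000.0)).rename("saccades_per_s")
    return freq.reset_index()


def compare_saccade_frequency(records: pd.DataFrame) -> tuple[pd.DataFrame, EffectReport]:
    """Paired single-vs-dual frequency test across participants.

    Participants missing a condition are dropped from the paired test.
    """
    freq = saccade_frequency(records)
    wide = freq.pivot(index="participant", columns="condition", values="saccades_per_s")
    wide = wide.dropna(subset=["single", "dual"])
    test = paired_t(
        wide["single"].to_numpy(), wide["dual"].to_numpy(), name="frequency_single_vs_dual"
    )
    return wide, test


def fit_fixation_model(records: pd.DataFrame, direction_map: pd.Series, name: str = "map_value") -> LmmFit:
    """Pupil ~ map value of the outgoing direction + covariates (mixed model).

    ``direction_map`` is a group-level preference or adjustment map over
    bin directions; each fixation gets the value of its outgoing
    direction's bin. Covariates and the map regressor are standardized,
    with a by-participant random intercept and slope for the map value.
    A negative slope means larger pupil (higher cost) where saccades are
    rarer (preference map) or cut under load (adjustment map).
    """
    r = records.copy()
    r["bin"] = direction_bin(r["direction_deg"])
    r[name] = r["bin"].map(dict(zip(direction_map.index.astype(int), direction_map.values)))
    r = r.dropna(subset=[name, "pupil_z"])
    cols = [c for c in MODEL_COVARIATES if c in r.columns]
    for c in cols + [name]:
        sd = r[c].std(ddof=1)
        r[c] = (r[c] - r[c].mean()) / sd if sd > 0 else 0.0
    formula = f"pupil_z ~ {name} + " + " + ".join(cols)
    return fit_lmm(formula, r, groups="participant", re_formula=f"~{name}")
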