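"""Reading and writing the long-format frame CSV and summary tables.

The frame schema has one row per frame per ROI:

    patient_id,center_id,observer_id,visit,modality,roi,phase,time_s,value,
    room_temp_c,rcs_on_day

Validation is strict: unknown modalities or ROI labels are rejected with
the offending value named, duplicate (patient, visit, modality, roi,
phase, time) rows are an error, and series whose times arrive out of
order are sorted with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FRAME_COLUMNS, MODALITIES, ROI_LABELS

PHASES = ("baseline", "post_challenge")
_SERIES_KEY = ["patient_id", "visit", "modality", "roi", "phase"]


def write_roi_timeseries(frames: pd.DataFrame, path) -> None:
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"frame table missing columns: {missing}")
    frames[FRAME_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_roi_timeseries(path) -> pd.DataFrame:
    """Read and validate a frame-level CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "center_id": str,
                                  "observer_id": str})
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing columns: {missing}")
    for col, vocab in (("modality", set(MODALITIES)),
                       ("roi", set(ROI_LABELS)),
                       ("phase", set(PHASES))):
        bad = set(df[col].unique()) - vocab
        if bad:
            raise ValueError(
                f"unknown {col} value(s) in {path}: {sorted(bad)!r}")
    if df.duplicated(_SERIES_KEY + ["time_s"]).any():
        dup = df[df.duplicated(_SERIES_KEY + ["time_s"], keep=False)]
        raise ValueError(
            "duplicate (patient, visit, modality, roi, time) rows, e.g. "
            f"{dup.iloc[0][_SERIES_KEY + ['time_s']].to_dict()}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError(f"non-finite values in {path}")
    # enforce per-series time ordering
    t = df.groupby(_SERIES_KEY, sort=False)["time_s"]
    if (t.apply(lambda s: (np.diff(s) < 0).any())).any():
        warnings.warn("frame times were out of order; sorting",
                      UserWarning, stacklevel=2)
        df = df.sort_values(_SERIES_KEY + ["time_s"], kind="stable",
                            ignore_index=True)
    return df


def write_summary(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False, float_format="%.10g")


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "center_id": str,
                                  "observer_id": str})
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    return df
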