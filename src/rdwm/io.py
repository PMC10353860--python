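"""CSV schemas for trial and spike tables, and RD-curve serialization."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "SPIKE_COLUMNS",
    "write_trial_table",
    "read_trial_table",
    "write_spike_table",
    "read_spike_table",
    "rd_curve_frame",
]

#: Required TrialTable columns (stim_1..stim_M vary with the session's set size).
TRIAL_COLUMNS = ["session", "trial", "set_size", "probe_index", "cued",
                 "ri_s", "iti_s", "target", "response", "error",
                 "zero_spike_flag", "beta"]

SPIKE_COLUMNS = ["neuron_id", "session", "trial", "stimulus", "spike_count"]


def _check(df: pd.DataFrame, required: list[str], kind: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} is missing columns: {missing}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    _check(df, TRIAL_COLUMNS, "trial table").to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return _check(pd.read_csv(path), TRIAL_COLUMNS, "trial table")


def write_spike_table(df: pd.DataFrame, path) -> None:
    _check(df, SPIKE_COLUMNS, "spike table").to_csv(path, index=False)


def read_spike_table(path) -> pd.DataFrame:
    return _check(pd.read_csv(path), SPIKE_COLUMNS, "spike table")


def rd_curve_frame(points) -> pd.DataFrame:
    """Long-format frame (beta, rate_nats, distortion) of RD points."""
    return pd.DataFrame(
        {"beta": [p.beta for p in points],
         "rate_nats": [p.rate for p in points],
         "distortion": [p.distortion for p in points]})
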