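"""Reading and writing the delimited trial-log and roster schemas.

Trial logs are comma-separated UTF-8 text with a header row and empty
fields for missing values (unlimited presentation, missing reaction time).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import MalformedDataError
from .experiments import TRIAL_COLUMNS

ROSTER_COLUMNS = ["participant_id", "group", "age", "frame_rate", "matched_cp"]


def write_trial_log(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "phase": str,
                                  "stimulus_class": str, "role": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedDataError(f"trial log {path} missing columns: {missing}")
    return df


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, index=False, columns=ROSTER_COLUMNS)


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns and c != "matched_cp"]
    if missing:
        raise MalformedDataError(f"roster {path} missing columns: {missing}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path):
    return json.loads(Path(path).read_text())
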