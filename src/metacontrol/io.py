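"""Trial-table CSV schema, validation, and round-trip readers/writers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "pair",
    "stake",
    "option_left",
    "option_right",
    "choice",
    "planet",
    "treasure",
    "points",
    "missed",
    "reward_red",
    "reward_purple",
]

MISSED_SENTINEL = ""


class SchemaError(ValueError):
    """A trial table violated the CSV schema; message names row and column."""


def validate_trials(table: pd.DataFrame, stake_multiplier: int = 5) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    table = table[TRIAL_COLUMNS].copy()
    table["missed"] = table["missed"].astype(bool)
    allowed_stakes = {1, stake_multiplier}
    for idx, row in table.iterrows():
        if int(row["stake"]) not in allowed_stakes:
            raise SchemaError(f"row {idx}, column 'stake': {row['stake']!r} "
                              f"not in {sorted(allowed_stakes)}")
        if not row["missed"]:
            tr = row["treasure"]
            if not (float(tr).is_integer() and 0 <= int(tr) <= 9):
                raise SchemaError(f"row {idx}, column 'treasure': {tr!r} not in 0..9")
            if row["choice"] not in (row["option_left"], row["option_right"]):
                raise SchemaError(
                    f"row {idx}, column 'choice': {row['choice']!r} not among "
                    f"shown options")
        for col in ("reward_red", "reward_purple"):
            if not np.isfinite(row[col]):
                raise SchemaError(f"row {idx}, column '{col}': non-finite value")
    return table


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    out = table[TRIAL_COLUMNS].copy()
    out["missed"] = out["missed"].astype(bool)
    out.loc[out["missed"], ["choice", "planet"]] = MISSED_SENTINEL
    out.to_csv(path, index=False, float_format="%.10g")


def read_trials(path: str | Path, stake_multiplier: int = 5) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"choice": "string", "planet": "string",
                                     "pair": "string", "subject_id": "string",
                                     "option_left": "string",
                                     "option_right": "string"},
                        keep_default_na=False, na_values=[])
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    table["missed"] = table["missed"].map(
        {"True": True, "False": False, True: True, False: False})
    if table["missed"].isna().any():
        row = int(table.index[table["missed"].isna()][0])
        raise SchemaError(f"row {row}, column 'missed': unparseable value")
    for col in ("trial", "stake", "points"):
        table[col] = pd.to_numeric(table[col]).astype(int)
    # treasure is blank on missed rows
    table["treasure"] = pd.to_numeric(
        table["treasure"].replace("", np.nan)).astype(float)
    table.loc[~table["missed"], "treasure"] = (
        table.loc[~table["missed"], "treasure"].round())
    for col in ("reward_red", "reward_purple"):
        table[col] = pd.to_numeric(table[col]).astype(float)
    for col in ("subject_id", "pair", "choice", "planet",
                "option_left", "option_right"):
        table[col] = table[col].astype(object)
    return validate_trials(table, stake_multiplier=stake_multiplier)


def write_fit_json(fit_row: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_row, fh, indent=2, sort_keys=True, default=float)


def read_fit_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
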