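"""Reading and writing the pipeline's delimited-text formats.

Response files are CSV with header ``person_id,gender,age_group,
item01..itemJJ``; scores are integers 0..K-1 (0 = symptom absent),
``NA`` or empty cells are missing.  All report writers emit plain CSV so
every artifact diffs cleanly under version control.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ResponseData

__all__ = ["read_responses", "write_responses"]

log = logging.getLogger(__name__)

VALID_GENDER = {"M", "F"}
VALID_AGE = {"younger", "older"}


def write_responses(data: ResponseData, path: str | Path) -> None:
    df = data.to_frame()
    item_cols = [c for c in df.columns if c.startswith("item")]
    for c in item_cols:
        df[c] = df[c].astype("Int64")  # keeps NA while printing integers
    df.to_csv(path, index=False, na_rep="NA")


def read_responses(path: str | Path, max_score: int = 3) -> ResponseData:
    """Load and validate a response CSV.

    Raises a row/column-addressed error for non-integer scores, scores
    outside 0..``max_score``, unknown group labels, or duplicate person
    ids.  Missing cells (``NA``/empty) are allowed and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = {"person_id", "gender", "age_group"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")
    item_cols = sorted(
        (c for c in df.columns if c.startswith("item") and c[4:].isdigit()),
        key=lambda c: int(c[4:]),
    )
    if not item_cols:
        raise ValueError(f"{path}: no item columns (item01, item02, ...)")
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"{path}: duplicate person_id {dup!r}")
    for col in ("gender", "age_group"):
        valid = VALID_GENDER if col == "gender" else VALID_AGE
        bad = ~df[col].astype(str).isin(valid)
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2  # 1-based + header line
            raise ValueError(
                f"{path}: invalid {col} {df[col][bad.values].iloc[0]!r} at line {row}"
            )
    scores = np.full((len(df), len(item_cols)), np.nan)
    n_missing = 0
    for jc, col in enumerate(item_cols):
        vals = df[col]
        obs = vals.notna()
        n_missing += int((~obs).sum())
        arr = vals[obs].to_numpy(dtype=float)
        frac, whole = np.modf(arr)
        bad = (frac != 0) | (whole < 0) | (whole > max_score)
        if bad.any():
            row = int(obs[obs].index[np.where(bad)[0][0]]) + 2
            raise ValueError(
                f"{path}: invalid score {arr[bad][0]!r} in column {col} at line "
                f"{row} (expected integer 0..{max_score})"
            )
        scores[obs.to_numpy(), jc] = arr
    if n_missing:
        log.info("%s: %d missing item responses loaded as NaN", path, n_missing)
    return ResponseData(
        scores=scores,
        gender=df["gender"].astype(str).to_numpy(),
        age_group=df["age_group"].astype(str).to_numpy(),
        person_id=df["person_id"].to_numpy(),
    )
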