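"""CSV round-tripping for sample tables and plate tables.

The on-disk contract is plain UTF-8 CSV with ``.`` decimals and no
thousands separators, so reruns under a fixed seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PLATE_COLUMNS, SAMPLE_COLUMNS
from .exceptions import SchemaError


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False)


def read_sample_table(path) -> pd.DataFrame:
    """Load and validate a long-format FCM sample table.

    Raises :class:`SchemaError` naming the offending column, the
    1-based data line of a negative FCM value, or a duplicated
    (bird, treatment, window) key.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {sorted(missing)}")
    df = df[list(SAMPLE_COLUMNS)]
    neg = df.index[df["fcm_pg_per_mg"] < 0]
    if len(neg):
        raise SchemaError(
            f"{path.name}: negative fcm_pg_per_mg at data line {int(neg[0]) + 1}")
    dup = df.duplicated(subset=["bird_id", "treatment", "window_index"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["bird_id", "treatment", "window_index"]]
        raise SchemaError(
            f"{path.name}: duplicate (bird, treatment, window) key "
            f"{tuple(first)} at data line {int(dup.idxmax()) + 1}")
    df["is_night"] = df["is_night"].astype(bool)
    df["window_index"] = df["window_index"].astype(int)
    return df


def write_plates(plates: pd.DataFrame, path) -> None:
    plates.loc[:, list(PLATE_COLUMNS)].to_csv(path, index=False)


def read_plate_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"series_id": str, "plate_id": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {sorted(missing)}")
    if (df["count"].to_numpy(float) < 0).any():
        raise SchemaError(f"{path.name}: negative tube count")
    return df[list(PLATE_COLUMNS)]
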