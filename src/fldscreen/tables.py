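"""The feature-table convention used throughout the pipeline.

A cohort is a plain :class:`pandas.DataFrame` with three reserved columns —

* ``sex``   : 0/1 (1 = male),
* ``age``   : non-negative years,
* ``fld``   : 0/1 label (ultrasound-diagnosed fatty liver), NaN when the
  patient has no ultrasound record,

— and any number of numeric feature columns (exam analytes). Missing exam
values are NaN. On disk the table is a CSV with a header row and empty
fields for missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Columns that are never treated as exam features.
RESERVED_COLUMNS = ("sex", "age", "fld")

LABEL = "fld"
SEX = "sex"
AGE = "age"


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the exam-feature columns, in table order."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def validate_table(table: pd.DataFrame) -> None:
    """Check the reserved-column invariants; raise :class:`InputError` on violation."""
    for col in (SEX, AGE):
        if col not in table.columns:
            raise InputError(f"table lacks required column {col!r}")
    if not table.empty:
        sex = table[SEX].to_numpy()
        if not np.isin(sex, (0, 1)).all():
            raise InputError("sex must be binary 0/1")
        age = table[AGE].to_numpy(dtype=float)
        if np.any(age < 0) or not np.all(np.isfinite(age)):
            raise InputError("age must be finite and non-negative")
        if LABEL in table.columns:
            lab = table[LABEL].to_numpy(dtype=float)
            seen = lab[~np.isnan(lab)]
            if not np.isin(seen, (0.0, 1.0)).all():
                raise InputError("fld label must be 0, 1 or missing")


def labelled_mask(table: pd.DataFrame) -> np.ndarray:
    """Boolean mask of rows whose ``fld`` label is present."""
    if LABEL not in table.columns:
        return np.zeros(len(table), dtype=bool)
    return table[LABEL].notna().to_numpy()


def labels(table: pd.DataFrame) -> np.ndarray:
    """Integer 0/1 labels; raises if any are missing."""
    lab = table[LABEL].to_numpy(dtype=float)
    if np.isnan(lab).any():
        raise InputError("table contains unlabelled rows; filter first")
    return lab.astype(int)


def write_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV (header row, empty fields for missing values)."""
    table.to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_csv`."""
    table = pd.read_csv(path)
    validate_table(table)
    return table
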