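"""Group-median imputation stratified by (age bin, sex).

Routine-exam analytes shift with age and differ between men and women,
so a missing value is best replaced by the median of patients in the
same demographic cell. The age cells come from a ChiMerge
:class:`~fldscreen.chimerge.BinningScheme` fitted on the training set.

The plan is fitted on training rows only and applied unchanged to any
table (no leakage). For a missing cell the first available of three
medians is used: the (age-bin, sex) group median, the sex-level median,
then the global median — a total fallback chain, since small cohorts can
leave demographic cells empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chimerge import BinningScheme, assign_bin
from .exceptions import EmptyCohortError, EvaluationError
from .tables import AGE, SEX, feature_columns


@dataclass
class ImputationPlan:
    """Fitted medians keyed by demographic cell, with fallbacks.

    ``group_medians[(bin_index, sex)][feature]`` -> median of observed
    training values in that cell; ``sex_medians[sex][feature]`` and
    ``global_medians[feature]`` back it up. ``unusable`` lists features
    with no observed training value at all (they cannot be imputed).
    """

    binning: BinningScheme
    group_medians: dict = field(default_factory=dict)
    sex_medians: dict = field(default_factory=dict)
    global_medians: dict = field(default_factory=dict)
    unusable: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "binning": json.loads(self.binning.to_json()),
            "group_medians": {f"{b}|{s}": med
                              for (b, s), med in self.group_medians.items()},
            "sex_medians": {str(s): med for s, med in self.sex_medians.items()},
            "global_medians": self.global_medians,
            "unusable": self.unusable,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ImputationPlan":
        doc = json.loads(text)
        binning = BinningScheme(tuple(doc["binning"]["cut_points"]),
                                int(doc["binning"]["target_bins"]))
        group = {(int(k.split("|")[0]), int(k.split("|")[1])): v
                 for k, v in doc["group_medians"].items()}
        return cls(binning=binning, group_medians=group,
                   sex_medians={int(k): v for k, v in doc["sex_medians"].items()},
                   global_medians=doc["global_medians"],
                   unusable=list(doc["unusable"]))


def fit_imputer(train: pd.DataFrame, binning: BinningScheme) -> ImputationPlan:
    """Compute the median table from training rows.

    Medians use observed values only (even counts: mean of the two
    central order statistics). Cells with no observed values simply get
    no entry; the fallback chain covers them at apply time.
    """
    if len(train) == 0:
        raise EmptyCohortError("cannot fit an imputer on an empty table")
    plan = ImputationPlan(binning=binning)
    features = feature_columns(train)
    bins = assign_bin(binning, train[AGE].to_numpy(dtype=float))
    sexes = train[SEX].to_numpy(dtype=int)

    for col in features:
        x = train[col].to_numpy(dtype=float)
        seen = ~np.isnan(x)
        if not seen.any():
            plan.unusable.append(col)
            continue
        plan.global_medians[col] = float(np.median(x[seen]))
        for s in (0, 1):
            m = seen & (sexes == s)
            if m.any():
                plan.sex_medians.setdefault(s, {})[col] = float(np.median(x[m]))
        for b in range(binning.n_bins):
            for s in (0, 1):
                m = seen & (bins == b) & (sexes == s)
                if m.any():
                    plan.group_medians.setdefault((b, s), {})[col] = \
                        float(np.median(x[m]))
    return plan


def apply_imputer(plan: ImputationPlan, table: pd.DataFrame) -> pd.DataFrame:
    """Fill every missing cell of the plan's features; returns a new table.

    Observed cells are untouched. Features not covered by the plan raise
    :class:`EvaluationError`; features the plan marked unusable are left
    as-is (drop them upstream).
    """
    known = set(plan.global_medians) | set(plan.unusable)
    unknown = [c for c in feature_columns(table) if c not in known]
    if unknown:
        raise EvaluationError(f"features absent from the imputation plan: {unknown}")
    out = table.copy()
    bins = assign_bin(plan.binning, out[AGE].to_numpy(dtype=float))
    sexes = out[SEX].to_numpy(dtype=int)
    for col in feature_columns(table):
        if col in plan.unusable:
            continue
        x = out[col].to_numpy(dtype=float)
        missing = np.flatnonzero(np.isnan(x))
        if missing.size == 0:
            continue
        fill = np.empty(missing.size)
        for j, i in enumerate(missing):
            cell = plan.group_medians.get((int(bins[i]), int(sexes[i])), {})
            if col in cell:
                fill[j] = cell[col]
            elif col in plan.sex_medians.get(int(sexes[i]), {}):
                fill[j] = plan.sex_medians[int(sexes[i])][col]
            else:
                fill[j] = plan.global_medians[col]
        x[missing] = fill
        out[col] = x
    return out
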