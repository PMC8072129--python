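"""Cohort preprocessing: label filtering, sparse-column removal, the
train/test split, and the per-class summary table.

The summary reports mean (SD) of each exam feature within cases and
controls and flags features whose distribution differs between classes.
Significance comes from a chi-square independence test on a quartile-
binned feature x label contingency table: each feature is cut at the
quartiles of its pooled observed values (4 bins) and tested against the
label at level ``alpha``. Features with too few observations, or whose
pooled values collapse to a single bin, are reported as untested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .exceptions import ConfigurationError, EmptyCohortError, StratificationError
from .tables import LABEL, feature_columns, labelled_mask, labels

_MIN_TESTED = 8  # fewer observed values than this -> feature left untested


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing thresholds and split parameters.

    ``max_missing_fraction`` drops features missing in more than that
    fraction of rows. ``max_missing_count``, when set, drops features with
    more than that many missing cells instead (absolute-count rule).
    """

    max_missing_fraction: float = 2.0 / 3.0
    max_missing_count: int | None = None
    train_fraction: float = 0.7
    split_seed: int = 0
    stratify: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigurationError("max_missing_fraction must lie in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.max_missing_count is not None and self.max_missing_count < 0:
            raise ConfigurationError("max_missing_count must be >= 0")


def filter_unlabeled(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows with an ultrasound label, preserving row order."""
    mask = labelled_mask(table)
    if not mask.any():
        raise EmptyCohortError("no labelled rows remain")
    return table.loc[mask]


def drop_sparse_features(table: pd.DataFrame,
                         config: PrepConfig) -> tuple[pd.DataFrame, list[str]]:
    """Remove features with too much missingness.

    Returns the reduced table and the names of the dropped columns.
    ``sex``, ``age`` and the label are never dropped.
    """
    config.validate()
    n = len(table)
    dropped: list[str] = []
    for col in feature_columns(table):
        n_missing = int(table[col].isna().sum())
        if config.max_missing_count is not None:
            if n_missing > config.max_missing_count:
                dropped.append(col)
        elif n > 0 and n_missing / n > config.max_missing_fraction:
            dropped.append(col)
    return table.drop(columns=dropped), dropped


def split_train_test(table: pd.DataFrame,
                     config: PrepConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 70/30 (by default) partition into train and test tables.

    The train size is ``round(train_fraction * n)`` exactly. With
    ``stratify`` the per-class training counts are proportional
    (largest-remainder rounding), so each class is within one sample of
    its global share. Seeded and deterministic.
    """
    config.validate()
    n = len(table)
    if n < 2:
        raise EmptyCohortError("need at least 2 rows to split")
    n_train = int(round(config.train_fraction * n))
    rng = np.random.default_rng(config.split_seed)

    if not config.stratify:
        order = rng.permutation(n)
        take = np.zeros(n, dtype=bool)
        take[order[:n_train]] = True
    else:
        y = labels(table)
        take = np.zeros(n, dtype=bool)
        class_idx = [np.flatnonzero(y == c) for c in (0, 1)]
        if any(len(ix) < 2 for ix in class_idx):
            raise StratificationError(
                "each class needs >= 2 rows for a stratified split")
        exact = [len(ix) * config.train_fraction for ix in class_idx]
        counts = [int(np.floor(e)) for e in exact]
        # largest-remainder rounding so the class counts sum to n_train
        frac_order = sorted(range(2), key=lambda c: exact[c] - counts[c],
                            reverse=True)
        for j in range(n_train - sum(counts)):
            counts[frac_order[j % 2]] += 1
        for ix, k in zip(class_idx, counts):
            chosen = rng.permutation(len(ix))[:k]
            take[ix[chosen]] = True
    train = table.loc[table.index[take]]
    test = table.loc[table.index[~take]]
    return train, test


def class_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature class comparison with chi-square significance flags.

    One row per exam feature: mean/SD among cases (``fld`` = 1) and
    controls, the chi-square statistic and p-value of the quartile-bin x
    label independence test, ``significant`` = (p <= alpha), and
    ``tested`` = False when the feature had fewer than 8 observed values
    or degenerate pooled quartiles.
    """
    y = labels(table)
    if len(np.unique(y)) < 2:
        raise EmptyCohortError("class summary requires both classes present")
    rows = []
    for col in feature_columns(table):
        x = table[col].to_numpy(dtype=float)
        seen = ~np.isnan(x)
        pos, neg = x[seen & (y == 1)], x[seen & (y == 0)]
        rec = {
            "feature": col,
            "n_observed": int(seen.sum()),
            "mean_fld": float(np.mean(pos)) if pos.size else np.nan,
            "sd_fld": float(np.std(pos, ddof=1)) if pos.size > 1 else np.nan,
            "mean_normal": float(np.mean(neg)) if neg.size else np.nan,
            "sd_normal": float(np.std(neg, ddof=1)) if neg.size > 1 else np.nan,
            "statistic": np.nan, "p_value": np.nan,
            "significant": False, "tested": False,
        }
        if seen.sum() >= _MIN_TESTED:
            edges = np.unique(np.quantile(x[seen], [0.25, 0.5, 0.75]))
            bins = np.searchsorted(edges, x[seen], side="left")
            contingency = pd.crosstab(bins, y[seen]).to_numpy()
            if contingency.shape[0] >= 2 and contingency.shape[1] == 2:
                stat, p, _, _ = chi2_contingency(contingency, correction=False)
                rec.update(statistic=float(stat), p_value=float(p),
                           significant=bool(p <= alpha), tested=True)
        rows.append(rec)
    return pd.DataFrame(rows)
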