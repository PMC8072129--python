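"""Gradient-boosted classification and its diagnostics.

The classifier itself is delegated to XGBoost — the one off-the-shelf
stage of the pipeline — configured with the screening model's fixed
hyperparameters (shallow trees, slow learning rate, positive-class
reweighting for the ~23% prevalence). Everything around it lives here:

* rank-based AUC (Mann-Whitney with ties counted 1/2),
* train/test learning curves over an ``n_estimators`` grid (bias-
  variance diagnostics),
* split-count feature importance — how often each feature is chosen as
  a split variable across the ensemble,
* the incremental-feature curve (retrain on the top-m features only),
* the false-negative summary (exam profile of missed cases vs all
  cases), and a plain 3-fold cross-validated AUC harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from xgboost import XGBClassifier

from .exceptions import InputError, TrainingError
from .tables import AGE, LABEL, SEX, labels


@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed hyperparameters of the screening classifier."""

    max_depth: int = 3
    learning_rate: float = 0.07
    n_estimators: int = 150
    scale_pos_weight: float = 2.0
    min_child_weight: float = 6.0
    gamma: float = 0.2
    reg_alpha: float = 0.1
    seed: int = 0

    def replace_estimators(self, n: int) -> "ClassifierConfig":
        return ClassifierConfig(self.max_depth, self.learning_rate, n,
                                self.scale_pos_weight, self.min_child_weight,
                                self.gamma, self.reg_alpha, self.seed)


@dataclass
class ModelHandle:
    """A fitted booster plus the feature-column order it was trained on."""

    model: XGBClassifier
    columns: list[str]

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted probability of fatty liver per row."""
        return self.model.predict_proba(table[self.columns])[:, 1]

    def split_counts(self) -> dict[str, int]:
        """Number of times each feature is used as a split variable."""
        raw = self.model.get_booster().get_score(importance_type="weight")
        return {c: int(raw.get(c, 0)) for c in self.columns}


def auc(scores, y) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random case outscores a random
    control, ties counted one half. Both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(y)
    if s.shape != lab.shape:
        raise InputError("scores and labels must have the same length")
    if not np.isin(lab, (0, 1)).all():
        raise InputError("labels must be binary 0/1")
    n1 = int(lab.sum())
    n0 = len(lab) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUC is undefined with a single class")
    ranks = rankdata(s)
    u = ranks[lab == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def model_columns(table: pd.DataFrame) -> list[str]:
    """Model inputs: sex, age, then every feature column, table order."""
    return [SEX, AGE] + [c for c in table.columns
                         if c not in (SEX, AGE, LABEL)]


def train_classifier(train: pd.DataFrame,
                     config: ClassifierConfig = ClassifierConfig(),
                     columns: Sequence[str] | None = None) -> ModelHandle:
    """Fit the boosted-tree classifier on a labelled, imputed table."""
    y = labels(train)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    cols = list(columns) if columns is not None else model_columns(train)
    model = XGBClassifier(
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        scale_pos_weight=config.scale_pos_weight,
        min_child_weight=config.min_child_weight,
        gamma=config.gamma,
        reg_alpha=config.reg_alpha,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(train[cols], y)
    return ModelHandle(model=model, columns=cols)


def learning_curve(train: pd.DataFrame, test: pd.DataFrame,
                   config: ClassifierConfig,
                   grid: Sequence[int]) -> pd.DataFrame:
    """Train/test AUC as the number of boosting rounds grows.

    Refits at each grid value; with deterministic histogram boosting the
    first k trees of a longer fit coincide with a k-round fit, so the
    train column is weakly increasing up to ties.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise InputError("grid must be non-empty and strictly ascending")
    rows = []
    y_train, y_test = labels(train), labels(test)
    for n in grid:
        handle = train_classifier(train, config.replace_estimators(int(n)))
        rows.append({
            "n_estimators": int(n),
            "train_auc": auc(handle.scores(train), y_train),
            "test_auc": auc(handle.scores(test), y_test),
        })
    return pd.DataFrame(rows)


def feature_importance(handle: ModelHandle) -> pd.DataFrame:
    """Split-count importances, descending, ties broken by name."""
    counts = handle.split_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(ranked, columns=["feature", "split_count"])


def incremental_feature_curve(train: pd.DataFrame, test: pd.DataFrame,
                              config: ClassifierConfig,
                              ranked_features: Sequence[str],
                              max_m: int) -> pd.DataFrame:
    """Test AUC of models retrained on the top-m features, m = 1..max_m."""
    ranked = list(ranked_features)
    if max_m < 1 or max_m > len(ranked):
        raise InputError("max_m must lie in [1, #ranked features]")
    y_test = labels(test)
    rows = []
    for m in range(1, max_m + 1):
        handle = train_classifier(train, config, columns=ranked[:m])
        rows.append({"n_features": m,
                     "test_auc": auc(handle.scores(test), y_test)})
    return pd.DataFrame(rows)


def false_negative_summary(test: pd.DataFrame, scores,
                           threshold: float = 0.5) -> pd.DataFrame:
    """Exam profile of missed cases.

    Per feature: mean/SD among false-negative cases (label 1 but score
    below ``threshold``) against mean/SD among all cases. Counts are
    included; with zero cases the table is empty.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InputError("threshold must lie in [0, 1]")
    y = labels(test)
    s = np.asarray(scores, dtype=float)
    pos = y == 1
    fn = pos & (s < threshold)
    rows = []
    for col in model_columns(test):
        x = test[col].to_numpy(dtype=float)
        xp, xf = x[pos], x[fn]
        rows.append({
            "feature": col,
            "n_positives": int(pos.sum()),
            "n_false_negatives": int(fn.sum()),
            "mean_false_negative": float(np.mean(xf)) if xf.size else np.nan,
            "sd_false_negative": float(np.std(xf, ddof=1)) if xf.size > 1 else np.nan,
            "mean_positive": float(np.mean(xp)) if xp.size else np.nan,
            "sd_positive": float(np.std(xp, ddof=1)) if xp.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def cross_val_auc(table: pd.DataFrame,
                  config: ClassifierConfig = ClassifierConfig(),
                  n_folds: int = 3) -> pd.DataFrame:
    """Plain stratified k-fold cross-validated AUC (default 3-fold)."""
    from sklearn.model_selection import StratifiedKFold

    y = labels(table)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        handle = train_classifier(table.iloc[tr], config)
        rows.append({"fold": fold,
                     "test_auc": auc(handle.scores(table.iloc[te]), y[te])})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Bundle of the evaluation artifacts for one pipeline run."""

    train_auc: float
    test_auc: float
    importances: pd.DataFrame
    learning_curve: pd.DataFrame | None = None
    incremental_curve: pd.DataFrame | None = None
    false_negatives: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)
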