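"""The canonical 39-feature participant table and its transformations.

Column order is immutable across the package: 31 eye-movement features
(pro/anti, pursuit, memory-guided, predictive blocks) followed by the 8
behavioral features.  Ablation subsets drop whole task blocks.  The
normalizer is a scikit-learn-style transformer fitted on training folds
only: median imputation of missing entries, then z-scoring with a floored
scale.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .behavior import BEHAVIOR_FEATURE_NAMES, assemble_behavior_features
from .eye_features import (EYE_FEATURE_NAMES, TASK_FEATURE_BLOCKS,
                           assemble_eye_features)

FEATURE_NAMES: list[str] = list(EYE_FEATURE_NAMES) + list(BEHAVIOR_FEATURE_NAMES)
ID_COLUMNS = ["participant_id", "group"]

SUBSETS: dict[str, list[str]] = {
    "combined": FEATURE_NAMES,
    "eye_only": list(EYE_FEATURE_NAMES),
    "behavior_only": list(BEHAVIOR_FEATURE_NAMES),
    "no_proanti": [c for c in FEATURE_NAMES
                   if c not in TASK_FEATURE_BLOCKS["prosaccade_antisaccade"]],
    "no_pursuit": [c for c in FEATURE_NAMES
                   if c not in TASK_FEATURE_BLOCKS["pursuit"]],
    "no_memory": [c for c in FEATURE_NAMES
                  if c not in TASK_FEATURE_BLOCKS["memory_guided"]],
    "no_predictive": [c for c in FEATURE_NAMES
                      if c not in TASK_FEATURE_BLOCKS["predictive"]],
}

SUBSET_SIZES = {"combined": 39, "eye_only": 31, "behavior_only": 8,
                "no_proanti": 29, "no_pursuit": 27, "no_memory": 34,
                "no_predictive": 35}


def build_feature_table(sessions) -> pd.DataFrame:
    """One row per participant: id, group, then the 39 canonical features.

    Participants whose recordings leave an entire task block unusable (all
    its features NaN) are dropped, and listed in ``df.attrs['dropped']``.
    """
    rows, dropped = [], []
    for s in sessions:
        feats = dict(assemble_eye_features(s))
        feats.update(assemble_behavior_features(s))
        blocks = list(TASK_FEATURE_BLOCKS.values()) + [BEHAVIOR_FEATURE_NAMES]
        if any(all(np.isnan(feats[c]) for c in block) for block in blocks):
            dropped.append(s.participant_id)
            continue
        rows.append({"participant_id": s.participant_id, "group": s.group,
                     **feats})
    df = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
    df.attrs["dropped"] = dropped
    return df


def select_subset(table: pd.DataFrame, name: str) -> pd.DataFrame:
    """Restrict a canonical table to one of the seven ablation subsets."""
    if name not in SUBSETS:
        raise ValueError(f"unknown subset {name!r}; known: {sorted(SUBSETS)}")
    cols = [c for c in ID_COLUMNS if c in table.columns] + SUBSETS[name]
    return table[cols]


class FeatureNormalizer(BaseEstimator, TransformerMixin):
    """Median-impute then z-score, with statistics from the fitted rows only.

    Constant columns get their scale floored (default 1e-8), so they map to
    zero rather than exploding.
    """

    def __init__(self, scale_floor: float = 1e-8):
        self.scale_floor = scale_floor

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("need a non-empty 2D array to fit")
        self.n_features_in_ = X.shape[1]
        self.median_ = np.nanmedian(X, axis=0)
        self.median_ = np.where(np.isnan(self.median_), 0.0, self.median_)
        Ximp = np.where(np.isnan(X), self.median_, X)
        self.center_ = Ximp.mean(axis=0)
        self.scale_ = np.maximum(Ximp.std(axis=0), self.scale_floor)
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with fitted normalizer")
        Ximp = np.where(np.isnan(X), self.median_, X)
        return (Ximp - self.center_) / self.scale_

    def inverse_transform(self, Z):
        return np.asarray(Z, float) * self.scale_ + self.center_


def fit_normalizer(train_rows) -> FeatureNormalizer:
    return FeatureNormalizer().fit(np.asarray(train_rows, float))


def apply_normalizer(rows, normalizer: FeatureNormalizer) -> np.ndarray:
    return normalizer.transform(np.asarray(rows, float))


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ID_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks canonical columns: {missing}")
    table[ID_COLUMNS + FEATURE_NAMES].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a canonical feature CSV; columns may arrive in any order but
    must be exactly the documented set."""
    df = pd.read_csv(path)
    expected = set(ID_COLUMNS + FEATURE_NAMES)
    unknown = set(df.columns) - expected
    if unknown:
        raise ValueError(f"unknown feature columns: {sorted(unknown)}")
    absent = expected - set(df.columns)
    if absent:
        raise ValueError(f"missing feature columns: {sorted(absent)}")
    return df[ID_COLUMNS + FEATURE_NAMES]


def feature_matrix(table: pd.DataFrame, subset: str = "combined"):
    """(X, y, ids) for modelling: values of the subset columns, group labels,
    participant ids."""
    sub = select_subset(table, subset)
    X = sub[SUBSETS[subset]].to_numpy(float)
    y = table["group"].to_numpy()
    ids = table["participant_id"].to_numpy()
    return X, y, ids
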