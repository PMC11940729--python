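"""Repeated-holdout evaluation protocol and descriptive statistics.

Each classification task (triple: young / elderly control / MCI; binary:
control / MCI) is evaluated over repeated 80/20 train/test splits (default
10 repeats, stratified by group).  Per repeat the normalizer is fitted on
the training fold only, the model is trained, and accuracy, per-class hit
rates (recall), confusion counts and misclassified participant IDs are
recorded; binary tasks additionally get the ROC AUC of the MCI-class
probability pooled over the test folds (a per-repeat average is reported
alongside).  The ablation suite runs the protocol over the seven feature
sets; the model comparison over the four classifier families.  Descriptive
screens: per-feature Welch t-tests (young vs pooled elderly, control vs
MCI) and the 31 x 8 Pearson correlation matrix between eye and behavioral
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .behavior import BEHAVIOR_FEATURE_NAMES
from .dataset import (SUBSETS, FeatureNormalizer, feature_matrix,
                      select_subset)
from .eye_features import EYE_FEATURE_NAMES
from .models import MODEL_KINDS, make_model

TRIPLE_CLASSES = ("control", "mci", "young")
BINARY_CLASSES = ("control", "mci")


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified holdout: 8:2 split, 10 repeats by default."""

    train_fraction: float = 0.8
    n_repeats: int = 10
    base_seed: int = 0
    stratified: bool = True


@dataclass
class EvalResult:
    task: str
    subset: str
    model_kind: str
    classes: tuple[str, ...]
    accuracies: list[float]
    hit_rates: dict[str, list[float]]
    confusions: list[np.ndarray]
    misclassified: list[list[tuple[str, str, str]]]  # (id, true, predicted)
    pooled_probs: np.ndarray = field(default=None, repr=False)
    pooled_labels: np.ndarray = field(default=None, repr=False)
    auc_per_repeat: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) \
            if len(self.accuracies) > 1 else 0.0

    def hit_rate_mean(self, cls: str) -> float:
        return float(np.nanmean(self.hit_rates[cls]))

    def hit_rate_sd(self, cls: str) -> float:
        v = np.asarray(self.hit_rates[cls], float)
        v = v[~np.isnan(v)]
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    @property
    def auc(self) -> float:
        """MCI-class AUC pooled over the test folds (binary tasks only)."""
        if self.pooled_probs is None:
            return float("nan")
        return roc_auc(self.pooled_probs, self.pooled_labels)

    def summary(self) -> dict:
        out = {"task": self.task, "subset": self.subset,
               "model": self.model_kind,
               "accuracy_mean": self.mean_accuracy,
               "accuracy_sd": self.sd_accuracy}
        for cls in self.classes:
            out[f"hit_rate_{cls}_mean"] = self.hit_rate_mean(cls)
            out[f"hit_rate_{cls}_sd"] = self.hit_rate_sd(cls)
        if self.task == "binary":
            out["auc_pooled"] = self.auc
            out["auc_mean"] = (float(np.nanmean(self.auc_per_repeat))
                               if self.auc_per_repeat else float("nan"))
        return out


def _task_table(table: pd.DataFrame, task: str) -> pd.DataFrame:
    if task == "triple":
        return table
    if task == "binary":
        return table[table["group"].isin(BINARY_CLASSES)].reset_index(drop=True)
    raise ValueError("task must be 'triple' or 'binary'")


def repeated_holdout(table: pd.DataFrame, task: str = "triple",
                     subset: str = "combined", model_kind: str = "cnn",
                     scheme: SplitScheme = SplitScheme(),
                     model_params: dict | None = None) -> EvalResult:
    """Run the full repeated-split protocol for one feature set and model."""
    tbl = _task_table(table, task)
    X, y, ids = feature_matrix(tbl, subset)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes present")
    result = EvalResult(task=task, subset=subset, model_kind=model_kind,
                        classes=classes, accuracies=[],
                        hit_rates={c: [] for c in classes}, confusions=[],
                        misclassified=[])
    pooled_p, pooled_y = [], []
    ss = np.random.SeedSequence([int(scheme.base_seed), 777])
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                    for s in ss.spawn(scheme.n_repeats)]
    for seed_r in repeat_seeds:
        for attempt in range(20):
            tr, te = train_test_split(
                np.arange(len(y)), train_size=scheme.train_fraction,
                random_state=(seed_r + attempt) % (2**31 - 1),
                stratify=y if scheme.stratified else None)
            if len(np.unique(y[tr])) == len(classes):
                break
        else:
            raise RuntimeError("could not draw a training fold with all classes")
        norm = FeatureNormalizer().fit(X[tr])
        Xtr, Xte = norm.transform(X[tr]), norm.transform(X[te])
        model = make_model(model_kind, seed=seed_r, **(model_params or {}))
        model.fit(Xtr, y[tr])
        proba = model.predict_proba(Xte)
        order = np.argsort(model.classes_)
        proba = proba[:, order]  # columns in sorted-class order
        pred = np.asarray(sorted(model.classes_))[proba.argmax(axis=1)]
        cm = confusion_matrix(y[te], pred, labels=list(classes))
        result.confusions.append(cm)
        result.accuracies.append(float(np.trace(cm) / cm.sum()))
        for ci, cls in enumerate(classes):
            total = cm[ci].sum()
            result.hit_rates[cls].append(
                float(cm[ci, ci] / total) if total else float("nan"))
        result.misclassified.append(
            [(str(ids[te][k]), str(y[te][k]), str(pred[k]))
             for k in range(len(te)) if pred[k] != y[te][k]])
        if task == "binary":
            mci_col = list(classes).index("mci")
            pooled_p.extend(proba[:, mci_col])
            pooled_y.extend(y[te] == "mci")
            fold_pos = y[te] == "mci"
            result.auc_per_repeat.append(
                roc_auc(proba[:, mci_col], fold_pos)
                if 0 < fold_pos.sum() < len(fold_pos) else float("nan"))
    if task == "binary":
        result.pooled_probs = np.asarray(pooled_p)
        result.pooled_labels = np.asarray(pooled_y)
    return result


def roc_auc(scores, positive) -> float:
    """AUC of the positive-class score; equals the normalised Mann-Whitney
    U statistic (pair-counting with half credit for ties)."""
    positive = np.asarray(positive, bool)
    if positive.all() or not positive.any():
        raise ValueError("AUC undefined: one class absent")
    return float(roc_auc_score(positive, np.asarray(scores, float)))


def ablation_suite(table: pd.DataFrame, task: str = "triple",
                   model_kind: str = "cnn",
                   scheme: SplitScheme = SplitScheme(),
                   model_params: dict | None = None
                   ) -> dict[str, EvalResult]:
    """The seven-feature-set ablation, one EvalResult per subset."""
    return {name: repeated_holdout(table, task, name, model_kind, scheme,
                                   model_params)
            for name in SUBSETS}


def model_comparison(table: pd.DataFrame, task: str = "triple",
                     scheme: SplitScheme = SplitScheme(),
                     model_params: dict | None = None
                     ) -> dict[str, EvalResult]:
    """CNN vs FCNN vs SVM vs Random Forest on the combined features."""
    out = {}
    for kind in MODEL_KINDS:
        params = model_params if kind in ("cnn", "fcnn") else None
        out[kind] = repeated_holdout(table, task, "combined", kind, scheme,
                                     params)
    return out


def results_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Format a suite of results as 'mean (SD)' percentage strings."""
    rows = []
    for name, r in results.items():
        row = {"feature_set": name,
               "accuracy": f"{100 * r.mean_accuracy:.2f} "
                           f"({100 * r.sd_accuracy:.2f})"}
        for cls in r.classes:
            row[f"hit_rate_{cls}"] = (f"{100 * r.hit_rate_mean(cls):.2f} "
                                      f"({100 * r.hit_rate_sd(cls):.2f})")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive statistics


def group_difference_screen(table: pd.DataFrame, alpha: float = 0.05,
                            correction: str | None = None) -> pd.DataFrame:
    """Per-feature Welch t-tests: young vs pooled elderly, control vs MCI.

    Raw p-values by default; ``correction='fdr_bh'`` applies
    Benjamini-Hochberg within each contrast.
    """
    groups = table["group"]
    young = table[groups == "young"]
    elderly = table[groups.isin(["control", "mci"])]
    control = table[groups == "control"]
    mci = table[groups == "mci"]
    for name, sub in (("young", young), ("elderly", elderly)):
        if len(sub) < 2:
            raise ValueError(f"need >= 2 rows in the {name} group")
    rows = []
    for feat in EYE_FEATURE_NAMES + BEHAVIOR_FEATURE_NAMES:
        t_ye, p_ye = stats.ttest_ind(young[feat].dropna(),
                                     elderly[feat].dropna(), equal_var=False)
        if len(control) >= 2 and len(mci) >= 2:
            t_cm, p_cm = stats.ttest_ind(control[feat].dropna(),
                                         mci[feat].dropna(), equal_var=False)
        else:
            t_cm, p_cm = float("nan"), float("nan")
        rows.append({"feature": feat,
                     "kind": "eye" if feat in EYE_FEATURE_NAMES else "behavior",
                     "t_young_elderly": float(t_ye),
                     "p_young_elderly": float(p_ye),
                     "t_control_mci": float(t_cm),
                     "p_control_mci": float(p_cm)})
    df = pd.DataFrame(rows)
    for col in ("p_young_elderly", "p_control_mci"):
        p = df[col].to_numpy()
        if correction == "fdr_bh":
            ok = ~np.isnan(p)
            adj = np.full_like(p, np.nan)
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            df[col.replace("p_", "p_adj_")] = adj
            df[col.replace("p_", "pass_")] = adj < alpha
        else:
            df[col.replace("p_", "pass_")] = p < alpha
    return df


def feature_behavior_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided p) between each eye and behavioral feature."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    rows = []
    for eye in EYE_FEATURE_NAMES:
        for beh in BEHAVIOR_FEATURE_NAMES:
            sub = table[[eye, beh]].dropna()
            a, b = sub[eye].to_numpy(), sub[beh].to_numpy()
            if len(a) < 3 or a.std() == 0 or b.std() == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(a, b)
            rows.append({"eye_feature": eye, "behavior_feature": beh,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
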