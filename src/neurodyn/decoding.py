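"""Condition decoding from pairwise-correlation features.

Verification stage: if the yes/no decision leaves a signature in
inter-regional coupling, a classifier fed per-trial pairwise correlations
of selected ROI time courses should predict the response above chance.
With 10 ROIs there are C(10,2) = 45 correlation features per trial. A
regularized linear model (standardized logistic regression) is evaluated
with stratified five-fold cross-validation, and chance level is calibrated
with a label-permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .spatiotemporal import NormalizedTrialSeries

FEATURE_PREFIX = "r_"


def feature_names(roi_subset) -> list:
    """Column names for the vectorized upper triangle, in lexicographic
    pair order of the given ROI ordering."""
    return [f"{FEATURE_PREFIX}{a}_{b}"
            for a, b in itertools.combinations(roi_subset, 2)]


def trial_features(norm: NormalizedTrialSeries, roi_subset) -> pd.DataFrame:
    """Per-trial pairwise-correlation feature rows for one subject.

    Each row is one trial: the upper triangle of the correlation matrix of
    the selected ROI rows over that trial's resampled segment, in fixed
    lexicographic pair order. Pairs involving a constant segment are set
    to 0 and flagged in the ``degenerate`` column.
    """
    roi_subset = list(roi_subset)
    if len(roi_subset) < 2:
        raise ValueError("need at least 2 ROIs")
    if norm.trial_length < 3:
        raise ValueError("trials need at least 3 samples for correlations")
    rows = [norm.roi_ids.index(r) for r in roi_subset]
    records = []
    iu = np.triu_indices(len(rows), k=1)
    for k in range(norm.n_trials):
        seg = norm.segment(k)[rows]
        sd = seg.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cmat = np.corrcoef(seg)
        degenerate = bool(np.any(sd == 0))
        feats = cmat[iu]
        feats = np.where(np.isfinite(feats), feats, 0.0)
        records.append({
            "subject": norm.subject_id, "trial": k, "label": norm.labels[k],
            "degenerate": degenerate,
            **dict(zip(feature_names(roi_subset), feats)),
        })
    return pd.DataFrame.from_records(records)


def build_feature_table(normalized_sets, roi_subset) -> pd.DataFrame:
    """Stack per-subject trial features into one cohort table."""
    frames = [trial_features(norm, roi_subset) for norm in normalized_sets]
    return pd.concat(frames, ignore_index=True)


def _split_xy(table: pd.DataFrame):
    cols = [c for c in table.columns if c.startswith(FEATURE_PREFIX)]
    X = table[cols].to_numpy(dtype=float)
    y = (table["label"] == "yes").to_numpy(dtype=int)
    return X, y


def _classifier(family: str, seed: int):
    if family == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(C=1.0, max_iter=2000,
                                                random_state=seed))
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class CvReport:
    """Cross-validated accuracy summary (fractions in [0, 1])."""

    train_acc_mean: float
    train_acc_sd: float
    test_acc_mean: float
    test_acc_sd: float
    n_folds: int
    n_trials: int
    seed: int

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}


def crossval_classify(table: pd.DataFrame, n_folds: int = 5, seed: int = 0,
                      classifier: str = "logistic",
                      group_by_subject: bool = False) -> CvReport:
    """Stratified K-fold accuracy of a regularized linear classifier.

    ``group_by_subject=True`` switches to subject-grouped folds, which
    prevents trials of one subject from straddling the train/test split
    (trial-level stratified CV can leak subject identity).
    """
    X, y = _split_xy(table)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both yes and no trials are required")
    if n_folds < 2 or n_folds > counts.min():
        raise ValueError("n_folds must be >= 2 and <= the smaller class count")
    if group_by_subject:
        groups = pd.factorize(table["subject"])[0]
        splits = GroupKFold(n_splits=n_folds).split(X, y, groups)
    else:
        splits = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                 random_state=seed).split(X, y)
    train_acc, test_acc = [], []
    for train, test in splits:
        model = _classifier(classifier, seed)
        model.fit(X[train], y[train])
        train_acc.append(model.score(X[train], y[train]))
        test_acc.append(model.score(X[test], y[test]))
    return CvReport(float(np.mean(train_acc)), float(np.std(train_acc)),
                    float(np.mean(test_acc)), float(np.std(test_acc)),
                    n_folds, len(y), seed)


@dataclass
class PermutationReport:
    """Label-permutation null for the cross-validated test accuracy."""

    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {"observed": float(self.observed),
                "null_mean": float(self.null.mean()),
                "null_sd": float(self.null.std()),
                "p_value": float(self.p_value),
                "n_permutations": int(self.n_permutations)}


def permutation_chance(table: pd.DataFrame, n_permutations: int = 1000,
                       seed: int = 0, n_folds: int = 5,
                       classifier: str = "logistic") -> PermutationReport:
    """Empirical chance distribution by shuffling trial labels.

    p is the fraction of permuted-label accuracies at least as large as the
    observed accuracy.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    observed = crossval_classify(table, n_folds=n_folds, seed=seed,
                                 classifier=classifier).test_acc_mean
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    shuffled = table.copy()
    for i in range(n_permutations):
        shuffled["label"] = rng.permutation(table["label"].to_numpy())
        null[i] = crossval_classify(shuffled, n_folds=n_folds, seed=seed,
                                    classifier=classifier).test_acc_mean
    p = float(np.mean(null >= observed))
    return PermutationReport(observed, null, p, n_permutations)
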