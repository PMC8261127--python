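"""Batch harmonization and random-forest rhythm classification.

Training (RNA-seq) and test (microarray-like) cohorts are merged per feature
gene and harmonized by a per-batch location-scale adjustment (each gene is
standardized to the pooled moments, then every batch's mean and variance are
matched to the pooled estimates).  A random forest on the key lncRNA plus its
ceRNA partner mRNAs is validated by stratified six-fold cross-validation
(pooled out-of-fold probabilities) and on the held-out cohort; discrimination
is the rank-based (Mann-Whitney) AUC with midrank tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .cerna import CeRNANetwork

__all__ = [
    "ClassifierReport",
    "combat_adjust",
    "extract_pair_features",
    "auc_rank",
    "cross_validate_rf",
    "fit_rf",
    "evaluate_test",
    "build_classifier_report",
]

N_TREES = 500


def combat_adjust(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-gene, per-batch location-scale harmonization.

    Each gene is standardized to its pooled mean and variance; within every
    batch the mean is removed and the variance rescaled to the pooled
    estimate.  After adjustment the per-gene batch means coincide.  A single
    batch therefore returns the input unchanged (within float precision).
    """
    batches = batches.loc[expr.columns]
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batch(es) with fewer than 2 samples: {bad}")
    X = expr.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    out = Z.copy()
    for b in counts.index:
        cols = (batches == b).to_numpy()
        zb = Z[:, cols]
        bm = zb.mean(axis=1, keepdims=True)
        bs = zb.std(axis=1, ddof=1, keepdims=True)
        bs = np.where(bs == 0, 1.0, bs)
        out[:, cols] = (zb - bm) / bs
    adjusted = out * sd_safe + mu
    return pd.DataFrame(adjusted, index=expr.index, columns=expr.columns)


def extract_pair_features(network: CeRNANetwork, lncrna: str) -> list[str]:
    """The lncRNA followed by its deduplicated, ID-sorted partner mRNAs."""
    if lncrna not in set(network.lncrnas()):
        raise ValueError(f"lncRNA {lncrna} not present in the ceRNA network")
    partners = network.partners(lncrna)
    if not partners:
        warnings.warn(f"lncRNA {lncrna} has no partner mRNAs; single-feature model")
    return [lncrna] + partners


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC ``U / (n1 n0)`` with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cross_validate_rf(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 6,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> tuple[float, list[float]]:
    """Stratified k-fold CV; pooled out-of-fold probabilities give one AUC.

    Per-fold AUCs are returned alongside.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if min(np.bincount(labels, minlength=2)) < k:
        raise ValueError("each class needs at least k samples for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(labels.size)
    fold_aucs = []
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold)
        rf.fit(X[tr], labels[tr])
        proba = rf.predict_proba(X[te])[:, list(rf.classes_).index(1)]
        oof[te] = proba
        fold_aucs.append(auc_rank(proba, labels[te]))
    return auc_rank(oof, labels), fold_aucs


def fit_rf(X: np.ndarray, labels: np.ndarray, seed: int = 0, n_trees: int = N_TREES):
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(np.asarray(X, dtype=float), np.asarray(labels).astype(int))
    return rf


def evaluate_test(
    model, X_test: np.ndarray, labels_test: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Held-out AUC (rank formulation) plus ROC points (FPR, TPR)."""
    labels_test = np.asarray(labels_test).astype(int)
    if labels_test.min() == labels_test.max():
        raise ValueError("test labels contain a single class")
    proba = model.predict_proba(np.asarray(X_test, dtype=float))
    proba = proba[:, list(model.classes_).index(1)]
    auc = auc_rank(proba, labels_test)
    fpr, tpr, _ = roc_curve(labels_test, proba)
    return auc, fpr, tpr


@dataclass
class ClassifierReport:
    """Everything reported for one key-lncRNA classifier."""

    lncrna: str
    features: list[str]
    cv_auc: float
    fold_aucs: list[float]
    test_auc: float
    roc_fpr: list[float]
    roc_tpr: list[float]
    seed: int
    batch_removed: bool

    def to_dict(self) -> dict:
        return {
            "lncrna": self.lncrna,
            "features": self.features,
            "cv_auc": self.cv_auc,
            "fold_aucs": self.fold_aucs,
            "test_auc": self.test_auc,
            "roc_fpr": self.roc_fpr,
            "roc_tpr": self.roc_tpr,
            "seed": self.seed,
            "batch_removed": self.batch_removed,
        }


def build_classifier_report(
    lncrna: str,
    features: Sequence[str],
    train_expr: pd.DataFrame,
    train_labels: pd.Series,
    test_expr: pd.DataFrame,
    test_labels: pd.Series,
    train_batches: pd.Series | None = None,
    test_batch: str = "test",
    remove_batch: bool = True,
    k: int = 6,
    seed: int = 0,
) -> ClassifierReport:
    """Merge cohorts on the feature genes, optionally harmonize batches, then
    cross-validate on the training cohort and evaluate on the held-out one.

    ``train_labels``/``test_labels`` are binary AF indicators (AF = 1).
    """
    missing = [g for g in features if g not in train_expr.index or g not in test_expr.index]
    if missing:
        raise ValueError(f"feature gene(s) missing from a cohort: {missing[:5]}")
    feats = list(features)
    merged = pd.concat([train_expr.loc[feats], test_expr.loc[feats]], axis=1)
    if train_batches is None:
        train_batches = pd.Series("train", index=train_expr.columns)
    batches = pd.concat(
        [train_batches, pd.Series(test_batch, index=test_expr.columns)]
    )
    if remove_batch:
        merged = combat_adjust(merged, batches)
    Xtr = merged[train_expr.columns].to_numpy().T
    Xte = merged[test_expr.columns].to_numpy().T
    ytr = train_labels.loc[train_expr.columns].to_numpy().astype(int)
    yte = test_labels.loc[test_expr.columns].to_numpy().astype(int)
    cv_auc, fold_aucs = cross_validate_rf(Xtr, ytr, k=k, seed=seed)
    model = fit_rf(Xtr, ytr, seed=seed)
    test_auc, fpr, tpr = evaluate_test(model, Xte, yte)
    return ClassifierReport(
        lncrna=lncrna,
        features=feats,
        cv_auc=float(cv_auc),
        fold_aucs=[float(a) for a in fold_aucs],
        test_auc=float(test_auc),
        roc_fpr=[float(x) for x in fpr],
        roc_tpr=[float(x) for x in tpr],
        seed=int(seed),
        batch_removed=bool(remove_batch),
    )
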