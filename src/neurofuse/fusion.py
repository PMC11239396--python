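"""Multimodal fusion and gradient-boosted classification.

Per-subject feature vectors from the three modalities are concatenated,

    F_i = X_i (+) Z_i (+) W_i,

with X_i the 1024 morphological features, Z_i the selected FNC connections
and W_i the selected SNP dosages, and classified with an additive ensemble
of classification-and-regression trees (XGBoost),

    y_i = sum_t f_t(F_i),  f_t in the CART function space.

Evaluation follows stratified 5-fold cross-validation (each fold holds out
20% of subjects); relevance-based feature selection and hyperparameter
tuning run inside each training fold only, so no held-out subject can
influence the features or the model that scores it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .selectors import (
    CNNHyperparams,
    FNC_THRESHOLD,
    SNP_TOP_K,
    apply_selection,
    rank_features,
    select_features,
    train_modality_cnn,
)

__all__ = [
    "FeatureBundle",
    "CVReport",
    "DEFAULT_GRID",
    "fuse",
    "train_classifier",
    "cross_validate",
    "compute_metrics",
]

MODALITY_ORDER = ("smri", "fnc", "snp")  # X, Z, W segments, in fusion order

#: tuning grid for the tree ensemble, searched on an inner validation
#: split carved from each training fold
DEFAULT_GRID = {
    "n_estimators": [100],
    "max_depth": [2, 4],
    "learning_rate": [0.1, 0.3],
    "subsample": [1.0],
}


@dataclass
class FeatureBundle:
    """Fused per-subject features with modality-segment bookkeeping."""

    fused: np.ndarray  # (n, total width)
    offsets: dict  # modality -> (start, stop) column range
    subject_ids: list = field(default_factory=list)
    labels: np.ndarray | None = None

    def segment(self, modality):
        start, stop = self.offsets[modality]
        return self.fused[:, start:stop]

    @property
    def width(self):
        return self.fused.shape[1]


def fuse(X=None, Z=None, W=None, subject_ids=None, labels=None) -> FeatureBundle:
    """Concatenate modality segments in the order X (morphological),
    Z (connectivity), W (genomic); any non-empty subset may be fused.

    ``subject_ids`` may be a per-modality dict used to verify row
    alignment across modalities.
    """
    segments = {"smri": X, "fnc": Z, "snp": W}
    present = {m: np.asarray(v, dtype=float)
               for m, v in segments.items() if v is not None}
    if not present:
        raise ValueError("at least one modality must be provided")
    counts = {m: v.shape[0] for m, v in present.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"subject counts differ across modalities: {counts}")
    ids = None
    if isinstance(subject_ids, dict):
        id_lists = {m: list(subject_ids[m]) for m in present if m in subject_ids}
        distinct = {tuple(v) for v in id_lists.values()}
        if len(distinct) > 1:
            raise ValueError("subject order differs across modalities")
        ids = list(distinct.pop()) if distinct else None
    elif subject_ids is not None:
        ids = list(subject_ids)
    parts, offsets, cursor = [], {}, 0
    for m in MODALITY_ORDER:
        if m in present:
            seg = present[m]
            offsets[m] = (cursor, cursor + seg.shape[1])
            cursor += seg.shape[1]
            parts.append(seg)
    return FeatureBundle(
        fused=np.concatenate(parts, axis=1),
        offsets=offsets,
        subject_ids=ids or [],
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )


def train_classifier(X, y, params=None, seed=0) -> XGBClassifier:
    """Fit the CART gradient-boosting ensemble; deterministic given seed."""
    if isinstance(X, FeatureBundle):
        if X.labels is None and y is None:
            raise ValueError("labels required")
        y = X.labels if y is None else y
        X = X.fused
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    params = dict(params or {})
    model = XGBClassifier(
        n_estimators=params.get("n_estimators", 100),
        max_depth=params.get("max_depth", 3),
        learning_rate=params.get("learning_rate", 0.3),
        subsample=params.get("subsample", 1.0),
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def compute_metrics(y_true, y_pred):
    """Accuracy, precision, recall, F1 with the case class positive.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 their harmonic mean;
    an all-negative prediction has precision 0 (with a warning).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    accuracy = (tp + tn) / len(y_true)
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision defined as 0",
                      stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


@dataclass
class CVReport:
    """Per-fold and summary metrics of one cross-validated run."""

    fold_metrics: list  # list of metric dicts, one per fold
    fold_test_indices: list  # held-out subject indices per fold
    modalities: tuple
    classifier_params: list  # chosen params per fold
    selection_sizes: list  # per fold: {modality: n_selected}
    seed: int
    k: int

    def summary(self):
        out = {}
        for key in ("accuracy", "precision", "recall", "f1"):
            vals = np.array([m[key] for m in self.fold_metrics])
            out[key] = {"mean": float(vals.mean()), "std": float(vals.std())}
        return out

    def to_dict(self):
        return {
            "k": self.k,
            "seed": self.seed,
            "modalities": list(self.modalities),
            "fold_metrics": self.fold_metrics,
            "fold_test_indices": [list(map(int, f)) for f in self.fold_test_indices],
            "classifier_params": self.classifier_params,
            "selection_sizes": self.selection_sizes,
            "summary": self.summary(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def stratified_folds(labels, k, seed):
    """Disjoint, exhaustive, class-balanced test folds."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _tune_and_fit(X_train, y_train, grid, seed):
    combos = [
        {"n_estimators": n, "max_depth": d, "learning_rate": lr, "subsample": s}
        for n in grid["n_estimators"]
        for d in grid["max_depth"]
        for lr in grid["learning_rate"]
        for s in grid["subsample"]
    ]
    if len(combos) == 1:
        return train_classifier(X_train, y_train, combos[0], seed), combos[0]
    tr, val = train_test_split(
        np.arange(len(y_train)), test_size=0.25, stratify=y_train,
        random_state=seed,
    )
    best, best_acc = None, -1.0
    for combo in combos:
        model = train_classifier(X_train[tr], y_train[tr], combo, seed)
        acc = float((model.predict(X_train[val]) == y_train[val]).mean())
        if acc > best_acc:
            best, best_acc = combo, acc
    return train_classifier(X_train, y_train, best, seed), best


def cross_validate(
    data,
    labels,
    modalities=MODALITY_ORDER,
    k=5,
    seed=0,
    fnc_rule=("threshold", FNC_THRESHOLD),
    snp_rule=("top_k", SNP_TOP_K),
    cnn_hyperparams=None,
    grid=None,
) -> CVReport:
    """Stratified k-fold evaluation of the (sub)set of modalities.

    ``data`` maps modality names to full-cohort matrices: ``smri`` the
    encoder output (used as-is: the encoder is a fixed, label-blind
    transform), ``fnc`` the vectorized 1378-connection features, ``snp``
    the dosage matrix. FNC/SNP relevance ranking and selection are re-run
    inside every training fold; the held-out 20% only ever sees the
    resulting column subset.
    """
    labels = np.asarray(labels, dtype=int)
    modalities = tuple(m for m in MODALITY_ORDER if m in modalities)
    if not modalities:
        raise ValueError("no valid modalities requested")
    for m in modalities:
        if m not in data:
            raise KeyError(f"modality {m!r} missing from data")
        if np.asarray(data[m]).shape[0] != len(labels):
            raise ValueError(f"modality {m!r} row count != label count")
    if k < 2:
        raise ValueError("k must be at least 2")
    grid = grid or DEFAULT_GRID
    hp = cnn_hyperparams or CNNHyperparams()
    folds = stratified_folds(labels, k, seed)
    rules = {"fnc": fnc_rule, "snp": snp_rule}

    fold_metrics, params_used, sel_sizes = [], [], []
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.where(train_mask)[0]
        y_tr, y_te = labels[train_idx], labels[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(f"fold {fold_id} lost a class after stratification")
        segs_tr, segs_te, sizes = {}, {}, {}
        for m in modalities:
            mat = np.asarray(data[m], dtype=float)
            if m == "smri":
                segs_tr[m], segs_te[m] = mat[train_idx], mat[test_idx]
                sizes[m] = mat.shape[1]
                continue
            net = train_modality_cnn(
                mat[train_idx], y_tr, hp, seed=seed * 1000 + fold_id
            )
            relevance = rank_features(net, mat[train_idx])
            selection = select_features(relevance, rules[m])
            selection.modality = m
            segs_tr[m] = apply_selection(mat[train_idx], selection)
            segs_te[m] = apply_selection(mat[test_idx], selection)
            sizes[m] = selection.n_selected
        bundle_tr = fuse(
            X=segs_tr.get("smri"), Z=segs_tr.get("fnc"), W=segs_tr.get("snp")
        )
        bundle_te = fuse(
            X=segs_te.get("smri"), Z=segs_te.get("fnc"), W=segs_te.get("snp")
        )
        model, chosen = _tune_and_fit(
            bundle_tr.fused, y_tr, grid, seed * 1000 + fold_id
        )
        y_pred = model.predict(bundle_te.fused)
        fold_metrics.append(compute_metrics(y_te, y_pred))
        params_used.append(chosen)
        sel_sizes.append(sizes)
    return CVReport(
        fold_metrics=fold_metrics,
        fold_test_indices=[list(map(int, f)) for f in folds],
        modalities=modalities,
        classifier_params=params_used,
        selection_sizes=sel_sizes,
        seed=seed,
        k=k,
    )
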