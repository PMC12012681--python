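"""Fold-in projection of unseen samples and classification in topic space.

A fitted topic model defines a low-dimensional embedding: a new sample
never seen during fitting is projected by
``P(topic|sample) = sum_g P(topic|gene) * P(gene|sample)``, i.e. its
normalized expression vector (restricted to the genes used in topic
modeling) multiplied by the genes x topics matrix.  For hard-membership
models P(topic|gene) is the membership indicator and the projection of
a training sample reproduces its half-edge theta exactly.

On top of the embedding sit a small feed-forward classifier (one hidden
layer of 100 rectified-linear units, stochastic gradient descent,
softmax output for tissues / single sigmoid for binary status) and a
5-nearest-neighbor euclidean baseline, both evaluated on a 95/5
train/test split with 25% of the training set held out for validation
and never retraining the topic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .latent_space import gene_topic_scores
from .topic_inference import CountMatrix, TopicModelResult

__all__ = [
    "EmbeddingMatrix",
    "fold_in_projection",
    "normalize_features",
    "train_topic_classifier",
    "knn_baseline",
    "evaluate_predictions",
]


@dataclass
class EmbeddingMatrix:
    """Design matrix X of P(topic|sample) rows plus its normalized form."""

    X: np.ndarray
    X_norm: np.ndarray
    feature_stats: pd.DataFrame
    sample_ids: list[str]


def _gene_topic_matrix(result: TopicModelResult) -> np.ndarray:
    """P(topic|gene) rows: hard-membership indicator when available."""
    if result.gene_topic_membership is not None:
        mat = np.zeros((len(result.gene_ids), result.n_topics))
        member = result.gene_topic_membership
        ok = member >= 0
        mat[np.nonzero(ok)[0], member[ok]] = 1.0
        return mat
    return gene_topic_scores(result).theta_gt


def fold_in_projection(
    expr_new: CountMatrix,
    result: TopicModelResult,
    selected_genes: list[str] | None = None,
) -> np.ndarray:
    """Project new samples into the fitted topic space.

    Expression is restricted to ``selected_genes`` (default: the genes
    the model was fitted on), normalized within that set to
    P(gene|sample), multiplied by the genes x topics P(topic|gene)
    matrix, and each row renormalized to sum to 1.  Genes of the model
    missing from the new matrix contribute zero.  Samples with no
    expression on the selected genes are an error.
    """
    genes = list(selected_genes) if selected_genes is not None else list(result.gene_ids)
    model_index = {g: i for i, g in enumerate(result.gene_ids)}
    unknown = [g for g in genes if g not in model_index]
    if unknown:
        raise ValueError(f"genes not in the fitted model: {unknown[:10]}")
    new_index = {g: i for i, g in enumerate(expr_new.gene_ids)}
    shared = [g for g in genes if g in new_index]
    if not shared:
        raise ValueError("no selected genes present in the new expression matrix")
    expr = expr_new.values[[new_index[g] for g in shared], :].astype(float)
    totals = expr.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(expr_new.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero expression on selected genes: {bad}")
    p_gene_sample = expr / totals  # genes x samples
    tg = _gene_topic_matrix(result)[[model_index[g] for g in shared], :]
    theta_new = p_gene_sample.T @ tg
    row_tot = theta_new.sum(axis=1, keepdims=True)
    if np.any(row_tot == 0):
        bad = [
            s for s, t in zip(expr_new.sample_ids, row_tot.ravel()) if t == 0
        ]
        raise ValueError(f"samples project to the zero vector: {bad}")
    return theta_new / row_tot


def normalize_features(
    X: np.ndarray,
    feature_stats: pd.DataFrame | None = None,
    per_sample: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Center by feature mean and scale by half the feature range.

    ``X̄ = (X - mean) / (0.5 (max - min))`` with statistics computed on
    the training set only (pass them back in for test data).  Constant
    features map to 0.  ``per_sample=True`` instead centers and scales
    each row by its own mean and range (the literal row-wise reading of
    the normalization formula), for comparison.
    """
    X = np.asarray(X, dtype=float)
    if per_sample:
        mean = X.mean(axis=1, keepdims=True)
        half_range = 0.5 * (X.max(axis=1, keepdims=True) - X.min(axis=1, keepdims=True))
        out = np.divide(
            X - mean, np.where(half_range == 0, 1.0, half_range),
            out=np.zeros_like(X), where=True,
        )
        return out, pd.DataFrame()
    if feature_stats is None:
        feature_stats = pd.DataFrame(
            {"mean": X.mean(axis=0), "min": X.min(axis=0), "max": X.max(axis=0)}
        )
    mean = feature_stats["mean"].to_numpy()
    half_range = 0.5 * (feature_stats["max"] - feature_stats["min"]).to_numpy()
    constant = half_range == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to 0", UserWarning
        )
    out = (X - mean) / np.where(constant, 1.0, half_range)
    out[:, constant] = 0.0
    return out, feature_stats


def _split(X, y, test_size, seed):
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_test = int(np.ceil(test_size * len(y))) if test_size < 1 else int(test_size)
    stratify = y if counts.min() >= 2 and n_test >= len(classes) else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=stratify
    )
    missing = set(classes.tolist()) - set(np.unique(y_tr).tolist())
    if missing:
        raise ValueError(f"classes absent from the training split: {sorted(missing)}")
    return X_tr, X_te, y_tr, y_te


def train_topic_classifier(
    X_norm: np.ndarray,
    labels,
    task: str = "multiclass",
    split_seed: int = 0,
    test_size: float = 0.05,
    max_iter: int = 1000,
    learning_rate_init: float = 0.05,
):
    """Train the one-hidden-layer network on topic-space features.

    100 ReLU units, SGD optimizer, early stopping on a 25% validation
    slice of the 95% training split; the softmax (multiclass) or
    logistic (binary) output comes with the task.  Returns the fitted
    classifier and an evaluation report on the held-out 5%.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if task not in ("multiclass", "binary"):
        raise ValueError("task must be 'multiclass' or 'binary'")
    if task == "binary" and len(np.unique(y)) != 2:
        raise ValueError("binary task requires exactly 2 classes")
    X_tr, X_te, y_tr, y_te = _split(X_norm, y, test_size, split_seed)
    clf = MLPClassifier(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="sgd",
        learning_rate_init=learning_rate_init,
        max_iter=max_iter,
        early_stopping=True,
        validation_fraction=0.25,
        n_iter_no_change=25,
        random_state=split_seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_tr, y_tr)
    scores = clf.predict_proba(X_te)
    report = evaluate_predictions(y_te, scores, classes=clf.classes_)
    report["n_train"] = len(y_tr)
    report["n_test"] = len(y_te)
    return clf, report


def knn_baseline(
    X: np.ndarray,
    labels,
    k: int = 5,
    split_seed: int = 0,
    test_size: float = 0.05,
):
    """5-nearest-neighbor euclidean vote with the same split protocol."""
    y = np.asarray(labels)
    X_tr, X_te, y_tr, y_te = _split(X, y, test_size, split_seed)
    if k >= len(y_tr):
        raise ValueError(f"k={k} must be below the training size {len(y_tr)}")
    knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    knn.fit(X_tr, y_tr)
    scores = knn.predict_proba(X_te)
    report = evaluate_predictions(y_te, scores, classes=knn.classes_)
    report["n_train"] = len(y_tr)
    report["n_test"] = len(y_te)
    return knn, report


def evaluate_predictions(truth, scores, classes=None) -> dict:
    """Accuracy, AUC, confusion matrix, and ROC points.

    ``scores`` is a samples x classes probability matrix (column order
    given by ``classes``) or a 1-d score for the positive class of a
    binary problem.  AUC is one-vs-rest macro-averaged for multiclass;
    ROC points are TPR (sensitivity) vs FPR (1 - specificity).  A
    single-class truth leaves the AUC undefined (None).
    """
    y = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        if classes is None:
            classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("1-d scores require a binary problem")
        scores = np.column_stack([1.0 - scores, scores])
    classes = np.asarray(classes if classes is not None else np.unique(y))
    pred = classes[np.argmax(scores, axis=1)]
    acc = float(accuracy_score(y, pred))
    cm = pd.DataFrame(
        confusion_matrix(y, pred, labels=classes), index=classes, columns=classes
    )
    present = np.unique(y)
    if len(present) < 2:
        warnings.warn("single-class truth: AUC undefined", UserWarning)
        return {"accuracy": acc, "auc": None, "confusion": cm, "roc": None}
    if len(classes) == 2:
        pos = scores[:, 1]
        auc = float(roc_auc_score(y == classes[1], pos))
        fpr, tpr, thr = roc_curve(y == classes[1], pos)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    else:
        keep = np.isin(classes, present)
        y_bin = np.column_stack([(y == c).astype(int) for c in classes[keep]])
        prob = scores[:, keep]
        prob = prob / prob.sum(axis=1, keepdims=True)
        auc = float(roc_auc_score(y_bin, prob, average="macro", multi_class="ovr"))
        roc = {}
        for i, c in enumerate(classes[keep]):
            fpr, tpr, thr = roc_curve(y_bin[:, i], prob[:, i])
            roc[str(c)] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return {"accuracy": acc, "auc": auc, "confusion": cm, "roc": roc}
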