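"""Four-encoding classifier benchmark.

Evaluates how well four per-cell encodings of the target-gene submatrix
predict the sample group: the one-dimensional MTIS, the full normalized
expression matrix, the per-cell sum of normalized values, and a seeded 2-D
UMAP embedding. Each encoding feeds a random forest (10 trees) and a
gradient-boosted tree classifier (max depth 3); evaluation is one-vs-rest
ROC with per-class, micro-average and macro-average AUC on a per-group
50/50 train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.preprocessing import label_binarize

from .autoencoder import MTISEncoder, normalize_counts
from .io import CellGeneMatrix

__all__ = [
    "BenchmarkResult",
    "build_features",
    "split_half",
    "roc_auc",
    "run_benchmark",
    "ENCODINGS",
    "CLASSIFIERS",
]

ENCODINGS = ("mtis", "raw", "sum", "embed2d")
CLASSIFIERS = ("random-forest", "gradient-boosted-trees")


@dataclass
class BenchmarkResult:
    encoding: str
    classifier: str
    per_class_auc: dict[str, float]
    micro_auc: float
    macro_auc: float
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)
    split_seed: int = 0
    params: dict = field(default_factory=dict)


def build_features(
    cg: CellGeneMatrix | np.ndarray,
    kind: str,
    model: MTISEncoder | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell feature table for one encoding of the target submatrix.

    ``mtis``: the trained model's one-dimensional score; ``raw``: the
    normalized expression values (d = Q); ``sum``: their per-cell row sum
    (d = 1); ``embed2d``: seeded 2-D UMAP of the normalized matrix.
    """
    if kind == "mtis":
        if model is None:
            raise ValueError("the mtis encoding requires a trained MTISEncoder")
        return model.transform(cg)
    norm, _, _ = normalize_counts(cg)
    if kind == "raw":
        return norm
    if kind == "sum":
        return norm.sum(axis=1, keepdims=True)
    if kind == "embed2d":
        import umap  # deferred: numba compilation is slow

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, random_state=seed)
            return np.asarray(reducer.fit_transform(norm), dtype=float)
    raise ValueError(f"unknown encoding {kind!r}")


def split_half(labels, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-group random 50/50 split (floor of n/2 to train on odd counts)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        perm = rng.permutation(idx)
        half = idx.size // 2
        train.append(perm[:half])
        test.append(perm[half:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def roc_auc(scores: np.ndarray, labels, classes=None):
    """One-vs-rest ROC evaluation of per-class scores.

    Parameters
    ----------
    scores
        (n_cells, n_classes) class scores (probabilities).
    labels
        Per-cell true class label.
    classes
        Column order of ``scores``; defaults to the sorted unique labels.

    Returns ``(per_class_auc, micro_auc, macro_auc, roc_points)``. Classes
    absent from ``labels`` are skipped with a warning and excluded from the
    macro average; micro pools all (cell, class) binary decisions.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = np.unique(labels)
    classes = list(classes)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n_cells, n_classes)")
    binary = label_binarize(labels, classes=classes)
    if len(classes) == 2:
        binary = np.column_stack([1 - binary[:, 0], binary[:, 0]])

    per_class: dict[str, float] = {}
    points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, cls in enumerate(classes):
        y = binary[:, j]
        if y.sum() == 0 or y.sum() == y.size:
            warnings.warn(f"class {cls!r} absent from one side; skipped", stacklevel=2)
            continue
        fpr, tpr, _ = _sk_roc_curve(y, scores[:, j])
        per_class[str(cls)] = float(_sk_auc(fpr, tpr))
        points[str(cls)] = (fpr, tpr)
    if not per_class:
        raise ValueError("no class with both positives and negatives")
    macro = float(np.mean(list(per_class.values())))
    fpr_mi, tpr_mi, _ = _sk_roc_curve(binary.ravel(), scores.ravel())
    micro = float(_sk_auc(fpr_mi, tpr_mi))
    points["micro"] = (fpr_mi, tpr_mi)
    return per_class, micro, macro, points


def _make_classifier(name: str, seed: int):
    if name == "random-forest":
        return RandomForestClassifier(n_estimators=10, random_state=seed)
    if name == "gradient-boosted-trees":
        from xgboost import XGBClassifier

        return XGBClassifier(max_depth=3, random_state=seed, verbosity=0)
    raise ValueError(f"unknown classifier {name!r}")


def run_benchmark(
    cg: CellGeneMatrix | np.ndarray,
    labels,
    model: MTISEncoder,
    seed: int = 0,
    encodings=ENCODINGS,
    classifiers=CLASSIFIERS,
    stratified: bool = True,
) -> list[BenchmarkResult]:
    """Full encoding x classifier benchmark.

    For each encoding the features are built on the full dataset (the 2-D
    embedding is fitted before splitting, as per-cell variables), then the
    cells are split 50/50 within each group, classifiers are fitted on the
    train half and their class probabilities on the test half are scored
    with one-vs-rest ROC. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if stratified:
        train_idx, test_idx = split_half(labels, seed=seed)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(labels.size)
        half = labels.size // 2
        train_idx, test_idx = np.sort(perm[:half]), np.sort(perm[half:])

    y_codes = np.searchsorted(np.asarray(classes), labels)  # integer classes for xgboost
    results = []
    for kind in encodings:
        feats = build_features(cg, kind, model=model, seed=seed)
        for clf_name in classifiers:
            clf = _make_classifier(clf_name, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(feats[train_idx], y_codes[train_idx])
                proba = clf.predict_proba(feats[test_idx])
            per_class, micro, macro, points = roc_auc(
                proba, labels[test_idx], classes=classes
            )
            results.append(
                BenchmarkResult(
                    encoding=kind,
                    classifier=clf_name,
                    per_class_auc=per_class,
                    micro_auc=micro,
                    macro_auc=macro,
                    roc_points=points,
                    split_seed=seed,
                    params={
                        "n_estimators": 10 if clf_name == "random-forest" else None,
                        "max_depth": 3 if clf_name == "gradient-boosted-trees" else None,
                    },
                )
            )
    return results


def results_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Flatten benchmark results to one row per encoding x classifier."""
    rows = []
    for r in results:
        row = {
            "encoding": r.encoding,
            "classifier": r.classifier,
            "micro_auc": r.micro_auc,
            "macro_auc": r.macro_auc,
            "split_seed": r.split_seed,
        }
        for cls, v in r.per_class_auc.items():
            row[f"auc_{cls}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
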