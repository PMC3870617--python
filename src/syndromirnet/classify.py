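"""SVM binary-tree class prediction over syndrome groups.

The class hierarchy is discovered, not given: at each node the set of
classes is split into the two super-classes whose separation, measured by
repeated stratified cross-validation of a linear SVM, is best; the chosen
split's mean percent-correct is the node score and the procedure recurses
into each side until single classes remain. With at most four classes all
bipartitions are enumerated exhaustively.

Features (miRNAs) are pre-selected at each node by an ordinary two-sample
t-test at alpha = 0.01 between the node's two super-classes; crucially the
selection is re-run inside every training fold, so no information from the
held-out samples leaks into the feature list. Because the study's groups
are tiny (3 samples per syndrome), a .632 bootstrap accuracy is reported
alongside the CV score whenever any class has fewer than twice the fold
count of samples, and the fold count degrades gracefully to the smallest
class size (leave-one-out in the extreme).

Kernel and regularization default to linear, C = 1 — the standard choice
for p >> n expression data — and are configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .preprocess import ExpressionMatrix

__all__ = ["ClassificationTree", "TreeNode", "select_features", "build_binary_tree"]


@dataclass
class TreeNode:
    node_id: int
    left_classes: tuple[str, ...]
    right_classes: tuple[str, ...]
    score: float                      # mean CV percent correct, [0, 100]
    score_rounded: int
    bootstrap_score: float | None     # .632 bootstrap percent, when computed
    features: list[str]               # selected on the node's full data (for reporting)


@dataclass
class ClassificationTree:
    nodes: list[TreeNode] = field(default_factory=list)
    leaves: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "nodes": [
                {
                    "node_id": n.node_id,
                    "left": list(n.left_classes),
                    "right": list(n.right_classes),
                    "score": n.score,
                    "score_rounded": n.score_rounded,
                    "bootstrap_score": n.bootstrap_score,
                    "n_features": len(n.features),
                    "features": n.features,
                }
                for n in self.nodes
            ],
            "leaves": self.leaves,
        }, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _t_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature two-sample pooled-variance t-test p-values (two-sided)."""
    res = stats.ttest_ind(X[y == 0], X[y == 1], axis=0, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # zero-variance features are uninformative
    return p


def select_features(X: np.ndarray, y: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Indices of features passing the univariate t-test at ``alpha``.

    ``X`` is samples x features; ``y`` is a binary label vector. Raises when
    no feature passes, suggesting a larger alpha.
    """
    if len(np.unique(y)) != 2:
        raise ValueError("feature selection needs exactly 2 super-classes")
    p = _t_pvalues(X, y)
    idx = np.nonzero(p < alpha)[0]
    if idx.size == 0:
        raise ValueError(
            f"no feature passes the univariate filter at alpha={alpha}; "
            "consider relaxing alpha")
    return idx


def _fold_features(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """In-fold selection; falls back to the single best feature on null-ish
    folds so cross-validation remains measurable."""
    p = _t_pvalues(X, y)
    idx = np.nonzero(p < alpha)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmin(p))])
    return idx


def _make_svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C)


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified fold assignment from the given stream."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, alpha: float, n_folds: int,
                 n_repeats: int, rng: np.random.Generator, C: float) -> float:
    """Mean repeated-CV fraction correct, feature selection inside folds."""
    counts = np.bincount(y)
    smallest = int(counts[counts > 0].min())
    folds_eff = min(n_folds, smallest, len(y))
    if folds_eff < n_folds:
        warnings.warn(
            f"fold count reduced from {n_folds} to {folds_eff} "
            "(smallest class too small)", RuntimeWarning)
    if folds_eff < 2:  # a 1-sample class: leave-one-out over all samples
        warnings.warn("class with a single sample: using leave-one-out",
                      RuntimeWarning)
        folds_eff = len(y)

    accs = []
    for _ in range(n_repeats):
        if folds_eff == len(y):
            fold_sets = [np.array([i]) for i in range(len(y))]
        else:
            fold_sets = _stratified_folds(y, folds_eff, rng)
        correct = 0
        for test in fold_sets:
            train = np.setdiff1d(np.arange(len(y)), test)
            if len(np.unique(y[train])) < 2:
                correct += int(np.sum(y[test] == np.bincount(y[train]).argmax()))
                continue
            feats = _fold_features(X[train], y[train], alpha)
            clf = _make_svm(C).fit(X[np.ix_(train, feats)], y[train])
            correct += int(np.sum(clf.predict(X[np.ix_(test, feats)]) == y[test]))
        accs.append(correct / len(y))
    return float(np.mean(accs))


def _bootstrap632(X: np.ndarray, y: np.ndarray, alpha: float, n_boot: int,
                  rng: np.random.Generator, C: float) -> float:
    """.632 bootstrap fraction correct (0.368*resubstitution + 0.632*OOB)."""
    n = len(y)
    feats_full = _fold_features(X, y, alpha)
    clf_full = _make_svm(C).fit(X[:, feats_full], y)
    acc_resub = float(np.mean(clf_full.predict(X[:, feats_full]) == y))

    oob_correct, oob_total = 0, 0
    for _ in range(n_boot):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        feats = _fold_features(X[boot], y[boot], alpha)
        clf = _make_svm(C).fit(X[np.ix_(boot, feats)], y[boot])
        oob_correct += int(np.sum(clf.predict(X[np.ix_(oob, feats)]) == y[oob]))
        oob_total += oob.size
    acc_oob = oob_correct / oob_total if oob_total else acc_resub
    return 0.368 * acc_resub + 0.632 * acc_oob


def _bipartitions(classes: tuple[str, ...]):
    """All unordered two-block partitions of the class set."""
    if len(classes) > 6:
        raise ValueError("exhaustive bipartition search limited to 6 classes")
    first, rest = classes[0], classes[1:]
    for mask in range(2 ** len(rest)):
        left = [first] + [c for k, c in enumerate(rest) if mask >> k & 1]
        right = [c for k, c in enumerate(rest) if not (mask >> k & 1)]
        if right:
            yield tuple(left), tuple(right)


def build_binary_tree(m: ExpressionMatrix, classes: list[str] | None = None,
                      alpha: float = 0.01, n_folds: int = 10,
                      n_repeats: int = 10, seed: int = 0, C: float = 1.0,
                      n_boot: int = 30) -> ClassificationTree:
    """Grow the SVM binary classification tree over the given groups.

    ``classes`` defaults to all group labels in the matrix. Samples are
    handled in sorted-id order and all randomness flows from ``seed``, so
    the result is invariant to input sample order and reproducible.
    """
    if classes is None:
        classes = sorted(set(m.groups))
    classes = sorted(classes)
    sample_ids = sorted(s for s in m.sample_ids if m.groups[s] in classes)
    X_all = m.values[sample_ids].to_numpy(dtype=float).T  # samples x features
    labels = np.array([m.groups[s] for s in sample_ids])
    feature_ids = np.array(m.mirna_ids)

    tree = ClassificationTree(leaves=list(classes))
    if len(classes) < 2:
        return tree

    root_seq = np.random.SeedSequence(seed)
    counter = [0]

    def grow(node_classes: tuple[str, ...]) -> None:
        if len(node_classes) < 2:
            return
        mask = np.isin(labels, node_classes)
        Xn, yn_lab = X_all[mask], labels[mask]

        best = None
        for left, right in sorted(_bipartitions(node_classes)):
            y = np.isin(yn_lab, right).astype(int)
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, hash_split(left, right) % (2**31))))
            acc = _cv_accuracy(Xn, y, alpha, n_folds, n_repeats, rng, C)
            cand = (acc, left, right)
            if best is None or cand[0] > best[0]:
                best = cand
        acc, left, right = best

        y = np.isin(yn_lab, right).astype(int)
        small = np.bincount(y).min() < 2 * n_folds
        boot = None
        if small:
            rng_b = np.random.default_rng(
                np.random.SeedSequence((seed, 7, hash_split(left, right) % (2**31))))
            boot = round(100.0 * _bootstrap632(Xn, y, alpha, n_boot, rng_b, C), 1)
        try:
            feats = select_features(Xn, y, alpha)
            names = [str(f) for f in feature_ids[feats]]
        except ValueError:
            names = []

        counter[0] += 1
        tree.nodes.append(TreeNode(
            node_id=counter[0], left_classes=left, right_classes=right,
            score=round(100.0 * acc, 2), score_rounded=int(round(100.0 * acc)),
            bootstrap_score=boot, features=names))
        grow(left)
        grow(right)

    grow(tuple(classes))
    return tree


def hash_split(left: tuple[str, ...], right: tuple[str, ...]) -> int:
    """Stable integer for a class bipartition (order-independent)."""
    import zlib

    key = "|".join(sorted(left)) + "||" + "|".join(sorted(right))
    return zlib.crc32(key.encode())
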