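"""Downstream classification harness for graph embeddings.

Embedding quality is measured through the accuracy of four standard binary
classifiers trained on the embedding vectors under stratified 10-fold
cross-validation:

- ``single_mlp``: one hidden layer of 128 ReLU units, softmax output, Adam,
  100 epochs;
- ``multi_mlp``: hidden layers of 128 and 64 ReLU units, otherwise equal;
- ``svm_rbf``: RBF-kernel SVM with C=100, gamma=0.1;
- ``lda``: linear discriminant analysis with tol=1e-4.

Scores are reported as mean +/- std over folds; methods are compared with a
two-tailed paired t-test over matched fold scores.  Balanced accuracy (mean
of per-class recalls) is available for imbalanced data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("single_mlp", "multi_mlp", "svm_rbf", "lda")


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str
    seed: int = 0
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class CVResult:
    """Per-fold scores with their mean and standard deviation."""

    fold_test_scores: tuple[float, ...]
    fold_train_scores: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_test_scores))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_test_scores))

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.fold_train_scores))

    def __str__(self) -> str:
        return f"{self.mean:.3f} ± {self.std:.3f}"


def make_classifier(cfg: ClassifierConfig):
    """Instantiate the scikit-learn estimator for a classifier kind."""
    if cfg.kind == "single_mlp":
        return MLPClassifier(
            hidden_layer_sizes=(128,),
            activation="relu",
            solver="adam",
            batch_size=32,
            max_iter=100,
            random_state=cfg.seed,
        )
    if cfg.kind == "multi_mlp":
        return MLPClassifier(
            hidden_layer_sizes=(128, 64),
            activation="relu",
            solver="adam",
            batch_size=32,
            max_iter=100,
            random_state=cfg.seed,
        )
    if cfg.kind == "svm_rbf":
        return SVC(C=100.0, gamma=0.1, random_state=cfg.seed)
    return LinearDiscriminantAnalysis(tol=1e-4)


def kfold_indices(
    y: Sequence[int], folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition: disjoint test sets whose union is 0..n-1."""
    y = np.asarray(y)
    if y.size < folds:
        raise ValueError(f"need at least {folds} samples, got {y.size}")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros((y.size, 1)), y)]


def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Mean of per-class recalls for binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("y_true must contain both classes")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def fit_and_score(
    cfg: ClassifierConfig,
    x_train: np.ndarray,
    y_train: Sequence[int],
    x_test: np.ndarray,
    y_test: Sequence[int],
) -> tuple[float, float]:
    """Train one classifier; return (train_score, test_score)."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training fold contains a single class; stratify the folds")
    clf = make_classifier(cfg)
    with warnings.catch_warnings():
        # 100 epochs is a fixed training budget, not a convergence criterion.
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x_train, y_train)
    score = balanced_accuracy if cfg.balanced else accuracy_score
    return (
        float(score(y_train, clf.predict(x_train))),
        float(score(np.asarray(y_test), clf.predict(x_test))),
    )


def cross_validate(
    cfg: ClassifierConfig,
    x: np.ndarray,
    y: Sequence[int],
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier kind."""
    y = np.asarray(y)
    test_scores, train_scores = [], []
    for train_idx, test_idx in kfold_indices(y, folds, seed):
        tr, te = fit_and_score(cfg, x[train_idx], y[train_idx], x[test_idx], y[test_idx])
        train_scores.append(tr)
        test_scores.append(te)
    return CVResult(tuple(test_scores), tuple(train_scores))


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, bool]:
    """Two-tailed paired t-test; returns (p_value, significant_at_0.05).

    Returns (nan, False) when all paired differences are zero (the statistic
    is undefined).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors of length >= 2")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        return float("nan"), False
    p = float(stats.ttest_rel(a, b).pvalue)
    return p, bool(p < 0.05)


def run_experiment(
    x: np.ndarray,
    y: Sequence[int],
    classifier_kinds: Sequence[str] = CLASSIFIER_KINDS,
    folds: int = 10,
    seed: int = 0,
    balanced: bool = False,
    out_csv: str | Path | None = None,
) -> dict[str, CVResult]:
    """Cross-validate every requested classifier on one embedding matrix.

    Optionally writes a results table (one row per classifier with the
    "mean +/- std" summary and the raw fold scores) to ``out_csv``.
    """
    results = {
        kind: cross_validate(
            ClassifierConfig(kind, seed=seed, balanced=balanced), x, y, folds, seed
        )
        for kind in classifier_kinds
    }
    if out_csv is not None:
        rows = []
        for kind, res in results.items():
            row = {
                "classifier": kind,
                "test_mean": res.mean,
                "test_std": res.std,
                "train_mean": res.train_mean,
                "summary": str(res),
            }
            for i, s in enumerate(res.fold_test_scores):
                row[f"fold_{i}"] = s
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_csv, index=False)
    return results


def tsne_channels(
    channel_embeddings: Sequence[np.ndarray],
    labels: Sequence[int],
    out_dir: str | Path,
    seed: int = 0,
) -> list[Path]:
    """2-D t-SNE scatter per channel, colored by binary label; returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    paths = []
    for j, emb in enumerate(channel_embeddings, start=1):
        perplexity = min(30.0, max(2.0, emb.shape[0] / 4))
        coords = TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(emb)
        fig, ax = plt.subplots(figsize=(4, 4))
        for label, color in ((0, "tab:blue"), (1, "tab:brown")):
            sel = labels == label
            ax.scatter(coords[sel, 0], coords[sel, 1], s=8, c=color, label=str(label))
        ax.set_title(f"Channel {j}")
        ax.legend(title="label", fontsize=8)
        path = out_dir / f"channel_{j:02d}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
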