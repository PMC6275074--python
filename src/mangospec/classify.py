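"""Fisher discriminant analysis for damage-severity classification.

Spectra restricted to the CARS-selected wavelengths are projected onto
canonical axes that maximise between-class relative to pooled within-class
scatter (the generalized eigenproblem Sb v = lambda Sw v, unstandardized
coefficients).  Classification assigns the class whose mean is nearest in
canonical space under equal priors, with ties broken by the declared class
order.  A small ridge is added to the pooled covariance when it is singular.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .quality import CLASS_ORDER

__all__ = [
    "DaModel",
    "ConfusionMatrix",
    "fit_lda",
    "classify",
    "confusion",
    "split_train_test",
]


@dataclass
class DaModel:
    classes: list[str]
    class_means: np.ndarray      # K x p
    pooled_cov: np.ndarray       # p x p within-class covariance
    axes: np.ndarray             # p x A canonical (unstandardized) coefficients
    eigenvalues: np.ndarray      # between/within ratio per axis
    priors: np.ndarray           # equal by default
    ridge: float = 0.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.axes

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "classes": self.classes,
                    "class_means": self.class_means.tolist(),
                    "pooled_cov": self.pooled_cov.tolist(),
                    "axes": self.axes.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "priors": self.priors.tolist(),
                    "ridge": self.ridge,
                },
                fh,
            )


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray           # actual rows x classified columns
    split: str = "testing"

    @property
    def percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore"):
            pct = np.where(totals > 0, self.counts / totals * 100.0, 0.0)
        return pct

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, c in enumerate(self.classes):
            row = self.counts[i].sum()
            out[c] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        """Row-percentage table: actual classes x classified classes + Total."""
        df = pd.DataFrame(
            np.round(self.percentages, 1), index=self.classes, columns=self.classes
        )
        df["Total"] = df.sum(axis=1).round(1)
        df.index.name = f"actual ({self.split})"
        return df


def fit_lda(X: np.ndarray, labels, class_order=CLASS_ORDER) -> DaModel:
    """Fit Fisher DA on features X (n x p) with class labels.

    Classes follow ``class_order`` restricted to the labels present; each
    class needs at least 2 samples.  Singular pooled covariance triggers a
    ridge of 1e-6 * trace / p with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    present = [c for c in class_order if c in labels]
    extra = sorted(set(labels) - set(present))
    classes = present + extra
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    K = len(classes)

    means = np.zeros((K, p))
    Sw = np.zeros((p, p))
    for k, c in enumerate(classes):
        Xk = X[labels == c]
        if Xk.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[k] = Xk.mean(axis=0)
        d = Xk - means[k]
        Sw += d.T @ d
    Sw /= n - K
    grand = X.mean(axis=0)
    Sb = np.zeros((p, p))
    for k, c in enumerate(classes):
        nk = int((labels == c).sum())
        diff = means[k] - grand
        Sb += nk * np.outer(diff, diff)
    Sb /= n

    ridge = 0.0
    Sw_r = Sw
    w_eigs = scipy.linalg.eigvalsh(Sw)
    if w_eigs[0] <= 1e-10 * max(w_eigs[-1], 1e-300):
        ridge = 1e-6 * np.trace(Sw) / p
        Sw_r = Sw + ridge * np.eye(p)
        warnings.warn("singular pooled covariance; ridge applied")

    evals, evecs = scipy.linalg.eigh(Sb, Sw_r)
    order = np.argsort(evals)[::-1]
    n_axes = min(K - 1, p)
    axes = evecs[:, order[:n_axes]]
    return DaModel(
        classes=classes,
        class_means=means,
        pooled_cov=Sw,
        axes=axes,
        eigenvalues=evals[order[:n_axes]],
        priors=np.full(K, 1.0 / K),
        ridge=ridge,
    )


def classify(model: DaModel, X: np.ndarray) -> np.ndarray:
    """Nearest class mean in canonical space, equal priors.

    Ties go to the earlier class in the model's class order (argmin takes
    the first minimum).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature count does not match training space")
    Z = model.transform(X)
    centroids = model.transform(model.class_means)
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    picks = np.argmin(d2, axis=1)
    return np.array([model.classes[k] for k in picks])


def confusion(y_true, y_pred, classes=None, split: str = "testing") -> ConfusionMatrix:
    """Count matrix with actual classes as rows, classified classes as columns."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        present = set(y_true) | set(y_pred)
        classes = [c for c in CLASS_ORDER if c in present]
        classes += sorted(present - set(classes))
    unseen = (set(y_true) | set(y_pred)) - set(classes)
    if unseen:
        raise ValueError(f"labels outside the declared classes: {sorted(unseen)}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(classes), counts, split=split)


def split_train_test(
    labels, ratio: float = 3 / 4, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of sample indices by class label.

    Each class contributes round(ratio * n_class) training samples; a class
    too small to leave a test sample goes entirely to training with a
    warning.  Deterministic per seed; the two index sets partition 0..n-1.
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    train, test = [], []
    for c in pd.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_train = int(round(ratio * idx.size))
        if n_train == idx.size:
            warnings.warn(f"class {c!r} too small to stratify; all in training")
            train.extend(idx)
            continue
        perm = rng.permutation(idx.size)
        train.extend(idx[perm[:n_train]])
        test.extend(idx[perm[n_train:]])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))
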