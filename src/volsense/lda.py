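"""Multi-class linear discriminant analysis, written from first principles.

Fisher's discriminant seeks directions w maximizing the between-class to
within-class scatter ratio (w'S_b w)/(w'S_w w). With k classes the solution
is the top eigenvectors of S_w^{-1} S_b, of which at most k − 1 have nonzero
eigenvalue, so the data are projected into a space of dimension ≤ k − 1.

With 66 trace features and only tens of cycles per class, the pooled
within-class scatter is ill-conditioned or singular; a shrinkage weight
λ ∈ [0, 1] blends S_w toward its own diagonal, (1−λ)S_w + λ diag(S_w),
the standard regularized-discriminant remedy.

The module follows the Model/Results convention: build a
:class:`LinearDiscriminantModel` from data, call :meth:`fit`, and work with
the returned :class:`LdaResults` (projection, prediction, summary).
Classification uses Gaussian class conditionals with a shared covariance in
the discriminant space; priors are the training class frequencies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .signal import ValidationError

__all__ = [
    "SingularScatterError",
    "LinearDiscriminantModel",
    "LdaResults",
    "SplitEvaluation",
    "test_set_size",
    "stratified_split",
    "evaluate_split",
    "load_results",
]


class SingularScatterError(np.linalg.LinAlgError):
    """Within-class scatter is singular; refit with shrinkage > 0."""


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


class LinearDiscriminantModel:
    """Linear discriminant analysis model bound to a training sample.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Feature matrix; all entries must be finite.
    y : length-n sequence
        Class labels; at least two classes, each with at least two samples.

    Examples
    --------
    >>> model = LinearDiscriminantModel(X, y)
    >>> res = model.fit(shrinkage=0.1)
    >>> res.predict(X_new)
    """

    def __init__(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X_arr, cols = _as_matrix(X)
        if feature_names is None:
            feature_names = cols
        y_arr = np.asarray(pd.Series(list(y)).astype(str))
        if X_arr.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if len(y_arr) != X_arr.shape[0]:
            raise ValidationError("X and y lengths differ")
        if not np.all(np.isfinite(X_arr)):
            raise ValidationError("X contains non-finite entries")
        labels, counts = np.unique(y_arr, return_counts=True)
        if len(labels) < 2:
            raise ValidationError("need at least 2 classes")
        if np.any(counts < 2):
            small = labels[counts < 2].tolist()
            raise ValidationError(f"classes with < 2 samples: {small}")
        self.exog = X_arr
        self.endog = y_arr
        self.class_labels: tuple[str, ...] = tuple(labels.tolist())
        self.feature_names = list(feature_names) if feature_names is not None else None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "class") -> "LinearDiscriminantModel":
        """Build a model from a tidy frame with one label column."""
        if label_col not in df.columns:
            raise ValidationError(f"missing label column {label_col!r}")
        X = df.drop(columns=[label_col])
        return cls(X, df[label_col])

    def fit(self, shrinkage: float = 0.1) -> "LdaResults":
        """Estimate scatter matrices and the discriminant basis.

        ``shrinkage`` blends the pooled within-class scatter toward its
        diagonal. The basis holds the top eigenvectors of S_w^{-1} S_b (at
        most k − 1), each with its largest-magnitude component made positive
        for a reproducible sign.
        """
        if not 0 <= shrinkage <= 1:
            raise ValidationError("shrinkage must lie in [0, 1]")
        X, y = self.exog, self.endog
        n, p = X.shape
        labels = self.class_labels
        k = len(labels)
        grand_mean = X.mean(axis=0)
        class_means = np.vstack([X[y == c].mean(axis=0) for c in labels])
        counts = np.array([(y == c).sum() for c in labels])
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for i, c in enumerate(labels):
            Xc = X[y == c] - class_means[i]
            Sw += Xc.T @ Xc
            d = (class_means[i] - grand_mean)[:, None]
            Sb += counts[i] * (d @ d.T)
        Sw_reg = (1.0 - shrinkage) * Sw + shrinkage * np.diag(np.diag(Sw))
        # guard: diagonal shrinkage cannot rescue features with zero variance
        try:
            evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
            raise SingularScatterError(
                "within-class scatter is singular; refit with shrinkage > 0 "
                "or drop constant/collinear features"
            ) from exc
        order = np.argsort(evals)[::-1]
        n_dir = min(k - 1, p)
        evals = evals[order][:n_dir]
        basis = evecs[:, order][:, :n_dir]
        # deterministic sign: largest-|component| positive per direction
        for j in range(basis.shape[1]):
            i_max = int(np.argmax(np.abs(basis[:, j])))
            if basis[i_max, j] < 0:
                basis[:, j] = -basis[:, j]
        priors = counts / n
        z = X @ basis
        z_means = class_means @ basis
        # pooled covariance of the projected training data (shared across classes)
        resid = np.vstack([z[y == c] - z_means[i] for i, c in enumerate(labels)])
        z_cov = (resid.T @ resid) / max(n - k, 1)
        z_cov += 1e-12 * np.eye(z_cov.shape[0])  # numerical floor
        res = LdaResults(
            class_labels=labels,
            priors=priors,
            class_means=class_means,
            pooled_within_scatter=Sw,
            between_scatter=Sb,
            basis=basis,
            eigenvalues=evals,
            z_means=z_means,
            z_cov=z_cov,
            shrinkage=shrinkage,
            n_obs=n,
            feature_names=self.feature_names,
            model=self,
        )
        res.training_projections = z
        res.training_accuracy = float(np.mean(res.predict(X)[0] == y))
        return res


@dataclass
class LdaResults:
    """Fitted discriminant model: estimates, basis and classification rule."""

    class_labels: tuple[str, ...]
    priors: np.ndarray
    class_means: np.ndarray
    pooled_within_scatter: np.ndarray
    between_scatter: np.ndarray
    basis: np.ndarray
    eigenvalues: np.ndarray
    z_means: np.ndarray
    z_cov: np.ndarray
    shrinkage: float
    n_obs: int
    feature_names: Optional[list[str]] = None
    model: Optional[LinearDiscriminantModel] = None
    training_projections: Optional[np.ndarray] = field(default=None, repr=False)
    training_accuracy: Optional[float] = None

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def _check_dim(self, X: np.ndarray) -> np.ndarray:
        X_arr, _ = _as_matrix(X)
        if X_arr.ndim == 1:
            X_arr = X_arr[None, :]
        if X_arr.shape[1] != self.basis.shape[0]:
            raise ValidationError(
                f"X has {X_arr.shape[1]} features, model trained with {self.basis.shape[0]}"
            )
        return X_arr

    def project(self, X) -> np.ndarray:
        """Map rows of X into the discriminant space (n × ≤ k−1)."""
        return self._check_dim(X) @ self.basis

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Classify rows of X.

        Returns ``(labels, posteriors)``: posteriors are Gaussian
        class-conditional probabilities with shared covariance in the
        discriminant space, scaled by the training priors; each row sums
        to 1. Ties resolve to the earlier class in label order.
        """
        z = self.project(X)
        cov_inv = np.linalg.inv(self.z_cov)
        log_post = np.empty((z.shape[0], len(self.class_labels)))
        for i in range(len(self.class_labels)):
            d = z - self.z_means[i]
            log_post[:, i] = -0.5 * np.einsum("ij,jk,ik->i", d, cov_inv, d)
            log_post[:, i] += np.log(self.priors[i])
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        idx = np.argmax(post, axis=1)  # first max wins ties (class order)
        labels = np.asarray(self.class_labels)[idx]
        return labels, post

    def score(self, X, y) -> float:
        """Classification accuracy on (X, y)."""
        pred, _ = self.predict(X)
        return float(np.mean(pred == np.asarray(pd.Series(list(y)).astype(str))))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Linear Discriminant Analysis Results",
            "=" * 44,
            f"No. observations: {self.n_obs}",
            f"No. features:     {self.basis.shape[0]}",
            f"Classes ({len(self.class_labels)}):     " + ", ".join(self.class_labels),
            f"Shrinkage:        {self.shrinkage:.3f}",
            f"Components:       {self.n_components}",
            "Eigenvalues:      " + ", ".join(f"{v:.4g}" for v in self.eigenvalues),
        ]
        total = float(np.sum(np.clip(self.eigenvalues, 0, None)))
        if total > 0:
            ratio = np.clip(self.eigenvalues, 0, None) / total
            lines.append("Explained ratio:  " + ", ".join(f"{v:.3f}" for v in ratio))
        if self.training_accuracy is not None:
            lines.append(f"Training accuracy: {self.training_accuracy:.4f}")
        lines.append("Priors:           " + ", ".join(
            f"{c}={p:.3f}" for c, p in zip(self.class_labels, self.priors)))
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fitted model to a JSON text file."""
        payload = {
            "class_labels": list(self.class_labels),
            "priors": self.priors.tolist(),
            "class_means": self.class_means.tolist(),
            "basis": self.basis.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "z_means": self.z_means.tolist(),
            "z_cov": self.z_cov.tolist(),
            "shrinkage": self.shrinkage,
            "n_obs": self.n_obs,
            "feature_names": self.feature_names,
            "training_accuracy": self.training_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def load_results(path) -> LdaResults:
    """Load a fitted model saved with :meth:`LdaResults.save`."""
    d = json.loads(Path(path).read_text())
    p = len(d["basis"])
    return LdaResults(
        class_labels=tuple(d["class_labels"]),
        priors=np.asarray(d["priors"]),
        class_means=np.asarray(d["class_means"]),
        pooled_within_scatter=np.zeros((p, p)),
        between_scatter=np.zeros((p, p)),
        basis=np.asarray(d["basis"]),
        eigenvalues=np.asarray(d["eigenvalues"]),
        z_means=np.asarray(d["z_means"]),
        z_cov=np.asarray(d["z_cov"]),
        shrinkage=d["shrinkage"],
        n_obs=d["n_obs"],
        feature_names=d["feature_names"],
        training_accuracy=d.get("training_accuracy"),
    )


def test_set_size(n: int, test_fraction: float) -> int:
    """Held-out count for one stratum: ceil(test_fraction × n)."""
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    return math.ceil(test_fraction * n)


def stratified_split(
    y, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-proportional train/test split (index arrays).

    Each class contributes ``ceil(test_fraction × n_c)`` test samples,
    capped so at least one training sample remains; classes with fewer than
    two samples are infeasible.
    """
    y_arr = np.asarray(pd.Series(list(y)).astype(str))
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(y_arr):
        idx = np.flatnonzero(y_arr == c)
        if idx.size < 2:
            raise ValidationError(f"class {c!r} has {idx.size} sample(s); cannot split")
        n_test = min(test_set_size(idx.size, test_fraction), idx.size - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


@dataclass
class SplitEvaluation:
    """Outcome of a stratified train/test evaluation."""

    results: LdaResults
    train_index: np.ndarray
    test_index: np.ndarray
    y_test: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray  # per-class posterior matrix, columns = class_labels
    accuracy: float


def evaluate_split(
    X,
    y,
    test_fraction: float = 0.2,
    seed: int = 0,
    shrinkage: float = 0.1,
) -> SplitEvaluation:
    """Fit on a stratified 1−test_fraction share and score the held-out rest."""
    X_arr, cols = _as_matrix(X)
    y_arr = np.asarray(pd.Series(list(y)).astype(str))
    train_idx, test_idx = stratified_split(y_arr, test_fraction, seed)
    model = LinearDiscriminantModel(X_arr[train_idx], y_arr[train_idx], feature_names=cols)
    res = model.fit(shrinkage=shrinkage)
    pred, post = res.predict(X_arr[test_idx])
    acc = float(np.mean(pred == y_arr[test_idx]))
    return SplitEvaluation(
        results=res,
        train_index=train_idx,
        test_index=test_idx,
        y_test=y_arr[test_idx],
        predictions=pred,
        scores=post,
        accuracy=acc,
    )
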