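"""Least-squares support vector machine with wavelet kernels.

The LS-SVM replaces the SVM's inequality constraints with equalities,
so training reduces to one (N+1) x (N+1) linear KKT system

    [ 0    z'          ] [ b ]   [ 0 ]
    [ z    Omega + I/g ] [ a ] = [ 1 ]

where ``Omega_ij = z_i z_j K(x_i, x_j)``, ``g`` (gamma) is the
regularization, and the decision function is
``sign( sum_i a_i z_i K(y, x_i) + b )`` for labels z in {-1, +1}.

Five kernels are provided: linear, polynomial, RBF and two wavelet
kernels — Mexican hat and Morlet — formed as products of per-coordinate
mother-wavelet factors.  Evaluation uses stratified k-fold
cross-validation with per-feature standardization fitted on training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .exceptions import InvalidInputError, InvalidParameterError, NumericalError
from .metrics import ConfusionCounts, confusion, metric_panel, roc_auc

__all__ = [
    "KernelSpec",
    "LSSVMModel",
    "kernel_eval",
    "kernel_matrix",
    "lssvm_train",
    "lssvm_predict",
    "cross_validate",
    "FoldResult",
    "CVResult",
]

KernelKind = Literal["linear", "polynomial", "mexican_hat", "morlet", "rbf"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its hyperparameters.

    ``degree`` (polynomial), ``sigma`` (RBF width), ``scale`` (wavelet
    dilation a), ``omega0`` (Morlet center frequency).
    """

    kind: KernelKind = "rbf"
    degree: int = 3
    sigma: float = 1.0
    scale: float = 1.0
    omega0: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "mexican_hat", "morlet", "rbf"):
            raise InvalidParameterError(f"unknown kernel kind {self.kind!r}")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise InvalidParameterError("polynomial degree must be a positive integer")
        if self.sigma <= 0 or self.scale <= 0:
            raise InvalidParameterError("kernel width/scale must be positive")


def kernel_matrix(spec: KernelSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = Psi(u_i, v_j) for row-vector collections."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if u.shape[1] != v.shape[1]:
        raise InvalidInputError(f"dimension mismatch: {u.shape[1]} vs {v.shape[1]}")
    if spec.kind == "linear":
        return u @ v.T
    if spec.kind == "polynomial":
        return (u @ v.T + 1.0) ** spec.degree
    if spec.kind == "rbf":
        return np.exp(-cdist(u, v, "sqeuclidean") / (2.0 * spec.sigma**2))
    # wavelet kernels: product over coordinates of a mother-wavelet factor
    diff = u[:, None, :] - v[None, :, :]
    gauss = np.exp(-(diff**2) / (2.0 * spec.scale**2))
    if spec.kind == "mexican_hat":
        factors = (1.0 - diff**2 / spec.scale**2) * gauss
    else:  # morlet
        factors = np.cos(spec.omega0 * diff / spec.scale) * gauss
    return factors.prod(axis=-1)


def kernel_eval(spec: KernelSpec, u: Sequence[float], v: Sequence[float]) -> float:
    """Kernel value for a single pair of feature vectors."""
    return float(kernel_matrix(spec, np.atleast_2d(u), np.atleast_2d(v))[0, 0])


@dataclass
class LSSVMModel:
    """Trained dual model: coefficients, bias and the training set."""

    alphas: np.ndarray
    bias: float
    gamma: float
    kernel: KernelSpec
    support_vectors: np.ndarray
    support_labels: np.ndarray  # in {-1, +1}
    classes: tuple = (-1, 1)  # original class tags, index 0 -> -1, 1 -> +1

    def decision_function(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        k = kernel_matrix(self.kernel, y, self.support_vectors)
        return k @ (self.alphas * self.support_labels) + self.bias

    def kkt_residual(self) -> float:
        """Relative residual of the defining linear system (training check)."""
        k = kernel_matrix(self.kernel, self.support_vectors, self.support_vectors)
        z = self.support_labels
        omega = (z[:, None] * z[None, :]) * k
        n = z.size
        lhs_top = float(z @ self.alphas)
        lhs = (omega + np.eye(n) / self.gamma) @ self.alphas + self.bias * z
        return float(np.hypot(lhs_top, linalg.norm(lhs - 1.0)) / max(1.0, linalg.norm(self.alphas)))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "kernel": asdict(self.kernel),
            "support_vectors": self.support_vectors.tolist(),
            "support_labels": self.support_labels.tolist(),
            "classes": list(map(str, self.classes)),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LSSVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            alphas=np.array(d["alphas"]),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            kernel=KernelSpec(**d["kernel"]),
            support_vectors=np.array(d["support_vectors"]),
            support_labels=np.array(d["support_labels"]),
            classes=tuple(d["classes"]),
        )


def _encode_labels(z: np.ndarray) -> tuple[np.ndarray, tuple]:
    classes = np.unique(z)
    if classes.size != 2:
        raise InvalidInputError(f"binary classifier needs exactly 2 classes, got {classes.size}")
    encoded = np.where(z == classes[0], -1.0, 1.0)
    return encoded, tuple(classes)


def lssvm_train(
    x: np.ndarray, z: Sequence, spec: KernelSpec | None = None, gamma: float = 10.0
) -> LSSVMModel:
    """Solve the KKT system for the dual coefficients and bias."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if gamma <= 0:
        raise InvalidParameterError("gamma must be positive")
    spec = spec or KernelSpec()
    z_enc, classes = _encode_labels(np.asarray(z))
    n = x.shape[0]

    k = kernel_matrix(spec, x, x)
    omega = (z_enc[:, None] * z_enc[None, :]) * k
    a_mat = np.zeros((n + 1, n + 1))
    a_mat[0, 1:] = z_enc
    a_mat[1:, 0] = z_enc
    a_mat[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], np.ones(n)])
    try:
        sol = linalg.solve(a_mat, rhs, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise NumericalError(f"KKT system is singular (ill-conditioned Gram matrix): {exc}")
    if not np.all(np.isfinite(sol)):
        raise NumericalError("KKT solve produced non-finite coefficients (conditioning)")
    return LSSVMModel(
        alphas=sol[1:],
        bias=float(sol[0]),
        gamma=gamma,
        kernel=spec,
        support_vectors=x,
        support_labels=z_enc,
        classes=classes,
    )


def lssvm_predict(model: LSSVMModel, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class tags and raw decision values (0 maps to class +1)."""
    values = model.decision_function(y)
    labels = np.where(values >= 0, model.classes[1], model.classes[0])
    return labels, values


@dataclass
class FoldResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    counts: ConfusionCounts
    decision_values: np.ndarray
    model: LSSVMModel


@dataclass
class CVResult:
    folds: list[FoldResult]
    counts: ConfusionCounts  # pooled over folds
    panel: dict[str, float]
    auc: float
    positive_class: object

    @property
    def accuracy(self) -> float:
        return self.panel["ACC"]


def cross_validate(
    x: np.ndarray,
    z: Sequence,
    spec: KernelSpec | None = None,
    gamma: float = 10.0,
    k: int = 10,
    seed: int = 0,
    positive_class: object | None = None,
    standardize: bool = True,
) -> CVResult:
    """Stratified k-fold CV; confusion counts pooled before the metric panel.

    Standardization statistics (mean/std per feature) are computed on
    each training fold only and applied to its test fold, so no test
    information leaks into training.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.asarray(z)
    classes, counts = np.unique(z, return_counts=True)
    if classes.size != 2:
        raise InvalidInputError("two classes are required")
    if counts.min() < k:
        raise InvalidInputError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    positive = classes[1] if positive_class is None else positive_class

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    y_true_all, y_pred_all, dv_all = [], [], []
    for train_idx, test_idx in skf.split(x, z):
        x_train, x_test = x[train_idx], x[test_idx]
        if standardize:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        model = lssvm_train(x_train, z[train_idx], spec=spec, gamma=gamma)
        pred, dv = lssvm_predict(model, x_test)
        folds.append(
            FoldResult(
                train_idx=train_idx,
                test_idx=test_idx,
                counts=confusion(z[test_idx], pred, positive_class=positive),
                decision_values=dv,
                model=model,
            )
        )
        y_true_all.append(z[test_idx])
        y_pred_all.append(pred)
        dv_all.append(dv if positive == model.classes[1] else -dv)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    pooled = confusion(y_true, y_pred, positive_class=positive)
    auc, _ = roc_auc(np.concatenate(dv_all), y_true == positive)
    return CVResult(
        folds=folds, counts=pooled, panel=metric_panel(pooled), auc=auc, positive_class=positive
    )
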