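"""Kernel evaluation for the main and privileged feature spaces.

Both feature maps absorb their bias (intercept) term into the weight vector by
appending a constant-1 auxiliary dimension; at the kernel level this is simply
adding 1 to every entry (:func:`augment_bias`), which works uniformly for
precomputed kernels too.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import pairwise

__all__ = ["KernelSpec", "kernel_matrix", "augment_bias"]

_FAMILIES = ("linear", "rbf", "polynomial", "precomputed")


@dataclass(frozen=True)
class KernelSpec:
    """Specification of a positive-semidefinite kernel.

    Parameters
    ----------
    family:
        One of ``linear``, ``rbf``, ``polynomial``, ``precomputed``.
    bandwidth:
        RBF inverse length-scale ``gamma`` in ``exp(-gamma * ||x - z||^2)``.
        ``None`` means the ``1 / n_features`` default, resolved at evaluation
        time.
    degree, coef0:
        Polynomial kernel ``(x.z + coef0) ** degree``.
    augment:
        Whether the bias-absorbing ``K + 1`` augmentation applies to this
        kernel.  Defaults to True (the convention used throughout the model);
        callers supplying a precomputed kernel that already encodes an
        intercept may set it to False.
    """

    family: str = "rbf"
    bandwidth: float | None = None
    degree: int = 3
    coef0: float = 0.0
    augment: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "rbf" and self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("rbf bandwidth (gamma) must be > 0")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "KernelSpec":
        return cls(**obj)


def _validate_features(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (samples x features), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def kernel_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Evaluate the kernel between every row of ``X`` and every row of ``Z``.

    Returns the ``rows(X) x rows(Z)`` matrix with entry ``(i, j) = k(X_i, Z_j)``.
    ``family='precomputed'`` is handled by the model layer (the caller already
    holds the Gram matrix) and is rejected here.
    """
    if spec.family == "precomputed":
        raise ValueError(
            "kernel_matrix cannot evaluate a precomputed kernel; pass the Gram matrix directly"
        )
    X = _validate_features(X, "X")
    Z = _validate_features(Z, "Z")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature-count mismatch: X has {X.shape[1]} features, Z has {Z.shape[1]}")

    if spec.family == "linear":
        return pairwise.linear_kernel(X, Z)
    if spec.family == "rbf":
        gamma = spec.bandwidth if spec.bandwidth is not None else 1.0 / max(X.shape[1], 1)
        return pairwise.rbf_kernel(X, Z, gamma=gamma)
    # polynomial: (x.z + coef0) ** degree
    return pairwise.polynomial_kernel(X, Z, degree=spec.degree, gamma=1.0, coef0=spec.coef0)


def augment_bias(K: np.ndarray) -> np.ndarray:
    """Add 1 to every kernel entry — the constant-1 auxiliary feature dimension.

    Equivalent to appending a 1 to every feature vector, so the learned
    function needs no separate intercept.  Preserves symmetry and positive
    semidefiniteness (adds the rank-1 matrix ``1 1^T``).
    """
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("kernel matrix contains non-finite entries")
    return K + 1.0
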