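"""The kernel l2-SVMp+ classifier.

Learning using partially available privileged information (LUPAPI): of the
``n`` training samples, a subset of size ``m`` carries an extra "privileged"
feature block that exists only at training time (e.g. an echocardiographic
measurement recorded for some patients).  For those samples the margin slack
is modelled as a *slack function* ``w~' phi~(x~)`` living in the privileged
feature space; the remaining samples keep ordinary squared slack variables.
With squared (l2) slacks the primal

    min_{w, w~, rho, zeta}  1/2 ||w||^2 + gamma/2 ||w~||^2
                            + C/2 sum_{i>m} zeta_i^2
                            + C~/2 sum_{i<=m} (w~' phi~(x~_i))^2  -  rho
    s.t.  y_i w' phi(x_i) >= rho - w~' phi~(x~_i)   (i <= m, has PI)
          y_i w' phi(x_i) >= rho - zeta_i           (i > m, no PI)

has a dual that collapses (after merging the two multiplier blocks into a
single vector ``a``) to a one-class-SVM-shaped simplex QP

    min_a 1/2 a' G a,   a >= 0, sum a = 1,
    G = Dy K Dy + blockdiag( K~ (gamma I + C~ K~)^{-1},  C^{-1} I_{n-m} ),

where K and K~ are the (bias-augmented) main and privileged kernel matrices
and Dy = diag(y).  Prediction uses only main features:
``f(x) = sum_i a_i y_i k(x_i, x)``, thresholded at 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import KernelSpec, augment_bias, kernel_matrix
from .solver import QPResult, smo_solve

__all__ = [
    "TrainingSet",
    "Hyperparams",
    "FittedModel",
    "PrimalDiagnostics",
    "privileged_block",
    "build_dual_matrix",
    "fit",
    "decision_scores",
    "predict",
    "primal_diagnostics",
]

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"


@dataclass
class TrainingSet:
    """Training data of the LUPAPI model: main features for everyone, a
    privileged block for the samples flagged in ``pi_mask``.

    ``X_priv`` rows where ``pi_mask`` is False may contain NaN (they are never
    read by the model); ``X_priv=None`` is shorthand for "no privileged block
    at all" and forces an all-False mask.
    """

    X: np.ndarray
    X_priv: np.ndarray | None
    pi_mask: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.pi_mask = np.asarray(self.pi_mask, dtype=bool)
        n = self.X.shape[0]
        if self.X.ndim != 2 or n < 2:
            raise ValueError("X must be 2-D with at least 2 samples")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.y.shape != (n,):
            raise ValueError("y must have one entry per sample")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present in y")
        if self.pi_mask.shape != (n,):
            raise ValueError("pi_mask must have one entry per sample")
        if self.X_priv is None:
            if self.pi_mask.any():
                raise ValueError("pi_mask is set but X_priv is None")
            self.X_priv = np.zeros((n, 0))
        else:
            self.X_priv = np.asarray(self.X_priv, dtype=float)
            if self.X_priv.ndim != 2 or self.X_priv.shape[0] != n:
                raise ValueError("X_priv must be 2-D with one row per sample")
            if not np.all(np.isfinite(self.X_priv[self.pi_mask])):
                raise ValueError("X_priv contains non-finite entries on PI rows")
        self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return int(self.pi_mask.sum())

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(self.X[idx], self.X_priv[idx], self.pi_mask[idx], self.y[idx])


@dataclass(frozen=True)
class Hyperparams:
    """Model hyperparameters.

    ``C`` weighs the squared slacks of the samples without PI, ``C_tilde`` the
    squared slack-function values of the PI samples, and ``gamma`` the ridge
    on the privileged-space weight vector.  Each space carries its own kernel.
    """

    C: float = 1.0
    C_tilde: float = 1.0
    gamma: float = 1.0
    kernel_main: KernelSpec = field(default_factory=KernelSpec)
    kernel_priv: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.C_tilde < 0:
            raise ValueError("C_tilde must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0 (the privileged-block inverse is undefined at 0)")

    def to_json(self) -> dict:
        return {
            "C": self.C,
            "C_tilde": self.C_tilde,
            "gamma": self.gamma,
            "kernel_main": self.kernel_main.to_json(),
            "kernel_priv": self.kernel_priv.to_json(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Hyperparams":
        obj = dict(obj)
        obj["kernel_main"] = KernelSpec.from_json(obj["kernel_main"])
        obj["kernel_priv"] = KernelSpec.from_json(obj["kernel_priv"])
        return cls(**obj)


@dataclass
class FittedModel:
    """Everything needed to evaluate the decision rule ``a' Dy Phi' phi(x)``."""

    alpha: np.ndarray            # dual weights, internal (PI-first) order
    y: np.ndarray                # labels, internal order
    X_sorted: np.ndarray         # main features, internal order
    permutation: np.ndarray      # internal order -> user order index map
    m: int                       # number of PI samples
    kernel_main: KernelSpec
    hyperparams: Hyperparams
    objective: float
    converged: bool
    solver_report: dict

    def to_json(self) -> dict:
        return {
            "version": _VERSION,
            "alpha": self.alpha.tolist(),
            "y": self.y.tolist(),
            "X_sorted": self.X_sorted.tolist(),
            "permutation": self.permutation.tolist(),
            "m": self.m,
            "kernel_main": self.kernel_main.to_json(),
            "hyperparams": self.hyperparams.to_json(),
            "objective": self.objective,
            "converged": self.converged,
            "solver_report": self.solver_report,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FittedModel":
        return cls(
            alpha=np.asarray(obj["alpha"], dtype=float),
            y=np.asarray(obj["y"], dtype=int),
            X_sorted=np.asarray(obj["X_sorted"], dtype=float),
            permutation=np.asarray(obj["permutation"], dtype=int),
            m=int(obj["m"]),
            kernel_main=KernelSpec.from_json(obj["kernel_main"]),
            hyperparams=Hyperparams.from_json(obj["hyperparams"]),
            objective=float(obj["objective"]),
            converged=bool(obj["converged"]),
            solver_report=dict(obj["solver_report"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass
class PrimalDiagnostics:
    """KKT-based reconstruction of the primal quantities of a fitted model."""

    rho: float
    zeta: np.ndarray              # slack variables of the n-m samples without PI
    slack_fn_values: np.ndarray   # w~' phi~(x~_i) for the m PI samples
    margin_residuals: np.ndarray  # y_i f(x_i) - rho + slack_i, internal order
    reliable: bool


def privileged_block(K_tilde_aug: np.ndarray, gamma: float, C_tilde: float) -> np.ndarray:
    """The PI block of the dual matrix: ``B~ = K~ (gamma I + C~ K~)^{-1}``.

    Computed through the eigendecomposition ``K~ = U L U'`` as
    ``U diag(l_i / (gamma + C~ l_i)) U'``, which is symmetric PSD by
    construction and stays well-behaved when ``gamma I + C~ K~`` is nearly
    singular.  Tiny negative round-off eigenvalues are clipped at zero.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if C_tilde < 0:
        raise ValueError("C_tilde must be >= 0")
    K = np.asarray(K_tilde_aug, dtype=float)
    if K.size == 0:
        return np.zeros((0, 0))
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K_tilde_aug must be square, got {K.shape}")
    scale = max(1.0, float(np.abs(K).max()))
    if np.abs(K - K.T).max() > 1e-8 * scale:
        raise ValueError("K_tilde_aug is not symmetric within tolerance")
    try:
        lam, U = scipy.linalg.eigh(K)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise RuntimeError(f"eigendecomposition of the privileged kernel failed: {exc}") from exc
    lam = np.clip(lam, 0.0, None)
    B = (U * (lam / (gamma + C_tilde * lam))) @ U.T
    return 0.5 * (B + B.T)


def build_dual_matrix(
    K_aug: np.ndarray, B_tilde: np.ndarray, C: float, y: np.ndarray, m: int
) -> np.ndarray:
    """Assemble ``G = Dy K Dy + blockdiag(B~, C^{-1} I_{n-m})``.

    Samples must be ordered PI-first: indices ``0..m-1`` carry privileged
    information.  ``m = n`` drops the ``C^{-1} I`` block, ``m = 0`` drops
    ``B~`` (giving the plain no-PI l2-SVM dual).  If round-off makes the
    smallest eigenvalue dip below ``-1e-8 * lambda_max``, a diagonal jitter of
    ``1e-10 * trace(G)/n`` is added and logged.
    """
    K_aug = np.asarray(K_aug, dtype=float)
    y = np.asarray(y, dtype=float)
    n = K_aug.shape[0]
    if K_aug.shape != (n, n):
        raise ValueError("K_aug must be square")
    if y.shape != (n,):
        raise ValueError("y length must match K_aug")
    if not (0 <= m <= n):
        raise ValueError(f"m={m} out of range for n={n}")
    B_tilde = np.asarray(B_tilde, dtype=float)
    if B_tilde.shape != (m, m):
        raise ValueError(f"B_tilde has shape {B_tilde.shape}, expected ({m}, {m})")
    if C <= 0:
        raise ValueError("C must be > 0")

    G = np.outer(y, y) * K_aug
    if m > 0:
        G[:m, :m] += B_tilde
    if m < n:
        G[m:, m:] += np.eye(n - m) / C
    G = 0.5 * (G + G.T)

    ev = np.linalg.eigvalsh(G)
    lam_min, lam_max = ev[0], ev[-1]
    if lam_min < -1e-8 * max(lam_max, 0.0):
        jitter = 1e-10 * np.trace(G) / n
        G[np.diag_indices_from(G)] += jitter
        logger.warning("build_dual_matrix: min eigenvalue %.3e; added jitter %.3e", lam_min, jitter)
    return G


def _pi_first_permutation(pi_mask: np.ndarray) -> np.ndarray:
    return np.concatenate([np.flatnonzero(pi_mask), np.flatnonzero(~pi_mask)])


def _main_gram(X_sorted: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "precomputed":
        K = X_sorted  # caller already permuted rows AND columns
    else:
        K = kernel_matrix(X_sorted, X_sorted, spec)
    return augment_bias(K) if spec.augment else np.asarray(K, dtype=float)


def fit(
    data: TrainingSet,
    hp: Hyperparams,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> FittedModel:
    """Fit the kernel l2-SVMp+ model.

    Samples are permuted internally to PI-first order (the user-facing order is
    arbitrary; the permutation is stored on the model).  The main and
    privileged Gram matrices are bias-augmented, the dual matrix ``G`` is
    assembled, and the simplex QP is solved by SMO.  A non-converged solve
    still returns a model, flagged ``converged=False``.

    For ``kernel_main.family='precomputed'``, ``data.X`` must be the n x n
    main-space Gram matrix in user order.
    """
    perm = _pi_first_permutation(data.pi_mask)
    m = data.m
    y_sorted = data.y[perm]
    if hp.kernel_main.family == "precomputed":
        if data.X.shape[0] != data.X.shape[1]:
            raise ValueError("precomputed main kernel requires X to be the square Gram matrix")
        X_sorted = data.X[np.ix_(perm, perm)]
    else:
        X_sorted = data.X[perm]

    K_aug = _main_gram(X_sorted, hp.kernel_main)

    if m > 0:
        Xp = data.X_priv[perm[:m]]
        if hp.kernel_priv.family == "precomputed":
            raise ValueError("precomputed privileged kernels are not supported; pass features")
        K_tilde = kernel_matrix(Xp, Xp, hp.kernel_priv)
        if hp.kernel_priv.augment:
            K_tilde = augment_bias(K_tilde)
        B_tilde = privileged_block(K_tilde, hp.gamma, hp.C_tilde)
    else:
        B_tilde = np.zeros((0, 0))

    G = build_dual_matrix(K_aug, B_tilde, hp.C, y_sorted, m)
    result = smo_solve(G, tol=tol, max_iter=max_iter)
    if not result.converged:
        logger.warning("fit: SMO did not converge (gap %.3e after %d updates)",
                       result.kkt_gap, result.iterations)
    return FittedModel(
        alpha=result.alpha,
        y=y_sorted,
        X_sorted=X_sorted,
        permutation=perm,
        m=m,
        kernel_main=hp.kernel_main,
        hyperparams=hp,
        objective=result.objective,
        converged=result.converged,
        solver_report={
            "iterations": result.iterations,
            "kkt_gap": result.kkt_gap,
            "converged": result.converged,
        },
    )


def decision_scores(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Decision function ``f(x) = sum_i alpha_i y_i k_aug(x_i, x)``.

    For a precomputed main kernel, ``X_new`` must be the q x n Gram matrix
    between the query points and the *original-order* training points.
    """
    spec = model.kernel_main
    if spec.family == "precomputed":
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != model.permutation.size:
            raise ValueError("precomputed query kernel must be q x n_train")
        K = X_new[:, model.permutation].T  # n x q, internal order
    else:
        K = kernel_matrix(model.X_sorted, np.atleast_2d(np.asarray(X_new, dtype=float)), spec)
    if spec.augment:
        K = K + 1.0
    return (model.alpha * model.y) @ K


def predict(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Class labels in {-1, +1}; a score of exactly 0 maps to +1."""
    s = decision_scores(model, X_new)
    return np.where(s >= 0, 1, -1)


def primal_diagnostics(model: FittedModel, data: TrainingSet) -> PrimalDiagnostics:
    """Reconstruct primal quantities from the dual solution via the KKT system.

    Stationarity gives ``zeta_i = alpha_i / C`` for the samples without PI and
    ``w~' phi~(x~_i) = (B~ a_{1..m})_i`` for the PI samples.  The margin level
    ``rho`` is recovered as the median of ``y_i f(x_i) + slack_i`` over the
    active constraints (``alpha_i`` above threshold); ``margin_residuals`` are
    ``y_i f(x_i) - rho + slack_i`` (nonnegative at an exact optimum, zero on
    active constraints).
    """
    m, n = model.m, model.alpha.size
    hp = model.hyperparams
    perm = model.permutation
    if m > 0:
        Xp = data.X_priv[perm[:m]]
        K_tilde = kernel_matrix(Xp, Xp, hp.kernel_priv)
        if hp.kernel_priv.augment:
            K_tilde = augment_bias(K_tilde)
        B_tilde = privileged_block(K_tilde, hp.gamma, hp.C_tilde)
        slack_fn = B_tilde @ model.alpha[:m]
    else:
        slack_fn = np.zeros(0)
    zeta = model.alpha[m:] / hp.C

    if model.kernel_main.family == "precomputed":
        f_sorted = decision_scores(model, data.X)[perm]
    else:
        f_sorted = decision_scores(model, model.X_sorted)
    margins = model.y * f_sorted
    slack_all = np.concatenate([slack_fn, zeta])
    active = model.alpha > 1e-6
    if active.any():
        rho = float(np.median(margins[active] + slack_all[active]))
    else:  # degenerate: nothing active (cannot happen on the simplex, but be safe)
        rho = float(np.min(margins + slack_all))
    residuals = margins - rho + slack_all
    if not model.converged:
        logger.warning("primal_diagnostics: model did not converge; diagnostics unreliable")
    return PrimalDiagnostics(
        rho=rho,
        zeta=zeta,
        slack_fn_values=slack_fn,
        margin_residuals=residuals,
        reliable=model.converged,
    )
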