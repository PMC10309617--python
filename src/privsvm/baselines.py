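"""Comparison arms: the no-PI standard SVM and imputation pipelines.

The standard SVM here is the ``m = 0`` reduction of the l2-SVMp+ dual
(``G = Dy K Dy + C^{-1} I``), i.e. an l2-loss kernel SVM — the natural
in-family baseline.  The imputation pipelines complete the privileged block
(column means, or a deterministic round-robin ridge imputer), concatenate it
to the main features and train the standard SVM on the widened matrix, so the
"privileged" columns are treated as ordinary features.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.linear_model import Ridge

from .model import FittedModel, Hyperparams, TrainingSet, fit

__all__ = [
    "fit_standard_svm",
    "mean_impute",
    "iterative_impute",
    "fit_imputed_svm",
    "ImputedSVMPipeline",
]

logger = logging.getLogger(__name__)


def fit_standard_svm(X: np.ndarray, y: np.ndarray, hp: Hyperparams, **fit_kwargs) -> FittedModel:
    """l2-loss kernel SVM without privileged information.

    Delegates to :func:`privsvm.model.fit` with an all-false PI mask; with
    ``m = 0`` the dual matrix is ``Dy K Dy + C^{-1} I`` and ``C_tilde`` and
    ``gamma`` have no effect.
    """
    X = np.asarray(X, dtype=float)
    data = TrainingSet(X=X, X_priv=None, pi_mask=np.zeros(X.shape[0], dtype=bool), y=y)
    return fit(data, hp, **fit_kwargs)


def _validate_missing_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float).copy()
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.all(np.isnan(M), axis=0).any():
        bad = np.flatnonzero(np.all(np.isnan(M), axis=0))
        raise ValueError(f"columns {bad.tolist()} have no observed values; cannot impute")
    return M


def mean_impute(M: np.ndarray) -> np.ndarray:
    """Fill each missing (NaN) cell with its column's observed mean."""
    M = _validate_missing_matrix(M)
    if M.shape[1] == 0:
        return M
    col_means = np.nanmean(M, axis=0)
    missing = np.isnan(M)
    M[missing] = np.broadcast_to(col_means, M.shape)[missing]
    return M


def iterative_impute(
    M: np.ndarray,
    max_rounds: int = 10,
    tol: float = 1e-6,
    seed: int | None = None,
    ridge: float = 1e-3,
) -> np.ndarray:
    """Round-robin regression imputation of the missing (NaN) cells.

    Missing cells start at their column means; then each incomplete column in
    turn is regressed (ridge, penalty ``ridge``) on all other columns using
    the rows where it is observed, and its missing cells are re-predicted.
    Iteration stops when no imputed cell moves by more than ``tol`` or after
    ``max_rounds`` sweeps.  Deterministic for a fixed column order; ``seed``
    is accepted for interface symmetry with stochastic imputers and unused.
    ``max_rounds = 0`` reduces to mean imputation.
    """
    del seed
    M = _validate_missing_matrix(M)
    missing = np.isnan(M)
    if not missing.any():
        return M
    M = mean_impute(M)
    if max_rounds == 0 or M.shape[1] < 2:
        return M
    obs_lo = np.nanmin(np.where(missing, np.nan, M), axis=0)
    obs_hi = np.nanmax(np.where(missing, np.nan, M), axis=0)
    incomplete = np.flatnonzero(missing.any(axis=0))
    for _ in range(max_rounds):
        max_change = 0.0
        for c in incomplete:
            others = np.delete(np.arange(M.shape[1]), c)
            rows_obs = ~missing[:, c]
            reg = Ridge(alpha=ridge).fit(M[np.ix_(rows_obs, others)], M[rows_obs, c])
            pred = reg.predict(M[np.ix_(missing[:, c], others)])
            max_change = max(max_change, float(np.abs(pred - M[missing[:, c], c]).max()))
            M[missing[:, c], c] = pred
        if max_change < tol:
            break
    for c in incomplete:
        rng = obs_hi[c] - obs_lo[c]
        vals = M[missing[:, c], c]
        if ((vals < obs_lo[c] - rng) | (vals > obs_hi[c] + rng)).any():
            logger.warning("iterative_impute: column %d imputed outside the observed "
                           "range +/- one range width (extrapolation)", c)
    return M


def fit_imputed_svm(
    data: TrainingSet, hp: Hyperparams, method: str = "mean", **fit_kwargs
) -> FittedModel:
    """Impute the privileged block, append it to the main features, fit the
    standard SVM on the concatenation.

    ``method`` is ``"mean"`` or ``"iterative"``.  Rows without PI have their
    privileged entries treated as missing.
    """
    if data.X_priv.shape[1] == 0:
        raise ValueError("data has no privileged columns to impute")
    P = data.X_priv.copy()
    P[~data.pi_mask] = np.nan
    if method == "mean":
        completed = mean_impute(P)
    elif method == "iterative":
        full = np.hstack([data.X, P])  # main features inform the regressions
        completed = iterative_impute(full)[:, data.X.shape[1]:]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    X_wide = np.hstack([data.X, completed])
    return fit_standard_svm(X_wide, data.y, hp, **fit_kwargs)


class ImputedSVMPipeline:
    """Imputed-PI baseline that can also score PI-free query points.

    Training: complete the privileged block (mean or round-robin ridge),
    concatenate it to the main features, fit the standard SVM on the widened
    matrix.  Querying: privileged features never exist at test time, so they
    are re-created from the main features alone — column means for ``mean``,
    per-column ridge regressions of priv on main (fit on the training rows
    where that column was observed) for ``iterative``.
    """

    def __init__(self, method: str = "mean", ridge: float = 1e-3):
        if method not in ("mean", "iterative"):
            raise ValueError(f"unknown imputation method {method!r}")
        self.method = method
        self.ridge = ridge
        self.model: FittedModel | None = None
        self._col_means: np.ndarray | None = None
        self._regressors: list[Ridge] | None = None

    def fit(self, data: TrainingSet, hp: Hyperparams, **fit_kwargs) -> "ImputedSVMPipeline":
        if data.X_priv.shape[1] == 0:
            raise ValueError("data has no privileged columns to impute")
        P = data.X_priv.copy()
        P[~data.pi_mask] = np.nan
        self._col_means = np.nanmean(P, axis=0)
        if self.method == "mean":
            completed = mean_impute(P)
            self._regressors = None
        else:
            completed = iterative_impute(np.hstack([data.X, P]),
                                         ridge=self.ridge)[:, data.X.shape[1]:]
            self._regressors = []
            for c in range(P.shape[1]):
                rows = ~np.isnan(P[:, c])
                self._regressors.append(
                    Ridge(alpha=self.ridge).fit(data.X[rows], P[rows, c]))
        self.model = fit_standard_svm(np.hstack([data.X, completed]), data.y, hp, **fit_kwargs)
        return self

    def _impute_query(self, X_new: np.ndarray) -> np.ndarray:
        if self.method == "mean":
            return np.broadcast_to(self._col_means, (X_new.shape[0], self._col_means.size)).copy()
        return np.column_stack([reg.predict(X_new) for reg in self._regressors])

    def decision_scores(self, X_new: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        from .model import decision_scores as _scores
        return _scores(self.model, np.hstack([X_new, self._impute_query(X_new)]))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X_new) >= 0, 1, -1)

    # --- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        obj = {
            "pipeline": "imputed_svm",
            "method": self.method,
            "ridge": self.ridge,
            "col_means": self._col_means.tolist(),
            "model": self.model.to_json(),
        }
        if self._regressors is not None:
            obj["regressors"] = [
                {"coef": r.coef_.tolist(), "intercept": float(r.intercept_)}
                for r in self._regressors
            ]
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "ImputedSVMPipeline":
        pipe = cls(method=obj["method"], ridge=obj["ridge"])
        pipe._col_means = np.asarray(obj["col_means"], dtype=float)
        pipe.model = FittedModel.from_json(obj["model"])
        if "regressors" in obj:
            pipe._regressors = []
            for r in obj["regressors"]:
                reg = Ridge(alpha=obj["ridge"])
                reg.coef_ = np.asarray(r["coef"], dtype=float)
                reg.intercept_ = float(r["intercept"])
                pipe._regressors.append(reg)
        return pipe
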