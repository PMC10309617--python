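"""Synthetic LUPI-structured data.

A latent factor ``t ~ N(0, I_latent)`` drives everything: the main features
are a noisy linear view ``x = A t + noise_main * eps``, the privileged
features a much cleaner view ``x~ = B t + noise_priv * eps~`` of the *same*
signal, and the label is ``sign(v' t)`` with independent flips.  Privileged
rows are then masked out completely at random (MCAR) to a controllable
availability ratio — mimicking a high-quality clinical measurement recorded
for only part of a cohort.  ``A``, ``B`` and ``v`` are drawn once per seed,
so every dataset is bit-reproducible.

Defaults are the "informative PI" regime: ``noise_priv`` well below
``noise_main``, so a model with access to the privileged view separates the
classes better than one restricted to the main view.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .model import TrainingSet

__all__ = ["SyntheticSpec", "generate", "pi_subsample", "pi_first_split", "SplitResult"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of the LUPI data model.

    noise_main / noise_priv are the per-coordinate Gaussian noise scales of
    the two views (informative PI needs ``noise_priv < noise_main``);
    ``label_flip`` is the independent label-noise rate; ``availability`` the
    MCAR fraction of rows keeping their privileged block (realized exactly:
    ``round(availability * n)`` rows).
    """

    n: int = 1200
    d: int = 100
    d_tilde: int = 5
    latent_dim: int = 5
    noise_main: float = 2.0
    noise_priv: float = 0.05
    label_flip: float = 0.10
    availability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1 or self.d_tilde < 0 or self.latent_dim < 1:
            raise ValueError("n >= 2, d >= 1, d_tilde >= 0, latent_dim >= 1 required")
        if self.noise_main <= 0 or self.noise_priv <= 0:
            raise ValueError("noise scales must be positive")
        if not (0 <= self.label_flip < 0.5):
            raise ValueError("label_flip must be in [0, 0.5)")
        if not (0 <= self.availability <= 1):
            raise ValueError("availability must be in [0, 1]")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "SyntheticSpec":
        return cls(**obj)


def generate(spec: SyntheticSpec) -> TrainingSet:
    """Draw a dataset from the latent-factor LUPI model; fully seed-determined."""
    rng = np.random.default_rng(spec.seed)
    A = rng.standard_normal((spec.d, spec.latent_dim))
    B = rng.standard_normal((spec.d_tilde, spec.latent_dim))
    v = rng.standard_normal(spec.latent_dim)

    t = rng.standard_normal((spec.n, spec.latent_dim))
    X = t @ A.T + spec.noise_main * rng.standard_normal((spec.n, spec.d))
    X_priv = t @ B.T + spec.noise_priv * rng.standard_normal((spec.n, spec.d_tilde))

    y = np.where(t @ v >= 0, 1, -1)
    flips = rng.random(spec.n) < spec.label_flip
    y = np.where(flips, -y, y)

    m = round(spec.availability * spec.n)
    pi_mask = np.zeros(spec.n, dtype=bool)
    pi_mask[rng.choice(spec.n, size=m, replace=False)] = True
    return TrainingSet(X=X, X_priv=X_priv, pi_mask=pi_mask, y=y)


def pi_subsample(data: TrainingSet, ratio: float, seed: int) -> TrainingSet:
    """Thin the PI mask uniformly at random down to availability ``ratio``.

    Keeps exactly ``round(ratio * n)`` of the currently-present privileged
    rows; main features and labels are untouched.  ``ratio`` may not exceed
    the current availability.
    """
    if not (0 <= ratio <= 1):
        raise ValueError("ratio must be in [0, 1]")
    target = round(ratio * data.n)
    present = np.flatnonzero(data.pi_mask)
    if target > present.size:
        raise ValueError(
            f"requested availability {ratio} needs {target} PI rows but only "
            f"{present.size} are present")
    rng = np.random.default_rng(seed)
    keep = rng.choice(present, size=target, replace=False)
    new_mask = np.zeros(data.n, dtype=bool)
    new_mask[keep] = True
    return TrainingSet(X=data.X, X_priv=data.X_priv, pi_mask=new_mask, y=data.y)


@dataclass
class SplitResult:
    train: TrainingSet
    validation: TrainingSet
    test: TrainingSet
    train_pi_ratio: float


def pi_first_split(data: TrainingSet, train_fraction: float, seed: int) -> SplitResult:
    """PI-first data split: every PI-present row goes to training.

    PI-missing rows are shuffled; enough of them top the training set up to
    ``round(train_fraction * n)`` rows, and the remainder is divided evenly
    between validation and test.  The realized PI availability inside training
    (``m / n_train``) is reported — varying ``train_fraction`` varies it.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n = data.n
    n_train = round(train_fraction * n)
    pi_rows = np.flatnonzero(data.pi_mask)
    no_pi_rows = np.flatnonzero(~data.pi_mask)
    if pi_rows.size > n_train:
        raise ValueError(
            f"train_fraction {train_fraction} gives {n_train} training rows but "
            f"{pi_rows.size} rows carry PI and must all be in training")
    n_fill = n_train - pi_rows.size
    n_rest = no_pi_rows.size - n_fill
    if n_rest < 2:
        raise ValueError("not enough PI-missing rows left for validation and test")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(no_pi_rows)
    train_idx = np.concatenate([pi_rows, shuffled[:n_fill]])
    rest = shuffled[n_fill:]
    n_val = rest.size // 2
    return SplitResult(
        train=data.subset(train_idx),
        validation=data.subset(rest[:n_val]),
        test=data.subset(rest[n_val:]),
        train_pi_ratio=pi_rows.size / n_train,
    )
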