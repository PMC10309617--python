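"""Experiment harness: hyperparameter selection and PI-availability sweeps.

The sweep mirrors the repeated-subsampling design used to study how much
partially available privileged information helps: fix one train /
validation / test split, then for each availability level ``r`` and
repetition ``k`` thin the training PI mask down to ``r`` with an independent
seed, select hyperparameters on the validation split (by AUROC; ties broken
toward smaller C, then smaller C~, then smaller gamma), and report test
AUROC / AUPRC / max-F1 plus the train-minus-test AUROC gap.  The no-PI
standard SVM enters the same table at availability 0.

All randomness flows from one master seed through a counter-based
``numpy.random.SeedSequence`` derivation, so a sweep is reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import ImputedSVMPipeline, fit_standard_svm
from .kernels import KernelSpec
from .metrics import auprc, auroc, max_f1
from .model import FittedModel, Hyperparams, TrainingSet, decision_scores, fit
from .synthetic import SyntheticSpec, generate, pi_subsample

__all__ = [
    "default_grid",
    "expand_grid",
    "select_hyperparams",
    "run_sweep",
    "SweepResult",
    "sweep_long_csv",
    "plot_sweep",
    "pi_benefit_experiment",
]

MODELS = ("svm", "l2svmp+", "mean_imp", "iter_imp")

#: models whose fit ignores C_tilde / gamma (the m = 0 reduction)
_NO_PI_MODELS = ("svm", "mean_imp", "iter_imp")


def default_grid() -> dict:
    """Shipped default hyperparameter grid (``None`` bandwidth = 1/d)."""
    return {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0],
        "C_tilde": [0.01, 0.1, 1.0, 10.0, 100.0],
        "gamma": [0.01, 0.1, 1.0, 10.0],
        "bandwidth": [0.1, None, 1.0],
    }


def expand_grid(
    grid: dict | None = None,
    kernel_main: KernelSpec | None = None,
    kernel_priv: KernelSpec | None = None,
) -> list[Hyperparams]:
    """Expand a ``{C, C_tilde, gamma, bandwidth}`` grid into Hyperparams.

    The ``bandwidth`` axis applies to both kernels when their family is rbf
    and is ignored otherwise.  Order is deterministic: sorted by
    ``(C, C_tilde, gamma, bandwidth position)`` so that earlier entries win
    ties during selection.
    """
    grid = dict(default_grid(), **(grid or {}))
    kernel_main = kernel_main or KernelSpec()
    kernel_priv = kernel_priv or KernelSpec()
    bandwidths = grid["bandwidth"] if kernel_main.family == "rbf" or kernel_priv.family == "rbf" else [None]
    out = []
    for C in sorted(grid["C"]):
        for Ct in sorted(grid["C_tilde"]):
            for g in sorted(grid["gamma"]):
                for bw in bandwidths:
                    km = dataclasses.replace(kernel_main, bandwidth=bw) \
                        if kernel_main.family == "rbf" else kernel_main
                    kp = dataclasses.replace(kernel_priv, bandwidth=bw) \
                        if kernel_priv.family == "rbf" else kernel_priv
                    out.append(Hyperparams(C=C, C_tilde=Ct, gamma=g,
                                           kernel_main=km, kernel_priv=kp))
    return out


def _dedupe_for_model(kind: str, grid: list[Hyperparams]) -> list[Hyperparams]:
    """Models without a PI block ignore C_tilde and gamma; collapse the grid."""
    if kind not in _NO_PI_MODELS:
        return grid
    seen, out = set(), []
    for hp in grid:
        key = (hp.C, hp.kernel_main)
        if key not in seen:
            seen.add(key)
            out.append(hp)
    return out


def _fit_one(kind: str, train: TrainingSet, hp: Hyperparams, **fit_kwargs):
    """Fit one model arm; returns an object exposing decision scores."""
    if kind == "l2svmp+":
        return fit(train, hp, **fit_kwargs)
    if kind == "svm":
        return fit_standard_svm(train.X, train.y, hp, **fit_kwargs)
    if kind == "mean_imp":
        return ImputedSVMPipeline("mean").fit(train, hp, **fit_kwargs)
    if kind == "iter_imp":
        return ImputedSVMPipeline("iterative").fit(train, hp, **fit_kwargs)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODELS}")


def _scores_of(fitted, X: np.ndarray) -> np.ndarray:
    if isinstance(fitted, FittedModel):
        return decision_scores(fitted, X)
    return fitted.decision_scores(X)


def select_hyperparams(
    kind: str,
    train: TrainingSet,
    validation: TrainingSet,
    grid: list[Hyperparams],
    **fit_kwargs,
):
    """Grid search by validation AUROC (main features only on validation).

    Receives only the training and validation splits — test data never enters
    model selection.  Returns ``(best_hp, best_model, best_val_auroc)``; ties
    keep the earliest grid entry, i.e. smaller C, then smaller C_tilde, then
    smaller gamma.
    """
    best = None
    for hp in _dedupe_for_model(kind, grid):
        fitted = _fit_one(kind, train, hp, **fit_kwargs)
        val_auc = auroc(_scores_of(fitted, validation.X), validation.y)
        if best is None or val_auc > best[2]:
            best = (hp, fitted, val_auc)
    if best is None:
        raise ValueError("empty hyperparameter grid")
    return best


@dataclass
class SweepResult:
    long: pd.DataFrame     # one row per model x availability x repetition
    summary: pd.DataFrame  # mean +/- sd per model x availability


def _derived_seed(master_seed: int, *counters: int) -> int:
    """Counter-based child seed: SeedSequence(master, key...) -> uint32 < 2^31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, counters)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _evaluate(fitted, train: TrainingSet, test: TrainingSet) -> dict:
    test_scores = _scores_of(fitted, test.X)
    train_auc = auroc(_scores_of(fitted, train.X), train.y)
    test_auc = auroc(test_scores, test.y)
    return {
        "train_auroc": train_auc,
        "test_auroc": test_auc,
        "auc_gap": train_auc - test_auc,
        "test_auprc": auprc(test_scores, test.y),
        "test_max_f1": max_f1(test_scores, test.y)["f1"],
    }


def run_sweep(
    data: SyntheticSpec | TrainingSet,
    *,
    n_train: int = 600,
    n_val: int = 300,
    n_test: int = 600,
    availabilities: tuple = (0.5, 0.7, 0.9, 1.0),
    repetitions: int = 5,
    grid: list[Hyperparams] | None = None,
    models: tuple = ("svm", "l2svmp+"),
    master_seed: int = 0,
    **fit_kwargs,
) -> SweepResult:
    """PI-availability sweep with repeated PI subsampling.

    ``data`` is either a :class:`SyntheticSpec` template (its ``n``,
    ``availability`` and ``seed`` fields are overridden: ``n`` becomes
    ``n_train + n_val + n_test``, training PI starts fully available, and the
    dataset seed derives from ``master_seed``) or an already-loaded
    :class:`TrainingSet`, which is split at the same proportions.

    For every model kind, availability level and repetition the training PI
    mask is thinned with an independent derived seed, hyperparameters are
    selected on the validation split, and test metrics are recorded.  Models
    that never see PI ("svm") are reported once at availability 0.
    """
    for kind in models:
        if kind not in MODELS:
            raise ValueError(f"unknown model kind {kind!r}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    availabilities = tuple(sorted(availabilities))
    if any(not (0 <= a <= 1) for a in availabilities):
        raise ValueError("availabilities must lie in [0, 1]")

    if isinstance(data, SyntheticSpec):
        n = n_train + n_val + n_test
        spec = dataclasses.replace(data, n=n, availability=1.0,
                                   seed=_derived_seed(master_seed, 0))
        full = generate(spec)
    else:
        full = data
        if full.n < n_train + n_val + n_test:
            raise ValueError("dataset smaller than n_train + n_val + n_test")

    rng = np.random.default_rng(_derived_seed(master_seed, 1))
    perm = rng.permutation(full.n)
    train = full.subset(perm[:n_train])
    validation = full.subset(perm[n_train:n_train + n_val])
    test = full.subset(perm[n_train + n_val:n_train + n_val + n_test])

    grid = grid if grid is not None else expand_grid()
    rows = []
    for kind in models:
        needs_pi = kind not in ("svm",)
        levels = availabilities if needs_pi else (0.0,)
        reps = repetitions if needs_pi else 1
        for ai, avail in enumerate(levels):
            for rep in range(reps):
                if needs_pi:
                    sub_seed = _derived_seed(master_seed, 2, MODELS.index(kind), ai, rep)
                    train_k = pi_subsample(train, avail, sub_seed)
                else:
                    train_k = train
                hp, fitted, val_auc = select_hyperparams(
                    kind, train_k, validation, grid, **fit_kwargs)
                row = {
                    "model": kind,
                    "availability": avail,
                    "rep": rep,
                    "C": hp.C,
                    "C_tilde": hp.C_tilde,
                    "gamma": hp.gamma,
                    "bandwidth": hp.kernel_main.bandwidth,
                    "val_auroc": val_auc,
                    "train_pi_ratio": train_k.m / train_k.n,
                }
                row.update(_evaluate(fitted, train_k, test))
                rows.append(row)

    long = pd.DataFrame(rows)
    metrics_cols = ["test_auroc", "test_auprc", "test_max_f1", "auc_gap"]
    summary = (
        long.groupby(["model", "availability"], sort=True)[metrics_cols]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    summary = summary.reset_index().fillna({f"{c}_std": 0.0 for c in metrics_cols})
    return SweepResult(long=long, summary=summary)


def pi_benefit_experiment(
    n_seeds: int = 20,
    *,
    spec: SyntheticSpec | None = None,
    availabilities: tuple = (0.5, 0.7, 0.9, 1.0),
    n_splits: int = 3,
    n_train: int = 600,
    n_val: int = 600,
    n_test: int = 600,
    C_grid: tuple = (0.1, 1.0, 10.0),
    pi_grid: tuple = ((0.01, 10.0), (1.0, 1.0)),
    master_seed: int = 0,
    tol: float = 1e-6,
) -> dict:
    """Paired PI-benefit study on the informative-PI synthetic preset.

    For each of ``n_seeds`` independently generated datasets (one pool of
    ``2 * (n_train + n_val + n_test)`` samples per seed), ``n_splits``
    train/validation/test splits are drawn.  On every split the no-PI
    standard SVM (C tuned on validation over ``C_grid``) is compared with
    l2-SVMp+ at each availability level, its hyperparameters re-selected on
    validation per level over ``C_grid`` x ``pi_grid`` (pairs of
    ``(C_tilde, gamma)``), mirroring the per-experiment tuning of the
    availability-sweep protocol.  Kernels are rbf with the package's 1/d
    default bandwidth in both spaces.

    Returns a dict with the per-seed paired AUROC differences (l2-SVMp+ at
    full availability minus standard SVM, averaged over splits), the win
    count and one-sided sign-test p-value, and the mean AUROC per
    availability level.
    """
    from scipy.stats import binomtest

    spec = spec or SyntheticSpec()
    availabilities = tuple(sorted(availabilities))
    diffs = []
    curves = []
    svm_aucs = []
    aux = {k: [] for k in ("svm_auprc", "svm_max_f1", "pi_auprc", "pi_max_f1")}
    for s in range(n_seeds):
        pool_spec = dataclasses.replace(
            spec, n=2 * (n_train + n_val + n_test), availability=1.0,
            seed=_derived_seed(master_seed, 3, s))
        pool = generate(pool_spec)
        split_diffs, split_curves, split_svm = [], [], []
        for sp in range(n_splits):
            rng = np.random.default_rng(_derived_seed(master_seed, 4, s, sp))
            perm = rng.permutation(pool.n)
            train = pool.subset(perm[:n_train])
            val = pool.subset(perm[n_train:n_train + n_val])
            test = pool.subset(perm[n_train + n_val:n_train + n_val + n_test])

            best_svm = None
            for C in C_grid:
                hp = Hyperparams(C=C)
                m = fit_standard_svm(train.X, train.y, hp, tol=tol)
                v = auroc(decision_scores(m, val.X), val.y)
                if best_svm is None or v > best_svm[0]:
                    best_svm = (v, m)
            svm_scores = decision_scores(best_svm[1], test.X)
            svm_auc = auroc(svm_scores, test.y)
            aux["svm_auprc"].append(auprc(svm_scores, test.y))
            aux["svm_max_f1"].append(max_f1(svm_scores, test.y)["f1"])

            curve = []
            for ai, avail in enumerate(availabilities):
                train_k = (train if avail >= 1.0 else
                           pi_subsample(train, avail,
                                        _derived_seed(master_seed, 5, s, sp, ai)))
                best_pi = None
                for C in C_grid:
                    for C_tilde, gamma in pi_grid:
                        hp = Hyperparams(C=C, C_tilde=C_tilde, gamma=gamma)
                        m = fit(train_k, hp, tol=tol)
                        v = auroc(decision_scores(m, val.X), val.y)
                        if best_pi is None or v > best_pi[0]:
                            best_pi = (v, m)
                pi_scores = decision_scores(best_pi[1], test.X)
                curve.append(auroc(pi_scores, test.y))
                if avail >= availabilities[-1]:
                    aux["pi_auprc"].append(auprc(pi_scores, test.y))
                    aux["pi_max_f1"].append(max_f1(pi_scores, test.y)["f1"])
            split_diffs.append(curve[-1] - svm_auc)
            split_curves.append(curve)
            split_svm.append(svm_auc)
        diffs.append(float(np.mean(split_diffs)))
        curves.append(np.mean(split_curves, axis=0))
        svm_aucs.append(float(np.mean(split_svm)))

    diffs = np.asarray(diffs)
    curves = np.asarray(curves)
    wins = int((diffs > 0).sum())
    losses = int((diffs < 0).sum())
    n_eff = wins + losses  # sign test drops exact ties
    p = binomtest(wins, n_eff, 0.5, alternative="greater").pvalue if n_eff else 1.0
    mean_curve = curves.mean(axis=0)
    increments = np.diff(mean_curve)
    return {
        "availabilities": list(availabilities),
        "diffs": diffs.tolist(),
        "wins": wins,
        "n_seeds": n_seeds,
        "sign_test_p": float(p),
        "mean_diff": float(diffs.mean()),
        "svm_auroc_mean": float(np.mean(svm_aucs)),
        "pi_auroc_by_availability": mean_curve.tolist(),
        "curve_increments": increments.tolist(),
        "n_inversions": int((increments < 0).sum()),
        "max_inversion": float(max(0.0, -increments.min())) if increments.size else 0.0,
        "svm_auprc_mean": float(np.mean(aux["svm_auprc"])),
        "svm_max_f1_mean": float(np.mean(aux["svm_max_f1"])),
        "pi_auprc_mean": float(np.mean(aux["pi_auprc"])),
        "pi_max_f1_mean": float(np.mean(aux["pi_max_f1"])),
    }


def sweep_long_csv(result: SweepResult) -> str:
    """Deterministic CSV rendering of the long-format sweep table."""
    return result.long.to_csv(index=False, float_format="%.10g")


def plot_sweep(result: SweepResult, path, metric: str = "test_auroc") -> None:
    """Metric-versus-availability line figure (one line per model)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for kind, df in result.summary.groupby("model"):
        ax.errorbar(df["availability"], df[f"{metric}_mean"],
                    yerr=df[f"{metric}_std"], marker="o", capsize=3, label=kind)
    ax.set_xlabel("PI availability")
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
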