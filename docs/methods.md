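# Methods

## Model

`privsvm` fits a binary kernel classifier under *learning using partially
available privileged information* (LUPAPI). Each training sample has main
features x ∈ R^d; a subset of m ≤ n samples additionally has privileged
features x̃ ∈ R^d̃ that never exist at prediction time. The privileged view
parameterizes the margin slack of its samples as a function in the privileged
feature space, w̃ᵀφ̃(x̃), instead of a free per-sample slack variable: samples
that the teacher view recognizes as hard are allowed slack cheaply, but the
slack pattern must be expressible as a smooth function of x̃, which
regularizes the fit. Samples without privileged features keep ordinary
slacks ζᵢ. All slack terms enter the objective squared (l2 loss), which is
what makes the dual collapse.

Bias terms are absorbed by augmenting both kernels with a constant feature:
`augment_bias(K) = K + 1`. This is applied to the main kernel and, by
default, to the privileged kernel (`KernelSpec.augment=False` disables it per
kernel, e.g. for precomputed Gram matrices that already contain an
intercept).

### Dual and solver

Merging the two Lagrange-multiplier blocks into one vector α ∈ R^n (PI
samples first) turns the dual into the simplex QP

    min ½ αᵀGα,  α ≥ 0, Σα = 1,
    G = ΔyKΔy + blockdiag(B̃, C⁻¹I_{n−m}),   B̃ = K̃(γI + C̃K̃)⁻¹.

`privileged_block` computes B̃ through the eigendecomposition K̃ = UΛUᵀ →
B̃ = U diag(λ/(γ + C̃λ)) Uᵀ, which is symmetric PSD by construction and
remains stable when γI + C̃K̃ is nearly singular; tiny negative round-off
eigenvalues are clipped at zero. C̃ = 0 is allowed (B̃ = K̃/γ); γ = 0 is
rejected. If assembly round-off drives G's smallest eigenvalue below
−1e−8·λmax, a diagonal jitter of 1e−10·trace(G)/n is added and logged.

`smo_solve` minimizes the simplex QP by sequential minimal optimization:

* working set: maximal violating pair — i = argmin (Gα)ᵢ over all
  coordinates, j = argmax (Gα)ⱼ over {αⱼ > 0};
* update: the exact 1-D minimizer δ = gap/(Gᵢᵢ+Gⱼⱼ−2Gᵢⱼ) clipped to
  [0, αⱼ] (δ = αⱼ on flat directions), so feasibility is preserved exactly
  and the objective never increases;
* stopping: gap < tol (default 1e−6);
* initialization: uniform α = 1/n;
* budget: max(100·n², 50 000) pair updates. The floor matters: on
  ill-conditioned small problems first-order pair selection zig-zags between
  two pairs and converges linearly with a rate near 1, needing thousands of
  updates even at n = 3. Exhaustion returns `converged=False` rather than
  raising; downstream diagnostics flag such models as unreliable.
* the maintained gradient is refreshed from scratch every 4096 updates to
  bound floating-point drift.

`qp_oracle` solves the identical problem with SLSQP (exact gradients,
ftol 1e−14) and serves as the independent reference in tests and the
acceptance run; LIBSVM's one-class solver at ν = 1/n (via scikit-learn's
`OneClassSVM` with a precomputed kernel) solves the same QP — the mapping
makes its box constraint α ≤ 1/(νn) = 1 inactive on the simplex — and is
cross-checked in the test suite, but nothing depends on it.

The decision rule uses main features only, f(x) = Σ αᵢyᵢ k_aug(xᵢ, x),
thresholded at 0 (a score of exactly 0 maps to +1). ρ is deliberately absent
from the rule; `primal_diagnostics` recovers it (median of yᵢf(xᵢ) + slackᵢ
over active constraints) together with ζ = α_{m+1..n}/C and the slack-function
values B̃α_{1..m}, and reports margin residuals for KKT certification. The
identity (Gα)ᵢ = yᵢf(xᵢ) + slackᵢ ties these residuals directly to the
solver's violating-pair gap.

Users never order their samples; `fit` permutes to PI-first internally and
stores the permutation.

### Tunable parameters

| parameter | meaning | default |
|---|---|---|
| C > 0 | weight of squared slacks of samples without PI | 1 |
| C̃ ≥ 0 | weight of squared slack-function values of PI samples | 1 |
| γ > 0 | ridge on the privileged-space weight vector w̃ | 1 |
| kernel bandwidth | rbf γ in exp(−γ‖x−z‖²); `None` = 1/d | `None` |
| tol | SMO violating-pair gap at convergence | 1e−6 |

Small C̃ with moderate γ makes B̃ ≈ K̃/γ: PI samples' slack penalty keeps
roughly the scale 1/γ per sample plus a smoothing discount for samples close
in privileged space. This is the regime where the teacher effect is visible
on the synthetic preset.

## Baselines

* **standard SVM** — the m = 0 reduction (G = ΔyKΔy + C⁻¹I), i.e. an
  l2-loss kernel SVM on the main features. C̃ and γ provably have no effect.
* **mean imputation** — privileged columns completed with their observed
  column means, appended to the main features, standard SVM on the result.
* **iterative imputation** — a deterministic round-robin ridge imputer
  (penalty 1e−3, input column order, initialized at column means, stopping
  when no imputed cell moves by more than tol or after `max_rounds`
  sweeps). It is a minimal, fully specified stand-in for library iterative
  imputers, whose estimator and schedule those libraries do not pin down;
  `max_rounds=0` reduces it to mean imputation, and re-running it on its own
  output is a no-op. At query time privileged features do not exist, so the
  imputed-SVM pipelines re-create them from the main features alone (train
  column means, or per-column ridge regressions of privileged on main).

## Metrics

`f1_score` is the counts form 2TP/(FN + 2TP + FP), defined as 0 on an empty
denominator. `max_f1` min-max rescales scores to [0,1] and maximizes F1 over
every threshold that can change the confusion table (midpoints between
consecutive distinct rescaled scores plus the endpoints 0 and 1; rule
score ≥ t), which dominates any finite threshold grid on [0,1]. `auroc` is
the Mann–Whitney statistic with ties counting one half. `auprc` is average
precision with tied scores treated as one group (step interpolation, not
trapezoidal). All four are verified exactly against exhaustive/naive
references on small inputs, and against scikit-learn on larger ones.

## Synthetic data

The generator emulates a cohort in which a clean but rarely recorded
measurement coexists with routine noisy measurements. A latent factor
t ~ N(0, I_q) drives everything:

    x = A t + noise_main · ε        (main view)
    x̃ = B t + noise_priv · ε̃       (privileged view)
    y = sign(vᵀ t), flipped independently with probability label_flip
    PI mask: exactly round(availability · n) rows, uniformly at random (MCAR)

A (d×q), B (d̃×q) and v are drawn once per seed, so datasets are
bit-reproducible. `pi_subsample` thins the mask to a target availability;
`pi_first_split` implements the design in which every PI-carrying row must
train and the PI-missing rows fill up train/validation/test.

**Informative-PI preset** (the `SyntheticSpec` defaults): d = 100, d̃ = 5,
q = 5, noise_main = 2.0, noise_priv = 0.05, label_flip = 0.10. The preset
was calibrated so that the privileged view is genuinely informative (a
classifier on x̃ alone clearly beats one on x alone) while the main view
leaves the classifier far enough from its ceiling for the teacher to matter
at the study's training size.

What the generator does *not* emulate: because all views are jointly
Gaussian and the label is a linear threshold of t, the optimal classifier on
the main view is globally linear. Real cohorts have nonlinear structure,
heteroscedastic noise and non-MCAR missingness; the teacher effect measured
here (a fraction of a percent of AUROC at n = 600) is therefore a
conservative, qualitative reproduction of the mechanism, not a forecast of
gains on clinical data. MAR/MNAR missingness is deliberately out of scope.

## The availability study

`pi_benefit_experiment` quantifies the trend "more privileged information →
better test AUROC". Per dataset seed it draws a pool, takes 3
train/validation/test splits (600/600/600), tunes the no-PI SVM's C on
validation over {0.1, 1, 10}, and at each availability in
{0.5, 0.7, 0.9, 1.0} subsamples the training PI mask and re-selects the
l2-SVMp+ hyperparameters on validation over C × {(C̃, γ)} =
{0.1, 1, 10} × {(0.01, 10), (1, 1)}. Test AUROC/AUPRC/max-F1 are recorded;
the per-seed paired difference (full-PI l2-SVMp+ minus SVM, averaged over
splits) feeds a one-sided sign test.

Two design points deserve emphasis:

* **Per-level re-tuning is essential.** With hyperparameters held fixed,
  partial availability is systematically *worse* than either extreme: the
  dual mass migrates to whichever slack block is cheaper, effectively
  shrinking the training set. Re-selection at every availability level — the
  natural protocol anyway — removes this artifact and yields the monotone
  curve.
* **Seed count.** The per-seed effect is ≈ +0.002 AUROC with a per-seed win
  probability near 0.75; the study uses 40 seeds, where the sign test at
  α = 0.05 has ≈ 95% power (20 seeds would be a coin flip). The whole study
  runs in about six minutes on one CPU.

The sweep harness (`run_sweep`, `privsvm sweep`) generalizes this protocol:
config-supplied grids (shipped default: C, C̃ ∈ {0.01, 0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, 10}, rbf bandwidth ∈ {0.1, 1/d, 1}), selection by
validation AUROC with ties broken toward smaller C then C̃, availability ×
repetition long tables with mean ± sd summaries, and counter-based seed
derivation (`SeedSequence([master, …])`, kept below 2³¹) making every report
byte-reproducible. Model selection sees only training and validation data;
the test split enters exactly once, after selection.

## Numerical choices and edge cases

* G symmetrized as (G + Gᵀ)/2 before solving; asymmetry beyond 1e−8 is an
  error upstream.
* n = 1 simplex QP returns α = (1) immediately.
* Emptied coordinates in SMO are set to exactly 0 so feasibility holds to
  machine precision.
* `max_f1` with all scores equal treats the rescaled scores as the constant
  ½ (thresholds 0 and 1 remain).
* Imputation never touches observed cells; imputed values outside the
  observed column range ± one range width log a warning (extrapolation
  indicator), not an error.
* Model JSON round-trips reproduce decision scores bit-identically on the
  same platform (floats serialize via repr).

## Known limitations

* Binary classification only; a single privileged block per sample.
* The hinge-loss (l1-slack) variant of the privileged-information SVM is not
  implemented; the standard-SVM baseline is the l2-loss reduction of this
  model, not a soft-margin l1 SVM.
* First-order working-set selection is simple and robust but not the fastest
  choice on badly conditioned problems; the iteration floor compensates.
* Statistical conclusions from the synthetic study transfer to real cohorts
  only qualitatively (see above).
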