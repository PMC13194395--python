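# Methods

## Problem and estimand

We observe N i.i.d. triples (Y, T, X): a scalar outcome, a continuous
(possibly vector-valued, τ ≥ 1) treatment, and p covariates.  Under
positivity, conditional unconfoundedness (X blocks all backdoor paths from
T to Y) and consistency, the interventional expectation is identified by
covariate adjustment, E[Y | do(T=t), X=x] = E[Y | T=t, X=x], and the
object of interest is the individual counterfactual dose-response curve

    θ_x(t) = E[Y | do(T=t), X=x],

a full curve in t for every covariate profile x, together with contrasts
θ_x(t_a) − θ_x(t_b).  These assumptions are contracts on the data, not
properties the package can verify; nothing here enforces them
algorithmically.

## The hypernetwork estimator

Three networks are composed:

* encoder f_φ: ℝ^p → ℝ^k maps covariates to a representation z;
* hypernetwork g_ψ: ℝ^k → ℝ^m maps z to the *entire* flat weight vector
  ω of the target network;
* target network h_ω: ℝ^τ → ℝ has a fixed, non-trainable architecture;
  its weights are generated per instance, and it maps the treatment alone
  to the predicted outcome.

Prediction is ŷ = h_{g_ψ(f_φ(x))}(t) and training minimizes plain MSE on
the observed outcomes, end to end: the gradient of the loss flows through
the generated weights into ψ and φ (hand-derived backpropagation; the
per-sample weight-gradient of h is computed batched and chained through
g and f).  The design forces the treatment to enter through its own small
network rather than as one coordinate among many, which is what
distinguishes it from an S-learner and protects treatment sensitivity in
the fit.  Causal regularizers (propensity weighting, representation
balancing, targeted regularization) are deliberately out of scope; the
objective stays a plain MSE.

The weight layout of ω is fixed and documented: layers in input-to-output
order, each as the row-major (fan_out × fan_in) weight matrix followed by
the bias vector; `pack_weights`/`unpack_weights` are exact inverses.

## Ablation baseline

`fit_slearner` trains a neural S-learner: the same encoder, with the
hypernetwork replaced by an MLP head on concat(z, t).  It shares the
scaler, optimizer, schedule, restart logic and selection rule with the
hypernetwork estimator so that benchmark differences isolate the
mechanism, and its trainable parameter count is kept within a factor two
of the hypernetwork model's (0.83× under the defaults).  A
`raw_covariates` flag feeds (X, t) directly to the head for the
encoder-free variant.

## Defaults and why

Inputs: covariates and treatment are min-max scaled to [0, 1] on training
statistics; the outcome is z-scored and predictions are un-scaled on
output.  We found that z-scoring covariates (unit variance) while the
treatment lives on a unit interval systematically biases fits toward
covariate-only structure — the flat-dose-response failure mode — so all
inputs share the unit scale.  Constant covariate columns are dropped with
a warning; a zero-range treatment is an error.

Architecture (all ELU, smooth and zero at zero):

| piece          | shape              | default size |
|----------------|--------------------|--------------|
| encoder        | p → 64 → k         | k = 8        |
| hypernetwork   | k → 32 → m         | m = 49       |
| target network | τ → 16 → 1         | fixed        |
| S-learner head | (k+τ) → 48 → 48 → 1| —            |

The narrow representation (k = 8) and small target network reflect the
small-sample regime (hundreds of rows): wider configurations memorize
outcome noise and produce erratic counterfactual curves.  The
hypernetwork's output layer is initialized with its weights shrunk (×0.1)
and its bias set to a concrete fan-in initialization of the target
network, so generated weights start near a standard init plus small
instance-specific perturbations; without this the generated weights start
an order of magnitude too large and training is unstable.

Optimization: Adam (lr 1e-3, cosine-decayed to ~0.1×), decoupled weight
decay 0.1 on weight matrices, minibatches of 64, fixed 400-epoch
schedule.  A 10% validation split is used for model selection only: the
kept parameters are an exponential moving average (decay 0.995) of the
trajectory, snapshotted at the epoch with the lowest validation loss of
the averaged model.  Two independent restarts are trained per fit and the
better is kept.  `patience` can re-enable classical early stopping; by
default the schedule runs to completion.

Restart selection adds a degeneracy penalty to the validation loss: the
candidate's counterfactual curves are evaluated on a coarse dose grid
over (a subsample of) the training covariates, in standardized outcome
units, and any excursion beyond 3 standard deviations of the training
outcome contributes its squared excess.  Validation MSE is measured at
*observed* (x, t) pairs and cannot see off-support explosions; this guard
removed rare replicates whose curves ran to ~14 SD while their validation
loss looked best.

All randomness derives from one integer seed through numpy SeedSequence
spawning (restarts → init/split/shuffle streams); identical seed, data
and config reproduce parameters bit for bit.

## Metrics

On a dose grid over the normalized support [0, 1] (uniform, 65 points by
default; trapezoid rule):

* MISE = mean over test units of ∫ (ŷ_i(t) − θ_{x_i}(t))² dt — error of
  the individual curves;
* AMSE = ∫ (μ̂(t) − μ(t))² dt with μ̂, μ the average predicted and true
  curves — error of the average dose-response function.

AMSE ≤ MISE on a common grid (Jensen).  Oracles are evaluated
noiselessly.  Replicate aggregation reports mean ± standard error
(sd/√R); the ± column of the published tables is interpreted as a
standard error, which is a documented convention choice.

Predicting a curve reuses one generated ω per unit across the whole grid.
A grid extending beyond the fitted treatment support (with 5% relative
slack, so a [0, 1] grid over data that nearly saturates the unit interval
is not flagged) raises an `ExtrapolationWarning` rather than an error.

## Synthetic data

`generate_nie2021` reproduces the fully synthetic confounded benchmark
introduced by Nie et al. (2021) and used widely since: six i.i.d.
Uniform(0, 1) covariates; treatment t = 1/(1+exp(−2·(score(x)+ε))) with a
nonlinear confounded score (formula in the module docstrings) and
ε ~ N(0, 0.25²); outcome

    y = cos(2π(t−0.5)) · (t² + 4·max(x1,x6)³/(1+2x3²)·sin(x4)) + N(0, 0.5²).

The noise standard deviations are explicit `DGPSpec` fields because
different transcriptions of this DGP circulate; the defaults above are
this package's fixed study conditions.  The benchmark protocol is 100
instances of 500 training and 200 test samples; the desk-scale harness
default is R = 20 replicates, which keeps a two-model benchmark under
three minutes on one CPU while the standard errors remain small relative
to the between-model gap.

The generator emulates confounded treatment assignment with a known
noiseless oracle.  It does not emulate features of real observational
data — measurement error in covariates, unobserved confounding,
non-Gaussian or heteroscedastic noise, discrete covariates — so passing
benchmarks here demonstrates correct mechanics and relative model
behavior under ideal assumptions, not field performance.

`generate_linear_dgp` is an affine-in-treatment design (y = α(x) +
β(x)·t + ε) with a controllable confounding knob, used for
parameter-recovery tests.  `replicate_stream` derives collision-free
per-instance seeds from (base_seed, index) so any replicate can be
regenerated in isolation.  Continuous-IHDP and TCGA builders are adapter
stubs only: their covariates are external downloads and are deliberately
not fabricated.

## Benchmark results at the defaults

With the frozen defaults, R = 20 replicates (base seed 1) of the
500/200 protocol give HNet MISE 0.338 ± 0.038 and AMSE 0.106 ± 0.014
versus S-learner MISE 0.690 ± 0.038 and AMSE 0.275 ± 0.021; the
hypernetwork beats the S-learner on 19/20 replicates by MISE and 20/20
by AMSE (`scripts/acceptance.py` recomputes all of this).  The relative
ordering — the mechanism claim — is robust.  The absolute levels are
higher than the smallest published values for this benchmark: most of
the remaining error sits at the edges of the dose support, where the
logistic treatment model saturates and observations pile up at t ≈ 0 and
t ≈ 1, leaving the interior approach to the edge data-poor; at n = 5000
the same estimator reaches MISE ≈ 0.03.  Published configurations for
this benchmark (exact layer sizes, schedules, tuning protocol, and noise
constants) vary and are not always fully specified, so absolute levels
should be compared across implementations with care.

## Known limitations

* Scalar-treatment dose grids: curves and MISE/AMSE require τ = 1
  (higher-dimensional treatments are supported for fitting and point
  prediction).
* No missing data, categorical treatments or censored outcomes.
* No overlap diagnostics beyond the extrapolation warning; positivity is
  assumed, not checked.
* The validation loss used for model selection measures observed-data
  fit, which is only a weak proxy for counterfactual-curve quality — a
  structural limitation of observational model selection that the
  degeneracy guard mitigates but does not remove.
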