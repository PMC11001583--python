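# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and what the package's tests do and do not establish.

## Task simulators

**Pavlovian conditioning.** Four trial types — three auditory cues predicting
reward with probability 0.75, 0.25 and 0, plus uncued reward delivery — are
interleaved by shuffling a concatenation of the exact per-type counts
(default 60 each), so per-session counts are exact rather than binomial; the
"pseudorandom order" of the design is read as balanced shuffling. Each cued
trial is a 2.6 s pip train (100 ms on / 50 ms off), a 0.5 s trace period, then
a reward click with the cue's probability; uncued trials are a bare click.
Intertrial intervals are uniform on 15–30 s. The stated 2.6 s cue duration and
the 17-pip × 150 ms arithmetic (2.55 s) differ by one pip gap; the generator
is parameterized by stated duration for this task and reports event times
explicitly, so nothing downstream depends on the discrepancy.

**Multiple-delay task.** Cues are pip trains of k ∈ {1, 17, 76} pips at the
150 ms pip period, a fixed 0.5 s trace, then a 75%-probable click. The
cue-to-outcome delay is `(k−1)·0.15 + 0.1 + 0.5` s — exactly 0.6 s and 3.0 s
for the short and intermediate cues. For the 76-pip cue this gives 11.85 s;
the design's nominal "12 s" is not reachable by any consistent pip arithmetic
(76 pips "totaling 11.4 s" + 0.5 s trace = 11.9 s either), so the realized
11.85 s is reported as-is and the nominal values appear only as labels.

**Instrumental task.** Left/right reward probabilities drawn independently
from {0.1, 0.5, 0.9} in blocks of 35–45 trials; a 0.5–1.5 s hold precedes the
Go cue. Choices come from a softmax over leaky-integrated per-side reward
history (β = 3, τ = 60 s). This policy exists only to produce plausible
outcome sequences for the history fits; it is not a model of rat behavior.

## Photometry synthesis

Each driven event (reward click; cue onset under a discounting truth) injects
an impulse scaled by the ground-truth model's prediction error, convolved
with a causal single-exponential kernel. Kernel decay constants default to
0.1 / 0.2 / 0.4 s for DLS / DMS / VS — free parameters of the simulator
encoding only the ordering, not claims about tissue kinetics. The signal
channel adds white noise (SD 0.02 ΔF/F) and a slow drift (random walk
low-passed at 0.1 Hz, scaled to SD 0.005); the control channel carries the
drift (times a gain) plus independent noise and no event response. The drift
SD is deliberately small relative to transient variance: a low-passed random
walk has very few effective degrees of freedom per record, so a large drift
induces spurious sample correlation with the transients and biases both the
control regression and the autocorrelation fit — with the default the fitted
ACF decay recovers the configured kernel within ~7%.

Not modelled: photon/shot noise, isosbestic hemodynamics, motion artifacts,
rise kinetics (the kernel is decay-only because the tempo analysis fits a
single exponential to the ACF over 40–200 ms lags). Passing recovery tests
therefore show the *fitting chain* is correct, not that real recordings meet
these assumptions.

## Signal conventions

ΔF/F uses an affine least-squares rescaling of the control channel onto the
signal channel, `dff = (signal − fit)/fit`. The design choice of including an
intercept (the convention's description says only "least-square fit") handles
baseline offsets between channels and is invariant to common positive
rescaling. Responses are normalized to the mean peak (within 1 s) response to
uncued reward. Cue responses take the extremum of larger absolute value
within 0.5 s of onset, ties toward the maximum. All peak windows are
half-open `(event, event + w]`: the sample at the event time itself is
excluded, since event-driven transients begin after the event. The
autocorrelation uses the biased, mean-subtracted estimator normalized to
lag 0, fit by `a·e^(−lag/τ)` over 40–200 ms with an R² ≥ 0.8 quality flag.
Half-width interpolates the half-maximum crossings linearly and censors at
the trace edge.

## Reward-history fits

The leaky integrator is implemented as `dV/dt = −V/τ + Σ δ(t − t_reward)`
(one printed form of this model writes the decay term as "−τ", which is
dimensionally inconsistent with exponential decay at time constant τ; the
verbal description is authoritative). Values are always evaluated at the left
limit — a reward exactly at the evaluation time is excluded.

The τ scan correlates (Pearson by default; Spearman optional) the rate at
each reward click against the per-click DA peak (0–1 s window, rewarded
trials) across a 50-point log grid on [1, 2500] s, returning the τ with the
most negative correlation (ties to smaller τ). Grid spacing is a design
choice; the scanned range is part of the procedure. Because a grid-minimized
correlation has no closed-form null, significance uses a seeded permutation
of trial order (default 1,000 draws when requested) with the scan re-run per
permutation. The α scan is identical with delta-rule pre-trial values over
α ∈ {0.01, …, 1}; α = 0 yields a constant regressor and is excluded from the
default grid.

Recovery conditions (the acceptance surface): τ* ∈ {10, 60, 300, 1000} s
embedded in 300-trial instrumental sessions — block-structured outcomes give
the rate the slow fluctuations that identify τ — with Gaussian response noise
at 25% of the signal SD. Across 50 seeded runs the median recovered τ is
within 7% of truth and the cross-condition ordering is preserved in 100% of
runs (the testable form of the subregional-ordering claim).

## Discounting fits

Nonlinear least squares on `f = b + A·e^(−t/τ)` or `f = b + A/(1 + t/τ)`,
multi-start (20 starts, τ initialized log-uniform on [0.1, 100] s,
parameterized as log τ with bounds [0.05, 1000] s). A fit with τ at a bound
or |A| ≈ 0 is flagged non-identifiable. With only four design delays the
three-parameter fit is near-saturated: under 10% multiplicative noise the
baseline b trades off against long τ (a τ = 16 s truth recovers at ~67 s with
b free). The recovery experiment therefore uses the stated baseline-free
variant (b = 0, two parameters), under which median recovered τ is within 3%
and ordering of three distinct truths is preserved in 100% of 200 replicates,
for both curve forms. The free-b fit remains available and is the right
choice when data constrain the baseline (more delays, or responses far into
the tail).

## CSC TD(λ)

Sub-states are 200 ms wide (a design choice; the width is not part of the
published description), spanning cue onset through ~1 s past reward
(21 sub-states). Each cue has its own serial one-hot chain; a shared chain
(gain 1, configurable) is active during the pip train only, producing
generalization between cues early in training. Updates follow
`δ_t = r_t + γV(x_t) − V(x_{t−1})`, `e ← γλe + x_{t−1}`, `w += αδe`, both
value terms evaluated with pre-update weights. Eligibility traces reset at
trial start and weights persist across trials: the intertrial interval is not
represented by sub-states, since this model is not designed for horizons
spanning trials. Uncued clicks enter at the trial frame origin. At
convergence on a deterministic cue with reward D steps after onset, the
cue-onset prediction error equals γ^D (verified to 1e−3) and the model
reduces exactly to TD(0) at λ = 0 (verified against an independently coded
oracle to 1e−12). γ is reported alongside its equivalent time constant via
γ = e^(−dt/τ).

## Recurrent actor-critic

Three pools of 32 standard LSTM units (no peepholes; forget-gate bias
initialized to 1) receive the same 24-dimensional input: one click dimension
(5 for exactly one 50 ms step per click, else 0), three one-hot cue
dimensions, 17 shared cue dimensions set to 1 during any cue presentation,
and three constant background dimensions. Pools have no cross connections;
each has a linear value head with discount `γ_i = e^(−dt/τ_i)`,
τ = (2, 10, 1000) s, and all pools feed one linear softmax policy over
{poke, no-poke} (a single readout layer; depth is unspecified in the
published description).

Environment: a click's unit reward is collected by the first poke at or after
the click, once. Poking costs −0.003, reduced to 10% of that (−0.0003) for
pokes continuing a consecutive run; "reduced for repeats" is read as the
first poke of every run costing the full amount. Rewards follow the
`r_{t+1}`-for-action-`a_t` convention.

Training minimizes `−L^P + β_V L^V − β_e L^e` over T-step sequences
(T = 10,000 by default), where L^P is the clipped PPO surrogate with
ε = 0.2 (the PPO convention; unspecified in the published description), the
advantage is the sum of the three per-pool GAEs (λ = 0.98) computed from
rollout values, L^V sums squared errors against discounted returns
bootstrapped by the value one step past the sequence, and L^e is the policy
entropy (β_V = 0.8, β_e = 0.001). One PPO epoch per sequence by default (the
ratio is then 1 and clipping is inactive; the epoch count is exposed in the
config). Hidden state carries across consecutive sequences, detached, so the
task never presents discrete trial boundaries. Adam with learning rate
5·10⁻⁴.

The implementation is plain numpy with hand-derived backpropagation through
time; the test suite checks every parameter block against central-difference
numerical gradients (relative error ~1e−6). The reported prediction error is
`RPE_i(t) = r_t + γ_i V_i(t) − V_i(t−1)`, reconstructible exactly from stored
values and rewards. Action sampling is stochastic during both training and
RPE extraction (greedy mode available).

**Reduced scale.** The packaged experiments train with T = 2,000-step
sequences for 150 updates and 3 seeds (~2 minutes of CPU total), a problem
size chosen so the full pipeline runs comfortably on a laptop while the
qualitative pattern is already statistically unambiguous: cue ordering
75% > 25% > 0% in the τ = 10 s pool (pooled Mann-Whitney p < 1e−7), smallest
cue/click response ratio in the τ = 2 s pool (p < 1e−3), and weaker, slower
cue discrimination in the τ = 1000 s pool than the τ = 10 s pool at both
mid- and end-of-training probes (Wilcoxon over seed × checkpoint pairs,
p ≈ 0.016). Full-scale runs (T = 10,000, hundreds of updates, 20 seeds) use
the same code path via `AgentConfig`.

## Pipeline and reproducibility

Every experiment is driven by an `ExperimentConfig` (experiment name, seed,
parameter dict) whose SHA-256 hash is embedded, with the seed and package
version, in the JSON report; per-stage tables are CSV. Reports are
figure-free: acceptance is numeric. The same config and seed reproduce
byte-identical reports. All randomness flows from `numpy.random.default_rng`
seeded per stage; derived seeds stay below 2³¹.

## Package shape

The grid scans and curve fits are exposed as scikit-learn-style estimators
(`LeakyIntegratorScan`, `DeltaRuleScan`, `DiscountCurveFit`: `fit`,
`get_params`, fitted attributes with trailing underscores) so they compose
with sklearn model-selection tooling; the simulators, the CSC model and the
recurrent agent are not fit/predict-shaped and keep a functional/dataclass
interface. Module-level functions (`scan_tau`, `scan_alpha`, `fit_discount`)
are thin wrappers over the same code.

## Known limitations

- The photometry simulator's noise model is intentionally minimal; recovery
  results bound estimator correctness, not robustness to real artifacts.
- The delay task's longest realized delay is 11.85 s, not the nominal 12 s
  (see above); discount fits use realized delays.
- With the four design delays, free-baseline discount fits are
  near-degenerate for τ beyond ~8 s; consult the `non_identifiable` flag.
- The reduced-scale agent shows the τ = 1000 s pool's 0% cue response still
  positive at the end of training (discrimination not yet complete); longer
  training continues to improve it, consistent with slow-timescale learning
  being slow. The packaged tests assert the relative pattern, not its
  asymptote.
- No arbitration between the three value systems is modelled; the policy
  simply sums their advantages.
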