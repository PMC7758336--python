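# Methods

This note documents the models implemented in `twopathway`, the
assumptions and numerical choices behind them, and what the synthetic
protocols do and do not establish.

## The classification task

All single-neuron and population analyses use the same synthetic task:
`P` input patterns with i.i.d. standard-normal entries arrive through two
pathways, `x` (dimension `N_x`) and `y` (dimension `N_y`), and each
pattern carries an independent fair ±1 target per readout unit.  Patterns
are unitless; nothing in the model sets a physical scale.  `N_y = 0`
encodes the single-pathway model, so every trainer accepts one ensemble
type.  Targets are unbalanced on purpose (independent fair draws, no
quota): balance constraints would correlate patterns and break the
stationarity arguments below.

All randomness derives from one root seed through
`numpy.random.SeedSequence` children, so pattern draws, stochastic
readouts, and perturbation noise are independently reproducible.

## Fast pathway: the margin perceptron

A readout unit classifies by `sign(u)` with `u = w·x` (plus `v·y` in the
two-pathway model).  Training pattern `mu` applies the one-step rule: if
the signed margin `u·zhat` is below `kappa` (default 1), the weights jump
by `(kappa·zhat − u)·x / D`; otherwise nothing happens.  Two
normalizations are provided:

* `by_N_x` (default): `D = N_x`.  For Gaussian inputs `|x|² ≈ N_x`, so
  the post-update margin is `kappa` up to an `O(1/√N_x)` fluctuation.
* `by_input_norm`: `D = |x|²`.  The post-update margin equals `kappa` to
  machine precision; this mode makes the geometric statement of the rule
  exact, and is what the margin-attainment check uses.

`sign(0)` is defined as +1 — a measure-zero event fixed for determinism.

**Cycled training and capacity.**  Cycling passes through all `P`
patterns until a pass makes no update.  Because the `by_N_x` step
approaches the margin only geometrically from below (its effective step
size `|x|²/N_x` fluctuates around 1), a literal zero-update criterion
never fires; `train_cycled` therefore treats a margin within `tol`
(default 1e-6, absolute) of `kappa` as satisfied.  With that tolerance
the empirical storage capacity — the load `P/N_x` at which the converged
fraction over seeds crosses one half (20 seeds per load, epoch cap 10^4,
`N_x = 200`) — lands near 1.9, consistent with the classical value 2 for
random dichotomies once finite-size rounding is allowed for.  The margin
value itself does not move the capacity: with unconstrained weight norm,
`kappa` can be absorbed into a rescaling of `w`.

**Sequential training and the forgetting curve.**  Trained in sequence
(each pattern once, never revisited), each new pattern partially
overwrites older ones.  The Monte-Carlo estimator trains `burn_in + P`
patterns (burn-in default `4·N_x`) and classifies the last `P` with the
final weights; the burn-in ensures tested patterns see the stationary
weight regime that the theory averages over.  Errors are reported at
exact per-pattern lags `tau = (P − nu)/N_x` with binomial standard errors
over runs.  A gradient-descent variant accumulates many small hinge-loss
steps (`max(0, kappa − u·zhat)`) per pattern instead of one jump; the
hinge is a choice — its minimum reproduces the margin condition — and its
forgetting curve is qualitatively the same monotone curve.

## Slow pathway: Hebbian learning with decay

One presentation of pattern `mu` updates the second-pathway weights as

    dV = −(alpha·n_mu / (N_y·nbar)) V + sqrt(2)·(beta·n_mu / (N_y·nbar)) zhat yᵀ

applied row-wise with each readout unit's target.  `n_mu` is the
pattern's repetition count and `nbar` the mean over patterns; the
`N_y·nbar` normalization gives a sensible large-`N_y` limit.  The decay
term keeps `|V|` bounded (stationary per-row norm `beta²/(alpha·nbar)`).
By default each physical presentation applies the rule with `n_mu = 1`
(`per_repetition`), because the alignment and control-transfer traces are
plotted per repetition; an `aggregated` mode applies one combined update
with the full `n_mu`, matching the written form of the rule exactly.  The
two modes agree to `O(alpha·n/N_y)`.

The supervised step uses the *total* current `u = w·x + v·y` and precedes
the Hebbian step within a presentation — fast learning is assumed fast
relative to slow learning, which is also why the Hebbian rule may use the
target rather than the realized output.  During repetitions after the
first, supervised updates still fire whenever the margin condition is
violated; no special-casing.

## Drift-diffusion theory of forgetting

The semi-analytic curves (`twopathway.theory`) treat the margin of one
tested pattern as an Ornstein–Uhlenbeck process driven by subsequent
training.  Writing `s_w = (w·x)·zhat`, `s_h = (v·y)·zhat`,
`sigma_tot² = Var(s_w) + Var(s_h)` in the stationary regime:

* a random pattern triggers a supervised update with probability
  `q = Phi(kappa/sigma_tot)`;
* each subsequent pattern moves the tested pattern's `s_w` by a random
  amount with conditional mean `−q·s_w/N_x` (Stein's lemma applied to the
  trigger indicator; the boundary term vanishes because the update
  amplitude is zero at the trigger boundary) and variance `C/N_x`, where
  `C = E[(kappa−s)²; s<kappa] = sigma_tot²[(1+k²)Phi(k) + k·phi(k)]`,
  `k = kappa/sigma_tot`;
* self-consistency `Var(s_w) = C/(2q)` fixes `sigma_tot` (solved by
  Brent's method to 1e-12);
* the Hebbian component is an OU process with rate `alpha/(r·nbar)` per
  unit `tau` (`r = N_y/N_x`) and stationary variance `beta²/(alpha·nbar)`;
* training sets the total margin to `kappa` if it was below (probability
  `q`), and each of `n_nu` repetitions adds `sqrt(2)·beta/nbar` to `s_h`;
* the recall error at lag `tau` is the probability that the evolved
  Gaussian margin is negative, averaged over the stationary initial
  condition (80-node Gauss–Hermite over `s_h`, adaptive quadrature with
  relative tolerance 1e-6 over the conditioned `s_w` tail).

In the single-pathway limit the self-consistency condition reduces to
`(1−k²)Phi(k) = k·phi(k)`, giving `k ≈ 0.840`, stationary margin SD
`≈ 1.19·kappa` and trigger probability `q ≈ 0.80`.  The evaluator is the
normative implementation; it is validated against Monte-Carlo simulation
at `N = 500–1000` over a `(tau, beta, n)` grid in the test suite (exact
binomial agreement at the 3-sigma level).  The mean-field description is
exact only as `N → ∞`; at `N = 500` residual biases are well inside the
Monte-Carlo uncertainty at a few hundred runs.

## Population readout, alignment, control transfer, lesions

With `N_z` readout units, the weight vectors become matrices and the
currents are `m = W x`, `h = V y`.  Reported summaries:

* alignment `m·h/(|m||h|)` (0 by convention if either norm vanishes);
* control ratio `(h·zhat)/((m+h)·zhat)` (0 when `h = 0`, 1 when `m = 0`);
* per-pattern population error: fraction of readout units whose sign
  disagrees with the target;
* lesions: readout from `h` alone (`m_zero`), `m` alone (`h_zero`), or
  `m + sigma_m·xi` with Gaussian noise (100 draws per amplitude by
  default).

Two protocol details matter and are easy to get wrong.  First, alignment
is trivially 1 when a single pattern is trained from zero weights: both
currents are then exact multiples of the same accumulated update
direction.  Alignment traces are therefore measured after bringing the
network to the stationary regime on background patterns (supervised-HL
experiments) or from random `O(1)`-current initial weights (RL
experiments).  Second, the silencing-similarity measures describe the
state right after practice; the practiced probe is trained last, since
after `~N_x` further patterns the fast current has diffused and the
`m`-silenced/`h`-silenced correlation decays regardless of practice.

## Reinforcement-learning variant

Readout units fire stochastically (`z_i = +1` with probability
`sigma(m_i + h_i)`), the reward is `R = z·zhat/√N_z`, and the fast
weights follow REINFORCE with a low-pass baseline (`tau_R = 10` trials):

    dW_ij = (eta/N_x)(R − Rbar) z_i sigma(−z_i(m_i+h_i)) x_j

Variants: `RL_only`, `RL_plus_HL` (Hebbian rule on `V`, rates
`(eta, beta) = (1, 0.01)`), and `RL_plus_RL` (the same REINFORCE rule on
`V` with `eta_2 = 0.01`).  Defaults `N_x = N_y = 1000`, `N_z = 10`.  One
"repetition" is one stochastic trial with one update of each plastic
pathway.  Lesion robustness is scored as the expected stochastic-readout
accuracy with a pathway silenced (`mean(sigma(h·zhat))` for `m` removed):
a hard sign would score even a vanishingly small aligned `h` perfectly
and erase the RL+HL/RL+RL contrast.

The Hebbian rule in RL+HL can associate `y` with the target (`target`,
the written form, valid while slow learning lags fast learning) or with
the realized output (`output`).  `train_rl` defaults to `target`; the
habit experiment defaults to `output`, because a habit is precisely a
response that keeps reinforcing itself: after the target switches, an
output-driven association keeps strengthening the old response, so
re-learning slows with pretraining and fails outright for strong habits,
whereas a target-driven association would simply re-associate to the new
target on the `N_y/alpha` timescale and the habit would always wash out.
The habit criterion is a 20-trial moving average of the per-unit match
with the new target reaching 75%; the post-switch cap is 10^4 trials
(both configurable; the window length is a smoothing choice for a 10-unit
readout).

## Center-out reaching task

A cursor starting at the origin must reach one of four unit targets in
`T = 10` steps, following the minimum-jerk speed profile
`30u² − 60u³ + 30u⁴` (unit integral, so the continuous-time displacement
equals the target; the discrete Riemann sum reproduces it to ~1e-4).
The controller is a two-pathway network with a hidden layer:
`N_x = N_y = 50` inputs per pathway, `N_z = 10` tanh hidden units (a
smooth saturating nonlinearity, since the fast pathway is trained by
backpropagated gradients), and a fixed linear 2-D readout giving the
velocity; position advances by `velocity/T` per step.  Each input
population receives a tonic cue for the current target plus a fixed
random projection of the cursor position (a previous-step-velocity
feedback mode is available; the position default reflects the view of
the feedback as the integrated readout).  Cue statistics differ by
pathway on purpose: the fast pathway's cues are independent Gaussian
vectors, whose chance overlaps (~`1/sqrt(N_x)` relative) let sequential
blocks genuinely interfere in `W`, while the slow pathway's cues are
mutually orthogonal, so the Hebbian associations stored for different
targets do not cross-contaminate.  With Gaussian cues in both pathways
the stored slow-pathway trace is occasionally maladaptive at test (its
cross-target component pushes stale activity patterns), and with
orthogonal cues in both pathways the fast pathway barely forgets, which
removes the effect being studied; the mixed design isolates it.  `W` is trained by per-trial
batch gradient descent on the squared velocity error with
`eta_SL = 1e-3`, treating each step's inputs as data (no
backpropagation through the feedback loop); `V` follows
`dV_ij = eta_HL(−V_ij + z_i y_j)` per step with `eta_HL = 1e-6`, active
only in the SL+HL condition.  `W` starts at fan-in-scaled random values,
`V` at zero in every condition.

Training is block-sequential — a long first block on target 1, then
shorter blocks on targets 2–4 — so later blocks overwrite `W`; the
interleaved condition draws targets uniformly per trial and is the
no-forgetting control.  Block lengths are a protocol choice (not given
with the task): because `V` decays on the `1/eta_HL = 10^6`-step
timescale, the Hebbian trace grows linearly with total exposure, and the
retention contrast between SL+HL and SL-only is reliable only once the
first-target association is strong relative to the crosstalk accumulated
in later blocks.  The defaults use 6000 trials for block 1 and 1500 for
each later block.  Retention is evaluated by frozen-weight rollouts per
target over matched network pairs (same construction seed, conditions
differing only in plasticity), with a one-sided Wilcoxon signed-rank test
on the paired first-target losses.  The paired contrast is directionally
consistent (positive mean and median improvement from Hebbian learning
across independent seed sets) but heterogeneous across networks —
interference in a 10-unit hidden layer is idiosyncratic — so its
significance at conventional levels fluctuates at a few dozen pairs;
this is a known limitation of the protocol, discussed honestly rather
than smoothed over.

## What the synthetic protocols do not show

The task ensembles are i.i.d. Gaussian with independent fair targets;
correlated or structured inputs, multi-step action sequences, plastic
second-pathway *representations* (only the readout weights `V` learn),
and recurrent readout dynamics are all outside the model.  Passing tests
establish the internal consistency of the theory and the direction of
the predicted lesion/perturbation/habit effects under these idealized
conditions, not quantitative agreement with any biological dataset.
Spaced repetition in this model is always worse than massed repetition
(shorter gaps are better at every testing interval), which disagrees
with the experimental spacing-effect literature — a known limitation of
the single-neuron account, not a bug.

## Problem sizes

Desk-scale defaults used in the test suite: `N_x = 200–500` for
capacity and forgetting curves (120–250 Monte-Carlo runs),
`N = N_z = 300–400` for population lesion/alignment analyses,
`N_x = N_y = 500–1000` for the RL experiments, and 21 matched network
pairs for the reaching comparison.  Figure-scale experiment defaults
(`N = 1000`, 200+ runs) are available through the experiment runner; the
`desk` preset shrinks them for interactive use.
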