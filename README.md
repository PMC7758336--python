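# twopathway

Simulator and semi-analytic theory for **fast and slow learning in
parallel input pathways** to a downstream neural population — a model of
how motor cortex (fast, error- or reward-driven plasticity) and thalamus
(slow, associative plasticity) jointly drive striatum during the
acquisition, retention and automatization of learned behaviors.

The package is aimed at computational neuroscientists studying synaptic
learning rules, memory retention and habit formation.  It provides:

* **Margin perceptron** (`twopathway.perceptron`): one-step supervised
  learning `Δw = (κ ẑ − u) x / N_x` (for `u ẑ < κ`), sequential and
  cycled training, storage-capacity estimation, and Monte-Carlo
  forgetting curves — recall error as a function of the normalized lag
  `τ = (P − ν)/N_x`.
* **Two-pathway learner** (`twopathway.pathways`): a second input with
  the decaying Hebbian rule
  `Δv = −(α n_μ / N_y n̄) v + √2 (β n_μ / N_y n̄) ẑ y`; repetition-dependent
  retention, input alignment `m·h/(|m||h|)`, control transfer, lesion and
  noise-perturbation tests on a population readout `z = sgn(m + h)`.
* **Drift-diffusion theory** (`twopathway.theory`): semi-analytic
  forgetting curves `F(τ)` and `G(τ, N_y/N_x, α, β, n_ν/n̄)` evaluated by
  quadrature and validated against simulation.
* **Reinforcement-learning variant** (`twopathway.reinforce`): stochastic
  readout `P(z_i = +1) = σ(m_i + h_i)`, REINFORCE with a low-pass reward
  baseline, the RL+HL vs RL+RL comparison, and habit formation after a
  target switch.
* **Center-out reaching** (`twopathway.reaching`): a two-pathway network
  with a hidden layer tracking minimum-jerk trajectories, block-sequential
  training and retention comparisons.
* **Experiment runner** (`twopathway` CLI): named,
  manifest-reproducible experiments with tidy CSV outputs.

See `docs/methods.md` for model details and `examples/` for short
narrative scripts, one per capability.

## Worked example

Forgetting in a sequentially trained perceptron, simulation vs. theory:

```python
from twopathway import estimate_forgetting_curve, theoretical_error_single

curve = estimate_forgetting_curve(N_x=250, n_runs=200, seed=1)
for tau in (0.0, 0.25, 0.5, 1.0, 2.0):
    mc, se = curve.at(tau)
    th = theoretical_error_single(tau)
    print(f"tau={tau:4.2f}  simulated={mc:.3f}+-{se:.3f}  theory={th:.3f}")
```

prints

```
tau=0.00  simulated=0.000+-0.000  theory=0.000
tau=0.25  simulated=0.095+-0.021  theory=0.101
tau=0.50  simulated=0.200+-0.028  theory=0.203
tau=1.00  simulated=0.305+-0.033  theory=0.318
tau=2.00  simulated=0.450+-0.035  theory=0.422
```

The most recently trained pattern (`τ = 0`) is always recalled; error
rises monotonically with the number of patterns learned since, reaching
chance (0.5) for the distant past.  Because the lag enters only through
`τ = (P − ν)/N_x`, memory is extensive in the synapse count.  The theory
column is the drift-diffusion prediction; it agrees with the simulation
within Monte-Carlo error.

Repetition-dependent retention in the two-pathway model:

```python
from twopathway import repeated_pattern_error

for n in (1, 5, 20):
    c = repeated_pattern_error(N_x=500, N_y=500, alpha=1.0, beta=1.0,
                               n_rep=n, lags=[1000], n_runs=200, seed=2)
    print(f"repetitions={n:2d}  error after 1000 patterns: "
          f"{c.error[0]:.3f}+-{c.se[0]:.3f}")
```

```
repetitions= 1  error after 1000 patterns: 0.365+-0.034
repetitions= 5  error after 1000 patterns: 0.220+-0.029
repetitions=20  error after 1000 patterns: 0.020+-0.010
```

A pattern practiced 20 times is still recalled almost perfectly after
1000 subsequent patterns (twice the total synapse count) — the slow
pathway has taken over the association.

## Command-line experiments

```bash
twopathway list
twopathway run fig1d --seed 1 --out results --preset desk
twopathway run fig2e --set p_theta=0.1 --set "intervals=[125, 250, 500]"
```

Each run writes tidy CSV tables, a JSON manifest and an echo of the full
configuration; re-running from the emitted `config.yaml` reproduces the
output exactly.

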