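"""Storage capacity of the cycled margin perceptron.

Cycling through P random +-1 classifications converges to zero training
error as long as the load P/N_x is below the critical capacity of 2
patterns per synapse; above it, training never finds a separating
weight vector.  The script sweeps the load and interpolates the
50%-convergence crossing.
"""
import numpy as np
from twopathway import capacity_crossing, estimate_capacity

ratios, fractions = estimate_capacity(N_x=100, ratios=np.arange(1.5, 2.51, 0.2),
                                      n_seeds=10, seed=0)
for r, f in zip(ratios, fractions):
    print(f"load P/N_x = {r:.1f}: converged fraction {f:.2f}")
print(f"estimated capacity (50% crossing): {capacity_crossing(ratios, fractions):.2f}")
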