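"""Hebbian learning protects a practiced reach from being overwritten.

Networks are trained on four center-out reaches in blocks (a long first
block, then three shorter ones).  Sequential training overwrites the
first target in the supervised-only network; with slow Hebbian learning
in the second pathway the practiced first reach is retained.  Uses a
small illustrative batch of network pairs to stay quick; the effect is
heterogeneous across networks, so the population-level comparison (40
matched pairs with a signed-rank test) runs in the test suite.
"""
from twopathway import ReachingSpec, retention_experiment

df = retention_experiment(("SL_only", "SL_plus_HL"), n_networks=5, seed=11,
                          spec=ReachingSpec())
print("mean test loss per target (5 matched network pairs)")
print(df.groupby(["condition", "target"]).loss.mean().unstack().round(3))
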