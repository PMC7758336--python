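"""Practice protects memories: repetition-dependent retention.

In the two-pathway model, repeating a pattern strengthens its slow
Hebbian association, shifting its forgetting curve so that the pattern
survives long after unrepeated patterns are overwritten.
"""
from twopathway import repeated_pattern_error

print("error of the practiced pattern after 1000 subsequent patterns")
for n in (1, 5, 20):
    c = repeated_pattern_error(N_x=500, N_y=500, alpha=1.0, beta=1.0,
                               n_rep=n, lags=[1000], n_runs=200, seed=2)
    print(f"  repetitions={n:2d}: {c.error[0]:.3f} +- {c.se[0]:.3f}")
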