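"""Drift-diffusion theory vs Monte-Carlo simulation.

The generalized forgetting curve of the two-pathway model, evaluated by
quadrature, against direct simulation for a pattern repeated 5 times.
"""
from twopathway import repeated_pattern_error, theoretical_error_two_pathway

N = 500
lags = [N // 2, N, 2 * N]
c = repeated_pattern_error(N, N, alpha=1.0, beta=1.0, n_rep=5, lags=lags,
                           n_runs=200, seed=7)
print("tau    simulated        theory")
for tau, err, se in zip(c.tau, c.error, c.se):
    th = theoretical_error_two_pathway(tau, 1.0, 1.0, 1.0, 5)
    print(f"{tau:4.2f}   {err:.3f} +- {se:.3f}   {th:.3f}")
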