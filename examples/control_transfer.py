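"""Input alignment and control transfer during practice.

As one pattern is repeated, the slow pathway's current h aligns with
the fast pathway's current m, and h carries a growing share of the
drive along the target readout direction: control of the population is
covertly transferred from the fast to the slow input.
"""
from twopathway import TwoPathwayState, generate_patterns, present_pattern

N, N_z = 400, 300
ens = generate_patterns(N + 1, N, N, N_z, seed=3)
state = TwoPathwayState.zeros(N, N, N_z)
for mu in range(N):                      # reach the stationary regime
    present_pattern(state, ens.X[mu], ens.Y[mu], ens.Zhat[mu])
traces = present_pattern(state, ens.X[-1], ens.Y[-1], ens.Zhat[-1], n=10)
print("rep  alignment  slow-pathway control share")
for rep, dec in enumerate(traces, start=1):
    print(f"{rep:3d}   {dec.alignment:8.3f}   {dec.control_ratio(ens.Zhat[-1]):.3f}")
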