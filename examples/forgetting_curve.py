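"""Forgetting in a sequentially trained margin perceptron.

Trains fresh random classifications in sequence and measures the recall
error of each pattern as a function of how many patterns were learned
after it, comparing the Monte-Carlo estimate with the drift-diffusion
theory.  Error is 0 for the most recent pattern and rises to chance
(0.5) for the distant past; the lag matters only through (P - nu)/N_x.
"""
from twopathway import estimate_forgetting_curve, theoretical_error_single

curve = estimate_forgetting_curve(N_x=250, n_runs=200, seed=1)
print("tau    simulated        theory")
for tau in (0.0, 0.25, 0.5, 1.0, 2.0):
    mc, se = curve.at(tau)
    print(f"{tau:4.2f}   {mc:.3f} +- {se:.3f}   {theoretical_error_single(tau):.3f}")
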