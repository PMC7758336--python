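"""Lesion asymmetry: practiced behaviors survive loss of the fast input.

After training with one heavily repeated pattern, silencing the fast
pathway (m = 0) barely affects the practiced pattern but hurts all
others; silencing the slow pathway (h = 0) destroys the practiced
pattern's recall.  This mirrors the asymmetric effects of cortical vs
thalamic lesions on well-practiced motor skills.
"""
import numpy as np
from twopathway import (TwoPathwayState, generate_patterns, lesion_test,
                        make_repetition_schedule, train_two_pathway)

N, P, rep = 400, 400, 200
ens = generate_patterns(P, N, N, 300, seed=4)
sched = make_repetition_schedule(P, {rep: 15})
state = TwoPathwayState.zeros(N, N, 300, nbar=sched.nbar)
train_two_pathway(ens, sched, state)
others = np.arange(P) != rep
for mode in ("intact", "m_zero", "h_zero"):
    err = lesion_test(state, ens, mode)
    print(f"{mode:7s}: practiced pattern error {err[rep]:.3f}, "
          f"mean error of others {err[others].mean():.3f}")
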