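"""Habit formation in the reinforcement-learning variant.

A model is trained to produce one output for an input, then the target
switches.  With Hebbian learning in the second pathway the old response
keeps reinforcing itself: re-learning slows with the amount of
pretraining and fails entirely for strong habits.
"""
from twopathway import habit_experiment

print("post-switch trials to reach 75% accuracy on the new target")
print("pretraining   RL only   RL + Hebbian")
for n_nu in (0, 60, 2000):
    r1 = habit_experiment("RL_only", n_nu, N_x=500, N_y=500, seed=5)
    r2 = habit_experiment("RL_plus_HL", n_nu, N_x=500, N_y=500, seed=5)
    fmt = lambda r: str(r.trials_to_criterion) if r.attained else "unattained"
    print(f"{n_nu:10d}   {fmt(r1):>7s}   {fmt(r2):>12s}")
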