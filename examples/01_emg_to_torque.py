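"""From raw surface EMG to ankle dorsiflexion torque.

Synthesizes one second-long burst of tibialis-anterior EMG, runs the full
EMG-driven pipeline (band-pass + rectify + low-pass envelope, delayed
neural-activation recursion, log/linear activation curve, Hill-type
muscle-tendon dynamics) at a fixed ankle angle, and prints the torque the
model predicts.
"""

import math

import numpy as np

import myoadmit as ma

fs = 1000.0
t = np.arange(0, 5, 1 / fs)
# effort profile: rest, 2 s ramp to 60% drive, hold
profile = 0.6 * np.clip((t - 1.0) / 2.0, 0, 1)

subject = ma.default_subject()
raw = ma.synth_emg(profile, fs, seed=0)

env = ma.compute_envelope(raw)
u = np.clip(ma.neural_activation(env), 0, 1)
a = subject.curve(u)

q = np.full(len(t), math.pi / 2)  # neutral ankle (90 deg)
traj = ma.simulate_muscle(a, q, fs, subject.hill, subject.geometry,
                          lm_init="equilibrium")

print(f"peak envelope          : {env.e.max():.3f}  (fraction of MVC)")
print(f"peak muscle activation : {a.max():.3f}")
print(f"peak tendon force      : {traj.Ft.max():.1f} N")
print(f"peak dorsiflexion torque: {traj.Mp.max():.2f} N*m")
print()
print("The torque is the moment arm (~4.5 cm at neutral) times the")
print("muscle-tendon force. The log/linear activation curve amplifies")
print("low-level drive, so a 60% neural command yields ~0.79 muscle")
print("activation and ~25 N*m of this subject's ~30 N*m maximum")
print("isometric dorsiflexion torque.")
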