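"""Stiffness verification by sinusoidal perturbation.

For each held TA activation level, a motor under PD control applies a
0.5 deg / 3 Hz perturbation while the virtual subject's ankle reacts
through its (linearized) joint stiffness; the "measured" stiffness is
recovered by regressing the sensed torque on angle and angular velocity,
and compared with the EMG-driven model estimate computed from the
trial's synthetic EMG.
"""

import numpy as np

import myoadmit as ma

subject = ma.VirtualSubject(params=ma.default_subject())
levels = [0.0, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35]

meas, est = [], []
for i, level in enumerate(levels):
    res = ma.run_perturbation_trial(subject=subject, activation_level=level,
                                    duration=10.0, seed=100 + i)
    meas.append(res.measured_K)
    est.append(res.estimated_K)

print(f"{'% MVC':>6} {'measured K':>12} {'estimated K':>12}   (N*m/rad)")
for lv, m, e in zip(levels, meas, est):
    print(f"{100*lv:>6.0f} {m:>12.2f} {e:>12.2f}")
r = ma.pearson_correlation(meas, est)
print(f"\nPearson r (measured vs estimated): {r:.3f}")
print()
print("Joint stiffness grows with activation (stiffer fibers and a")
print("tauter tendon); a correlation near 1 across levels verifies the")
print("EMG-driven stiffness estimate against the mechanical measurement,")
print("mirroring the published single-subject verification (r = 0.992).")
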