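"""Subject-specific calibration from maximum-voluntary-contraction trials.

Generates noise-free MVC trials at the two calibration angles (90 and
120 deg) with a known parameter set, then refits the three subject
parameters — activation-curve shape A, tendon slack length lst, and
maximum isometric force Fmx — by Nelder-Mead on the mean squared torque
error, starting from a point perturbed by +/-20%.
"""

import math

import myoadmit as ma

truth = ma.default_subject()
subject = ma.VirtualSubject(params=truth)

trials = [ma.run_mvc_trial(subject, math.radians(angle), ideal=True)
          for angle in (90, 120)]

fit = ma.calibrate(trials, truth,
                   init={"A": truth.A * 1.2, "lst": truth.lst * 0.9,
                         "Fmx": truth.Fmx * 1.2})

print(f"{'parameter':<10}{'true':>10}{'recovered':>12}{'error %':>10}")
for name, tv, rv in [("A", truth.A, fit.A),
                     ("lst [m]", truth.lst, fit.lst_m),
                     ("Fmx [N]", truth.Fmx, fit.Fmx_N)]:
    print(f"{name:<10}{tv:>10.4f}{rv:>12.4f}{100*abs(rv-tv)/tv:>10.4f}")
print(f"\nfinal torque MSE: {fit.Er:.3g} (N*m)^2 "
      f"after {fit.n_iter} objective evaluations")
print()
print("Sub-percent recovery of all three parameters shows the two-angle")
print("MVC protocol identifies the model: the two angles separate lst")
print("from Fmx (different tendon operating points) and the effort ramp")
print("identifies the activation-curve shape A.")
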