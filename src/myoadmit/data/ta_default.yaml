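# Default tibialis anterior (TA) parameter set.
#
# Geometry and muscle architecture are generic adult values from a
# standard lower-limb musculoskeletal model; they are DEFAULTS intended
# as a starting point for subject-specific calibration, which refits
# A, lst_m and Fmx_N from MVC trials.
OA_m: 0.32        # origin-to-ankle-centre distance
OB_m: 0.045       # insertion-to-ankle-centre distance
l0_m: 0.098       # optimum fiber length
phi0_rad: 0.08727 # optimal pennation angle (5 deg)
Fmx_N: 905.0      # maximum isometric force
lst_m: 0.223      # tendon slack length
A: 0.06           # activation-curve shape parameter
lambda: 0.15      # activation shift of the optimal fiber length
gamma: 23.4       # fiber-stiffness scaling constant
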