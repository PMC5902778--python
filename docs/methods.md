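# Methods

`myoadmit` implements an EMG-driven musculoskeletal model (EDMM) of the
tibialis anterior (TA) acting about the ankle, the joint-stiffness
estimate derived from it, and a stiffness-adaptive admittance control
scheme for a dorsiflexion-assisting ankle exoskeleton — together with a
closed-loop simulator that stands in for the hardware and the human
subject. This note documents the models, their assumptions, the
numerical choices, and what the simulated experiments do and do not
establish.

## 1. EMG to muscle activation

Raw surface EMG (1 kHz) is band-pass filtered 20–450 Hz (4th-order
Butterworth), full-wave rectified, low-pass filtered at 2 Hz (2nd-order
Butterworth) and normalized by the maximal processed-envelope amplitude
recorded over the MVC trials at both calibration angles. Filters are
causal by default, matching real-time use; a zero-phase mode exists for
offline work. The envelope e(t) drives a delayed second-order recursion

    u(t) = α e(t − d) − β₁ u(t−1) − β₂ u(t−2),
    α = 0.9486, β₁ = −0.052, β₂ = 0.000627, d = 80 ms,

run per sample at the envelope rate (d rounded to whole samples). Both
characteristic roots (0.033, 0.019) lie far inside the unit circle, and
the DC gain is α/(1+β₁+β₂) ≈ 0.99997. Neural activation u is clamped
to [0, 1] before the activation nonlinearity

    a = b ln(c u + 1)   (u < u₀),      a = m u + n   (u ≥ u₀),

whose node is placed by one shape parameter A: u₀ = 0.3085 − A cos 45°,
a₀ = 0.3085 + A sin 45°. The line is fixed by (u₀, a₀) and (1, 1);
c = (e^{a₀/b} − 1)/u₀ enforces continuity, and b is solved so both
branches share their slope at the node, by a bisection-safeguarded
Newton iteration on h(b) = b(1 − e^{−a₀/b})/u₀ − m (tolerance 1e-10).
h is strictly increasing with limit a₀/u₀, so a root exists iff
m < a₀/u₀, i.e. A > 0; b is *not* bounded by 1 (A = 0.01 gives
b ≈ 2.35). A = 0 is the exact linear limit, represented by b = 1e6
(slope mismatch < 2e-7); A < 0 is rejected — the concave log branch
cannot match the then-required slope.

## 2. Musculotendon mechanics

The TA follows a straight-line path from origin to insertion across the
joint centre; with anatomical angle q (neutral π/2, dorsiflexion
decreases q),

    lmt(q) = √(OA² + OB² − 2·OA·OB·cos q),   rmt = OA·OB·sin q / lmt,

and the moment-arm gradient ∂rmt/∂q is analytic (checked against finite
differences in tests). The Hill-type unit is a contractile element and
parallel passive element in series with a nonlinear-spring tendon at
pennation angle φ (constant width: lm sin φ = l₀ sin φ₀):

    Fmt = (Fce + Fpe) cos φ = Ft
    Fce = f(l) f(v) Fmx a,     Fpe = fp(l) Fmx
    f(l)  = sin(−1.317 l² − 0.403 l + 2.454)  (radians; clamped ≥ 0)
    f(v)  = 0.3(v+1)/(−v+0.3)            v < 0
          = (2.34 v + 0.039)/(1.3 v + 0.039)  v > 0   (f(0) = 1)
    fp(l) = 0.129 (e^{4.525(l−1)} − 1)   (clamped ≥ 0)
    Ft    = 0                    ε ≤ 0
          = 1480.3 Fmx ε²        0 < ε < 0.0127
          = (37.5 ε − 0.2375) Fmx  ε ≥ 0.0127,     ε = (lt − lst)/lst

with l = lm/lm0, lm0 = l₀(λ(1−a)+1), λ = 0.15, and vmax = 10 l₀/s.
Shortening is negative v (the lower force-velocity branch vanishes at
v = −1).

Fiber dynamics invert the force balance: given (a, q), the tendon force
fixes the required f(v); its exact algebraic inverse gives v and
d lm/dt = v·vmax. Numerical guards, all applied only inside the
inversion: activation floor a_min = 0.01, force-length floor 1e-3, and
a cap f(v) ≤ 1.78 just below the lengthening asymptote (1.8). The
floor gives the resting muscle a small tonus (≈0.35 N·m at neutral for
the default subject) — the price of a well-conditioned inversion; the
virtual subject's internal model accounts for it (§5).

Integration: `simulate_muscle` uses adaptive Runge–Kutta (scipy RK45,
rtol 1e-6, atol 1e-9 on lm) — the same adaptive RK4(5) family as the
classical Runge–Kutta–Fehlberg scheme — or a per-sample quasi-static
equilibrium solve (warm-started Newton + brentq), valid because the
2 Hz envelope varies far more slowly than the ~30 ms fiber time
constant. Inside the 1 kHz closed loop the fiber is advanced by RK4
with substeps chosen from a probed local Lipschitz estimate (≤ 40
substeps; the balance stiffens when the tendon is taut at low
activation). Initial fiber length is the rigid-tendon estimate
lm = (lmt − lst)/cos φ₀ projected into the pennation domain, or the
isometric equilibrium when a trial starts from rest. Joint torque is
Mp = rmt·Fmt.

## 3. Joint stiffness

    Km  = γ Fm / lm0,  γ = 23.4        (fiber, force-proportional)
    Kt  = dFt/dlt                       (analytic tendon slope)
    Kmt = Km Kt / (Km + Kt)             (series)
    Kj  = Kmt rmt² + (∂rmt/∂q) Fmt      (joint level)

`lm0` in Km is read as the activation-shifted optimal length at the
*current* activation (switch `lm0_mode` also offers plain l₀; the
phrase "optimal length at maximum activation" is ambiguous against the
activation-shift relation that reuses the symbol). Kt is
right-continuous at both breakpoints, keeping it non-decreasing. Kj is
floored at 0 before gain adaptation; the geometric term can be negative
in principle. For the default subject, Kj spans roughly 4–100 N·m/rad
between rest and 35% MVC — the experimentally reported range.

## 4. Calibration

(A, lst, Fmx) are refit per subject by minimizing the mean squared
torque error Er = (1/N) Σ (Mp − Mm)², pooled over all MVC trials
(single global N), with Nelder–Mead. Defaults: bounds A ∈ [0, 0.35]
(solvability, see §1), lst within 0.5–1.5× the subject default, Fmx ∈
[100, 3000] N; lst and Fmx searched on a log scale; trials trimmed to
the central 3 s plateau of the 5 s trial; fit on a 100 Hz grid (the
envelope is 2 Hz band-limited). The u(t) series is precomputed once per
trial — it does not depend on the fitted parameters. The default
optimization is two-stage: the quasi-static forward converges first
(pinning lst and Fmx), then the fiber-ODE forward refines from a tight
simplex — the ramp transients it reproduces carry most of the
information about A. The refinement objective is nearly flat along A,
so convergence is declared on improvement over the converged coarse
stage rather than on the simplex spread. On noiseless synthetic MVC
trials the fit recovers all three parameters to better than 0.3% from
a ±20%-perturbed start, and with 5% additive torque noise the bias
stays below 1% (tests).

## 5. The closed-loop simulator

The simulator replaces hardware and subject in three protocols. Angles
inside it are dorsiflexion-positive deviations θ from neutral
(q = π/2 − θ).

**Synthetic EMG.** A unit-RMS 20–450 Hz Gaussian carrier is
amplitude-modulated by the activation profile plus a noise floor
(0.5% MVC), scaled to 0.5 mV RMS at full activation. Two imperfections
of real surface EMG are modelled: slow multiplicative amplitude
variability (CV 15%, < 3 Hz — amplitude estimates of real sEMG
fluctuate 10–25% at constant effort) and antagonist crosstalk (10% of
the plantarflexors' normalized activity leaks into the TA channel).
Identical seeds give bit-identical signals.

**Plant.** Footplate + limb as inertia 0.01 kg·m², viscous damping
0.1 N·m·s/rad and passive stiffness 10 N·m/rad about neutral,
integrated semi-implicitly at 1 kHz. The stiffness sets the task's
torque scale: ~4.4 N·m at the ±25° extremes, matching the
interaction-torque scale of the physical device and putting peak TA
drive near 12% MVC — comfortably above the EMG noise floor. The limb
is treated as massless on the sensor's human side, so the sensed
interaction torque equals the torque the human applies to the device;
with no assist it is exactly the human torque.

**Virtual subject.** The subject is modelled as a practised tracker:

* *Feedforward*: the plant torque demanded by the target (including
  the TA's own resting torque), evaluated 0.11 s ahead — anticipation
  of the subject's own neuromuscular latency, set at the value that
  minimizes their unassisted tracking error. A proportional-only
  intent law was rejected: with the ~200 ms neuromuscular loop delay it
  is unstable at any gain accurate enough for the task (loop gain
  g·35 N·m per unit activation against a 10 N·m/rad plant crosses
  −180° near 8 rad/s with |L| ≫ 1).
* *Motor noise*: slow (≤1 Hz) multiplicative noise, SD 10%, on the
  feedforward — signal-dependent motor noise makes execution imperfect
  and gives the ~1.4° baseline tracking error.
* *Feedback*: weak proportional correction (1 N·m/rad on the 5 Hz
  filtered error) — kept small for stability under the loop delay.
* *Effort adaptation ("slacking")*: the low-pass filtered (0.5 Hz)
  felt assist, scaled by 1.25, reduces the *amplitude* of the
  dorsiflexion feedforward. Assisted subjects withdraw somewhat more
  effort than the assist replaces, trading accuracy for comfort — the
  classic motivation for assist-as-needed control.
* *Plantarflexion*: negative torque demands go to a direct torque
  channel with the same 80 ms delay and a 3 Hz excitation lag (the
  plantarflexors are recorded but not modelled by the EDMM; the assist
  is dorsiflexion-only). Its strength is normalized by a 40 N·m
  plantarflexor MVC for the crosstalk model.

The TA command passes through the same delay + recursion + activation
curve as the estimator assumes, with the subject's learned inverse
(activation-curve inverse and isometric torque slope) mapping desired
torque to neural drive.

**Controller.** The admittance filter qi = q + Mp_est/(k + b s), k = 2,
b = 0.1, m = 0, is discretized exactly (zero-order hold:
x⁺ = e^{−k dt/b} x + (1 − e^{−k dt/b}) Mp/k), giving DC gain 1/k and
time constant 50 ms, BIBO-stable for every step size. The inner PD law
is τ = K Δq + 0.2 K Δq̇ with Δq = qi − q and Δq̇ from a 10 Hz-smoothed
first difference; assistance is gated to dorsiflexion (Δq > 0). Fixed
gains K ∈ {0, 0.1, 0.3, 0.5} N·m/rad give the non-adaptive scheme; the
adaptive scheme maps the estimated joint stiffness affinely from
[Kj_min, Kj_max] — the extremes observed during an assistance-free
trial's analysis window — onto [0, 0.5], clamped. With the stiffness
input pinned at Kj_max the adaptive scheme is bit-identical to the
fixed scheme at K = 0.5 (tested).

**Protocols.** MVC trials: 5 s at a fixed angle, raised-cosine effort
ramp (0.5–2.0 s) to full drive; measured torque from the subject's own
forward model; an `ideal` mode stores the drive as the envelope for
noise-free calibration checks. Perturbation trials: motor PD (P = 5,
D = 0.5) tracks 0.5°/3 Hz for 30 s while the subject holds an
envelope level (0–35% MVC, mapped through the activation curve to true
activation); the plant reacts through the locally linearized subject
stiffness (a 0.5° perturbation stays linear) plus the tonic torque;
measured stiffness is the angle coefficient of a least-squares
regression of sensed torque on [angle, angular velocity, 1], skipping
the first 2 s. Tracking trials: seeded 3–5 s rest, then 11 cycles of a
±25°, 10 s-period sinusoid at 1 kHz.

## 6. Indicators and analysis

Indicators are evaluated on the analysis window — samples whose
*target* lies within ±20° of neutral (controller-independent cropping;
near the extremes the real device's static friction corrupts the
data). Contiguous segments are preserved, and the jerk value (RMS of
the third derivative of the actual angle) is computed per segment after
a 20 Hz zero-phase pre-filter — raw triple differencing at 1 kHz
amplifies quantization noise — with cascaded central differences and
0.1 s edge trimming, then pooled by sum of squares. Position error,
interaction torque and TA envelope RMS are plain RMS values. Jerk is
reported in rad/s³ and not compared against published magnitudes,
whose units are not stated. `compare_controllers` runs each
configuration over each seed (10 seeds by default stand in for the
8 subjects × 2 trials of the human study) and tabulates mean (sd).

## 7. What the simulation shows — and what it cannot

On the default virtual subject (10 seeds × 11 cycles per gain level):
interaction torque and TA envelope RMS fall strictly and monotonically
as K rises 0 → 0.5 (load sharing plus slacking), position error rises
strictly over 0.1 → 0.3 → 0.5, jerk rises at high K (the assist
amplifies EMG-estimate variability), and the adaptive scheme lands
between the fixed extremes on every indicator. One qualitative feature
of the human study is *not* reproduced: there, position error already
worsened at K = 0.1, while here the very first gain step improves it
slightly (≈0.7%). The cause is structural: an idealized assist — a
clean, low-pass-filtered echo of the subject's own torque delivered
through a noiseless, frictionless actuator — mildly smooths the
movement reversals at low gain (the error PSD drops ~30% in the
0.2–0.5 Hz band, and jerk also dips at K = 0.1). Degradation at low
gain evidently requires actuator and drive-train roughness, which this
package deliberately does not model (no motor/servo dynamics, no
friction). The effect is robust to the slacking gain and structure,
the adaptation bandwidth, the subject's feedback gain, the
plantarflexor latency, and the EMG imperfection levels.

Human-subject magnitudes are not reproduced and not claimed: absolute
torques, EMG levels and errors depend on the plant scale and subject
strength chosen here. Passing tests establish internal consistency
(estimator vs ground truth, regression vs programmed stiffness,
calibration recovery) and trend directions, not fidelity to any
individual human.

## 8. Numerical conventions and edge cases

* Envelope clamped at 0 (filter ringing); u clamped to [0, 1] before
  the activation curve; curve output clamped to [0, 1].
* Tendon curve branch point at ε = 0.0127: the two branches agree to
  1.2e-5 Fmx; stiffness takes the right branch at both breakpoints.
* f(v) inversion: inputs ≤ 0 map to v = −1; at/beyond 1.78 the op-level
  inverse warns and clamps (the in-loop path pre-clamps silently).
* Degenerate inputs raise typed errors: fs ≤ 900 Hz, zero MVC peak,
  all-zero calibration torque, constant stiffness series for gain
  bounds, empty analysis window, plant excursion beyond ±90°.
* Determinism: every stochastic component draws from one
  `numpy.random.Generator` seeded per trial; identical seed and
  configuration give bit-identical trial logs.
* Problem sizes: unit tests use 1–2-cycle tracking trials and 8–10 s
  perturbation trials; the full-length protocols (11 cycles, 30 s) are
  exercised by the trend test and the acceptance script.
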