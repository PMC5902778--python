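"""Synthetic data generation and closed-loop emulation of the three
experimental protocols: MVC calibration trials, sinusoidal-perturbation
stiffness verification, and sinusoidal trajectory tracking under
admittance control.

The simulator stands in for the exoskeleton hardware and the human
subject.  Its pieces:

* :func:`synth_emg` — surface EMG as a 20–450 Hz band-limited Gaussian
  carrier amplitude-modulated by an activation profile plus a small
  noise floor; 1 kHz, seeded, reproducible.
* :class:`VirtualSubject` — a subject parameter set plus an *intent
  model*: an internal-model feedforward drive (the learned torque
  profile of the task, corrupted by slow multiplicative motor noise),
  weak proportional feedback on the tracking error, an assist-aware
  effort reduction (the subject scales back drive by the low-pass
  filtered assist torque they feel), and a direct plantarflexor torque
  channel for the negative half of the task (the plantarflexors are
  recorded but not modelled, matching a dorsiflexion-only assist).
* :class:`AnklePlant` — footplate + limb as inertia, viscous damping
  and passive stiffness about the neutral angle.
* Trial runners for each protocol.  Angles inside the simulator are
  expressed as dorsiflexion-positive deviations ``theta`` from neutral
  (anatomical angle q = pi/2 - theta).

Sign conventions: the TA is a dorsiflexor, so its torque rmt * Fmt is
positive in theta.  The torque sensor sits between the motor and the
footplate with the limb treated as massless, so the sensed interaction
torque equals the torque the human applies to the device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import activation as _act
from ._streaming import DelayLine, NeuralRecursion, OnePole, StreamingSOS
from .controller import ControllerConfig, adapt_gain
from .exceptions import TrialAbortedError
from .musculotendon import (
    _fiber_rhs,
    geometry,
    isometric_state,
    moment_arm_gradient,
    rigid_tendon_initial_lm,
    simulate_muscle,
    tendon_stiffness_scalar,
)
from .stiffness import stiffness_series
from .subject import SubjectParams

__all__ = [
    "EmgModel",
    "IntentModel",
    "VirtualSubject",
    "AnklePlant",
    "TrialLog",
    "PerturbationResult",
    "synth_emg",
    "run_mvc_trial",
    "run_perturbation_trial",
    "run_tracking_trial",
]

#: Mean of |x| for unit-variance Gaussian x: sqrt(2/pi).
_RECT_MEAN = math.sqrt(2.0 / math.pi)


@dataclass
class EmgModel:
    """Surface-EMG synthesis constants.

    ``mvc_volts`` is the carrier RMS at full activation; ``noise_floor``
    the baseline level as a fraction of MVC (quiet-muscle instrument and
    physiological noise).  ``amp_cv`` is slow multiplicative amplitude
    variability (coefficient of variation, bandwidth ``amp_cv_fc``):
    single-channel surface-EMG amplitude estimates fluctuate by
    10-25% even at constant effort, and this variability — amplified by
    any EMG-driven assist — is what makes high fixed assist gains
    rough.
    """

    mvc_volts: float = 5e-4
    noise_floor: float = 0.005
    amp_cv: float = 0.15
    amp_cv_fc: float = 3.0
    #: Fraction of the plantarflexors' normalized activity picked up by
    #: the TA electrodes (surface-EMG crosstalk between adjacent shank
    #: muscles; it inflates the TA envelope whenever the antagonists
    #: work, e.g. during the plantarflexion half of the task).
    crosstalk: float = 0.10

    def analytic_mvc_peak(self) -> float:
        """Expected processed-envelope amplitude at full activation."""
        return self.mvc_volts * (1.0 + self.noise_floor) * _RECT_MEAN


@dataclass
class IntentModel:
    """Virtual subject's motor-control law for the tracking task.

    The subject knows the task (a slow sinusoid) well after practice
    trials, so the drive is dominated by an internal-model feedforward
    equal to the plant torque required by the target, scaled to
    activation units.  Slow multiplicative motor noise (sd
    ``motor_noise_sd``, bandwidth ``noise_fc``) makes execution
    imperfect; weak proportional feedback ``fb_gain_nm`` (N*m/rad,
    small because the neuromuscular loop delay destabilizes high gains)
    corrects drift; and the drive is reduced by the low-pass filtered
    assist torque felt from the robot (effort minimization,
    ``adapt_fc``).  Negative torque demands go to a direct
    plantarflexor torque channel with a short excitation lag.
    """

    fb_gain_nm: float = 1.0
    motor_noise_sd: float = 0.10
    noise_fc: float = 1.0
    err_fc: float = 5.0
    pf_lag_fc: float = 3.0
    adapt_fc: float = 0.5
    #: Effort-withdrawal gain on the felt assist ("slacking"): assisted
    #: subjects reduce their drive by somewhat more than the assist
    #: replaces, trading tracking accuracy for reduced effort — the
    #: classic motivation for assist-as-needed control.
    slack_gain: float = 1.25
    #: Anticipation of the subject's own neuromuscular latency
    #: (electromechanical delay + excitation dynamics) on the known
    #: target; practised subjects lead a predictable trajectory.
    lead_s: float = 0.11
    #: Plantarflexor MVC torque (N*m), used to express the direct
    #: plantarflexor torque as a normalized activity level (the ankle
    #: plantarflexors are several-fold stronger than the TA).
    pf_mvc_nm: float = 40.0


@dataclass
class VirtualSubject:
    """Ground-truth subject: parameters, intent model and EMG model."""

    params: SubjectParams
    intent: IntentModel = field(default_factory=IntentModel)
    emg: EmgModel = field(default_factory=EmgModel)
    mvc_peak: float | None = None  # volts; analytic default if None

    def mvc_peak_volts(self) -> float:
        return (self.mvc_peak if self.mvc_peak is not None
                else self.emg.analytic_mvc_peak())

    def act_per_nm(self, q: float = math.pi / 2) -> float:
        """Activation per N*m of dorsiflexion torque near rest (the
        subject's learned inverse of their own strength)."""
        _, tq = isometric_state(0.05, q, self.params.hill,
                                self.params.geometry)
        return 0.05 / tq.Mp


@dataclass
class AnklePlant:
    """Footplate + limb about the ankle: inertia, damping, passive spring.

    The passive stiffness (footplate suspension plus the non-TA passive
    tissues about neutral) sets the torque scale of the tracking task;
    the default 10 N*m/rad demands ~4.4 N*m at the 25 deg extremes,
    matching the interaction-torque scale observed on the real device,
    and puts peak TA drive near 12% MVC, well above the EMG noise floor.
    """

    inertia: float = 0.01           # kg m^2
    damping: float = 0.1            # N m s / rad
    passive_stiffness: float = 10.0  # N m / rad

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")


@dataclass
class TrialLog:
    """Synchronized time series from one simulated trial.

    Angles are dorsiflexion-positive deviations from neutral (rad).
    ``torque_interaction`` is the torque sensed between motor and
    footplate (= the torque the human applies to the device).
    """

    fs: float
    t: np.ndarray
    target: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    qi: np.ndarray
    torque_human: np.ndarray
    torque_est: np.ndarray
    torque_assist: np.ndarray
    torque_interaction: np.ndarray
    emg: np.ndarray
    envelope: np.ndarray
    kj: np.ndarray
    gain_k: np.ndarray
    meta: dict = field(default_factory=dict)
    segments: list | None = None


@dataclass
class PerturbationResult:
    """Outcome of one stiffness-verification trial."""

    measured_K: float
    estimated_K: float | None
    theta: np.ndarray
    torque: np.ndarray
    fs: float


def _band_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 20-450 Hz band-limited Gaussian carrier."""
    x = rng.standard_normal(n)
    x = signal.sosfilt(_act.band_sos(fs), x)
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def _amplitude_jitter(n: int, fs: float, rng: np.random.Generator,
                      emg: EmgModel) -> np.ndarray:
    """Slow multiplicative amplitude variability, unit mean."""
    if emg.amp_cv <= 0:
        return np.ones(n)
    sos = signal.butter(2, emg.amp_cv_fc, fs=fs, output="sos")
    xi = signal.sosfilt(sos, rng.standard_normal(n))
    sd = float(np.std(xi[min(n - 1, int(fs)):])) or 1.0
    xi = emg.amp_cv * xi / sd
    return np.clip(1.0 + xi, 0.1, None)


def synth_emg(activation_profile, fs: float = 1000.0,
              seed: int | np.random.Generator = 0,
              emg: EmgModel | None = None) -> _act.RawEmg:
    """Synthesize raw surface EMG for a given activation profile.

    The output is a zero-mean band-limited (20-450 Hz) Gaussian carrier
    amplitude-modulated by ``activation_profile + noise_floor`` and
    scaled to ``mvc_volts`` RMS at full activation.  Identical seeds
    give bit-identical output.
    """
    emg = emg or EmgModel()
    prof = np.asarray(activation_profile, dtype=float)
    if np.any(prof < -1e-12) or np.any(prof > 1.0 + 1e-12):
        raise ValueError("activation profile must lie in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    carrier = _band_carrier(len(prof), fs, rng)
    jitter = _amplitude_jitter(len(prof), fs, rng, emg)
    samples = emg.mvc_volts * (prof * jitter + emg.noise_floor) * carrier
    return _act.RawEmg(samples=samples, fs=fs,
                       mvc_peak=emg.analytic_mvc_peak())


# ---------------------------------------------------------------------------
# MVC calibration trials
# ---------------------------------------------------------------------------

def mvc_activation_profile(duration: float, fs: float,
                           ramp: tuple[float, float] = (0.5, 2.0)) -> np.ndarray:
    """Raised-cosine ramp from rest to full effort, then hold."""
    t = np.arange(int(round(duration * fs))) / fs
    t0, t1 = ramp
    prof = np.where(
        t < t0, 0.0,
        np.where(t > t1, 1.0,
                 0.5 * (1.0 - np.cos(math.pi * (t - t0) / (t1 - t0)))),
    )
    return prof


def run_mvc_trial(subject: VirtualSubject, angle_rad: float,
                  seed: int = 0, duration: float = 5.0, fs: float = 1000.0,
                  ideal: bool = False):
    """Simulate one MVC trial at a fixed anatomical ankle angle.

    The subject's neural drive ramps to full effort (raised cosine,
    0.5-2.0 s) and holds for the rest of the 5 s trial.  The measured
    torque is produced by the subject's own forward model: drive ->
    electromechanical delay -> activation recursion -> activation curve
    -> fiber dynamics -> rmt * Fmt at the fixed angle.  ``ideal=True``
    stores the drive itself as a normalized envelope (no EMG carrier),
    for noise-free calibration checks; otherwise raw synthetic EMG is
    stored and the calibration pipeline must process it.
    """
    from .calibration import MvcTrial  # avoid import cycle at module load

    p, g = subject.params.hill, subject.params.geometry
    lmt, _ = geometry(angle_rad, g)  # validates the angle / geometry
    prof = mvc_activation_profile(duration, fs)
    env = _act.EnvelopeSignal(e=prof, fs=fs)
    u = np.clip(_act.neural_activation(env), 0.0, 1.0)
    a_true = subject.params.curve(u)
    q_series = np.full(len(prof), angle_rad)
    traj = simulate_muscle(a_true, q_series, fs, p, g,
                           lm_init="equilibrium")
    if ideal:
        return MvcTrial(angle_rad=angle_rad, emg=None, envelope=prof,
                        torque=traj.Mp, fs=fs)
    raw = synth_emg(prof, fs, seed=seed, emg=subject.emg)
    return MvcTrial(angle_rad=angle_rad, emg=raw, envelope=None,
                    torque=traj.Mp, fs=fs)


# ---------------------------------------------------------------------------
# Perturbation stiffness verification
# ---------------------------------------------------------------------------

def measure_stiffness_regression(theta: np.ndarray, torque: np.ndarray,
                                 fs: float, skip_s: float = 2.0) -> float:
    """Stiffness by multiple linear regression of torque on angle and
    angular velocity (plus intercept); returns the angle coefficient."""
    i0 = int(skip_s * fs)
    th = np.asarray(theta, dtype=float)[i0:]
    tq = np.asarray(torque, dtype=float)[i0:]
    thd = np.gradient(th) * fs
    X = np.column_stack([th, thd, np.ones_like(th)])
    coef, *_ = np.linalg.lstsq(X, tq, rcond=None)
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("rank-deficient stiffness regression")
    return float(coef[0])


def run_perturbation_trial(subject: VirtualSubject | None = None,
                           activation_level: float = 0.0,
                           plant: AnklePlant | None = None,
                           programmed_stiffness: float | None = None,
                           seed: int = 0, duration: float = 30.0,
                           fs: float = 1000.0,
                           amplitude_rad: float = math.radians(0.5),
                           freq_hz: float = 3.0,
                           P: float = 5.0, D: float = 0.5,
                           estimate: bool = True) -> PerturbationResult:
    """Simulate one stiffness-verification trial.

    The motor, under PD position control (P = 5, D = 0.5), tracks a
    0.5 deg / 3 Hz sinusoid about neutral while the subject holds a
    constant TA activation level.  The ankle reacts through the torque
    sensor with its (locally linearized) stiffness, damping, and tonic
    muscle torque; the measured stiffness is recovered by regressing
    the sensed torque on angle and angular velocity, and compared with
    the mean model estimate driven by the trial's synthetic EMG.

    ``programmed_stiffness`` replaces the subject-derived stiffness
    with a known linear value (no subject, no tonic torque) — the
    regression-recovery oracle mode.
    """
    plant = plant or AnklePlant()
    if programmed_stiffness is not None:
        k_prog = float(programmed_stiffness)
        tonic = 0.0
    else:
        if subject is None:
            raise ValueError("need a subject or a programmed stiffness")
        p, g = subject.params.hill, subject.params.geometry
        # The held level is an EMG-envelope level (fraction of MVC); the
        # muscle activation behind it goes through the activation curve,
        # exactly as the estimator's pipeline will map it.
        a_true = subject.params.curve(float(activation_level))
        st, tq = isometric_state(a_true, math.pi / 2, p, g)
        traj_like = _single_state_kj(st, tq, a_true, subject.params)
        k_prog = plant.passive_stiffness + traj_like
        tonic = tq.Mp

    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    theta_d = amplitude_rad * np.sin(2.0 * math.pi * freq_hz * t)
    theta_d_dot = (amplitude_rad * 2.0 * math.pi * freq_hz
                   * np.cos(2.0 * math.pi * freq_hz * t))

    theta = 0.0
    theta_dot = 0.0
    inertia, b_ankle = plant.inertia, plant.damping
    th_log = np.empty(n)
    tq_log = np.empty(n)
    for i in range(n):
        tau_s = k_prog * theta + b_ankle * theta_dot + tonic
        tau_m = P * (theta_d[i] - theta) + D * (theta_d_dot[i] - theta_dot)
        theta_ddot = (tau_m - tau_s) / inertia
        theta_dot += theta_ddot * dt
        theta += theta_dot * dt
        th_log[i] = theta
        tq_log[i] = tau_s

    measured_K = measure_stiffness_regression(th_log, tq_log, fs)

    estimated_K = None
    if estimate and subject is not None:
        estimated_K = _estimate_mean_kj(subject, activation_level, th_log,
                                        fs, seed)
    return PerturbationResult(measured_K=measured_K, estimated_K=estimated_K,
                              theta=th_log, torque=tq_log, fs=fs)


def _single_state_kj(st, tq, a: float, params: SubjectParams) -> float:
    """Joint stiffness of a single isometric state (ground truth)."""
    from .stiffness import (joint_stiffness, muscle_stiffness,
                            series_stiffness, tendon_stiffness)

    p, g = params.hill, params.geometry
    lm0 = p.l0 * (p.lam * (1.0 - a) + 1.0)
    Km = muscle_stiffness(st.Fm, lm0, params.gamma)
    Kt = tendon_stiffness(st.lt, p)
    Kmt = series_stiffness(Km, Kt)
    drmt = moment_arm_gradient(tq.q, g)
    return joint_stiffness(Kmt, tq.rmt, drmt, st.Fmt, floor=True)


def _estimate_mean_kj(subject: VirtualSubject, level: float,
                      theta: np.ndarray, fs: float, seed: int,
                      skip_s: float = 2.0) -> float:
    """EMG-driven joint-stiffness estimate averaged over the trial."""
    prof = np.full(len(theta), float(level))
    raw = synth_emg(prof, fs, seed=seed, emg=subject.emg)
    raw.mvc_peak = subject.mvc_peak_volts()
    env = _act.compute_envelope(raw)
    u = np.clip(_act.neural_activation(env), 0.0, 1.0)
    a_est = subject.params.curve(u)
    q_series = math.pi / 2 - theta
    traj = simulate_muscle(a_est, q_series, fs, subject.params.hill,
                           subject.params.geometry, lm_init="equilibrium")
    stiff = stiffness_series(traj, a_est, q_series, subject.params.hill,
                             subject.params.geometry,
                             gamma=subject.params.gamma)
    i0 = int(skip_s * fs)
    return float(np.mean(stiff["Kj"][i0:]))


# ---------------------------------------------------------------------------
# Closed-loop sinusoidal tracking
# ---------------------------------------------------------------------------

def target_trajectory(n: int, fs: float, delay_s: float,
                      amplitude_rad: float, period_s: float) -> tuple:
    """Target angle/velocity/acceleration: rest, then a sinusoid."""
    t = np.arange(n) / fs
    w = 2.0 * math.pi / period_s
    tt = t - delay_s
    active = tt >= 0.0
    th = np.where(active, amplitude_rad * np.sin(w * tt), 0.0)
    thd = np.where(active, amplitude_rad * w * np.cos(w * tt), 0.0)
    thdd = np.where(active, -amplitude_rad * w * w * np.sin(w * tt), 0.0)
    return th, thd, thdd


def run_tracking_trial(subject: VirtualSubject,
                       controller: ControllerConfig,
                       plant: AnklePlant | None = None,
                       seed: int = 0,
                       n_cycles: int = 11,
                       period_s: float = 10.0,
                       amplitude_rad: float = math.radians(25.0),
                       fs: float = 1000.0) -> TrialLog:
    """Run one closed-loop sinusoidal tracking trial.

    Loop at ``fs`` (default 1 kHz): subject intent -> synthetic EMG ->
    EMG-driven model (torque and stiffness estimates) -> admittance
    filter -> gain law -> PD assist -> plant.  The target starts after
    a seeded random delay of 3-5 s and runs ``n_cycles`` sinusoid
    cycles (the full protocol is 11 cycles of a 10 s period).
    Identical seed and configuration give a bit-identical log.
    """
    plant = plant or AnklePlant()
    params = subject.params
    p_hill, g_geom = params.hill, params.geometry
    curve = params.curve
    intent = subject.intent
    dt = 1.0 / fs
    rng = np.random.default_rng(seed)

    delay_s = float(rng.uniform(3.0, 5.0))
    n = int(round((delay_s + n_cycles * period_s) * fs))
    theta_d, theta_d_dot, theta_d_ddot = target_trajectory(
        n, fs, delay_s, amplitude_rad, period_s)
    # Led copies of the target drive the feedforward (anticipation of
    # the subject's own latency); the displayed target stays theta_d.
    theta_f, theta_f_dot, theta_f_ddot = target_trajectory(
        n, fs, delay_s - intent.lead_s, amplitude_rad, period_s)

    # Subject-side precomputations -----------------------------------
    inertia, b_v, k_p = plant.inertia, plant.damping, plant.passive_stiffness
    # Internal-model feedforward: plant torque demanded by the target,
    # minus the TA's own resting torque (passive stretch plus the small
    # tonus at the resting activation floor — the subject has learned
    # both), in the dorsiflexion-positive convention.
    th_grid = np.linspace(-1.2 * amplitude_rad - 0.05,
                          1.2 * amplitude_rad + 0.05, 41)
    tau_pass_grid = np.array([
        isometric_state(p_hill.a_min, math.pi / 2 - th, p_hill, g_geom)[1].Mp
        for th in th_grid
    ])
    tau_pass_d = np.interp(theta_f, th_grid, tau_pass_grid)
    tau_req = (inertia * theta_f_ddot + b_v * theta_f_dot + k_p * theta_f
               - tau_pass_d)
    carrier = _band_carrier(n, fs, rng)
    emg_jitter = _amplitude_jitter(n, fs, rng, subject.emg)
    # Slow multiplicative motor noise, unit sd after scaling.
    white = rng.standard_normal(n)
    sos_noise = signal.butter(2, intent.noise_fc, fs=fs, output="sos")
    eta = signal.sosfilt(sos_noise, white)
    eta_std = float(np.std(eta[int(2.0 * fs):])) or 1.0
    eta = intent.motor_noise_sd * eta / eta_std

    act_per_nm = subject.act_per_nm()
    tau_norm = max(float(np.max(np.abs(tau_req))), 1e-6)
    mvc_peak = subject.mvc_peak_volts()
    mvc_volts = subject.emg.mvc_volts
    noise_floor = subject.emg.noise_floor

    # Streaming state -------------------------------------------------
    d_samples = int(round(0.080 * fs))
    env_band = StreamingSOS(_act.band_sos(fs))
    env_low = StreamingSOS(_act.low_sos(fs))
    delay_est = DelayLine(d_samples)
    rec_est = NeuralRecursion()
    delay_true = DelayLine(d_samples)
    rec_true = NeuralRecursion()
    delay_pf = DelayLine(d_samples)  # the antagonists share the same EMD
    err_lp = OnePole(intent.err_fc, dt)
    pf_lp = OnePole(intent.pf_lag_fc, dt)
    adapt_lp = OnePole(intent.adapt_fc, dt)
    dqdot_lp = OnePole(controller.deriv_smooth_hz, dt)

    k_adm, b_adm = controller.k_adm, controller.b_adm
    b_ratio = controller.b_ratio
    E_adm = math.exp(-k_adm * dt / b_adm) if b_adm > 0 else 0.0
    sched = controller.schedule()
    aacs = controller.mode == "aacs"
    if aacs and controller.kj_override is None and (
            sched.Kjmin is None or sched.Kjmax is None):
        raise ValueError("AACS requires kj_min/kj_max (assist-free trial)")

    # Muscle states: the subject's true fiber and the estimator's copy.
    lmt0, _ = geometry(math.pi / 2, g_geom)
    lm_true = rigid_tendon_initial_lm(lmt0, p_hill)
    lm_est = lm_true
    width = p_hill.width
    vmax = p_hill.vmax

    def fiber_step(lm: float, a: float, lmt: float) -> float:
        """One dt of fiber dynamics: RK4 with substeps scaled to the
        local rate.

        The force-balance ODE stiffens when the tendon is taut and
        activation is low; a probe evaluation estimates the local
        Lipschitz constant and the step is subdivided so each RK4
        substep sees lambda*h <~ 1.
        """
        d1, _aux = _fiber_rhs(lm, a, lmt, p_hill)
        lam_loc = abs(_fiber_rhs(lm + 1e-6, a, lmt, p_hill)[0] - d1) / 1e-6
        nsub = min(max(1, int(lam_loc * dt) + 1), 40)
        h = dt / nsub
        y = lm
        for _ in range(nsub):
            k1, _x = _fiber_rhs(y, a, lmt, p_hill)
            k2, _x = _fiber_rhs(y + 0.5 * h * k1, a, lmt, p_hill)
            k3, _x = _fiber_rhs(y + 0.5 * h * k2, a, lmt, p_hill)
            k4, _x = _fiber_rhs(y + h * k3, a, lmt, p_hill)
            y += h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if y < width * (1.0 + 1e-9):
                y = width * (1.0 + 1e-9)
        return y

    # Logs -------------------------------------------------------------
    L = {name: np.empty(n) for name in
         ("q", "qdot", "qi", "torque_human", "torque_est", "torque_assist",
          "torque_interaction", "emg", "envelope", "kj", "gain_k")}

    theta = 0.0
    theta_dot = 0.0
    x_adm = 0.0
    x_prev = 0.0
    tau_a = 0.0
    lam_g, gamma = p_hill.lam, params.gamma
    l0 = p_hill.l0

    for i in range(n):
        # --- subject intent -----------------------------------------
        err = theta_d[i] - theta
        err_f = err_lp.step(err)
        # Slacking: the felt assist lowers the *amplitude* of the
        # dorsiflexion feedforward (a slowly adapting gain), rather than
        # being subtracted waveform-for-waveform — subjects scale back
        # overall effort, they do not mirror the robot's torque shape.
        slack = adapt_lp.step(intent.slack_gain * tau_a / tau_norm)
        if slack > 0.9:
            slack = 0.9
        elif slack < 0.0:
            slack = 0.0
        ff = tau_req[i]
        if ff > 0.0:
            ff *= 1.0 - slack
        tau_des = ff * (1.0 + eta[i]) + intent.fb_gain_nm * err_f
        if tau_des > 0.0:
            a_des = tau_des * act_per_nm
            if a_des > 1.0:
                a_des = 1.0
            # neural command: the subject's learned inverse includes the
            # activation nonlinearity
            act_cmd = curve.inverse(a_des)
            tau_pf_cmd = 0.0
        else:
            act_cmd = 0.0
            tau_pf_cmd = tau_des
        tau_pf = pf_lp.step(delay_pf.step(tau_pf_cmd))

        # --- true neuromuscular path --------------------------------
        u_true = rec_true.step(delay_true.step(act_cmd))
        if u_true < 0.0:
            u_true = 0.0
        elif u_true > 1.0:
            u_true = 1.0
        if u_true < curve.u0:
            a_true = curve.b * math.log(curve.c * u_true + 1.0)
        else:
            a_true = curve.m * u_true + curve.n
        if a_true < 0.0:
            a_true = 0.0
        elif a_true > 1.0:
            a_true = 1.0
        q_anat = math.pi / 2 - theta
        lmt = math.sqrt(g_geom.OA**2 + g_geom.OB**2
                        - 2.0 * g_geom.OA * g_geom.OB * math.cos(q_anat))
        rmt = g_geom.OA * g_geom.OB * math.sin(q_anat) / lmt
        lm_true = fiber_step(lm_true, a_true, lmt)
        _, aux_t = _fiber_rhs(lm_true, a_true, lmt, p_hill)
        Ft_true = aux_t[3]
        Mp_true = rmt * Ft_true

        # --- measured EMG and the model estimate --------------------
        xtalk = subject.emg.crosstalk * abs(tau_pf) / intent.pf_mvc_nm
        emg_i = mvc_volts * ((act_cmd + xtalk) * emg_jitter[i]
                             + noise_floor) * carrier[i]
        env_i = env_low.step(abs(env_band.step(emg_i)))
        if env_i < 0.0:
            env_i = 0.0
        e_norm = env_i / mvc_peak
        u_est = rec_est.step(delay_est.step(e_norm))
        if u_est < 0.0:
            u_est = 0.0
        elif u_est > 1.0:
            u_est = 1.0
        if u_est < curve.u0:
            a_est = curve.b * math.log(curve.c * u_est + 1.0)
        else:
            a_est = curve.m * u_est + curve.n
        if a_est < 0.0:
            a_est = 0.0
        elif a_est > 1.0:
            a_est = 1.0
        lm_est = fiber_step(lm_est, a_est, lmt)
        _, aux_e = _fiber_rhs(lm_est, a_est, lmt, p_hill)
        lt_e, cosphi_e, _l_e, Ft_est, _Fpe_e, _fv_e, _v_e = aux_e
        Mp_est = rmt * Ft_est

        # stiffness estimate
        lm0_e = l0 * (lam_g * (1.0 - a_est) + 1.0)
        Fm_e = Ft_est / cosphi_e
        Km = gamma * Fm_e / lm0_e
        Kt = tendon_stiffness_scalar(lt_e, p_hill)
        s = Km + Kt
        Kmt = Km * Kt / s if s > 0.0 else 0.0
        drmt = (g_geom.OA * g_geom.OB
                * (math.cos(q_anat) * lmt - math.sin(q_anat) * rmt) / lmt**2)
        Kj = Kmt * rmt * rmt + drmt * Ft_est
        if Kj < 0.0:
            Kj = 0.0

        # --- admittance filter and gain law -------------------------
        x_adm = E_adm * x_adm + (1.0 - E_adm) * Mp_est / k_adm
        qi = theta + x_adm
        if aacs:
            kj_in = (controller.kj_override
                     if controller.kj_override is not None else Kj)
            K = adapt_gain(kj_in, sched)
        else:
            K = controller.K_fixed
        dq = x_adm
        dqdot = dqdot_lp.step((x_adm - x_prev) / dt)
        x_prev = x_adm
        if dq > 0.0:  # dorsiflexion-only assistance gate
            tau_a = K * dq + b_ratio * K * dqdot
        else:
            tau_a = 0.0

        # --- plant (device; limb massless, human pushes through the
        #     sensor) -------------------------------------------------
        tau_human = Mp_true + tau_pf
        theta_ddot = (tau_a + tau_human - b_v * theta_dot
                      - k_p * theta) / inertia
        theta_dot += theta_ddot * dt
        theta += theta_dot * dt
        if abs(theta) > math.pi / 2:
            raise TrialAbortedError(
                f"plant left its envelope (|theta| > 90 deg) at t={i*dt:.2f}s"
            )

        L["q"][i] = theta
        L["qdot"][i] = theta_dot
        L["qi"][i] = qi
        L["torque_human"][i] = tau_human
        L["torque_est"][i] = Mp_est
        L["torque_assist"][i] = tau_a
        L["torque_interaction"][i] = tau_human
        L["emg"][i] = emg_i
        L["envelope"][i] = e_norm
        L["kj"][i] = Kj
        L["gain_k"][i] = K

    t = np.arange(n) / fs
    meta = {
        "seed": seed, "delay_s": delay_s, "n_cycles": n_cycles,
        "period_s": period_s, "amplitude_rad": amplitude_rad,
        "mode": controller.mode, "K_fixed": controller.K_fixed,
        "kj_min": controller.kj_min, "kj_max": controller.kj_max,
        "kj_override": controller.kj_override,
    }
    return TrialLog(fs=fs, t=t, target=theta_d, q=L["q"], qdot=L["qdot"],
                    qi=L["qi"], torque_human=L["torque_human"],
                    torque_est=L["torque_est"],
                    torque_assist=L["torque_assist"],
                    torque_interaction=L["torque_interaction"],
                    emg=L["emg"], envelope=L["envelope"], kj=L["kj"],
                    gain_k=L["gain_k"], meta=meta)
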