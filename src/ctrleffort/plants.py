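"""Closed-loop surrogate plants: a muscle-driven and a torque-driven 1-DOF limb.

Two movement tasks are bundled, each in a biological (antagonistic
muscle-pair) and a technical (ideal torque actuator) version:

* ``pointing`` — drive a single-joint arm from a start angle to a goal
  angle within the movement time and hold it there.  The muscle version is
  stimulated by a delayed proprioceptive feedback law; the torque version
  uses an ideal PD controller with no delay.
* ``periodic`` — track a sinusoidal limb oscillation (a walking-like
  rhythmic task).  Forward progress and an upright-height analogue are
  derived from the joint state, so a speed band and a height floor can
  abort the run the way a falling walker ends a trial.

The muscle model is a deliberately small Hill-type surrogate: first-order
activation dynamics, a bell-shaped force-length curve, a Hill hyperbola in
shortening with a saturating eccentric branch, and a passive elastic term.
Both muscles operate on the ascending limb of the force-length curve so
that co-contraction yields intrinsic joint stiffness, and the
force-velocity slope yields intrinsic damping — the zero-delay "preflex"
response that makes the muscle plant tolerant of coarse control signals.

Integration is fixed-step RK4 (default 1 ms) so that runs are bit-exactly
reproducible and discretization timing is deterministic.  The controller
runs on a 10 ms tick; sensor readings reach it through a configurable
delay line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .codec import DiscretizedTrace, SignalSpec, quantize_amplitude

__all__ = [
    "MuscleParams",
    "ArmParams",
    "PointingTask",
    "PeriodicTask",
    "MuscleController",
    "TorqueController",
    "PlantConfig",
    "SimResult",
    "DelayLine",
    "PeriodicAbortMonitor",
    "muscle_force",
    "muscle_actuator_step",
    "pd_torque_controller",
    "simulate",
    "extract_reference_ranges",
    "default_pointing_config",
    "default_periodic_config",
    "build_periodic_torque_config",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class MuscleParams:
    """Hill-type surrogate muscle.

    ``F_max`` [N] peak isometric force; ``l_opt`` [m] optimal fiber length;
    ``w`` width of the bell force-length curve (fraction of ``l_opt``);
    ``v_max`` [m/s] maximal shortening velocity; ``K`` Hill curvature;
    ``f_ecc`` eccentric force cap; ``tau_act`` [s] activation time constant;
    ``rho`` [m] constant moment arm; ``l_ref_frac`` operating length at the
    joint midpoint (fraction of ``l_opt``, < 1 puts both muscles on the
    ascending limb); ``l_slack_frac``/``w_pas`` shape the passive elastic
    force.
    """

    F_max: float = 1000.0
    l_opt: float = 0.1
    w: float = 0.4
    v_max: float = 0.45
    K: float = 5.0
    f_ecc: float = 1.5
    tau_act: float = 0.03
    rho: float = 0.02
    l_ref_frac: float = 0.9
    l_slack_frac: float = 0.95
    w_pas: float = 0.3


@dataclass(frozen=True)
class ArmParams:
    """Rigid 1-DOF limb in the horizontal plane (no gravity)."""

    inertia: float = 0.09     # kg m^2
    damping: float = 0.05     # N m s/rad, passive joint damping
    length: float = 0.3       # m, end-effector lever


@dataclass(frozen=True)
class PointingTask:
    q0: float = -0.6          # rad, start angle
    q_goal: float = 0.4       # rad, goal angle
    T: float = 1.0            # s, movement duration


@dataclass(frozen=True)
class PeriodicTask:
    """Walking-like oscillation with a controlled-falling character.

    ``k_unstable`` is a destabilizing joint stiffness (torque ``+k q`` away
    from the upright oscillation center): left alone the limb falls over,
    like an inverted pendulum.  Muscle co-contraction stiffness exceeds it,
    so the muscle plant is passively stabilized; the torque plant must buy
    stability with feedback information.  Forward speed is derived from the
    low-pass filtered joint velocity (time constant ``speed_tau``) — body
    translation integrates limb motion, high-frequency jitter does not turn
    into distance.
    """

    amplitude: float = 0.25   # rad
    freq: float = 0.6         # Hz
    T_settle: float = 1.0     # s, transient before evaluation starts
    T_eval: float = 5.0       # s, evaluation window
    y0: float = 1.30          # m, nominal height analogue
    c_y: float = 0.5          # m/rad^2, height penalty on tracking error
    speed_scale: float = 0.0  # m, filled by default_periodic_config
    k_unstable: float = 2.0   # N m/rad, destabilizing joint stiffness
    speed_tau: float = 0.1    # s, velocity low-pass for forward speed

    @property
    def T_total(self) -> float:
        return self.T_settle + self.T_eval

    def q_ref(self, t: float) -> float:
        return self.amplitude * math.sin(2.0 * math.pi * self.freq * t)

    def dq_ref(self, t: float) -> float:
        w = 2.0 * math.pi * self.freq
        return self.amplitude * w * math.cos(w * t)


@dataclass(frozen=True)
class MuscleController:
    """Delayed proprioceptive feedback to antagonist stimulations.

    The controller extrapolates the delayed joint state by its *internal
    latency model* ``latency_model`` (its assumption about sensor delay plus
    activation lag).  With the physical delay present the prediction is
    timed correctly; removing the physical delay leaves the internal model
    mistimed — the controller is adapted to its own physiology.
    """

    u0: float = 0.5           # co-contraction baseline
    kp: float = 0.8           # stim per rad of predicted error
    kv: float = 0.04          # stim per rad/s
    kff: float = 0.0          # feedforward on reference velocity (periodic)
    latency_model: float = 0.03  # s, the controller's model of its sensor delay


@dataclass(frozen=True)
class TorqueController:
    """Ideal PD torque law ``u = kP (q - q_ref) + kD (dq - dq_ref)``.

    The shipped gains are negative, so the commanded torque opposes the
    tracking error; the command saturates at ``±limit``.
    """

    kP: float = -12.0
    kD: float = -2.0
    limit: float = 20.0


@dataclass(frozen=True)
class PlantConfig:
    plant: str = "muscle"             # "muscle" | "torque"
    task: str = "pointing"            # "pointing" | "periodic"
    arm: ArmParams = field(default_factory=ArmParams)
    muscle: MuscleParams = field(default_factory=MuscleParams)
    pointing: PointingTask = field(default_factory=PointingTask)
    periodic: PeriodicTask = field(default_factory=PeriodicTask)
    muscle_ctrl: MuscleController = field(default_factory=MuscleController)
    torque_ctrl: TorqueController = field(default_factory=TorqueController)
    dt: float = 0.001                 # s, integrator step
    tick: float = 0.01                # s, controller update interval
    delay: float = 0.0                # s, sensor delay (multiple of dt)
    noise_std: float = 0.0            # controller-output noise, signal units
    # recorded reference kinematics for the periodic torque plant
    ref_q: Optional[tuple[float, ...]] = None
    ref_dq: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.plant not in ("muscle", "torque"):
            raise ValueError(f"unknown plant kind {self.plant!r}")
        if self.task not in ("pointing", "periodic"):
            raise ValueError(f"unknown task kind {self.task!r}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        for name, interval in (("tick", self.tick), ("delay", self.delay)):
            k = interval / self.dt
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dt")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    @property
    def T_total(self) -> float:
        return self.pointing.T if self.task == "pointing" else self.periodic.T_total

    @property
    def window(self) -> tuple[float, float]:
        """(start, duration) of the discretization/evaluation window."""
        if self.task == "pointing":
            return 0.0, self.pointing.T
        return self.periodic.T_settle, self.periodic.T_eval

    @property
    def output_names(self) -> tuple[str, ...]:
        if self.plant == "muscle":
            return ("stim_flex", "stim_ext")
        return ("torque",)

    @property
    def sensor_names(self) -> tuple[str, ...]:
        return ("sens_q", "sens_dq")


# ---------------------------------------------------------------------------
# result container

@dataclass
class SimResult:
    """Trajectories and recorded signals of one closed-loop run."""

    config: PlantConfig
    times: np.ndarray
    q: np.ndarray
    dq: np.ndarray
    activations: Optional[np.ndarray]      # (steps, 2) for the muscle plant
    signals: dict[str, np.ndarray]         # raw streams on the dt grid
    applied: dict[str, np.ndarray]         # post-discretization streams
    traces: dict[str, DiscretizedTrace]    # emitted symbol sequences
    t_stop: float
    stop_reason: str                       # "completed"|"speed"|"height"|"diverged"
    warnings: list[str] = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.stop_reason == "completed"

    # pointing geometry -----------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.config.arm.length * np.cos(self.q)

    @property
    def y(self) -> np.ndarray:
        return self.config.arm.length * np.sin(self.q)

    @property
    def x_end(self) -> float:
        return float(self.x[-1])

    @property
    def y_end(self) -> float:
        return float(self.y[-1])

    @property
    def dq_end(self) -> float:
        return float(self.dq[-1])

    # periodic analogues ----------------------------------------------------
    @property
    def x_hat(self) -> np.ndarray:
        return self.signals["x_hat"]

    @property
    def y_hat(self) -> np.ndarray:
        return self.signals["y_hat"]

    def goal_xy(self) -> tuple[float, float]:
        L = self.config.arm.length
        g = self.config.pointing.q_goal
        return L * math.cos(g), L * math.sin(g)

    def to_hdf5(self, path) -> None:
        """Export trajectories and recorded signals to an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["plant"] = self.config.plant
            fh.attrs["task"] = self.config.task
            fh.attrs["t_stop"] = self.t_stop
            fh.attrs["stop_reason"] = self.stop_reason
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("q", data=self.q)
            fh.create_dataset("dq", data=self.dq)
            if self.activations is not None:
                fh.create_dataset("activations", data=self.activations)
            sig = fh.create_group("signals")
            for name, arr in self.signals.items():
                sig.create_dataset(name, data=arr)
            app = fh.create_group("applied")
            for name, arr in self.applied.items():
                app.create_dataset(name, data=arr)


# ---------------------------------------------------------------------------
# actuator pieces

def _f_l(l: float, p: MuscleParams) -> float:
    z = (l - p.l_opt) / (p.w * p.l_opt)
    return math.exp(-z * z)


def _f_v(v: float, p: MuscleParams) -> float:
    # v = dl/dt, shortening negative; C1-continuous at v = 0
    vt = v / p.v_max
    if vt <= 0.0:
        if vt <= -1.0:
            return 0.0
        return (1.0 + vt) / (1.0 - p.K * vt)
    c_ecc = (1.0 + p.K) / (p.f_ecc - 1.0)
    return p.f_ecc - (p.f_ecc - 1.0) / (1.0 + c_ecc * vt)


def _f_passive(l: float, p: MuscleParams) -> float:
    ls = p.l_slack_frac * p.l_opt
    if l <= ls:
        return 0.0
    z = (l - ls) / (p.w_pas * p.l_opt)
    return p.F_max * z * z


def passive_elastic_energy(l: float, p: MuscleParams) -> float:
    """Stored energy of the passive elastic element (for energy audits)."""
    ls = p.l_slack_frac * p.l_opt
    if l <= ls:
        return 0.0
    d = p.w_pas * p.l_opt
    return p.F_max * (l - ls) ** 3 / (3.0 * d * d)


def muscle_force(
    activation: float, length: float, velocity: float, p: MuscleParams
) -> float:
    """Total fiber force: active (a·F_max·f_l·f_v) plus passive elastic."""
    return (activation * p.F_max * _f_l(length, p) * _f_v(velocity, p)
            + _f_passive(length, p))


def muscle_actuator_step(
    activation: float,
    stimulation: float,
    length: float,
    velocity: float,
    p: MuscleParams,
    dt: float,
) -> tuple[float, float]:
    """Advance activation one step and return ``(new activation, force)``.

    First-order activation dynamics ``da/dt = (u - a)/tau`` (exact
    exponential update over the step); the returned force uses the new
    activation.  Stimulation is clamped to [0, 1].
    """
    u = min(max(stimulation, 0.0), 1.0)
    decay = math.exp(-dt / p.tau_act)
    a_new = u + (activation - u) * decay
    return a_new, muscle_force(a_new, length, velocity, p)


def pd_torque_controller(
    q: float, dq: float, q_ref: float, dq_ref: float,
    kP: float, kD: float, limit: float,
) -> float:
    """PD torque command, saturated at ``±limit``."""
    u = kP * (q - q_ref) + kD * (dq - dq_ref)
    return min(max(u, -limit), limit)


class DelayLine:
    """Fixed-delay ring buffer; emits the initial value until it fills."""

    def __init__(self, delay_steps: int, initial):
        if delay_steps < 0:
            raise ValueError("delay must be non-negative")
        self._n = delay_steps
        self._buf = [initial] * max(delay_steps, 1)
        self._idx = 0

    def push_pop(self, value):
        """Insert the newest value, return the value from ``delay`` steps ago."""
        if self._n == 0:
            return value
        out = self._buf[self._idx]
        self._buf[self._idx] = value
        self._idx = (self._idx + 1) % self._n
        return out


class PeriodicAbortMonitor:
    """Abort rule for the periodic task: speed band + height floor.

    The speed test compares a sliding-window mean of the forward speed
    (window of one nominal cycle) against the reference speed; the height
    test is instantaneous.  Checks are active only inside the evaluation
    window, and the speed test only once the window is fully covered.
    """

    def __init__(self, ref_speed: float, band: float, y_min: float,
                 window_s: float, eval_start: float, dt: float):
        if not ref_speed > 0:
            raise ValueError("reference speed must be positive")
        self.ref_speed = ref_speed
        self.band = band
        self.y_min = y_min
        self.eval_start = eval_start
        self.window_steps = max(1, int(round(window_s / dt)))
        self._ring = [0.0] * self.window_steps
        self._sum = 0.0
        self._count = 0
        self._idx = 0

    def step(self, t: float, speed: float, y_hat: float) -> Optional[str]:
        """Feed one sample; returns an abort reason or None."""
        if t >= self.eval_start:
            if y_hat <= self.y_min:
                return "height"
            self._sum += speed - self._ring[self._idx]
            self._ring[self._idx] = speed
            self._idx = (self._idx + 1) % self.window_steps
            self._count += 1
            if self._count >= self.window_steps:
                mean = self._sum / self.window_steps
                if abs(self.ref_speed - mean) / self.ref_speed >= self.band:
                    return "speed"
        return None


# ---------------------------------------------------------------------------
# discretizer applied inside the loop

class _RunningDiscretizer:
    """Zero-order-hold quantizer running on the simulation clock.

    Samples the raw stream at its own ``m`` uniformly spaced instants within
    the discretization window and holds the quantized level in between.
    Outside the window (the settling phase) the raw value passes through.
    """

    def __init__(self, spec: SignalSpec, n: int, m: int,
                 window_start: float, window_len: float):
        self.spec = spec
        self.n = int(n)
        self.m = int(m)
        if self.n < 1 or self.m < 1:
            raise ValueError("resolution parameters must be >= 1")
        self.sample_times = [window_start + k * window_len / self.m
                             for k in range(self.m)]
        self._next = 0
        self.held: Optional[float] = None
        self.rec_t: list[float] = []
        self.rec_sym: list[int] = []
        self.rec_lvl: list[float] = []

    def update(self, t: float, raw: float) -> float:
        while self._next < self.m and self.sample_times[self._next] <= t + 1e-12:
            sym, lvl = quantize_amplitude(raw, self.spec, self.n)
            self.rec_t.append(self.sample_times[self._next])
            self.rec_sym.append(sym)
            self.rec_lvl.append(lvl)
            self.held = lvl
            self._next += 1
        return raw if self.held is None else self.held

    def trace(self) -> DiscretizedTrace:
        return DiscretizedTrace(
            spec=self.spec, n=self.n,
            sample_times=np.array(self.rec_t, dtype=float),
            symbols=np.array(self.rec_sym, dtype=int),
            levels=np.array(self.rec_lvl, dtype=float))


# ---------------------------------------------------------------------------
# closed-loop simulation

def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def simulate(
    config: PlantConfig,
    discretization: Optional[dict[str, tuple[SignalSpec, int, int]]] = None,
    scenario: Optional[str] = None,
    seed: Optional[int] = None,
    abort: Optional[PeriodicAbortMonitor] = None,
) -> SimResult:
    """Run the closed loop once and record everything.

    ``discretization`` maps signal names to ``(SignalSpec, n, m)``; named
    signals pass through an amplitude quantizer with zero-order hold on
    their own ``m``-point sample grid inside the task's evaluation window.
    ``scenario`` (``"STIM" | "SENS" | "TORQUE"``) is validated against the
    plant kind; ``None`` runs an undiscretized reference.  ``seed`` drives
    the controller-output noise; identical configs and seeds give
    bit-identical results.
    """
    if scenario is not None:
        needs = "torque" if scenario == "TORQUE" else "muscle"
        if scenario not in ("STIM", "SENS", "TORQUE"):
            raise ValueError(f"unknown scenario {scenario!r}")
        if config.plant != needs:
            raise ValueError(f"scenario {scenario} requires the {needs} plant")

    p = config.muscle
    arm = config.arm
    dt = config.dt
    n_steps = int(round(config.T_total / dt))
    tick_steps = int(round(config.tick / dt))
    delay_steps = int(round(config.delay / dt))
    win_start, win_len = config.window
    warnings: list[str] = []

    discs: dict[str, _RunningDiscretizer] = {}
    if discretization:
        known = set(config.output_names) | set(config.sensor_names)
        for name, (spec, n, m) in discretization.items():
            if name not in known:
                raise ValueError(f"unknown signal {name!r} for this plant")
            if m > int(round(win_len / dt)):
                warnings.append(
                    f"{name}: m={m} exceeds the simulator step count; "
                    "effective time resolution saturates at the step rate")
            discs[name] = _RunningDiscretizer(spec, n, m, win_start, win_len)

    # controller noise, one draw per tick and output signal
    n_ticks = n_steps // tick_steps + 1
    out_names = config.output_names
    if config.noise_std > 0.0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, config.noise_std, size=(n_ticks, len(out_names)))
    else:
        noise = np.zeros((n_ticks, len(out_names)))

    # state
    muscle_plant = config.plant == "muscle"
    task = config.task
    if task == "pointing":
        q = config.pointing.q0
    else:
        q = config.periodic.q_ref(0.0)
    dq = 0.0
    a1 = a2 = 0.0
    x_hat = 0.0
    dq_filt = 0.0
    l_ref0 = p.l_ref_frac * p.l_opt
    mc = config.muscle_ctrl
    tc = config.torque_ctrl
    per = config.periodic
    delay_line = DelayLine(delay_steps, (q, dq))
    raw_cmd = [0.0] * len(out_names)
    applied_cmd = list(raw_cmd)

    # histories
    H_t = np.empty(n_steps + 1)
    H_q = np.empty(n_steps + 1)
    H_dq = np.empty(n_steps + 1)
    H_act = np.empty((n_steps + 1, 2)) if muscle_plant else None
    H_sig = {name: np.empty(n_steps + 1) for name in out_names}
    H_app = {name: np.empty(n_steps + 1) for name in out_names}
    H_sq = np.empty(n_steps + 1)
    H_sdq = np.empty(n_steps + 1)
    H_xh = np.empty(n_steps + 1) if task == "periodic" else None
    H_yh = np.empty(n_steps + 1) if task == "periodic" else None

    k_unst = per.k_unstable if task == "periodic" else 0.0

    def muscle_deriv(q_, dq_, a1_, a2_, u1, u2):
        l1 = l_ref0 - p.rho * q_
        l2 = l_ref0 + p.rho * q_
        F1 = a1_ * p.F_max * _f_l(l1, p) * _f_v(-p.rho * dq_, p) + _f_passive(l1, p)
        F2 = a2_ * p.F_max * _f_l(l2, p) * _f_v(p.rho * dq_, p) + _f_passive(l2, p)
        tau = p.rho * (F1 - F2) + k_unst * q_ - arm.damping * dq_
        return dq_, tau / arm.inertia, (u1 - a1_) / p.tau_act, (u2 - a2_) / p.tau_act

    def torque_deriv(q_, dq_, u):
        return dq_, (u + k_unst * q_ - arm.damping * dq_) / arm.inertia

    t_stop = config.T_total
    stop_reason = "completed"
    ref_q_arr = config.ref_q
    ref_dq_arr = config.ref_dq
    last_step = n_steps

    for step in range(n_steps + 1):
        t = step * dt

        # delayed sensors
        sq, sdq = delay_line.push_pop((q, dq))
        if "sens_q" in discs:
            sq_eff = discs["sens_q"].update(t, sq)
        else:
            sq_eff = sq
        if "sens_dq" in discs:
            sdq_eff = discs["sens_dq"].update(t, sdq)
        else:
            sdq_eff = sdq

        # controller tick
        if step % tick_steps == 0:
            k_tick = step // tick_steps
            if muscle_plant:
                q_pred = sq_eff + mc.latency_model * sdq_eff
                if task == "pointing":
                    err = config.pointing.q_goal - q_pred
                    dref = 0.0
                else:
                    err = per.q_ref(t) - q_pred
                    dref = per.dq_ref(t)
                u1 = mc.u0 + mc.kp * err + mc.kv * (dref - sdq_eff) + mc.kff * dref
                u2 = mc.u0 - mc.kp * err - mc.kv * (dref - sdq_eff) - mc.kff * dref
                raw_cmd[0] = _clip01(u1 + noise[k_tick, 0])
                raw_cmd[1] = _clip01(u2 + noise[k_tick, 1])
            else:
                if task == "pointing":
                    qr, dqr = config.pointing.q_goal, 0.0
                else:
                    i = min(step, len(ref_q_arr) - 1)
                    qr, dqr = ref_q_arr[i], ref_dq_arr[i]
                u = pd_torque_controller(sq_eff, sdq_eff, qr, dqr,
                                         tc.kP, tc.kD, tc.limit)
                u = u + noise[k_tick, 0]
                raw_cmd[0] = min(max(u, -tc.limit), tc.limit)

        # output discretizers run on the simulation clock
        for j, name in enumerate(out_names):
            if name in discs:
                applied_cmd[j] = discs[name].update(t, raw_cmd[j])
            else:
                applied_cmd[j] = raw_cmd[j]

        # record
        H_t[step] = t
        H_q[step] = q
        H_dq[step] = dq
        H_sq[step] = sq
        H_sdq[step] = sdq
        if muscle_plant:
            H_act[step, 0] = a1
            H_act[step, 1] = a2
        for j, name in enumerate(out_names):
            H_sig[name][step] = raw_cmd[j]
            H_app[name][step] = applied_cmd[j]
        if task == "periodic":
            dq_filt += (dq - dq_filt) * (dt / per.speed_tau)
            speed = per.speed_scale * abs(dq_filt)
            x_hat += speed * dt
            e_trk = q - (ref_q_arr[min(step, len(ref_q_arr) - 1)]
                         if (not muscle_plant and ref_q_arr is not None)
                         else per.q_ref(t))
            y_hat = per.y0 - per.c_y * e_trk * e_trk
            H_xh[step] = x_hat
            H_yh[step] = y_hat
            if abort is not None:
                reason = abort.step(t, speed, y_hat)
                if reason is not None:
                    t_stop, stop_reason, last_step = t, reason, step
                    break

        if not (math.isfinite(q) and math.isfinite(dq)):
            t_stop, stop_reason, last_step = t, "diverged", step
            break
        if step == n_steps:
            break

        # RK4 with zero-order-hold actuation
        if muscle_plant:
            u1c, u2c = applied_cmd[0], applied_cmd[1]
            k1 = muscle_deriv(q, dq, a1, a2, u1c, u2c)
            k2 = muscle_deriv(q + 0.5 * dt * k1[0], dq + 0.5 * dt * k1[1],
                              a1 + 0.5 * dt * k1[2], a2 + 0.5 * dt * k1[3], u1c, u2c)
            k3 = muscle_deriv(q + 0.5 * dt * k2[0], dq + 0.5 * dt * k2[1],
                              a1 + 0.5 * dt * k2[2], a2 + 0.5 * dt * k2[3], u1c, u2c)
            k4 = muscle_deriv(q + dt * k3[0], dq + dt * k3[1],
                              a1 + dt * k3[2], a2 + dt * k3[3], u1c, u2c)
            q += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            dq += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            a1 += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            a2 += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            a1 = _clip01(a1)
            a2 = _clip01(a2)
        else:
            uc = applied_cmd[0]
            k1 = torque_deriv(q, dq, uc)
            k2 = torque_deriv(q + 0.5 * dt * k1[0], dq + 0.5 * dt * k1[1], uc)
            k3 = torque_deriv(q + 0.5 * dt * k2[0], dq + 0.5 * dt * k2[1], uc)
            k4 = torque_deriv(q + dt * k3[0], dq + dt * k3[1], uc)
            q += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            dq += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])

    end = last_step + 1
    signals = {name: H_sig[name][:end] for name in out_names}
    signals["sens_q"] = H_sq[:end]
    signals["sens_dq"] = H_sdq[:end]
    if task == "periodic":
        signals["x_hat"] = H_xh[:end]
        signals["y_hat"] = H_yh[:end]
    applied = {name: H_app[name][:end] for name in out_names}
    traces = {name: d.trace() for name, d in discs.items()}
    return SimResult(
        config=config,
        times=H_t[:end],
        q=H_q[:end],
        dq=H_dq[:end],
        activations=H_act[:end] if muscle_plant else None,
        signals=signals,
        applied=applied,
        traces=traces,
        t_stop=t_stop,
        stop_reason=stop_reason,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# reference-run helpers

def extract_reference_ranges(
    reference: SimResult, signal_names: Sequence[str],
    role: str = "controller-input",
) -> list[SignalSpec]:
    """Per-signal amplitude ranges from an undiscretized reference run.

    Min/max are taken over the evaluation window, exactly, with no padding;
    a constant signal yields ``u_min == u_max`` (single-level semantics
    downstream).
    """
    if reference.traces:
        raise ValueError("reference run must be undiscretized")
    win_start, win_len = reference.config.window
    T = win_len
    t = reference.times
    mask = (t >= win_start - 1e-12) & (t <= win_start + win_len + 1e-12)
    specs = []
    for name in signal_names:
        arr = reference.signals[name][mask]
        specs.append(SignalSpec(name=name, u_min=float(arr.min()),
                                u_max=float(arr.max()), T=T, role=role))
    return specs


def default_pointing_config(plant: str = "muscle", *,
                            delay: Optional[float] = None,
                            noise_std: Optional[float] = None) -> PlantConfig:
    """Shipped pointing fixture: muscle plant with 30 ms sensor delay and
    mild motor noise, torque plant with zero delay."""
    if plant == "muscle":
        return PlantConfig(
            plant="muscle", task="pointing",
            delay=0.03 if delay is None else delay,
            noise_std=0.01 if noise_std is None else noise_std,
            muscle_ctrl=MuscleController(u0=0.5, kp=0.8, kv=0.04,
                                         latency_model=0.03),
        )
    return PlantConfig(
        plant="torque", task="pointing",
        delay=0.0 if delay is None else delay,
        noise_std=0.2 if noise_std is None else noise_std,
        torque_ctrl=TorqueController(kP=-12.0, kD=-2.0, limit=20.0),
    )


def default_periodic_config(plant: str = "muscle", *,
                            delay: Optional[float] = None) -> PlantConfig:
    """Shipped periodic (walking-like) fixture, muscle version.

    The torque version needs recorded reference kinematics; build it with
    :func:`build_periodic_torque_config` from a muscle reference run.
    """
    task = PeriodicTask()
    # scale forward progress so the nominal oscillation walks at ~1.33 m/s
    mean_abs_dq = 2.0 * task.amplitude * 2.0 * math.pi * task.freq / math.pi
    task = replace(task, speed_scale=1.33 / mean_abs_dq)
    if plant != "muscle":
        raise ValueError("use build_periodic_torque_config for the torque plant")
    return PlantConfig(
        plant="muscle", task="periodic", periodic=task,
        delay=0.01 if delay is None else delay,
        noise_std=0.0,
        muscle_ctrl=MuscleController(u0=0.5, kp=0.3, kv=0.1, kff=0.12,
                                     latency_model=0.04),
    )


def muscle_joint_torque(result: SimResult) -> np.ndarray:
    """Actuator torque time series of a muscle-plant run (for torque limits)."""
    p = result.config.muscle
    l_ref0 = p.l_ref_frac * p.l_opt
    q = result.q
    dq = result.dq
    a = result.activations
    out = np.empty_like(q)
    for i in range(q.size):
        l1 = l_ref0 - p.rho * q[i]
        l2 = l_ref0 + p.rho * q[i]
        F1 = a[i, 0] * p.F_max * _f_l(l1, p) * _f_v(-p.rho * dq[i], p) + _f_passive(l1, p)
        F2 = a[i, 1] * p.F_max * _f_l(l2, p) * _f_v(p.rho * dq[i], p) + _f_passive(l2, p)
        out[i] = p.rho * (F1 - F2)
    return out


def build_periodic_torque_config(
    muscle_reference: SimResult, *,
    delay: Optional[float] = None,
    kP: float = -60.0, kD: float = -8.0,
) -> PlantConfig:
    """Torque twin of the periodic task, tracking the muscle reference.

    The PD controller enforces the joint kinematics recorded from the
    muscle reference run; the torque limit is 1.5x the peak actuator torque
    of that run.
    """
    ref = muscle_reference
    if ref.config.plant != "muscle" or ref.config.task != "periodic":
        raise ValueError("need an undiscretized muscle periodic reference run")
    limit = 1.5 * float(np.abs(muscle_joint_torque(ref)).max())
    return PlantConfig(
        plant="torque", task="periodic",
        periodic=ref.config.periodic,
        delay=0.0 if delay is None else delay,
        noise_std=0.0,
        torque_ctrl=TorqueController(kP=kP, kD=kD, limit=limit),
        ref_q=tuple(float(v) for v in ref.q),
        ref_dq=tuple(float(v) for v in ref.dq),
    )
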