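"""Closed-loop stance model with haptic feedback gain manipulation.

The body is a linearised inverted pendulum stabilised by a delayed
proportional-derivative controller.  Two sensory channels feed the
controller: a "space" channel (body orientation relative to vertical, e.g.
vestibular/proprioceptive) and a "touch" channel (horizontal hand-object
distance from light fingertip contact with a robot whose motion is a
programmed gain G times body motion).  A conflict estimator compares the
body-velocity estimates of the two channels; when their difference exceeds
a threshold Te the difference is subtracted from the touch loop, which
attenuates haptic input caused by object motion rather than self-motion.
Sway is driven by a single low-pass-filtered noise source added to both
channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _engine
from .errors import ConfigurationError, InvalidNumericError

__all__ = [
    "BodyParams",
    "ControlParams",
    "ConflictParams",
    "NoiseParams",
    "GainCondition",
    "SimTrace",
    "ModelConfig",
    "STUDY_GAIN_GRID",
    "plant_step",
    "sensory_estimates",
    "conflict_correction",
    "noise_step",
    "simulate_trial",
    "run_condition_battery",
    "linear_spectral_radius",
    "linear_velocity_psd",
    "linear_position_psd",
]

#: Haptic gain grid used in the study protocol (robot motion / body motion).
STUDY_GAIN_GRID = (-2.0, -1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0, 2.0)

#: Default integration step: 10x the 120-Hz sensor rate.
DEFAULT_DT = 1.0 / 1200.0


@dataclass(frozen=True)
class BodyParams:
    """Anthropometric constants of the inverted pendulum.

    Defaults are the fixed whole-body values used throughout: COM height
    0.96 m, mass 68.5 kg, moment of inertia about the ankle 76.4 kg m^2.
    """

    h: float = 0.96
    m: float = 68.5
    J: float = 76.4
    g: float = 9.81

    def __post_init__(self):
        if not (self.h > 0 and self.m > 0 and self.J > 0):
            raise ConfigurationError("BodyParams requires h, m, J > 0")

    @property
    def mgh(self) -> float:
        """Gravitational toppling stiffness m*g*h (N m/rad)."""
        return self.m * self.g * self.h


def _default_ctrl_gains(body: BodyParams | None = None):
    body = body or BodyParams()
    Kp = 1.5 * body.mgh
    return Kp, 0.25 * Kp


@dataclass(frozen=True)
class ControlParams:
    """Delayed PD controller and sensory channel weights.

    ``Kp`` must exceed m*g*h for the upright equilibrium to be stabilisable.
    ``w_touch`` and ``w_space`` weight the touch- and space-channel state
    estimates and must sum to 1; ``w_touch = 0`` encodes the no-touch
    condition.  Defaults: Kp = 1.5*m*g*h, Kd = 0.25*Kp s, delay = 0.10 s,
    w_touch = 0.3 — physiological magnitudes, selected so the linear loop's
    position and velocity band power both decrease monotonically with the
    effective loop gain over the stable gain range while G = +1 is soft and
    G = +2 statically unstable (see docs/methods.md).
    """

    Kp: float = field(default_factory=lambda: _default_ctrl_gains()[0])
    Kd: float = field(default_factory=lambda: _default_ctrl_gains()[1])
    delay: float = 0.10
    w_touch: float = 0.3

    def __post_init__(self):
        if self.delay < 0:
            raise ConfigurationError("delay must be >= 0")
        if not (0.0 <= self.w_touch <= 1.0):
            raise ConfigurationError("w_touch must be in [0, 1]")
        if self.Kp <= 0 or self.Kd < 0:
            raise ConfigurationError("Kp must be > 0 and Kd >= 0")

    @property
    def w_space(self) -> float:
        return 1.0 - self.w_touch

    def validate_against(self, body: BodyParams) -> None:
        if self.Kp <= body.mgh:
            raise ConfigurationError(
                f"Kp = {self.Kp:.1f} N m/rad does not exceed m*g*h = "
                f"{body.mgh:.1f} N m/rad; the pendulum cannot be stabilised"
            )


@dataclass(frozen=True)
class ConflictParams:
    """Conflict estimator: velocity threshold and correction form.

    ``mode='literal'`` subtracts the full touch-space velocity difference
    once it exceeds ``Te``; ``mode='deadzone'`` subtracts only the
    supra-threshold excess.  The velocity correction is carried into the
    touch position cue through an integrator, leaky with time constant
    ``leak_tau`` (default ``inf`` = pure integration: a finite leak removes
    the correction at DC, where the inverted pendulum is statically
    unstable, and lets strongly positive gains diverge).  Fitted Te values
    are mode-dependent.
    """

    Te: float = 0.008
    mode: str = "deadzone"
    leak_tau: float = math.inf

    def __post_init__(self):
        if self.Te < 0:
            raise ConfigurationError("Te must be >= 0")
        if self.mode not in ("literal", "deadzone"):
            raise ConfigurationError("mode must be 'literal' or 'deadzone'")
        if not (self.leak_tau > 0):
            raise ConfigurationError("leak_tau must be > 0 (inf allowed)")


@dataclass(frozen=True)
class NoiseParams:
    """Single low-pass-filtered, gain-scaled white-noise source.

    The same realisation feeds the position cues of both channels; its
    analytic derivative feeds the velocity cues.  ``k_noise`` (rad) scales
    the filter output; ``tau_noise`` (s) is the first-order low-pass time
    constant.  Identical seed => identical realisation.
    """

    k_noise: float = 0.08
    tau_noise: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.k_noise < 0:
            raise ConfigurationError("k_noise must be >= 0")
        if not (self.tau_noise > 0):
            raise ConfigurationError("tau_noise must be > 0")


@dataclass(frozen=True)
class GainCondition:
    """Haptic feedback gain G and the body->robot device latency."""

    G: float = 0.0
    device_lag: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.G):
            raise InvalidNumericError("gain G must be finite")
        if self.device_lag < 0:
            raise ConfigurationError("device_lag must be >= 0")


@dataclass
class SimTrace:
    """One simulated closed-loop run at a fixed step.

    ``theta_touch`` stores the conflict-corrected touch position estimate.
    ``diverged`` is set instead of raising when |theta| exceeded the
    divergence limit; arrays are truncated at that point.
    """

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    x_robot: np.ndarray
    theta_touch: np.ndarray
    theta_space: np.ndarray
    conflict: np.ndarray
    torque: np.ndarray
    noise: np.ndarray
    dt: float
    gain: GainCondition
    body: BodyParams
    seed: int
    diverged: bool = False
    discard_s: float = 0.0

    @property
    def x_body(self) -> np.ndarray:
        """AP marker position (m): h * theta."""
        return self.body.h * self.theta

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def decimate(self, q: int) -> "SimTrace":
        """Keep every q-th sample (the loop is low-pass; plain stride)."""
        if q <= 0:
            raise ConfigurationError("decimation factor must be positive")
        arrays = {
            name: getattr(self, name)[::q]
            for name in (
                "t",
                "theta",
                "theta_dot",
                "x_robot",
                "theta_touch",
                "theta_space",
                "conflict",
                "torque",
                "noise",
            )
        }
        return SimTrace(
            dt=self.dt * q,
            gain=self.gain,
            body=self.body,
            seed=self.seed,
            diverged=self.diverged,
            discard_s=self.discard_s,
            **arrays,
        )

    def analysis_slice(self) -> slice:
        """Index slice excluding the initial discard window."""
        return slice(int(round(self.discard_s / self.dt)), None)


# ---------------------------------------------------------------------------
# elementary operations (scalar/array reference forms of the kernel logic)
# ---------------------------------------------------------------------------


def plant_step(state, torque, body: BodyParams, dt: float):
    """Advance the linearised pendulum one semi-implicit Euler step.

    J*theta_ddot = m*g*h*theta - torque (small-angle linearisation).
    """
    theta, theta_dot = state
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if not (np.isfinite(theta) and np.isfinite(theta_dot) and np.isfinite(torque)):
        raise InvalidNumericError("non-finite state or torque")
    theta_dot = theta_dot + dt * (body.mgh * theta - torque) / body.J
    theta = theta + dt * theta_dot
    return theta, theta_dot


def sensory_estimates(
    theta,
    theta_dot,
    gain: GainCondition,
    noise_sample,
    body: BodyParams,
    x_body_delayed=None,
    xdot_body_delayed=None,
):
    """Per-channel angle/velocity estimates for one instant.

    The space channel reads body orientation directly; the touch channel
    reads the horizontal hand-body distance s = G*x_body(t - lag) - x_body
    and maps it back to an angle via -s/h.  The same noise sample (n, ndot)
    enters both channels.
    """
    if body.h == 0:
        raise ConfigurationError("body.h must be nonzero")
    n, n_dot = noise_sample
    x_body = body.h * theta
    xdot_body = body.h * theta_dot
    if x_body_delayed is None:
        x_body_delayed = x_body
    if xdot_body_delayed is None:
        xdot_body_delayed = xdot_body
    s = gain.G * x_body_delayed - x_body
    s_dot = gain.G * xdot_body_delayed - xdot_body
    theta_space = theta + n
    thetadot_space = theta_dot + n_dot
    theta_touch = -s / body.h + n
    thetadot_touch = -s_dot / body.h + n_dot
    return theta_space, thetadot_space, theta_touch, thetadot_touch


def conflict_correction(v_touch: float, v_space: float, cp: ConflictParams) -> float:
    """Velocity correction applied to the touch loop.

    d = v_touch - v_space.  literal: full d once |d| > Te; deadzone: the
    supra-threshold excess sign(d)*(|d| - Te).  Zero otherwise.
    """
    d = v_touch - v_space
    if not np.isfinite(cp.Te):
        return 0.0
    if abs(d) <= cp.Te:
        return 0.0
    if cp.mode == "deadzone":
        return math.copysign(abs(d) - cp.Te, d)
    return d


def noise_filter_coefficients(params: NoiseParams, dt: float):
    """(a, b) of the exact ZOH discretisation n[k+1] = a n[k] + b w[k]."""
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    a = math.exp(-dt / params.tau_noise)
    b = (1.0 - a) * params.k_noise
    return a, b


def noise_step(state: float, params: NoiseParams, dt: float, rng: np.random.Generator):
    """Advance the filtered-noise process one step.

    Returns ``(n_next, (n, n_dot))``: the updated filter state and the
    (value, derivative) pair valid over the step just taken, so position
    and velocity cues use a consistent realisation.
    """
    a, b = noise_filter_coefficients(params, dt)
    w = rng.standard_normal()
    n = state
    n_dot = (params.k_noise * w - n) / params.tau_noise
    n_next = a * n + b * w
    return n_next, (n, n_dot)


def stationary_noise_std(params: NoiseParams, dt: float) -> float:
    """Closed-form stationary s.d. of the discretised noise process."""
    a, b = noise_filter_coefficients(params, dt)
    return b / math.sqrt(1.0 - a * a)


# ---------------------------------------------------------------------------
# linear (conflict-off) analysis: stability and spectra
# ---------------------------------------------------------------------------


def effective_loop_gain(ctrl: ControlParams, G: float) -> float:
    """Position-loop gain factor w_space + w_touch*(1 - G) of the linear loop."""
    return ctrl.w_space + ctrl.w_touch * (1.0 - G)


def linear_spectral_radius(
    body: BodyParams,
    ctrl: ControlParams,
    G: float = 0.0,
    dt: float = DEFAULT_DT,
) -> float:
    """Spectral radius of the discrete closed loop with the conflict
    estimator off (Te = inf) and zero device lag.

    < 1 means the linearised loop is asymptotically stable.  Used as a
    startup check before simulating.
    """
    k_eff = effective_loop_gain(ctrl, G)
    alpha = ctrl.Kp * k_eff
    beta = ctrl.Kd * k_eff
    mgh, J = body.mgh, body.J
    d = int(round(ctrl.delay / dt))
    if d == 0:
        A = np.array(
            [
                [1 + dt * dt * (mgh - alpha) / J, dt * (1 - dt * beta / J)],
                [dt * (mgh - alpha) / J, 1 - dt * beta / J],
            ]
        )
        return float(np.max(np.abs(np.linalg.eigvals(A))))
    n = d + 2
    A = np.zeros((n, n))
    # state: [theta, theta_dot, u[k-1], ..., u[k-d]]
    A[0, 0] = 1 + dt * dt * mgh / J
    A[0, 1] = dt
    A[0, 1 + d] = -dt * dt / J
    A[1, 0] = dt * mgh / J
    A[1, 1] = 1.0
    A[1, 1 + d] = -dt / J
    A[2, 0] = alpha
    A[2, 1] = beta
    for i in range(3, n):
        A[i, i - 1] = 1.0
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _noise_transfer(z, noisep: NoiseParams, dt: float):
    """Per-sample transfers W -> (N, Ndot) of the discretised noise filter."""
    a, _ = noise_filter_coefficients(noisep, dt)
    k, tau = noisep.k_noise, noisep.tau_noise
    Nw = (1.0 - a) * k / (z - a)
    Ndw = k * (z - 1.0) / (tau * (z - a))
    return Nw, Ndw


def _velocity_transfer(f, body, ctrl, noisep, dt, G=0.0):
    """H(f): unit-variance white noise w[k] -> theta_dot, linear loop."""
    f = np.asarray(f, dtype=float)
    z = np.exp(2j * np.pi * f * dt)
    d = int(round(ctrl.delay / dt))
    mgh, J = body.mgh, body.J
    k_eff = effective_loop_gain(ctrl, G)
    Nw, Ndw = _noise_transfer(z, noisep, dt)
    zd = z ** (-d)
    pos = dt * z / (z - 1.0)  # theta = pos * theta_dot
    denom = (z - 1.0) - (dt / J) * mgh * pos + (dt / J) * zd * k_eff * (
        ctrl.Kp * pos + ctrl.Kd
    )
    numer = -(dt / J) * zd * (ctrl.Kp * Nw + ctrl.Kd * Ndw)
    return numer / denom


def linear_velocity_psd(
    f,
    body: BodyParams,
    ctrl: ControlParams,
    noisep: NoiseParams,
    dt: float = DEFAULT_DT,
    G: float = 0.0,
):
    """One-sided theoretical PSD of theta_dot ((rad/s)^2/Hz) for the linear
    closed loop (conflict off, zero device lag), on frequency grid ``f``.

    Independent frequency-domain route: exact discrete transfer function of
    the semi-implicit integrator, integer-step delay and ZOH noise filter,
    times the one-sided white-noise floor 2*dt.
    """
    H = _velocity_transfer(f, body, ctrl, noisep, dt, G)
    return 2.0 * dt * np.abs(H) ** 2


def linear_position_psd(f, body, ctrl, noisep, dt=DEFAULT_DT, G=0.0):
    """One-sided theoretical PSD of theta (rad^2/Hz), linear closed loop."""
    f = np.asarray(f, dtype=float)
    z = np.exp(2j * np.pi * f * dt)
    H = _velocity_transfer(f, body, ctrl, noisep, dt, G) * dt * z / (z - 1.0)
    return 2.0 * dt * np.abs(H) ** 2


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_trial(
    body: BodyParams,
    ctrl: ControlParams,
    cp: ConflictParams,
    noisep: NoiseParams,
    gain: GainCondition,
    duration: float,
    dt: float = DEFAULT_DT,
    keep_every: int = 1,
    discard_s: float = 0.0,
    check_stability: bool = True,
) -> SimTrace:
    """Simulate one closed-loop run of ``duration`` seconds.

    Deterministic given ``noisep.seed``.  Divergence (|theta| > 0.5 rad) is
    flagged on the returned trace, not raised, so ablation studies can count
    unstable runs.  ``check_stability`` verifies the linearised G=0 loop
    (conflict off) is stable before running and raises otherwise.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if duration < 50 * dt:
        raise ConfigurationError("duration must cover at least 50 steps")
    ctrl.validate_against(body)
    if check_stability:
        rho = linear_spectral_radius(body, ctrl, G=0.0, dt=dt)
        if rho >= 1.0:
            raise ConfigurationError(
                f"linearised G=0 loop is unstable (spectral radius {rho:.4f}); "
                "adjust Kp/Kd/delay"
            )

    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(noisep.seed)
    w = rng.standard_normal(n_steps)
    a, _ = noise_filter_coefficients(noisep, dt)

    out = {
        name: np.empty(n_steps)
        for name in (
            "theta",
            "theta_dot",
            "x_robot",
            "theta_touch",
            "theta_space",
            "conflict",
            "torque",
            "noise",
        )
    }
    leak_rate = 0.0 if math.isinf(cp.leak_tau) else 1.0 / cp.leak_tau
    n_valid = _engine.simulate_loop(
        n_steps,
        dt,
        body.mgh,
        body.J,
        ctrl.Kp,
        ctrl.Kd,
        int(round(ctrl.delay / dt)),
        ctrl.w_touch,
        ctrl.w_space,
        gain.G,
        int(round(gain.device_lag / dt)),
        body.h,
        cp.Te,
        cp.mode == "deadzone",
        leak_rate,
        noisep.k_noise,
        a,
        noisep.tau_noise,
        w,
        out["theta"],
        out["theta_dot"],
        out["x_robot"],
        out["theta_touch"],
        out["theta_space"],
        out["conflict"],
        out["torque"],
        out["noise"],
    )
    diverged = n_valid < n_steps
    t = np.arange(n_valid) * dt
    trace = SimTrace(
        t=t,
        dt=dt,
        gain=gain,
        body=body,
        seed=noisep.seed,
        diverged=diverged,
        discard_s=discard_s,
        **{k: v[:n_valid] for k, v in out.items()},
    )
    if keep_every > 1:
        trace = trace.decimate(keep_every)
    return trace


@dataclass(frozen=True)
class ModelConfig:
    """Bundle of all model parameters plus simulation settings."""

    body: BodyParams = field(default_factory=BodyParams)
    ctrl: ControlParams = field(default_factory=ControlParams)
    conflict: ConflictParams = field(default_factory=ConflictParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    dt: float = DEFAULT_DT
    duration: float = 2810.0
    device_lag: float = 0.0
    keep_every: int = 10
    discard_s: float = 10.0

    def with_noise(self, **kw) -> "ModelConfig":
        return replace(self, noise=replace(self.noise, **kw))

    def to_dict(self) -> dict:
        return {
            "body": {"h": self.body.h, "m": self.body.m, "J": self.body.J},
            "control": {
                "Kp": self.ctrl.Kp,
                "Kd": self.ctrl.Kd,
                "delay": self.ctrl.delay,
                "w_touch": self.ctrl.w_touch,
            },
            "conflict": {
                "Te": self.conflict.Te,
                "mode": self.conflict.mode,
                "leak_tau": self.conflict.leak_tau,
            },
            "noise": {
                "k_noise": self.noise.k_noise,
                "tau_noise": self.noise.tau_noise,
                "seed": self.noise.seed,
            },
            "sim": {
                "dt": self.dt,
                "duration": self.duration,
                "device_lag": self.device_lag,
                "keep_every": self.keep_every,
                "discard_s": self.discard_s,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        sim = d.get("sim", {})
        return cls(
            body=BodyParams(**d.get("body", {})),
            ctrl=ControlParams(**d.get("control", {})),
            conflict=ConflictParams(**d.get("conflict", {})),
            noise=NoiseParams(**d.get("noise", {})),
            dt=sim.get("dt", DEFAULT_DT),
            duration=sim.get("duration", 2810.0),
            device_lag=sim.get("device_lag", 0.0),
            keep_every=sim.get("keep_every", 10),
            discard_s=sim.get("discard_s", 10.0),
        )


def run_condition_battery(
    config: ModelConfig,
    gains: Sequence[float] | None = None,
    duration: float | None = None,
    seeds: Sequence[int] = (0,),
) -> dict[float, list[SimTrace]]:
    """One run per (gain, seed); first ``discard_s`` seconds marked discard.

    The same seed produces the same noise realisation at every gain
    (common random numbers), so condition contrasts are not washed out by
    Monte-Carlo variability; distinct seeds give independent realisations.
    """
    if gains is None:
        gains = STUDY_GAIN_GRID
    gains = list(gains)
    if not gains:
        raise ConfigurationError("gain list must not be empty")
    if duration is None:
        duration = config.duration
    out: dict[float, list[SimTrace]] = {}
    for G in gains:
        cond = GainCondition(G=G, device_lag=config.device_lag)
        runs = []
        for seed in seeds:
            noisep = replace(config.noise, seed=int(seed))
            runs.append(
                simulate_trial(
                    config.body,
                    config.ctrl,
                    config.conflict,
                    noisep,
                    cond,
                    duration,
                    dt=config.dt,
                    keep_every=config.keep_every,
                    discard_s=config.discard_s,
                )
            )
        out[G] = runs
    return out
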