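"""Synthetic stand-in for the (undeposited) human light-touch dataset.

Generates a full pseudo-experiment with the study's design — 14 subjects,
nine haptic gains plus a no-touch condition, five 50-s trials per condition
at 120 Hz — so the whole downstream pipeline (metrics, statistics, fitting)
is testable without any download.  Sway comes from the closed-loop model;
hand force is synthesised by a minimal delayed linear coupling that
reproduces the three observed force facts (sub-1 N magnitude, moderate
positive force-position correlation below gain +1 with sign reversal at +2,
body preceding force by ~0.4-0.7 s).  No claim of grip mechanics is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .model_core import (
    STUDY_GAIN_GRID,
    BodyParams,
    GainCondition,
    ModelConfig,
    simulate_trial,
)
from .sway_metrics import TrialRecord

__all__ = [
    "ExperimentDesign",
    "ForceCouplingParams",
    "synth_hand_force",
    "generate_dataset",
    "NO_TOUCH",
]

#: Condition label for trials without manipulandum contact.
NO_TOUCH = "no_touch"


@dataclass(frozen=True)
class ExperimentDesign:
    """Study design template: who, what conditions, how long, how often."""

    n_subjects: int = 14
    gains: tuple = STUDY_GAIN_GRID
    include_no_touch: bool = True
    trials_per_condition: int = 5
    trial_s: float = 50.0
    fs: float = 120.0
    discard_s: float = 10.0
    device_lag: float = 0.060
    master_seed: int = 0
    body_jitter_sd: float = 0.05  # log-normal sigma: ~ +/-10% at 2 sigma
    noise_jitter_sd: float = 0.10  # ~ +/-20% at 2 sigma

    @property
    def n_conditions(self) -> int:
        return len(self.gains) + (1 if self.include_no_touch else 0)

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * self.n_conditions * self.trials_per_condition

    def condition_labels(self) -> list[str]:
        labels = [format_gain(g) for g in self.gains]
        if self.include_no_touch:
            labels.append(NO_TOUCH)
        return labels


def format_gain(g: float) -> str:
    """Canonical condition label for a gain value ('-0.5', '2', ...)."""
    return f"{g:g}"


@dataclass(frozen=True)
class ForceCouplingParams:
    """Delayed linear hand-force model.

    AP force = -stiffness x (hand-body displacement, delayed by ``lag_s``)
    plus a static baseline contact vector and low-pass noise.  Off-axis
    components carry baseline + noise only.  Defaults keep trial-mean |F|
    well under 1 N for millimetre-scale sway.
    """

    stiffness: float = 8.0  # N/m
    lag_s: float = 0.55  # within the 0.4-0.7 s band
    baseline: float = 0.4  # N, magnitude of the static contact vector
    noise_sd: float = 0.05  # N per component
    noise_tau: float = 0.05  # s, low-pass constant of the force noise

    def __post_init__(self):
        if self.lag_s <= 0:
            raise ConfigurationError("lag_s must be > 0")
        if self.stiffness < 0 or self.baseline < 0 or self.noise_sd < 0:
            raise ConfigurationError("stiffness, baseline, noise_sd must be >= 0")


# unit vector of the static contact force (hand pushes slightly forward,
# inward and down onto the ball of the manipulandum)
_BASELINE_DIR = np.array([0.5, 0.5, -np.sqrt(0.5)])


def _filtered_noise(n: int, fs: float, sd: float, tau: float, rng) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to the requested sd."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    a = np.exp(-1.0 / (fs * tau))
    y = signal.lfilter([1 - a], [1, -a], w)
    std = y.std()
    return y * (sd / std) if std > 0 else y


def _delay_samples(x: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples, holding the initial value at the edge."""
    if k >= x.size:
        raise ConfigurationError("lag exceeds series duration")
    out = np.empty_like(x)
    out[:k] = x[0]
    out[k:] = x[: x.size - k]
    return out


def synth_hand_force(
    rel_disp: np.ndarray,
    force: ForceCouplingParams,
    fs: float,
    seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesise (Fx, Fy, Fz) from relative hand-body displacement.

    ``rel_disp`` is x_robot - x_trunk (m); Fx is the AP component carrying
    the delayed elastic coupling; Fy, Fz carry baseline + noise only.
    """
    rel_disp = np.asarray(rel_disp, dtype=float)
    k = int(round(force.lag_s * fs))
    rng = np.random.default_rng(seed)
    base = force.baseline * _BASELINE_DIR
    coupled = -force.stiffness * _delay_samples(rel_disp, k)
    n = rel_disp.size
    Fx = base[0] + coupled + _filtered_noise(n, fs, force.noise_sd, force.noise_tau, rng)
    Fy = base[1] + _filtered_noise(n, fs, force.noise_sd, force.noise_tau, rng)
    Fz = base[2] + _filtered_noise(n, fs, force.noise_sd, force.noise_tau, rng)
    return Fx, Fy, Fz


def _trial_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit seed for one trial from the master seed."""
    return int(np.random.SeedSequence((master,) + key).generate_state(1)[0] % (2**31))


def generate_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    model: ModelConfig | None = None,
    force: ForceCouplingParams = ForceCouplingParams(),
) -> tuple[list[TrialRecord], dict]:
    """Simulate the full pseudo-experiment.

    Per subject, body size and noise gain are jittered log-normally around
    the defaults; per trial, sway is simulated at the trial's gain with the
    configured device lag (no-touch trials run with w_touch = 0), and hand
    forces are synthesised from the relative hand-body displacement.
    Byte-identical for a given ``design.master_seed``.  Returns the trial
    list and a manifest sufficient to regenerate the set.
    """
    model = model or ModelConfig()
    records: list[TrialRecord] = []
    subjects_meta = {}
    q = int(round(1.0 / (model.dt * design.fs)))  # decimation to sensor rate
    for si in range(design.n_subjects):
        subj = f"S{si + 1:02d}"
        rng = np.random.default_rng(
            np.random.SeedSequence((design.master_seed, si, 0xB0D1))
        )
        h = model.body.h * np.exp(design.body_jitter_sd * rng.standard_normal())
        m = model.body.m * np.exp(design.body_jitter_sd * rng.standard_normal())
        # inertia scales with m*h^2, keeping the default shape factor
        J = model.body.J * (m / model.body.m) * (h / model.body.h) ** 2
        k_noise = model.noise.k_noise * np.exp(
            design.noise_jitter_sd * rng.standard_normal()
        )
        body = BodyParams(h=h, m=m, J=J)
        # controller gains scale with the subject's toppling stiffness
        scale = body.mgh / model.body.mgh
        ctrl = replace(
            model.ctrl, Kp=model.ctrl.Kp * scale, Kd=model.ctrl.Kd * scale
        )
        subjects_meta[subj] = {
            "h": h,
            "m": m,
            "J": J,
            "k_noise": k_noise,
            "Kp": ctrl.Kp,
            "Kd": ctrl.Kd,
        }
        for ci, label in enumerate(design.condition_labels()):
            no_touch = label == NO_TOUCH
            G = 0.0 if no_touch else design.gains[ci]
            for ti in range(design.trials_per_condition):
                seed = _trial_seed(design.master_seed, si, ci, ti)
                noisep = replace(model.noise, k_noise=k_noise, seed=seed)
                ctrl_t = replace(ctrl, w_touch=0.0) if no_touch else ctrl
                trace = simulate_trial(
                    body,
                    ctrl_t,
                    model.conflict,
                    noisep,
                    GainCondition(G=G, device_lag=design.device_lag),
                    design.trial_s,
                    dt=model.dt,
                    keep_every=q,
                    discard_s=design.discard_s,
                    check_stability=False,
                )
                x_trunk = trace.x_body
                x_robot = np.zeros_like(x_trunk) if no_touch else trace.x_robot
                # no-touch: nobody holds the sensor, so no elastic coupling
                rel = np.zeros_like(x_trunk) if no_touch else x_robot - x_trunk
                Fx, Fy, Fz = synth_hand_force(
                    rel, force, design.fs, _trial_seed(design.master_seed, si, ci, ti, 0xF)
                )
                records.append(
                    TrialRecord(
                        t=trace.t.copy(),
                        x_trunk=x_trunk,
                        x_robot=x_robot,
                        Fx=Fx,
                        Fy=Fy,
                        Fz=Fz,
                        fs=design.fs,
                        subject=subj,
                        condition=label,
                        trial=ti + 1,
                        discard_s=design.discard_s,
                    )
                )
    manifest = {
        "design": {
            "n_subjects": design.n_subjects,
            "gains": list(design.gains),
            "include_no_touch": design.include_no_touch,
            "trials_per_condition": design.trials_per_condition,
            "trial_s": design.trial_s,
            "fs": design.fs,
            "discard_s": design.discard_s,
            "device_lag": design.device_lag,
            "master_seed": design.master_seed,
            "body_jitter_sd": design.body_jitter_sd,
            "noise_jitter_sd": design.noise_jitter_sd,
        },
        "model": model.to_dict(),
        "force": {
            "stiffness": force.stiffness,
            "lag_s": force.lag_s,
            "baseline": force.baseline,
            "noise_sd": force.noise_sd,
            "noise_tau": force.noise_tau,
        },
        "subjects": subjects_meta,
    }
    return records, manifest
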