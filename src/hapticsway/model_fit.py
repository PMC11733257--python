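"""Fitting the model's free parameters to sway velocity spectra.

Three parameters are free: the noise gain, the noise low-pass filter
constant and the conflict threshold Te.  The objective is the squared
difference between target and simulated mean velocity spectra, weighted by
1/f and summed over the 0.025-4 Hz band and over all haptic gain
conditions.  The same noise realisation (fixed seed) is reused at every
objective evaluation so the objective is deterministic and a standard
trust-region least-squares optimiser converges; positivity is enforced by
searching in log-parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitError
from .model_core import (
    STUDY_GAIN_GRID,
    GainCondition,
    ModelConfig,
    SimTrace,
    simulate_trial,
)
from .sway_metrics import BAND, Spectrum, lowpass_then_differentiate, segmented_psd

__all__ = [
    "FitResult",
    "velocity_spectrum",
    "simulate_velocity_spectra",
    "spectral_objective",
    "fit_parameters",
    "DEFAULT_BOUNDS",
]

#: Log-space search bounds for (k_noise [rad], tau_noise [s], Te [rad/s]).
DEFAULT_BOUNDS = ((1e-4, 1.0), (0.05, 30.0), (1e-4, 1.0))

#: Residual fill-in when a simulation diverges: 1e3 x the largest target
#: PSD value, so the optimiser retreats from infeasible regions smoothly.
DIVERGENCE_PENALTY_FACTOR = 1e3


@dataclass
class FitResult:
    """Fitted parameters with convergence metadata."""

    k_noise_hat: float
    tau_noise_hat: float
    Te_hat: float
    objective: float
    n_evals: int
    starts: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    noise_seed: int = 0
    success: bool = True

    def params(self) -> tuple[float, float, float]:
        return (self.k_noise_hat, self.tau_noise_hat, self.Te_hat)

    def to_dict(self) -> dict:
        return {
            "k_noise_hat": self.k_noise_hat,
            "tau_noise_hat": self.tau_noise_hat,
            "Te_hat": self.Te_hat,
            "objective": self.objective,
            "n_evals": self.n_evals,
            "noise_seed": self.noise_seed,
            "success": self.success,
            "starts": [
                {"start": list(s), "converged_to": list(c)} for s, c in self.starts
            ],
        }


def velocity_spectrum(trace: SimTrace) -> Spectrum:
    """Velocity PSD of a simulated trace via the empirical pipeline.

    The trace (already decimated to the sensor rate) is converted to AP
    position, the discard window dropped, then low-pass filtered,
    differentiated and fed to the segmented periodogram — identical
    processing to recorded trials, so model and data spectra are
    like-for-like.
    """
    sl = trace.analysis_slice()
    x = trace.x_body[sl]
    v = lowpass_then_differentiate(x, trace.fs)
    return segmented_psd(v, trace.fs)


def simulate_velocity_spectra(
    config: ModelConfig,
    seed: int,
    gains: Sequence[float] = STUDY_GAIN_GRID,
    duration: float | None = None,
) -> tuple[dict[float, Spectrum], dict[float, bool]]:
    """Mean velocity spectrum per gain, one independent noise realisation
    per gain condition (seeds derived deterministically from ``seed``), as
    in the experiment where every condition's trials carry independent
    sway noise.  Independence across gains is what lets the spectral
    objective average Monte-Carlo error over conditions.

    Returns (spectra, diverged-flags); a diverged run yields no spectrum
    (None entry) and its flag set.
    """
    duration = duration if duration is not None else config.duration
    spectra: dict[float, Spectrum] = {}
    diverged: dict[float, bool] = {}
    for G in gains:
        # per-gain stream keyed by the gain value itself (order-independent)
        gain_key = int(round(G * 1000)) % (2**32)
        gain_seed = int(
            np.random.SeedSequence((int(seed), gain_key)).generate_state(1)[0]
            % (2**31)
        )
        noisep = replace(config.noise, seed=gain_seed)
        trace = simulate_trial(
            config.body,
            config.ctrl,
            config.conflict,
            noisep,
            GainCondition(G=G, device_lag=config.device_lag),
            duration,
            dt=config.dt,
            keep_every=config.keep_every,
            discard_s=config.discard_s,
        )
        diverged[G] = trace.diverged
        if trace.diverged:
            spectra[G] = None
        else:
            spectra[G] = velocity_spectrum(trace)
    return spectra, diverged


def _band_mask(f: np.ndarray) -> np.ndarray:
    return (f >= BAND[0] - 1e-12) & (f <= BAND[1] + 1e-12)


def spectral_objective(
    params: Sequence[float],
    target: Mapping[float, Spectrum],
    sim_config: ModelConfig,
    seed: int,
    duration: float | None = None,
) -> tuple[np.ndarray, float]:
    """Residual vector and scalar objective at (k_noise, tau_noise, Te).

    Residuals r(g, f) = sqrt(1/f) * (S_target(g, f) - S_sim(g, f)) stacked
    over the in-band frequencies of every gain condition; the scalar is
    sum(r^2), i.e. the 1/f-weighted squared spectral difference summed
    across frequencies and gains.  Deterministic given (params, seed).
    """
    k_noise, tau_noise, Te = (float(p) for p in params)
    cfg = replace(
        sim_config,
        noise=replace(sim_config.noise, k_noise=k_noise, tau_noise=tau_noise),
        conflict=replace(sim_config.conflict, Te=Te),
    )
    gains = sorted(target.keys())
    sim_spec, diverged = simulate_velocity_spectra(cfg, seed, gains, duration)
    penalty = DIVERGENCE_PENALTY_FACTOR * max(
        float(np.max(target[g].S)) for g in gains
    )
    chunks = []
    for g in gains:
        tgt = target[g]
        mask = _band_mask(tgt.f)
        f = tgt.f[mask]
        if diverged[g]:
            chunks.append(np.full(mask.sum(), penalty))
            continue
        sim = sim_spec[g]
        if len(sim.f) != len(tgt.f) or not np.allclose(sim.f, tgt.f):
            raise ConfigurationError(
                "target spectra are not on the simulation frequency grid"
            )
        chunks.append(np.sqrt(1.0 / f) * (tgt.S[mask] - sim.S[mask]))
    r = np.concatenate(chunks)
    return r, float(np.dot(r, r))


def fit_parameters(
    target: Mapping[float, Spectrum],
    starts: Sequence[Sequence[float]],
    sim_config: ModelConfig,
    seed: int,
    duration: float | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    max_nfev: int | None = 60,
    ftol: float = 1e-6,
    xtol: float = 1e-6,
) -> FitResult:
    """Trust-region nonlinear least squares from each start; best kept.

    The search runs in log-parameter space within ``bounds`` (positivity by
    construction).  Every start's (start, converged-to) pair is recorded so
    multi-start basin agreement is reportable.  Termination tolerances
    default to 1e-6 — far below the parameter precision the Monte-Carlo
    floor of a finite-duration objective supports, while stopping the
    optimiser from grinding against that floor (tighten them for long-
    duration, multi-realisation fits).
    """
    if not starts:
        raise ConfigurationError("at least one start is required")
    lo = np.log([b[0] for b in bounds])
    hi = np.log([b[1] for b in bounds])
    n_evals = 0

    def resid(logp):
        nonlocal n_evals
        n_evals += 1
        r, _ = spectral_objective(np.exp(logp), target, sim_config, seed, duration)
        return r

    best = None
    records = []
    failures = []
    for start in starts:
        x0 = np.clip(np.log(np.asarray(start, dtype=float)), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                x_scale="jac", max_nfev=max_nfev, ftol=ftol, xtol=xtol,
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append((tuple(start), repr(exc)))
            continue
        params = tuple(np.exp(sol.x))
        records.append((tuple(float(s) for s in start), params))
        if best is None or sol.cost < best[0]:
            best = (sol.cost, params, sol)
    if best is None:
        raise FitError(f"all starts failed to converge: {failures}")
    _, params, sol = best
    return FitResult(
        k_noise_hat=params[0],
        tau_noise_hat=params[1],
        Te_hat=params[2],
        objective=float(2.0 * sol.cost),  # least_squares cost = 0.5 * sum r^2
        n_evals=n_evals,
        starts=records,
        noise_seed=int(seed),
        success=bool(sol.success),
    )
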