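"""Empirical sway analysis pipeline.

Filtering and differentiation of position traces, segmented power spectral
densities with band integration, hand-force magnitude, and unbiased
normalised cross-correlation with peak extraction.  All operations work on
plain position series in SI units; model traces are converted from angle to
position (x = h*theta) at the comparison boundary, never inside here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .errors import ConfigurationError, UndefinedCorrelationError

__all__ = [
    "TrialRecord",
    "Spectrum",
    "XcorrResult",
    "lowpass_then_differentiate",
    "segmented_psd",
    "average_spectra",
    "integrate_spectrum",
    "force_magnitude",
    "xcorr_unbiased",
    "peak_xcorr",
]

#: Analysis band (Hz) over which PSDs are integrated.
BAND = (0.025, 4.0)

#: Segment length (s) used for all spectral estimates; sets the 0.025-Hz grid.
SEGMENT_S = 40.0


@dataclass
class TrialRecord:
    """One experimental (or synthetic) trial sampled at fs = 120 Hz.

    ``x_trunk``/``x_robot`` are AP positions in m; ``Fx`` is the AP hand
    force component, ``Fy`` lateral, ``Fz`` vertical (N).  The first
    ``discard_s`` seconds are excluded from analysis.
    """

    t: np.ndarray
    x_trunk: np.ndarray
    x_robot: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    fs: float = 120.0
    subject: str = ""
    condition: str = ""
    trial: int = 0
    discard_s: float = 10.0

    def analysis_slice(self) -> slice:
        return slice(int(round(self.discard_s * self.fs)), None)

    def __post_init__(self):
        n = len(self.t)
        for name in ("x_trunk", "x_robot", "Fx", "Fy", "Fz"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"column {name} length != t length")


@dataclass
class Spectrum:
    """One-sided PSD on a uniform grid (Delta f = 1/segment length)."""

    f: np.ndarray
    S: np.ndarray
    n_segments: int = 1

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0]) if len(self.f) > 1 else float(self.f[0])


@dataclass
class XcorrResult:
    """Unbiased normalised cross-correlation over symmetric lags.

    Positive lag means the first signal precedes the second.
    """

    lags: np.ndarray
    R: np.ndarray
    peak_R: float = field(default=np.nan)
    peak_lag: float = field(default=np.nan)


def lowpass_then_differentiate(
    x: np.ndarray, fs: float, fc: float = 5.0, order: int = 2, zero_phase: bool = True
) -> np.ndarray:
    """Velocity from position: low-pass Butterworth, then central difference.

    The filter is the 2nd-order 5-Hz Butterworth applied zero-phase
    (forward-backward) by default, so no phase lag contaminates velocity
    spectra; set ``zero_phase=False`` for the causal single pass.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ConfigurationError("series must have at least 3 samples")
    if fs <= 2 * fc:
        raise ConfigurationError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)
    return np.gradient(xf, 1.0 / fs)


def butter_frequency_response(f, fs: float, fc: float = 5.0, order: int = 2,
                              zero_phase: bool = True) -> np.ndarray:
    """|H(f)| of the filter above (squared magnitude when zero-phase)."""
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    _, H = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(f, float) / fs)
    mag = np.abs(H)
    return mag**2 if zero_phase else mag


def segmented_psd(
    x: np.ndarray, fs: float, segment_s: float = SEGMENT_S, t: Optional[np.ndarray] = None
) -> Spectrum:
    """Mean-removed rectangular periodogram per segment, averaged.

    The series is cut into non-overlapping ``segment_s`` pieces (40 s at
    120 Hz gives the 0.025-Hz grid); each segment is demeaned and its
    one-sided periodogram computed; segments are averaged.  Satisfies
    Parseval per segment: sum(S)*df = segment variance.
    """
    x = np.asarray(x, dtype=float)
    if t is not None:
        dts = np.diff(np.asarray(t, float))
        if dts.size and (np.max(dts) - np.min(dts)) > 1e-9:
            raise ConfigurationError("non-uniform sampling")
    nper = int(round(segment_s * fs))
    n_seg = x.size // nper
    if n_seg < 1:
        raise ConfigurationError(
            f"series too short for one {segment_s}-s segment at fs={fs}"
        )
    segs = x[: n_seg * nper].reshape(n_seg, nper)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs, axis=1)
    # one-sided PSD: 2|X|^2/(fs*N), DC and Nyquist unduplicated
    S = (np.abs(spec) ** 2) / (fs * nper)
    S[:, 1:] *= 2.0
    if nper % 2 == 0:
        S[:, -1] /= 2.0
    f = np.fft.rfftfreq(nper, d=1.0 / fs)
    # drop the (demeaned, zero) DC bin: the grid starts at Delta f
    return Spectrum(f=f[1:], S=S.mean(axis=0)[1:], n_segments=n_seg)


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Average spectra sharing one grid, weighting by segment counts."""
    if not spectra:
        raise ConfigurationError("no spectra to average")
    f0 = spectra[0].f
    for s in spectra[1:]:
        if len(s.f) != len(f0) or not np.allclose(s.f, f0):
            raise ConfigurationError("spectra are on different frequency grids")
    w = np.array([s.n_segments for s in spectra], dtype=float)
    S = np.sum([s.S * wi for s, wi in zip(spectra, w)], axis=0) / w.sum()
    return Spectrum(f=f0.copy(), S=S, n_segments=int(w.sum()))


def integrate_spectrum(spec: Spectrum, fmin: float = BAND[0], fmax: float = BAND[1]) -> float:
    """Band power: sum of S over bins in the closed band, times Delta f."""
    mask = (spec.f >= fmin - 1e-12) & (spec.f <= fmax + 1e-12)
    if not np.any(mask):
        raise ConfigurationError("integration band contains no bins")
    return float(np.sum(spec.S[mask]) * spec.df)


def force_magnitude(Fx, Fy, Fz):
    """Elementwise |F| = sqrt(Fx^2+Fy^2+Fz^2) and its mean over the series."""
    Fx, Fy, Fz = (np.asarray(a, dtype=float) for a in (Fx, Fy, Fz))
    if not (Fx.shape == Fy.shape == Fz.shape):
        raise ConfigurationError("force components must have equal length")
    mag = np.sqrt(Fx**2 + Fy**2 + Fz**2)
    return mag, float(mag.mean())


def xcorr_unbiased(x, y, fs: float, maxlag: float = 10.0) -> XcorrResult:
    """Unbiased normalised cross-correlation of two equal-length series.

    R(tau) = [sum_t x(t) y(t+tau) / (N - |k|)] / (sigma_x sigma_y), both
    series demeaned internally; positive lag = x precedes y.  The unbiased
    1/(N-|k|) edge factor can push |R| marginally above 1 at extreme lags.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("series must have equal length")
    n = x.size
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero-variance input")
    xd, yd = x - x.mean(), y - y.mean()
    maxk = min(int(round(maxlag * fs)), n - 1)
    # full correlation: c[k] = sum_t xd[t] * yd[t+k], k = -(n-1)..(n-1)
    c = signal.correlate(yd, xd, mode="full", method="fft")
    ks = np.arange(-maxk, maxk + 1)
    mid = n - 1
    c = c[mid + ks[0] : mid + ks[-1] + 1]
    R = c / ((n - np.abs(ks)) * sx * sy)
    res = XcorrResult(lags=ks / fs, R=R)
    res.peak_R, res.peak_lag = peak_xcorr(res)
    return res


def peak_xcorr(r: XcorrResult) -> tuple[float, float]:
    """Signed R at the extremum of |R|; ties go to the smallest |lag|,
    then to the positive lag."""
    absR = np.abs(r.R)
    best = np.max(absR)
    cand = np.flatnonzero(absR >= best - 1e-15)
    # tie-break: smallest |lag|, then positive lag
    order = np.lexsort((-np.sign(r.lags[cand]), np.abs(r.lags[cand])))
    idx = cand[order[0]]
    return float(r.R[idx]), float(r.lags[idx])
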