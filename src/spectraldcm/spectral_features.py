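"""Windowed spectral data features.

Sliding-window Fourier summaries, the k x k window-by-window correlation
matrix of band power ("delay-delay" matrix), and windowed multivariate
autoregressive (MAR) complex cross-spectral densities with an eigenmode
summary.

Conventions: `sliding_spectra` reports Fourier amplitude per window and
channel; `mar_csd` reports per-sample cross-spectral density
S(f) = H(f) Sigma H(f)^H, i.e. for a univariate AR(1) with coefficient a
and innovation variance s2 the auto-spectrum is s2 / |1 - a e^{-i2pi f/fs}|^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.signal

from .errors import ConditioningError, ParameterError
from .neural_mass import CrossSpectrum, FrequencyGrid

__all__ = [
    "WindowingScheme",
    "SpectralSeries",
    "sliding_spectra",
    "power_corr_matrix",
    "mar_csd",
    "windowed_mar_csd",
    "eigenmode_summary",
    "window_count",
]


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window geometry in seconds."""

    length_s: float
    step_s: float

    def __post_init__(self):
        if self.length_s <= 0 or self.step_s <= 0:
            raise ParameterError("window length and step must be positive")
        if self.step_s > self.length_s:
            raise ParameterError("step_s must not exceed length_s")

    def n_windows(self, duration_s: float) -> int:
        if duration_s < self.length_s:
            raise ParameterError(
                f"recording of {duration_s}s shorter than one "
                f"{self.length_s}s window"
            )
        return int(np.floor((duration_s - self.length_s) / self.step_s)) + 1

    def sample_slices(self, n_samples: int, fs: float) -> list[slice]:
        n_len = int(round(self.length_s * fs))
        n_step = int(round(self.step_s * fs))
        if n_samples < n_len:
            raise ParameterError(
                f"recording of {n_samples} samples shorter than one window "
                f"({n_len} samples)"
            )
        k = (n_samples - n_len) // n_step + 1
        return [slice(i * n_step, i * n_step + n_len) for i in range(k)]


def window_count(duration_s: float, length_s: float, step_s: float) -> int:
    """k = floor((T - length)/step) + 1."""
    return WindowingScheme(length_s, step_s).n_windows(duration_s)


@dataclass(frozen=True)
class SpectralSeries:
    """Per-window, per-channel Fourier amplitude over 0..fs/2."""

    window_times: np.ndarray  # (k,) window-centre times in s
    frequencies: np.ndarray   # (F,) Hz
    amplitude: np.ndarray     # (k, n_channels, F)

    @property
    def n_windows(self) -> int:
        return self.window_times.size

    @property
    def n_channels(self) -> int:
        return self.amplitude.shape[1]


def sliding_spectra(
    x: np.ndarray, fs: float, w: WindowingScheme, detrend: bool = False
) -> SpectralSeries:
    """Windowed Fourier amplitude of a multichannel series (channels x samples)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    slices = w.sample_slices(x.shape[1], fs)
    n_len = slices[0].stop - slices[0].start
    freqs = np.fft.rfftfreq(n_len, d=1.0 / fs)
    amp = np.empty((len(slices), x.shape[0], freqs.size))
    times = np.empty(len(slices))
    for k, sl in enumerate(slices):
        seg = x[:, sl]
        if detrend:
            seg = scipy.signal.detrend(seg, axis=1)
        amp[k] = np.abs(np.fft.rfft(seg, axis=1)) * (2.0 / n_len)
        times[k] = (sl.start + 0.5 * n_len) / fs
    return SpectralSeries(window_times=times, frequencies=freqs, amplitude=amp)


def power_corr_matrix(
    s: SpectralSeries,
    band_hz: tuple[float, float] = (0.0, 10.0),
    per_frequency: bool = False,
) -> np.ndarray:
    """k x k Pearson correlation of per-window band-power vectors.

    Each window is summarised by its per-channel mean power over
    ``band_hz`` (power = amplitude squared); with ``per_frequency=True``
    the frequency-resolved per-channel powers are concatenated instead.
    Windows whose power vector has zero variance are marked with NaN in
    their row/column (diagonal stays 1) rather than propagating NaN.
    """
    if s.n_windows < 2:
        raise ParameterError("need at least 2 windows for a correlation matrix")
    lo, hi = band_hz
    sel = (s.frequencies >= lo) & (s.frequencies <= hi)
    power = s.amplitude[:, :, sel] ** 2
    if per_frequency:
        vectors = power.reshape(s.n_windows, -1)
    else:
        vectors = power.mean(axis=2)
    degenerate = vectors.std(axis=1) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vectors)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0, out=corr)


def _fit_mar(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares MAR fit. x: (n_channels, n_samples).

    Returns (A, Sigma): A is (order, n, n) with x_t = sum_l A_l x_{t-l} + e_t,
    Sigma the innovation covariance.
    """
    n, T = x.shape
    if T < 10 * order * n:
        raise ParameterError(
            f"segment of {T} samples too short for MAR order {order} with "
            f"{n} channels (need >= {10 * order * n})"
        )
    sd = x.std(axis=1)
    if np.any(sd == 0.0):
        bad = int(np.argmin(sd))
        raise ConditioningError(
            f"channel {bad} is constant: MAR regression is rank deficient"
        )
    Y = x[:, order:].T  # (T-order, n)
    Z = np.hstack([x[:, order - l : T - l].T for l in range(1, order + 1)])
    # guard against hidden collinearity beyond the constant-channel case
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise ConditioningError(
            f"MAR regressor matrix is rank deficient ({rank} < {Z.shape[1]})"
        )
    coef, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ coef
    sigma = resid.T @ resid / max(1, Y.shape[0] - Z.shape[1])
    A = coef.T.reshape(n, order, n).transpose(1, 0, 2)
    return A, sigma


def mar_csd(
    x_window: np.ndarray,
    fs: float,
    order: int,
    grid: FrequencyGrid,
    detrend: bool = True,
) -> CrossSpectrum:
    """Cross-spectral density of one segment from a MAR model.

    The segment is mean-removed and linearly detrended (unless disabled)
    before the autoregression. S(f) = H(f) Sigma H(f)^H with
    H(f) = (I - sum_l A_l e^{-i 2 pi f l / fs})^{-1}.
    """
    x = np.atleast_2d(np.asarray(x_window, dtype=float))
    if detrend:
        x = scipy.signal.detrend(x, axis=1, type="linear")
        x = scipy.signal.detrend(x, axis=1, type="constant")
    A, sigma = _fit_mar(x, order)
    n = x.shape[0]
    freqs = grid.frequencies
    if freqs.max() > fs / 2.0 + 1e-9:
        raise ParameterError(
            f"grid maximum {freqs.max()} Hz exceeds Nyquist {fs / 2} Hz"
        )
    out = np.empty((freqs.size, n, n), dtype=complex)
    lags = np.arange(1, order + 1)
    eye = np.eye(n)
    for k, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * lags / fs)  # (order,)
        Af = eye - np.tensordot(phase, A, axes=(0, 0))
        H = np.linalg.inv(Af)
        S = H @ sigma @ H.conj().T
        out[k] = 0.5 * (S + S.conj().T)
    return CrossSpectrum(grid=grid, csd=out)


def windowed_mar_csd(
    x: np.ndarray,
    fs: float,
    scheme: WindowingScheme,
    order: int,
    grid: FrequencyGrid,
) -> tuple[np.ndarray, list[CrossSpectrum]]:
    """MAR cross-spectra for every sliding window of a recording.

    Returns window-centre times and a list of per-window CrossSpectrum.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    slices = scheme.sample_slices(x.shape[1], fs)
    n_len = slices[0].stop - slices[0].start
    times = np.array([(sl.start + 0.5 * n_len) / fs for sl in slices])
    spectra = [mar_csd(x[:, sl], fs, order, grid) for sl in slices]
    return times, spectra


def eigenmode_summary(
    spectra: Sequence[CrossSpectrum],
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant spectral mode per window.

    For each window the channel-space matrix (cross-spectra integrated over
    frequency, real part) is eigendecomposed; the mode is the leading
    eigenvector's projected spectrum and the weights are the unit-norm
    eigenvector with its largest-magnitude entry made positive.

    Returns (modes, weights): modes is (k, F) real, weights (k, n_channels).
    """
    if len(spectra) == 0:
        raise ParameterError("need at least one window")
    modes, weights = [], []
    for S in spectra:
        M = np.trapezoid(S.csd.real, x=S.grid.frequencies, axis=0)
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        pivot = np.argmax(np.abs(w))
        if w[pivot] < 0:
            w = -w
        mode = np.einsum("i,fij,j->f", w, S.csd, w).real
        modes.append(mode)
        weights.append(w)
    return np.asarray(modes), np.asarray(weights)
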