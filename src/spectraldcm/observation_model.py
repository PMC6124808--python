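"""Calcium-indicator observation model.

Builds the composite indicator response kernel -- an inverted quadratic
rise of duration ``t_up`` joined to an exponential decay, each branch
normalised so the kernel equals 1 at the end of the rise -- convolves
simulated population signals with it, and resamples to the imaging rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .config import load_defaults
from .errors import ParameterError

__all__ = [
    "KernelSpec",
    "build_kernel",
    "apply_kernel",
    "convolve_kernel",
    "observation_power_transfer",
]


@dataclass(frozen=True)
class KernelSpec:
    """Sampling specification for the indicator kernel (times in ms)."""

    t_up: float = 250.0
    tau_decay: float = 1000.0
    dt_ms: float = 1.0
    length_ms: float = 5500.0

    def __post_init__(self):
        if not (self.t_up > 0 and self.tau_decay > 0 and self.dt_ms > 0):
            raise ParameterError("t_up, tau_decay and dt_ms must be positive")
        if self.length_ms < self.t_up + 5.0 * self.tau_decay:
            raise ParameterError(
                "length_ms must cover the rise plus five decay constants "
                f"(>= {self.t_up + 5 * self.tau_decay} ms)"
            )

    @classmethod
    def from_config(cls, config: dict | None = None) -> "KernelSpec":
        cfg = (config or load_defaults())["observation_model"]
        return cls(
            t_up=float(cfg["t_up_ms"]),
            tau_decay=float(cfg["tau_decay_ms"]),
            dt_ms=float(cfg["dt_ms"]),
            length_ms=float(cfg["length_ms"]),
        )


def build_kernel(spec: KernelSpec) -> np.ndarray:
    """Sample the composite rise/decay kernel on the spec's time grid.

    Rise branch (0 <= t <= t_up): y(t) = 2*t*t_up - t^2, normalised by its
    value at t_up; decay branch (t > t_up): exp(-(t - t_up)/tau_decay).
    Both branches equal exactly 1 at t = t_up.
    """
    if spec.dt_ms > spec.t_up:
        raise ParameterError(
            f"dt_ms={spec.dt_ms} coarser than the rise time {spec.t_up} ms: "
            "kernel rise unresolvable"
        )
    t = np.arange(0.0, spec.length_ms + 0.5 * spec.dt_ms, spec.dt_ms)
    y = np.empty_like(t)
    rising = t <= spec.t_up
    y[rising] = (2.0 * t[rising] * spec.t_up - t[rising] ** 2) / spec.t_up**2
    y[~rising] = np.exp(-(t[~rising] - spec.t_up) / spec.tau_decay)
    return y


def convolve_kernel(x: np.ndarray, fs_in: float, spec: KernelSpec) -> np.ndarray:
    """Convolve multichannel rows of ``x`` with the kernel at rate ``fs_in``.

    Full convolution truncated to the input length; the first kernel-length
    worth of samples is transient (callers treating edges as burn-in should
    drop ``n_burn_samples(spec, fs_in)``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    kspec = KernelSpec(spec.t_up, spec.tau_decay, 1000.0 / fs_in, spec.length_ms)
    k = build_kernel(kspec)
    out = scipy.signal.fftconvolve(x, k[None, :], mode="full", axes=1)
    return out[:, : x.shape[1]]


def observation_power_transfer(
    frequencies: np.ndarray,
    spec: KernelSpec,
    fs_in: float = 1000.0,
    fs_out: float | None = None,
    antialias_frac: float = 0.9,
) -> np.ndarray:
    """Power transfer |H(f)|^2 of the observation chain at given frequencies.

    Combines the indicator kernel's magnitude response with the zero-phase
    anti-alias filter applied before decimation (if ``fs_out`` is given).
    The absolute scale is arbitrary -- it is normalised to 1 at the lowest
    requested frequency, since inversions rescale data anyway.
    """
    f = np.asarray(frequencies, dtype=float)
    kspec = KernelSpec(spec.t_up, spec.tau_decay, 1000.0 / fs_in, spec.length_ms)
    k = build_kernel(kspec)
    n_fft = max(1 << 18, 4 * k.size)
    K = np.abs(np.fft.rfft(k, n_fft)) ** 2
    fk = np.fft.rfftfreq(n_fft, 1.0 / fs_in)
    h = np.interp(f, fk, K)
    if fs_out is not None and fs_out < fs_in:
        q = int(round(fs_in / fs_out))
        cutoff = antialias_frac * (fs_out / 2.0)
        fir = scipy.signal.firwin(4 * q * 10 + 1, cutoff, fs=fs_in)
        _, resp = scipy.signal.freqz(fir, worN=f, fs=fs_in)
        h = h * np.abs(resp) ** 4  # filtfilt applies the FIR twice
    return h / h[0]


def n_burn_samples(spec: KernelSpec, fs: float) -> int:
    """Number of leading convolution-transient samples at rate ``fs``."""
    return int(np.ceil(spec.length_ms / 1000.0 * fs))


def apply_kernel(
    x: np.ndarray,
    fs_in: float,
    spec: KernelSpec,
    fs_out: float,
    antialias_frac: float = 0.9,
) -> np.ndarray:
    """Kernel-convolve then downsample to the imaging rate.

    The convolution runs at ``fs_in``; before decimation the signal is
    low-pass filtered (zero-phase FIR, cutoff ``antialias_frac`` times the
    output Nyquist). Output length is floor(input_duration * fs_out).
    When ``fs_out == fs_in`` no resampling or filtering is applied, which
    exposes the raw convolution (impulse in -> kernel shape out).
    """
    if fs_out > fs_in:
        raise ParameterError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if fs_out == fs_in:
        return convolve_kernel(x, fs_in, spec)
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ParameterError(
            f"fs_in/fs_out must be an integer decimation factor, got {q}"
        )
    q = int(round(q))
    cutoff = antialias_frac * (fs_out / 2.0)
    ntaps = 4 * q * 10 + 1
    fir = scipy.signal.firwin(ntaps, cutoff, fs=fs_in)
    # fuse the indicator kernel with the zero-phase (forward-backward)
    # anti-alias response and decimate polyphase: only every q-th output
    # sample of the full-rate convolution is ever computed
    kspec = KernelSpec(spec.t_up, spec.tau_decay, 1000.0 / fs_in, spec.length_ms)
    k = build_kernel(kspec)
    comb = np.convolve(k, np.convolve(fir, fir[::-1]))
    dec = scipy.signal.upfirdn(comb, x, up=1, down=q, axis=1)
    offset = (ntaps - 1) // q  # zero-phase group delay; ntaps-1 = 40 q
    n_out = int(np.floor(x.shape[1] / fs_in * fs_out))
    return dec[:, offset : offset + n_out]
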