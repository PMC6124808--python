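"""Three-population neural mass sources and coupled-network spectra.

Each regional "source" is a mean-field microcircuit of three populations:
a projection population (P), an excitatory interneuron population (E) and
an inhibitory interneuron population (I). Population firing is a sigmoid
(tanh) of membrane potential; membrane responses are second-order linear
synaptic kernels normalised to unit DC gain, with excitatory post-synaptic
compartments sharing the time constant T_E and inhibitory ones T_I.

Five intrinsic connections parameterise the microcircuit:

    H1 : P -> E   (excitatory)
    H2 : E -> P   (excitatory)
    H3 : P -> I   (excitatory)
    H4 : I -> P   (inhibitory)
    H5 : I -> I   (inhibitory self-connection)

All free parameters are dimensionless log-scalings of fixed prior means,
so a value of 0 reproduces the prior-mean physical parameter exactly.
Sources are coupled by forward connections (targeting E, like ascending
drive) and backward connections (targeting P) between their projection
outputs. Exogenous input is one parameterised pink-noise stream per
source, entering E directly and, with a small fixed weight, the
projection population's inhibitory compartment -- the second route keeps
the input-path gain spectrally distinguishable from a plain amplitude
change.

The module provides a stochastic time-domain simulator (`simulate_lfp`)
and a linearised steady-state cross-spectral predictor (`transfer_csd`)
that are mutually consistent: the Welch spectrum of a long simulation
matches the analytic prediction for stable models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import scipy.optimize

from ._integrator import euler_core
from .config import load_defaults
from .errors import (
    InstabilityError,
    NonConvergenceError,
    ParameterError,
    StabilityError,
)

N_POP_STATES = 10  # five second-order synaptic compartments per source

__all__ = [
    "ModelConstants",
    "SourceParams",
    "NetworkModel",
    "FrequencyGrid",
    "CrossSpectrum",
    "PhysicalParams",
    "effective_params",
    "fixed_point",
    "simulate_lfp",
    "integrate_network",
    "transfer_csd",
    "single_source_model",
]


# ---------------------------------------------------------------------------
# constants and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConstants:
    """Fixed physical prior means shared by every source.

    These set the operating point of the model family; inference only ever
    sees log-deviations from them.
    """

    gain_means: tuple[float, ...] = (0.8, 0.6, 1.0, 1.0, 0.3)
    t_e_ms: float = 5.0
    t_i_ms: float = 24.0
    noise_amp: float = 0.02
    noise_exp: float = 1.0
    noise_f_floor_hz: float = 0.05
    noise_input_p: float = 0.3
    ext_gain_mean: float = 0.03
    blowup_abs: float = 1.0e6

    @classmethod
    def from_config(cls, config: dict | None = None) -> "ModelConstants":
        cfg = (config or load_defaults())["neural_mass"]
        return cls(
            gain_means=tuple(float(v) for v in cfg["gain_means"]),
            t_e_ms=float(cfg["t_e_ms"]),
            t_i_ms=float(cfg["t_i_ms"]),
            noise_amp=float(cfg["noise_amp"]),
            noise_exp=float(cfg["noise_exp"]),
            noise_f_floor_hz=float(cfg["noise_f_floor_hz"]),
            noise_input_p=float(cfg["noise_input_p"]),
            ext_gain_mean=float(cfg["ext_gain_mean"]),
            blowup_abs=float(cfg["blowup_abs"]),
        )


def _require_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        # -inf is allowed only on noise_amp (noise switched off)
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return arr


@dataclass(frozen=True)
class SourceParams:
    """Log-scaling parameters of one source (all dimensionless)."""

    h: np.ndarray = field(default_factory=lambda: np.zeros(5))
    t_e: float = 0.0
    t_i: float = 0.0
    noise_amp: float = 0.0
    noise_exp: float = 0.0

    def __post_init__(self):
        h = np.array(self.h, dtype=float).reshape(-1)
        if h.size != 5:
            raise ParameterError(f"h must have 5 entries, got {h.size}")
        _require_finite("h", h)
        h.setflags(write=False)
        object.__setattr__(self, "h", h)
        for name in ("t_e", "t_i", "noise_exp"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)
        amp = float(self.noise_amp)
        if np.isnan(amp) or amp == np.inf:
            raise ParameterError(f"noise_amp must be finite or -inf, got {amp}")
        object.__setattr__(self, "noise_amp", amp)

    def with_updates(self, **kwargs) -> "SourceParams":
        if "h" in kwargs:
            kwargs["h"] = np.asarray(kwargs["h"], dtype=float)
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhysicalParams:
    """Physical-parameter view of a source (gains a.u., times in ms)."""

    gains: np.ndarray
    t_e_ms: float
    t_i_ms: float
    noise_amp: float
    noise_exp: float


def effective_params(
    p: SourceParams, constants: ModelConstants | None = None
) -> PhysicalParams:
    """Map log-scalings to physical values: value_i = prior_mean_i * exp(p_i)."""
    c = constants or ModelConstants()
    return PhysicalParams(
        gains=np.asarray(c.gain_means) * np.exp(p.h),
        t_e_ms=c.t_e_ms * np.exp(p.t_e),
        t_i_ms=c.t_i_ms * np.exp(p.t_i),
        noise_amp=c.noise_amp * np.exp(p.noise_amp),
        noise_exp=c.noise_exp * np.exp(p.noise_exp),
    )


@dataclass(frozen=True)
class NetworkModel:
    """A set of sources plus masked extrinsic coupling (the architecture)."""

    sources: tuple[SourceParams, ...]
    a_fwd: np.ndarray | None = None
    a_bwd: np.ndarray | None = None
    mask_fwd: np.ndarray | None = None
    mask_bwd: np.ndarray | None = None
    lead: np.ndarray | None = None
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self):
        sources = tuple(self.sources)
        if not sources:
            raise ParameterError("a NetworkModel needs at least one source")
        object.__setattr__(self, "sources", sources)
        n = len(sources)
        for name, default in (
            ("a_fwd", 0.0), ("a_bwd", 0.0), ("mask_fwd", 0.0), ("mask_bwd", 0.0),
        ):
            m = getattr(self, name)
            m = np.full((n, n), default) if m is None else np.array(m, dtype=float)
            if m.shape != (n, n):
                raise ParameterError(f"{name} must be {n}x{n}, got {m.shape}")
            _require_finite(name, m)
            m.setflags(write=False)
            object.__setattr__(self, name, m)
        for name in ("mask_fwd", "mask_bwd"):
            m = getattr(self, name)
            if not np.all(np.isin(m, (0.0, 1.0))):
                raise ParameterError(f"{name} must be binary")
            if np.any(np.diag(m) != 0):
                raise ParameterError(f"{name} has extrinsic self-connections")
        lead = self.lead
        lead = np.ones(n) if lead is None else np.array(lead, dtype=float)
        if lead.shape != (n,):
            raise ParameterError(f"lead must have shape ({n},)")
        _require_finite("lead", lead)
        lead.setflags(write=False)
        object.__setattr__(self, "lead", lead)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def effective_extrinsic(self) -> tuple[np.ndarray, np.ndarray]:
        """Masked physical extrinsic gain matrices (forward, backward)."""
        c = self.constants
        return (
            c.ext_gain_mean * np.exp(self.a_fwd) * self.mask_fwd,
            c.ext_gain_mean * np.exp(self.a_bwd) * self.mask_bwd,
        )


def single_source_model(
    params: SourceParams | None = None,
    constants: ModelConstants | None = None,
) -> NetworkModel:
    """Convenience constructor for an uncoupled single-source model."""
    return NetworkModel(
        sources=(params or SourceParams(),),
        constants=constants or ModelConstants(),
    )


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.array(self.frequencies, dtype=float).reshape(-1)
        if f.size == 0:
            raise ParameterError("empty frequency grid")
        if np.any(f <= 0):
            raise ParameterError("frequencies must be strictly positive")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be strictly increasing")
        f.setflags(write=False)
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def regular(cls, f_min: float, f_max: float, step: float) -> "FrequencyGrid":
        n = int(round((f_max - f_min) / step)) + 1
        return cls(f_min + step * np.arange(n))

    @property
    def resolution(self) -> float:
        f = self.frequencies
        return float(np.median(np.diff(f))) if f.size > 1 else float(f[0])

    def __len__(self) -> int:
        return self.frequencies.size


HERMITIAN_TOL = 1e-10


@dataclass(frozen=True)
class CrossSpectrum:
    """Complex cross-spectral density matrices over a frequency grid."""

    grid: FrequencyGrid
    csd: np.ndarray  # (n_freq, n_channels, n_channels) complex

    def __post_init__(self):
        csd = np.array(self.csd, dtype=complex)
        if csd.ndim == 1:
            csd = csd[:, None, None]
        if csd.ndim != 3 or csd.shape[1] != csd.shape[2]:
            raise ParameterError(f"csd must be (F, n, n), got {csd.shape}")
        if csd.shape[0] != len(self.grid):
            raise ParameterError("csd frequency axis does not match grid")
        scale = max(1.0, float(np.abs(csd).max(initial=0.0)))
        if np.abs(csd - csd.conj().transpose(0, 2, 1)).max(initial=0.0) > HERMITIAN_TOL * scale:
            raise ParameterError("csd is not Hermitian at every frequency")
        diags = np.diagonal(csd, axis1=1, axis2=2)
        if np.any(diags.real < -HERMITIAN_TOL * scale):
            raise ParameterError("auto-spectra must be non-negative")
        # canonicalise: exactly Hermitian, real diagonal
        csd = 0.5 * (csd + csd.conj().transpose(0, 2, 1))
        ii = np.arange(csd.shape[1])
        csd[:, ii, ii] = np.clip(csd[:, ii, ii].real, 0.0, None)
        csd.setflags(write=False)
        object.__setattr__(self, "csd", csd)

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]

    def auto(self, channel: int) -> np.ndarray:
        """Real auto-spectrum of one channel."""
        return self.csd[:, channel, channel].real


# ---------------------------------------------------------------------------
# dynamics: drift, fixed point, linearisation
# ---------------------------------------------------------------------------

def _effective_arrays(m: NetworkModel):
    """Per-source effective parameter arrays in SI units."""
    n = m.n_sources
    g = np.empty((n, 5))
    te = np.empty(n)
    ti = np.empty(n)
    amp = np.empty(n)
    nexp = np.empty(n)
    for i, src in enumerate(m.sources):
        eff = effective_params(src, m.constants)
        g[i] = eff.gains
        te[i] = eff.t_e_ms / 1000.0
        ti[i] = eff.t_i_ms / 1000.0
        amp[i] = eff.noise_amp
        nexp[i] = eff.noise_exp
    afwd, abwd = m.effective_extrinsic()
    return g, te, ti, amp, nexp, afwd, abwd


def _drift(state: np.ndarray, m: NetworkModel, arrays=None) -> np.ndarray:
    """Deterministic drift f(x) with exogenous input at zero. state: (n, 10)."""
    g, te, ti, _, _, afwd, abwd = arrays or _effective_arrays(m)
    x = state
    vp = x[:, 2] - x[:, 8]
    ve = x[:, 0]
    vi = x[:, 4] - x[:, 6]
    sp, se, si = np.tanh(vp), np.tanh(ve), np.tanh(vi)
    te2, ti2 = te**2, ti**2
    dx = np.empty_like(x)
    dx[:, 0] = x[:, 1]
    dx[:, 1] = (g[:, 0] * sp + afwd @ sp) / te2 - 2 * x[:, 1] / te - x[:, 0] / te2
    dx[:, 2] = x[:, 3]
    dx[:, 3] = (g[:, 1] * se + abwd @ sp) / te2 - 2 * x[:, 3] / te - x[:, 2] / te2
    dx[:, 4] = x[:, 5]
    dx[:, 5] = (g[:, 2] * sp) / te2 - 2 * x[:, 5] / te - x[:, 4] / te2
    dx[:, 6] = x[:, 7]
    dx[:, 7] = (g[:, 4] * si) / ti2 - 2 * x[:, 7] / ti - x[:, 6] / ti2
    dx[:, 8] = x[:, 9]
    dx[:, 9] = (g[:, 3] * si) / ti2 - 2 * x[:, 9] / ti - x[:, 8] / ti2
    return dx


def fixed_point(
    m: NetworkModel,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Deterministic steady state of the noise-free network, shape (n, 10).

    Raises
    ------
    NonConvergenceError
        If no state with ``||f(x)|| < tol`` is found within the iteration
        budget; the message names the worst-converged source.
    """
    arrays = _effective_arrays(m)
    n = m.n_sources
    shape = (n, N_POP_STATES)
    start = np.zeros(shape) if x0 is None else np.asarray(x0, float).reshape(shape)

    def fun(flat):
        return _drift(flat.reshape(shape), m, arrays).ravel()

    sol = scipy.optimize.root(fun, start.ravel(), method="hybr",
                              options={"maxfev": max_iter * (n * N_POP_STATES + 1)})
    x = sol.x.reshape(shape)
    resid = _drift(x, m, arrays)
    norm = float(np.linalg.norm(resid))
    if norm >= tol:
        worst = int(np.argmax(np.linalg.norm(resid, axis=1)))
        raise NonConvergenceError(
            f"fixed point did not converge (||f||={norm:.3e}); "
            f"worst source index {worst}"
        )
    return x


def _sech2(v: np.ndarray) -> np.ndarray:
    return 1.0 / np.cosh(v) ** 2


def jacobian(m: NetworkModel, x: np.ndarray | None = None) -> np.ndarray:
    """Jacobian of the drift at state ``x`` (defaults to the fixed point)."""
    arrays = _effective_arrays(m)
    g, te, ti, _, _, afwd, abwd = arrays
    n = m.n_sources
    if x is None:
        x = fixed_point(m)
    x = np.asarray(x, float).reshape(n, N_POP_STATES)
    vp = x[:, 2] - x[:, 8]
    ve = x[:, 0]
    vi = x[:, 4] - x[:, 6]
    dp, de, di = _sech2(vp), _sech2(ve), _sech2(vi)
    J = np.zeros((n * N_POP_STATES, n * N_POP_STATES))

    def idx(i, s):
        return i * N_POP_STATES + s

    te2, ti2 = te**2, ti**2
    for i in range(n):
        # velocity rows
        for s in (0, 2, 4, 6, 8):
            J[idx(i, s), idx(i, s + 1)] = 1.0
        # leak/damping terms
        for s, T, T2 in ((0, te[i], te2[i]), (2, te[i], te2[i]), (4, te[i], te2[i]),
                         (6, ti[i], ti2[i]), (8, ti[i], ti2[i])):
            J[idx(i, s + 1), idx(i, s)] += -1.0 / T2
            J[idx(i, s + 1), idx(i, s + 1)] += -2.0 / T
        # intrinsic couplings (v_P = aP - bP, v_I = aI - bI)
        J[idx(i, 1), idx(i, 2)] += g[i, 0] * dp[i] / te2[i]
        J[idx(i, 1), idx(i, 8)] += -g[i, 0] * dp[i] / te2[i]
        J[idx(i, 3), idx(i, 0)] += g[i, 1] * de[i] / te2[i]
        J[idx(i, 5), idx(i, 2)] += g[i, 2] * dp[i] / te2[i]
        J[idx(i, 5), idx(i, 8)] += -g[i, 2] * dp[i] / te2[i]
        J[idx(i, 7), idx(i, 4)] += g[i, 4] * di[i] / ti2[i]
        J[idx(i, 7), idx(i, 6)] += -g[i, 4] * di[i] / ti2[i]
        J[idx(i, 9), idx(i, 4)] += g[i, 3] * di[i] / ti2[i]
        J[idx(i, 9), idx(i, 6)] += -g[i, 3] * di[i] / ti2[i]
        # extrinsic couplings from the projection output of j
        for j in range(n):
            if i == j:
                continue
            if afwd[i, j] != 0.0:
                J[idx(i, 1), idx(j, 2)] += afwd[i, j] * dp[j] / te2[i]
                J[idx(i, 1), idx(j, 8)] += -afwd[i, j] * dp[j] / te2[i]
            if abwd[i, j] != 0.0:
                J[idx(i, 3), idx(j, 2)] += abwd[i, j] * dp[j] / te2[i]
                J[idx(i, 3), idx(j, 8)] += -abwd[i, j] * dp[j] / te2[i]
    return J


def input_noise_psd(m: NetworkModel, frequencies: np.ndarray) -> np.ndarray:
    """One-sided PSD of each source's exogenous input, shape (F, n).

    g_u(f) = amp^2 / max(f, floor)^exp  -- parameterised pink noise.
    """
    _, _, _, amp, nexp, _, _ = _effective_arrays(m)
    f = np.maximum(np.asarray(frequencies, float), m.constants.noise_f_floor_hz)
    return (amp**2)[None, :] * f[:, None] ** (-nexp[None, :])


# ---------------------------------------------------------------------------
# operations: simulation and spectral prediction
# ---------------------------------------------------------------------------

def _pink_noise(
    rng: np.random.Generator,
    n_steps: int,
    dt: float,
    amp: np.ndarray,
    nexp: np.ndarray,
    f_floor: float,
) -> np.ndarray:
    """Coloured noise per source with one-sided PSD amp^2/f^exp, (n_steps, n)."""
    import scipy.fft

    n = amp.size
    n_fft = scipy.fft.next_fast_len(n_steps, real=True)
    w = rng.standard_normal((n_steps, n))
    spec = scipy.fft.rfft(np.ascontiguousarray(w.T), n=n_fft, axis=1)
    f = scipy.fft.rfftfreq(n_fft, d=dt)
    f_eff = np.maximum(f, f_floor)
    psd = (amp**2)[:, None] * f_eff[None, :] ** (-nexp[:, None])
    scale = np.sqrt(psd / (2.0 * dt))
    scale[:, 0] = 0.0  # no DC drive
    out = scipy.fft.irfft(spec * scale, n=n_fft, axis=1)[:, :n_steps]
    return out.T.copy()


def integrate_network(
    m: NetworkModel,
    u: np.ndarray,
    dt_s: float,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the network under a given input sequence.

    ``u`` is (n_steps, n_sources); the state ``x0`` (n_sources, 10) is
    advanced in place semantics-wise -- the final state is returned so
    callers can continue seamlessly across parameter changes. Returns
    ``(output (n_sources, n_steps), final_state)``.
    """
    g, te, ti, _, _, afwd, abwd = _effective_arrays(m)
    u = np.ascontiguousarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != m.n_sources:
        raise ParameterError("u must be (n_steps, n_sources)")
    if dt_s > te.min() / 5.0:
        raise ParameterError(
            f"dt_s={dt_s} too coarse for fastest time constant {te.min():.4g}s "
            "(need dt <= T_E/5)"
        )
    x = (np.zeros((m.n_sources, N_POP_STATES)) if x0 is None
         else np.array(x0, dtype=float))
    out = np.empty((u.shape[0], m.n_sources))
    bad = euler_core(
        x, u, dt_s, te, ti, g, afwd, abwd, np.asarray(m.lead, float),
        m.constants.noise_input_p, m.constants.blowup_abs, out,
    )
    if bad >= 0:
        t_div = bad * dt_s
        raise InstabilityError(
            f"simulation diverged at t={t_div:.3f}s (|state| > "
            f"{m.constants.blowup_abs:g})", time_s=t_div,
        )
    return out.T, x


def simulate_lfp(
    m: NetworkModel,
    duration_s: float,
    dt_s: float,
    seed: int,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate LFP-like output (projection membrane potential) per source.

    The model is integrated with a fixed-step explicit Euler scheme driven
    by a per-source pink-noise stream; the first 10% of samples are treated
    as burn-in and dropped, so the returned array covers the final 90% of
    ``duration_s``. Shape: (n_sources, n_kept).
    """
    _, te, _, amp, nexp, _, _ = _effective_arrays(m)
    n_total = int(round(duration_s / dt_s))
    if n_total < 100:
        raise ParameterError("duration_s/dt_s must be at least 100 samples")
    rng = np.random.default_rng(seed)
    u = _pink_noise(rng, n_total, dt_s, amp, nexp, m.constants.noise_f_floor_hz)
    x0 = fixed_point(m) if x0 is None else x0
    out, _ = integrate_network(m, u, dt_s, x0=x0)
    n_burn = n_total // 10
    return out[:, n_burn:].copy()


def transfer_csd(
    m: NetworkModel,
    grid: FrequencyGrid,
    check_stability: bool = True,
) -> CrossSpectrum:
    """Steady-state cross-spectral prediction from the linearised network.

    Propagates each source's parameterised input-noise spectrum through the
    transfer function of the dynamics linearised about the fixed point.
    Raises ``StabilityError`` if the fixed point is not linearly stable.
    """
    x_star = fixed_point(m)
    J = jacobian(m, x_star)
    if check_stability:
        eig = np.linalg.eigvals(J)
        if np.max(eig.real) >= 0.0:
            raise StabilityError(
                f"fixed point is linearly unstable "
                f"(max Re(eig) = {np.max(eig.real):.3e})"
            )
    n = m.n_sources
    _, te, ti_eff, _, _, _, _ = _effective_arrays(m)
    nstate = n * N_POP_STATES
    B = np.zeros((nstate, n))
    w_p = m.constants.noise_input_p
    for i in range(n):
        # one coherent stream per source: weight 1 into the excitatory
        # interneuron compartment, weight w_p into the projection
        # population's inhibitory compartment (slow kernel)
        B[i * N_POP_STATES + 1, i] = 1.0 / te[i] ** 2
        B[i * N_POP_STATES + 9, i] = w_p / ti_eff[i] ** 2
    C = np.zeros((n, nstate))
    for i in range(n):
        C[i, i * N_POP_STATES + 2] = m.lead[i]
        C[i, i * N_POP_STATES + 8] = -m.lead[i]
    freqs = grid.frequencies
    gu = input_noise_psd(m, freqs)  # (F, n)
    eye = np.eye(nstate)
    out = np.empty((len(freqs), n, n), dtype=complex)
    for k, f in enumerate(freqs):
        M = 2j * np.pi * f * eye - J
        X = np.linalg.solve(M, B)
        Tr = C @ X  # (n, n): response of outputs to unit inputs
        S = (Tr * gu[k][None, :]) @ Tr.conj().T
        out[k] = 0.5 * (S + S.conj().T)
    return CrossSpectrum(grid=grid, csd=out)
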