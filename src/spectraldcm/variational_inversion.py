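"""Variational Laplace inversion of network models on cross-spectral data.

A network model's free parameters (log-scalings) are given a Gaussian
prior; the complex cross-spectral density predicted by `transfer_csd` is
compared with the observed one under a Gaussian likelihood with a single
log-precision hyperparameter; a Gauss-Newton ascent on the free energy
yields a Gaussian posterior, the free energy F (a lower bound on log model
evidence) and the predicted spectra.

The data feature vector stacks the real parts of the upper triangle
(including the diagonal) and the imaginary parts of the strict upper
triangle of the CSD at every grid frequency. Features are weighted by an
inverse mean-power profile computed once from the data, so all frequency
bands inform the fit on a comparable (relative-error) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.optimize

from .config import load_defaults
from .errors import ParameterError, SpectralDCMError, StabilityError
from .neural_mass import (
    CrossSpectrum,
    NetworkModel,
    transfer_csd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterMap",
    "PriorDensity",
    "InversionResult",
    "WindowedInversion",
    "default_prior",
    "invert",
    "invert_windows",
    "variance_explained",
    "vectorize_csd",
    "csd_feature_weights",
    "reference_scale",
]

INTRINSIC_FIELDS = ("h1", "h2", "h3", "h4", "h5", "t_e", "t_i",
                    "noise_amp", "noise_exp")


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

class ParameterMap:
    """Maps a flat free-parameter vector onto a NetworkModel.

    Free parameters are the selected intrinsic fields of every source plus
    (optionally) the extrinsic log-gains wherever the structural masks are
    one, plus (optionally) a shared log observation gain.
    """

    def __init__(
        self,
        base: NetworkModel,
        intrinsic: Sequence[str] = INTRINSIC_FIELDS,
        extrinsic: bool = True,
        lead: bool = False,
    ):
        unknown = set(intrinsic) - set(INTRINSIC_FIELDS)
        if unknown:
            raise ParameterError(f"unknown intrinsic fields: {sorted(unknown)}")
        self.base = base
        self.intrinsic = tuple(intrinsic)
        self.with_extrinsic = bool(extrinsic)
        self.with_lead = bool(lead)
        names: list[str] = []
        for i in range(base.n_sources):
            names.extend(f"s{i}.{f}" for f in self.intrinsic)
        self._fwd_edges: list[tuple[int, int]] = []
        self._bwd_edges: list[tuple[int, int]] = []
        if self.with_extrinsic:
            self._fwd_edges = [tuple(ij) for ij in np.argwhere(base.mask_fwd == 1)]
            self._bwd_edges = [tuple(ij) for ij in np.argwhere(base.mask_bwd == 1)]
            names.extend(f"fwd[{i},{j}]" for i, j in self._fwd_edges)
            names.extend(f"bwd[{i},{j}]" for i, j in self._bwd_edges)
        if self.with_lead:
            names.append("lead")
        self.names = tuple(names)

    def __len__(self) -> int:
        return len(self.names)

    def pack(self, m: NetworkModel | None = None) -> np.ndarray:
        """Current values of the free parameters of ``m`` (default: base)."""
        m = m or self.base
        theta = []
        for src in m.sources:
            for f in self.intrinsic:
                if f.startswith("h"):
                    theta.append(src.h[int(f[1]) - 1])
                else:
                    theta.append(getattr(src, f))
        theta.extend(m.a_fwd[i, j] for i, j in self._fwd_edges)
        theta.extend(m.a_bwd[i, j] for i, j in self._bwd_edges)
        if self.with_lead:
            theta.append(np.log(m.lead[0]))
        return np.asarray(theta, dtype=float)

    def apply(self, theta: np.ndarray) -> NetworkModel:
        """Build a model with the free parameters set to ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self),):
            raise ParameterError(
                f"expected {len(self)} parameters, got {theta.shape}"
            )
        base = self.base
        k = 0
        sources = []
        for src in base.sources:
            h = np.array(src.h)
            kw = {}
            for f in self.intrinsic:
                if f.startswith("h"):
                    h[int(f[1]) - 1] = theta[k]
                else:
                    kw[f] = theta[k]
                k += 1
            sources.append(src.with_updates(h=h, **kw))
        a_fwd = np.array(base.a_fwd)
        a_bwd = np.array(base.a_bwd)
        for i, j in self._fwd_edges:
            a_fwd[i, j] = theta[k]
            k += 1
        for i, j in self._bwd_edges:
            a_bwd[i, j] = theta[k]
            k += 1
        lead = np.array(base.lead)
        if self.with_lead:
            lead = np.full(base.n_sources, np.exp(theta[k]))
            k += 1
        return replace(
            base, sources=tuple(sources), a_fwd=a_fwd, a_bwd=a_bwd, lead=lead
        )


@dataclass(frozen=True)
class PriorDensity:
    """Gaussian prior over a flat parameter vector.

    Zero-variance (or pinned, tiny-variance) entries mark effectively
    fixed parameters.
    """

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).reshape(-1)
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (mean.size, mean.size):
            raise ParameterError("prior covariance shape mismatch")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ParameterError("prior covariance must be symmetric")
        eigs = np.linalg.eigvalsh(cov)
        if eigs.min() < -1e-10 * max(1.0, eigs.max()):
            raise ParameterError("prior covariance must be PSD")
        mean.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def n(self) -> int:
        return self.mean.size


def default_prior(pmap: ParameterMap, config: dict | None = None) -> PriorDensity:
    """Spherical prior with per-kind variances from the configuration."""
    cfg = (config or load_defaults())["inversion"]
    var = []
    for name in pmap.names:
        leaf = name.split(".")[-1]
        if leaf.startswith("noise"):
            var.append(cfg["prior_var_noise"])
        elif leaf.startswith(("fwd", "bwd", "lead")):
            var.append(cfg["prior_var_extrinsic"])
        else:
            var.append(cfg["prior_var_intrinsic"])
    return PriorDensity(mean=pmap.pack(), cov=np.diag(var), names=pmap.names)


@dataclass(frozen=True)
class InversionResult:
    """Gaussian posterior, free energy and fit diagnostics for one dataset."""

    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    predicted: CrossSpectrum
    variance_explained: float
    iterations: int
    converged: bool
    names: tuple[str, ...]
    prior: PriorDensity
    log_precision: float
    data_scale: float = 1.0
    f_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def named_posterior(self) -> dict[str, float]:
        return dict(zip(self.names, self.posterior_mean))


# ---------------------------------------------------------------------------
# data featurisation
# ---------------------------------------------------------------------------

def _triu_indices(n: int):
    iu = np.triu_indices(n)
    iu_strict = np.triu_indices(n, k=1)
    return iu, iu_strict


def vectorize_csd(cs: CrossSpectrum, weights: np.ndarray | None = None) -> np.ndarray:
    """Stack Re(upper triangle incl diag) and Im(strict upper) per frequency."""
    n = cs.n_channels
    iu, ius = _triu_indices(n)
    parts = []
    for k in range(len(cs.grid)):
        S = cs.csd[k]
        w = 1.0 if weights is None else weights[k]
        parts.append(S[iu].real * w)
        if ius[0].size:
            parts.append(S[ius].imag * w)
    return np.concatenate(parts)


def csd_feature_weights(data: CrossSpectrum) -> np.ndarray:
    """Per-frequency inverse mean-auto-power weights (relative-error scale)."""
    mean_auto = np.einsum("fii->f", data.csd).real / data.n_channels
    floor = 1e-6 * float(mean_auto.max()) + 1e-300
    return 1.0 / np.maximum(mean_auto, floor)


def reference_scale(
    m: NetworkModel,
    datas: CrossSpectrum | Sequence[CrossSpectrum],
    obs_power_transfer: np.ndarray | None = None,
) -> float:
    """Scalar aligning observed CSDs with the prior-mean model prediction.

    Fluorescence units are arbitrary, so data are rescaled once (shared
    across all windows of a recording, preserving relative amplitudes) such
    that the pooled mean auto-power matches the model's at the prior mean.
    """
    if isinstance(datas, CrossSpectrum):
        datas = [datas]
    pred = transfer_csd(m, datas[0].grid)
    csd = pred.csd
    if obs_power_transfer is not None:
        csd = csd * np.asarray(obs_power_transfer)[:, None, None]
    model_power = float(np.einsum("fii->", csd).real)
    # sort before averaging so the scale is invariant to window order
    powers = np.sort([np.einsum("fii->", d.csd).real for d in datas])
    data_power = float(powers.mean())
    if data_power <= 0:
        raise ParameterError("data has zero total power")
    return model_power / data_power


def _scaled(data: CrossSpectrum, scale: float) -> CrossSpectrum:
    if scale == 1.0:
        return data
    return CrossSpectrum(grid=data.grid, csd=data.csd * scale)


# ---------------------------------------------------------------------------
# free energy machinery
# ---------------------------------------------------------------------------

def _safe_logdet(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise SpectralDCMError("non-positive-definite matrix in log-det")
    return float(ld)


def _free_energy_terms(e, lam, theta, prior_mean, P0, ld_prior_cov, JtJ, lam0, s_lam):
    """Laplace free energy for the current (theta, lambda)."""
    n_y = e.size
    tau = np.exp(lam)
    sse = float(e @ e)
    P_post = tau * JtJ + P0
    ld_post_cov = -_safe_logdet(P_post)
    d = theta - prior_mean
    # lambda posterior curvature: 0.5*tau*(sse + tr(J Sq J')) + 1/s_lam
    tr_term = tau * float(np.trace(np.linalg.solve(P_post, JtJ)))
    h_lam = 0.5 * tau * sse + 0.5 * tr_term + 1.0 / s_lam
    f = (
        -0.5 * tau * sse
        + 0.5 * n_y * lam
        - 0.5 * n_y * np.log(2 * np.pi)
        - 0.5 * float(d @ (P0 @ d))
        - 0.5 * ld_prior_cov
        + 0.5 * ld_post_cov
        - 0.5 * (lam - lam0) ** 2 / s_lam
        - 0.5 * np.log(s_lam)
        - 0.5 * np.log(h_lam)
    )
    return float(f), P_post


def _prior_precision(prior: PriorDensity, pinned_floor: float = 1e-10):
    """Precision and log-det of the prior covariance, regularising pins."""
    cov = np.array(prior.cov)
    # zero-variance entries mark fixed parameters: give them a tiny variance
    zero = np.diag(cov) <= 0
    if zero.any():
        cov[zero, :] = 0.0
        cov[:, zero] = 0.0
        cov[np.where(zero)[0], np.where(zero)[0]] = pinned_floor
    P0 = np.linalg.inv(cov)
    return P0, _safe_logdet(cov)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def invert(
    m: NetworkModel,
    data: CrossSpectrum,
    prior: PriorDensity | None = None,
    pmap: ParameterMap | None = None,
    config: dict | None = None,
    weights: np.ndarray | None = None,
    data_scale: float | None = None,
    obs_power_transfer: np.ndarray | None = None,
) -> InversionResult:
    """Fit ``m`` to an observed cross-spectrum by variational Laplace.

    The ascent is a Gauss-Newton scheme with finite-difference sensitivities
    and step-halving: steps that would lower the free energy (or land on an
    unstable parameter regime) are shortened, so the accepted F trace is
    non-decreasing. Deterministic given identical inputs.

    ``data_scale`` rescales the observed CSD onto the model's (arbitrary)
    power scale; when None it is computed from this dataset alone. Pass a
    shared value (see `reference_scale`) when several datasets must keep
    their relative amplitudes.
    """
    cfg = (config or load_defaults())["inversion"]
    pmap = pmap or ParameterMap(m)
    prior = prior or default_prior(pmap, config)
    if prior.n != len(pmap):
        raise ParameterError(
            f"prior dimension {prior.n} does not match free-parameter "
            f"count {len(pmap)}"
        )
    if data.n_channels != m.n_sources:
        raise ParameterError("data channel count does not match model sources")

    if obs_power_transfer is not None:
        obs_power_transfer = np.asarray(obs_power_transfer, dtype=float)
        if obs_power_transfer.shape != (len(data.grid),):
            raise ParameterError("obs_power_transfer must match the grid")
    if data_scale is None:
        data_scale = reference_scale(
            pmap.apply(prior.mean), data, obs_power_transfer
        )
    data = _scaled(data, data_scale)
    grid = data.grid

    # optional data reduction: fit the leading spectral eigenmodes of the
    # channel space instead of the full CSD (config: inversion.fit_eigenmodes
    # = false | number of modes)
    modes_cfg = cfg.get("fit_eigenmodes", False)
    U = None
    if modes_cfg and data.n_channels > 1:
        n_modes = data.n_channels if modes_cfg is True else int(modes_cfg)
        if n_modes < data.n_channels:
            M = np.trapezoid(data.csd.real, x=grid.frequencies, axis=0)
            _, vecs = np.linalg.eigh(M)
            U = vecs[:, -n_modes:]
            data = CrossSpectrum(
                grid=grid,
                csd=np.einsum("ia,fij,jb->fab", U, data.csd, U),
            )
    weights = csd_feature_weights(data) if weights is None else weights
    y = vectorize_csd(data, weights)

    def predict(theta: np.ndarray) -> np.ndarray | None:
        try:
            S = transfer_csd(pmap.apply(theta), grid)
        except SpectralDCMError:
            return None
        csd = S.csd
        if obs_power_transfer is not None:
            csd = csd * obs_power_transfer[:, None, None]
        if U is not None:
            csd = np.einsum("ia,fij,jb->fab", U, csd, U)
        if csd is not S.csd:
            S = CrossSpectrum(grid=grid, csd=csd)
        return vectorize_csd(S, weights)

    lam0 = float(cfg["log_precision_prior_mean"])
    s_lam = float(cfg["log_precision_prior_var"])
    tol = float(cfg["tol_df"])
    max_iter = int(cfg["max_iterations"])
    P0, ld_prior = _prior_precision(prior, float(cfg["pinned_var"]))

    theta = prior.mean.copy()
    h = predict(theta)
    if h is None:
        raise StabilityError("model is unstable at the prior mean")
    lam = lam0
    n_p = len(pmap)
    fd_step = 1e-4
    f_trace: list[float] = []
    f_cur = -np.inf
    P_post = np.eye(n_p)
    JtJ = np.zeros((n_p, n_p))
    J = np.zeros((y.size, n_p))
    converged = False
    slow_count = 0
    unstable_strikes = 0
    it = 0
    for it in range(1, max_iter + 1):
        # sensitivities at the current expansion point
        for i in range(n_p):
            tp = theta.copy()
            tp[i] += fd_step
            hp = predict(tp)
            if hp is None:
                tp[i] = theta[i] - fd_step
                hm = predict(tp)
                if hm is None:
                    J[:, i] = 0.0
                    continue
                J[:, i] = (h - hm) / fd_step
            else:
                J[:, i] = (hp - h) / fd_step
        JtJ = J.T @ J
        # PSD-project: tiny negative eigenvalues otherwise explode once the
        # noise precision grows large on near-noiseless data
        evals, evecs = np.linalg.eigh(0.5 * (JtJ + JtJ.T))
        JtJ = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        e = y - h
        # optimise the log noise precision for the current residuals
        def neg_f_lam(l):
            f, _ = _free_energy_terms(
                e, l, theta, prior.mean, P0, ld_prior, JtJ, lam0, s_lam
            )
            return -f
        lam_lo = max(lam - 8.0, lam0 - 24.0)
        lam_hi = min(lam + 8.0, lam0 + 24.0)
        res = scipy.optimize.minimize_scalar(
            neg_f_lam, bounds=(lam_lo, lam_hi), method="bounded",
            options={"xatol": 1e-4},
        )
        if -res.fun >= -neg_f_lam(lam):
            lam = float(res.x)
        f_cur, P_post = _free_energy_terms(
            e, lam, theta, prior.mean, P0, ld_prior, JtJ, lam0, s_lam
        )
        # Gauss-Newton direction with step halving on F decrease
        tau = np.exp(lam)
        g = tau * (J.T @ e) - P0 @ (theta - prior.mean)
        dtheta = np.linalg.solve(P_post, g)
        improved = False
        any_stable = False
        alpha = 1.0
        df = 0.0
        for _ in range(12):
            cand = theta + alpha * dtheta
            h_cand = predict(cand)
            if h_cand is not None:
                any_stable = True
                f_cand, _ = _free_energy_terms(
                    y - h_cand, lam, cand, prior.mean, P0, ld_prior,
                    JtJ, lam0, s_lam,
                )
                if f_cand >= f_cur - 1e-9:
                    theta, h = cand, h_cand
                    improved = f_cand > f_cur
                    df = f_cand - f_cur
                    f_cur = f_cand
                    break
            alpha *= 0.5
        f_trace.append(f_cur)
        if not any_stable:
            unstable_strikes += 1
            if unstable_strikes >= 2:
                logger.warning(
                    "persistent instability of proposed parameters at "
                    "iteration %d; returning last stable iterate", it,
                )
                converged = False
                break
            continue
        unstable_strikes = 0
        if (not improved) or abs(df) < tol:
            slow_count += 1
        else:
            slow_count = 0
        if slow_count >= 2:
            converged = True
            break

    # final posterior at the accepted expansion point
    e = y - h
    f_cur, P_post = _free_energy_terms(
        e, lam, theta, prior.mean, P0, ld_prior, JtJ, lam0, s_lam
    )
    post_cov = np.linalg.inv(P_post)
    post_cov = 0.5 * (post_cov + post_cov.T)
    predicted = transfer_csd(pmap.apply(theta), grid)
    pred_csd = predicted.csd
    if obs_power_transfer is not None:
        pred_csd = pred_csd * obs_power_transfer[:, None, None]
    if U is not None:
        pred_csd = np.einsum("ia,fij,jb->fab", U, pred_csd, U)
    if pred_csd is not predicted.csd:
        predicted = CrossSpectrum(grid=grid, csd=pred_csd)
    ve = _variance_explained_vec(vectorize_csd(predicted), vectorize_csd(data))
    return InversionResult(
        posterior_mean=theta,
        posterior_cov=post_cov,
        free_energy=float(f_cur),
        predicted=predicted,
        variance_explained=ve,
        iterations=it,
        converged=converged,
        names=pmap.names,
        prior=prior,
        log_precision=float(lam),
        data_scale=float(data_scale),
        f_trace=np.asarray(f_trace),
    )


def _variance_explained_vec(pred: np.ndarray, obs: np.ndarray) -> float:
    total = float(obs @ obs)
    if total <= 0:
        raise ParameterError("data has zero power")
    resid = obs - pred
    raw = 1.0 - float(resid @ resid) / total
    if raw <= 0:
        logger.warning(
            "model underperforms the zero prediction (raw R^2 = %.3f); "
            "reporting 0", raw,
        )
        return 0.0
    return raw


def variance_explained(result: InversionResult, data: CrossSpectrum) -> float:
    """Fraction of CSD power (real+imag features) explained by the fit."""
    if not np.array_equal(result.predicted.grid.frequencies, data.grid.frequencies):
        raise ParameterError("frequency grids do not match")
    return _variance_explained_vec(
        vectorize_csd(result.predicted),
        vectorize_csd(_scaled(data, result.data_scale)),
    )


@dataclass(frozen=True)
class WindowedInversion:
    """First-level results for a series of windows (independent fits)."""

    window_times: np.ndarray
    results: tuple[InversionResult | None, ...]
    aggregate_variance_explained: float

    @property
    def n_ok(self) -> int:
        return sum(r is not None for r in self.results)


def invert_windows(
    m: NetworkModel,
    windows: Sequence[CrossSpectrum],
    prior: PriorDensity | None = None,
    pmap: ParameterMap | None = None,
    window_times: np.ndarray | None = None,
    config: dict | None = None,
    obs_power_transfer: np.ndarray | None = None,
) -> WindowedInversion:
    """Invert each window independently (first-level models).

    Window failures are logged and marked with ``None``; the run continues.
    """
    if len(windows) == 0:
        raise ParameterError("need at least one window")
    pmap = pmap or ParameterMap(m)
    prior = prior or default_prior(pmap, config)
    times = (np.arange(len(windows), dtype=float)
             if window_times is None else np.asarray(window_times, float))
    # one shared scale so between-window amplitude changes stay informative
    scale = reference_scale(pmap.apply(prior.mean), windows, obs_power_transfer)
    results: list[InversionResult | None] = []
    num, den = 0.0, 0.0
    for w, data in enumerate(windows):
        try:
            r = invert(m, data, prior=prior, pmap=pmap, config=config,
                       data_scale=scale, obs_power_transfer=obs_power_transfer)
        except SpectralDCMError as exc:
            logger.warning("window %d inversion failed: %s", w, exc)
            results.append(None)
            continue
        results.append(r)
        obs = vectorize_csd(_scaled(data, scale))
        pred = vectorize_csd(r.predicted)
        num += float((obs - pred) @ (obs - pred))
        den += float(obs @ obs)
    agg = max(0.0, 1.0 - num / den) if den > 0 else 0.0
    return WindowedInversion(
        window_times=times,
        results=tuple(results),
        aggregate_variance_explained=agg,
    )
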