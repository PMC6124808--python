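"""Second-level (parametric empirical Bayes) model of slow parameter drift.

First-level window posteriors are treated as noisy observations of a
linear mixture of temporal basis functions (tonic step, monophasic
pharmacokinetic bump, ramp, slow discrete-cosine drifts, per-fish
effects) plus an isotropic random between-window effect. The group model
has closed-form Gaussian evidence given the random-effect variance, which
is optimised under a broad hyperprior; Bayesian model reduction over the
group-level coefficients compares hypotheses about *which* parameters
fluctuate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .config import load_defaults
from .errors import ConditioningError, ParameterError
from .spectral_features import mar_csd
from .variational_inversion import (
    InversionResult,
    ParameterMap,
    default_prior,
    invert,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalBasis",
    "GroupPosterior",
    "build_basis",
    "peb_fit",
    "peb_compare_sets",
    "fig1_construct_validity",
]

EXPERIMENTAL_COLUMNS = ("tonic_step", "pk_monophasic", "ramp",
                        "dct1", "dct2", "dct3")


# ---------------------------------------------------------------------------
# temporal basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalBasis:
    """Second-level design matrix over window times."""

    window_times: np.ndarray    # (k,) seconds
    regressors: np.ndarray      # (k, c)
    names: tuple[str, ...]
    ptz_onset_s: float

    def __post_init__(self):
        if self.regressors.shape != (self.window_times.size, len(self.names)):
            raise ParameterError("regressor matrix shape mismatch")

    def column(self, name: str) -> np.ndarray:
        return self.regressors[:, self.names.index(name)]

    def select(self, names: Sequence[str]) -> "TemporalBasis":
        idx = [self.names.index(n) for n in names]
        return TemporalBasis(
            window_times=self.window_times,
            regressors=self.regressors[:, idx],
            names=tuple(names),
            ptz_onset_s=self.ptz_onset_s,
        )


def pk_rise_constant(peak_s: float, tau2_s: float) -> float:
    """Rise constant tau1 of (1 - e^(-t/tau1)) e^(-t/tau2) peaking at peak_s."""
    def f(tau1):
        return np.exp(-peak_s / tau1) * (tau1 + tau2_s) - tau1
    return float(scipy.optimize.brentq(f, 1.0, 1e7, xtol=1e-9))


def pk_bump(t_after_onset: np.ndarray, peak_s: float, tau2_s: float) -> np.ndarray:
    """Monophasic first-order pharmacokinetic effect, normalised to peak 1."""
    tau1 = pk_rise_constant(peak_s, tau2_s)
    raw = (1.0 - np.exp(-t_after_onset / tau1)) * np.exp(-t_after_onset / tau2_s)
    peak = (1.0 - np.exp(-peak_s / tau1)) * np.exp(-peak_s / tau2_s)
    return np.where(t_after_onset >= 0, raw / peak, 0.0)


def build_basis(
    window_times: np.ndarray,
    ptz_onset_s: float,
    fish_ids: Sequence[int] | None = None,
    config: dict | None = None,
) -> TemporalBasis:
    """Construct the temporal basis at the given window-centre times.

    Columns: ``tonic_step`` (0 before onset, 1 from onset), ``pk_monophasic``
    (pharmacokinetic bump peaking 30 min post onset), ``ramp`` (linear rise
    from onset scaled to max 1), ``dct1..3`` (lowest non-constant cosine
    drifts over the post-onset windows) and one indicator per fish.
    """
    cfg = (config or load_defaults())["peb"]
    t = np.asarray(window_times, dtype=float).reshape(-1)
    if not (t.min() <= ptz_onset_s <= t.max()):
        raise ParameterError(
            f"onset {ptz_onset_s}s outside the recording span "
            f"[{t.min()}, {t.max()}]s"
        )
    post = t >= ptz_onset_s
    s = t - ptz_onset_s
    cols = {
        "tonic_step": post.astype(float),
        "pk_monophasic": pk_bump(s, float(cfg["pk_peak_s"]), float(cfg["pk_tau2_s"])),
        "ramp": np.where(post, s, 0.0),
    }
    if cols["ramp"].max() > 0:
        cols["ramp"] = cols["ramp"] / cols["ramp"].max()
    n_post = int(post.sum())
    j = np.cumsum(post) - 1  # index among post-onset windows
    for kk in range(1, int(cfg["n_dct"]) + 1):
        if n_post > kk:
            col = np.cos(np.pi * kk * (j + 0.5) / n_post)
        else:
            col = np.zeros_like(t)
        cols[f"dct{kk}"] = np.where(post, col, 0.0)
    fish_ids = [0] * t.size if fish_ids is None else list(fish_ids)
    if len(fish_ids) != t.size:
        raise ParameterError("fish_ids length must match window count")
    for fid in sorted(set(fish_ids)):
        cols[f"fish_{fid}"] = np.array(
            [1.0 if f == fid else 0.0 for f in fish_ids]
        )
    names = tuple(cols)
    X = np.column_stack([cols[n] for n in names])
    return TemporalBasis(window_times=t, regressors=X, names=names,
                         ptz_onset_s=float(ptz_onset_s))


# ---------------------------------------------------------------------------
# group model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPosterior:
    """Posterior over second-level coefficients and updated window posteriors."""

    beta: np.ndarray            # (c, p) effect of regressor c on parameter p
    beta_cov: np.ndarray        # (c*p, c*p), beta ravelled row-major (c, p)
    F_group: float
    log_q: float                # log random-effect variance at its MAP
    param_names: tuple[str, ...]
    regressor_names: tuple[str, ...]
    window_means: np.ndarray    # (k, p) empirically re-weighted window posteriors
    window_covs: np.ndarray     # (k, p, p)

    def effect(self, regressor: str, param: str) -> float:
        c = self.regressor_names.index(regressor)
        p = self.param_names.index(param)
        return float(self.beta[c, p])


def _collect_first_level(
    first_level: Sequence[InversionResult | None],
    which_params: Sequence[str],
):
    keep, mus, covs = [], [], []
    for w, r in enumerate(first_level):
        if r is None:
            continue
        idx = [r.names.index(p) for p in which_params]
        keep.append(w)
        mus.append(r.posterior_mean[idx])
        covs.append(r.posterior_cov[np.ix_(idx, idx)])
    if len(keep) < 2:
        raise ParameterError("need at least 2 successful windows for PEB")
    return np.array(keep), np.array(mus), np.array(covs)


def _design_checks(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ConditioningError(
            f"design has more columns ({X.shape[1]}) than windows ({X.shape[0]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]]
        raise ConditioningError(
            f"second-level design is rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear columns: {bad}"
        )


def _evidence_terms(mus, covs, X, v_beta, log_q):
    """Woodbury-form log evidence pieces for the stacked linear model."""
    k, p = mus.shape
    c = X.shape[1]
    q = np.exp(log_q)
    ld_D = 0.0
    quad_D = 0.0
    A = np.zeros((c * p, c * p))
    b = np.zeros(c * p)
    for w in range(k):
        Dw = covs[w] + q * np.eye(p)
        sign, ld = np.linalg.slogdet(Dw)
        if sign <= 0:
            raise ParameterError("window covariance not positive definite")
        ld_D += ld
        Dinv = np.linalg.inv(Dw)
        dw_mu = Dinv @ mus[w]
        quad_D += float(mus[w] @ dw_mu)
        A += np.kron(np.outer(X[w], X[w]), Dinv)
        b += np.kron(X[w], dw_mu)
    M = np.eye(c * p) / v_beta + A
    sign, ld_M = np.linalg.slogdet(M)
    if sign <= 0:
        raise ParameterError("group precision not positive definite")
    mu_beta = np.linalg.solve(M, b)
    log_ev = -0.5 * (
        k * p * np.log(2 * np.pi) + ld_D + c * p * np.log(v_beta) + ld_M
        + quad_D - float(b @ mu_beta)
    )
    return log_ev, mu_beta, M


def peb_fit(
    first_level: Sequence[InversionResult | None],
    basis: TemporalBasis,
    which_params: Sequence[str],
    config: dict | None = None,
) -> GroupPosterior:
    """Fit the hierarchical (empirical Bayes) model of parameter drift.

    Returns the posterior over regressor effects, the group free energy
    (for model comparison via `peb_compare_sets`) and window posteriors
    re-weighted by the empirical priors (shrunk toward the basis fit).
    """
    cfg = (config or load_defaults())["peb"]
    if len(which_params) == 0:
        raise ParameterError("which_params must be non-empty")
    keep, mus, covs = _collect_first_level(first_level, which_params)
    X = basis.regressors[keep]
    _design_checks(X, basis.names)
    v_beta = float(cfg["beta_prior_var"])
    g0 = float(cfg["log_q_prior_mean"])
    sg = float(cfg["log_q_prior_var"])

    def neg_joint(log_q):
        log_ev, _, _ = _evidence_terms(mus, covs, X, v_beta, log_q)
        return -(log_ev - 0.5 * (log_q - g0) ** 2 / sg)

    res = scipy.optimize.minimize_scalar(
        neg_joint, bounds=(g0 - 12.0, g0 + 12.0), method="bounded",
        options={"xatol": 1e-3},
    )
    log_q = float(res.x)
    F_group = -float(res.fun)
    log_ev, mu_beta, M = _evidence_terms(mus, covs, X, v_beta, log_q)
    k, p = mus.shape
    c = X.shape[1]
    beta = mu_beta.reshape(c, p)
    beta_cov = np.linalg.inv(M)
    beta_cov = 0.5 * (beta_cov + beta_cov.T)

    # empirical-prior update of each window posterior
    q = np.exp(log_q)
    win_means = np.empty((len(first_level), p))
    win_covs = np.empty((len(first_level), p, p))
    win_means[:] = np.nan
    win_covs[:] = np.nan
    for j, w in enumerate(keep):
        Xw = basis.regressors[w]
        K = np.kron(Xw[None, :], np.eye(p))  # (p, c*p)
        prior_mean = K @ mu_beta
        prior_cov = q * np.eye(p) + K @ beta_cov @ K.T
        P1 = np.linalg.inv(covs[j])
        P2 = np.linalg.inv(prior_cov)
        cov_upd = np.linalg.inv(P1 + P2)
        win_covs[w] = 0.5 * (cov_upd + cov_upd.T)
        win_means[w] = cov_upd @ (P1 @ mus[j] + P2 @ prior_mean)
    return GroupPosterior(
        beta=beta,
        beta_cov=beta_cov,
        F_group=F_group,
        log_q=log_q,
        param_names=tuple(which_params),
        regressor_names=basis.names,
        window_means=win_means,
        window_covs=win_covs,
    )


def _gaussian_bmr(mu, cov, v_full: np.ndarray, v_reduced: np.ndarray) -> float:
    """Log-evidence change when shrinking a zero-mean Gaussian prior.

    ``v_full`` and ``v_reduced`` are prior variance vectors (diagonal).
    """
    P0 = np.diag(1.0 / v_full)
    Pr0 = np.diag(1.0 / v_reduced)
    P = np.linalg.inv(cov)
    Pr = P + Pr0 - P0
    evals = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if evals.min() <= 0:
        raise ParameterError("reduced covariance is not positive definite")
    br = P @ mu
    mur = np.linalg.solve(Pr, br)
    _, ld_P = np.linalg.slogdet(P)
    _, ld_Pr = np.linalg.slogdet(Pr)
    dF = 0.5 * (
        np.sum(np.log(v_full)) - np.sum(np.log(v_reduced))
        + ld_P - ld_Pr
        + float(mur @ (Pr @ mur)) - float(mu @ br)
    )
    return float(dF)


def peb_compare_sets(
    first_level: Sequence[InversionResult | None],
    basis: TemporalBasis,
    families: Mapping[str, Sequence[str]],
    config: dict | None = None,
    experimental: Sequence[str] | None = None,
    group: GroupPosterior | None = None,
) -> tuple[dict[str, float], str, GroupPosterior]:
    """Compare hypotheses about which parameters fluctuate over windows.

    ``families`` maps a family name to the set of parameter names allowed
    to carry experimental (time-varying) effects; all other parameters'
    experimental coefficients are pinned to zero by Bayesian model
    reduction of the full group model. Nuisance columns (per-fish effects,
    or any column not listed in ``experimental``) stay free in every
    family. Returns (per-family F relative to the best, winner, full fit).
    """
    cfg = (config or load_defaults())["peb"]
    all_params: list[str] = []
    for fam in families.values():
        for p in fam:
            if p not in all_params:
                all_params.append(p)
    if not all_params:
        raise ParameterError("families define no parameters")
    if group is None:
        group = peb_fit(first_level, basis, all_params, config=config)
    exp_cols = [n for n in basis.names
                if n in (experimental or EXPERIMENTAL_COLUMNS)]
    v_beta = float(cfg["beta_prior_var"])
    pinned = float((config or load_defaults())["inversion"]["pinned_var"])
    c, p = group.beta.shape
    mu = group.beta.ravel()
    v_full = np.full(c * p, v_beta)
    scores: dict[str, float] = {}
    for name, fam in families.items():
        v_red = v_full.copy()
        for ci, cname in enumerate(group.regressor_names):
            if cname not in exp_cols:
                continue
            for pi, pname in enumerate(group.param_names):
                if pname not in fam:
                    v_red[ci * p + pi] = pinned
        scores[name] = group.F_group + _gaussian_bmr(
            mu, group.beta_cov, v_full, v_red
        )
    best = max(scores.values())
    rel = {k: v - best for k, v in scores.items()}
    winner = max(rel, key=rel.get)
    return rel, winner, group


# ---------------------------------------------------------------------------
# construct-validity experiment (single source, segment-wise ramp)
# ---------------------------------------------------------------------------

def fig1_construct_validity(
    segments: Sequence[np.ndarray],
    fs: float = 20.0,
    candidate_params: Sequence[str] | None = None,
    config: dict | None = None,
    mar_order: int | None = None,
    model_kernel: bool = True,
):
    """Which single parameter explains differences between fluorescence segments?

    Each segment (one channel) is summarised by a MAR cross-spectral
    density, inverted with a single-source model, and the between-segment
    drift is modelled with an intercept plus a linear regressor. Candidate
    single-parameter explanations are compared by BMR of the group model.

    With ``model_kernel`` the known indicator-kernel power transfer is part
    of the forward prediction, so fluorescence spectra are inverted with a
    fluorescence generative model.

    Returns ``(winner, estimates, scores, group)`` where ``estimates`` are
    the empirically re-weighted per-segment posteriors of the winning
    parameter.
    """
    from .neural_mass import FrequencyGrid, ModelConstants, single_source_model
    from .observation_model import KernelSpec, observation_power_transfer
    from .variational_inversion import reference_scale

    full_cfg = config or load_defaults()
    sf = full_cfg["spectral_features"]
    grid = FrequencyGrid.regular(
        float(sf["f_min_hz"]), float(sf["f_max_hz"]), float(sf["f_step_hz"])
    )
    order = int(mar_order or sf["mar_order"])
    base = single_source_model(constants=ModelConstants.from_config(full_cfg))
    pmap = ParameterMap(base, extrinsic=False)
    prior = default_prior(pmap, full_cfg)
    datas = [mar_csd(np.atleast_2d(seg), fs, order, grid) for seg in segments]
    transfer = None
    if model_kernel:
        transfer = observation_power_transfer(
            grid.frequencies, KernelSpec.from_config(full_cfg), fs_out=fs
        )
    scale = reference_scale(base, datas, transfer)  # shared across segments
    results = [
        invert(base, d, prior=prior, pmap=pmap, config=full_cfg,
               data_scale=scale, obs_power_transfer=transfer)
        for d in datas
    ]
    k = len(results)
    ramp = np.linspace(-0.5, 0.5, k)
    X = np.column_stack([np.ones(k), ramp])
    basis = TemporalBasis(
        window_times=np.arange(k, dtype=float),
        regressors=X,
        names=("intercept", "ramp"),
        ptz_onset_s=0.0,
    )
    candidates = list(candidate_params or
                      ("h1", "h2", "h3", "h4", "h5", "t_e", "t_i"))
    families: dict[str, tuple[str, ...]] = {"null": ()}
    for c in candidates:
        name = f"s0.{c}" if "." not in c else c
        families[name] = (name,)
    # model every source parameter at the second level: the noise parameters
    # are pinned in all families, so a candidate cannot silently offload its
    # amplitude side-effects onto unmodelled input-noise drift
    group = peb_fit(results, basis, list(pmap.names), config=full_cfg)
    scores, winner, group = peb_compare_sets(
        results, basis, families, config=full_cfg, experimental=("ramp",),
        group=group,
    )
    w_idx = group.param_names.index(winner)
    estimates = group.window_means[:, w_idx]
    return winner, estimates, scores, group
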