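"""Synthetic experiment generation with known ground truth.

Generates (i) the construct-validity segment set: six fluorescence traces
from a single source whose H1 parameter ramps linearly, and (ii) full
multi-fish, 10-region, 150-minute experiments in which parameters drift
according to the second-level temporal basis times a known coefficient
matrix. Both emulate the acquisition chain: population-level simulation at
millisecond resolution, convolution with the indicator kernel, decimation
to the imaging rate and additive measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import load_defaults
from .errors import ParameterError
from .model_space import DEFAULT_REGIONS, build_factorial_space, node_names
from .neural_mass import (
    ModelConstants,
    NetworkModel,
    SourceParams,
    _effective_arrays as _nm_arrays,
    _pink_noise,
    integrate_network,
    simulate_lfp,
    single_source_model,
)
from .observation_model import KernelSpec, apply_kernel
from .peb_hierarchy import TemporalBasis, build_basis
from .variational_inversion import ParameterMap

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "SyntheticExperiment",
    "default_true_beta",
    "generate_fig1_segments",
    "generate_experiment",
    "seizure_architecture",
]


def _rng(*key) -> np.random.Generator:
    """Deterministic generator from a mixed int/str key tuple."""
    import hashlib

    words = []
    for k in key:
        if isinstance(k, str):
            digest = hashlib.sha256(k.encode()).digest()
            words.append(int.from_bytes(digest[:4], "little"))
        else:
            words.append(int(k))
    return np.random.default_rng(np.random.SeedSequence(words))


def seizure_architecture(
    constants: ModelConstants | None = None,
) -> NetworkModel:
    """The generative 10-source network: tectal hub + neighbouring + homotopic."""
    models = build_factorial_space()
    win = next(
        m for m in models
        if m.factor.hub == "Tect" and m.factor.neighbouring and m.factor.homotopic
    )
    return NetworkModel(
        sources=tuple(SourceParams() for _ in range(10)),
        mask_fwd=win.mask_fwd,
        mask_bwd=win.mask_bwd,
        constants=constants or ModelConstants(),
    )


def default_true_beta(pmap: ParameterMap, basis_names: Sequence[str]) -> np.ndarray:
    """Seizure-like ground-truth coefficients (basis columns x parameters).

    Directions mimic the reported physiology: tonic reduction of forward
    drive onto the tectal hub, reduced intrinsic inhibitory gains, faster
    excitation (T_E down) and slower inhibition (T_I up), with an extra
    transient low-frequency push on the pharmacokinetic bump.
    """
    beta = np.zeros((len(basis_names), len(pmap.names)))
    cols = {n: i for i, n in enumerate(basis_names)}

    def region_of(pname: str) -> int | None:
        if not pname.startswith("s"):
            return None
        return int(pname.split(".")[0][1:]) // 2  # bilateral pair index

    def put(col, leaf_match, value, region_weights=None):
        if col not in cols:
            return
        for j, pname in enumerate(pmap.names):
            leaf = pname.split(".")[-1]
            hit = leaf_match(pname) if callable(leaf_match) else leaf == leaf_match
            if not hit:
                continue
            v = value
            if region_weights is not None:
                r = region_of(pname)
                if r is not None:
                    v = value * region_weights[r]
            beta[cols[col], j] = v

    # region order: Tect, Crbl, RHbr, MHbr, CHbr/RSc. Effects are graded
    # across regions so each seizure phase carries a distinct spatial
    # pattern of band power, as in the recordings being emulated.
    # Sustained seizure state: disinhibition, faster excitation, slower
    # inhibition, reduced forward drive onto the tectal hub, and an input
    # surge dominated by the rostral hindbrain.
    put("tonic_step", "h4", -0.4, (1.0, 0.6, 1.0, 0.6, 0.4))
    put("tonic_step", "h5", -0.4, (1.0, 0.6, 1.0, 0.6, 0.4))
    put("tonic_step", "t_e", -0.3)
    put("tonic_step", "t_i", 0.3)
    put("tonic_step", "noise_amp", 0.4, (0.4, 0.2, 1.0, 0.4, -0.5))
    put("tonic_step",
        lambda p: p.startswith("fwd[0,") or p.startswith("fwd[1,"), -0.5)
    # transient drug effect: steep low-frequency surge early in the
    # seizure, strongest over tectum and rostral hindbrain
    put("pk_monophasic", "noise_exp", 0.5, (1.0, 0.5, 1.0, 0.5, 0.3))
    # prolonged-seizure effect: power shifts caudally in the late phase
    put("ramp", "noise_amp", 0.5, (0.2, 0.4, 0.2, 1.0, 1.0))
    # slow oscillatory components: intermittent broadband bursts
    put("dct1", "noise_amp", 0.3)
    put("dct2", "noise_exp", 0.2)
    return beta


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic multi-fish seizure experiment."""

    n_fish: int = 3
    duration_s: float = 9000.0
    fs_hz: float = 20.0
    lfp_fs_hz: float = 1000.0
    ptz_onset_s: float = 1800.0
    regions: tuple[str, ...] = DEFAULT_REGIONS
    segment_s: float = 50.0
    blend_s: float = 1.0
    measurement_snr: float = 10.0
    seed: int = 0
    true_beta: np.ndarray | None = None   # (n_basis_columns, n_params)
    fish_effect_sd: float = 0.05

    def __post_init__(self):
        if self.ptz_onset_s >= self.duration_s:
            raise ParameterError("onset must lie within the recording")
        if len(self.regions) != 5:
            raise ParameterError("regions must be 5 bilateral pairs")
        if self.n_fish < 1:
            raise ParameterError("need at least one fish")

    @property
    def channel_names(self) -> list[str]:
        return node_names(self.regions)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Generated recordings plus the ground truth that produced them."""

    design: ExperimentDesign
    time_s: np.ndarray                      # (T,) at the imaging rate
    data: tuple[np.ndarray, ...]            # per fish: (10, T)
    channel_names: tuple[str, ...]
    basis: TemporalBasis                    # segment-centre basis (per fish)
    true_beta: np.ndarray                   # (columns, params)
    param_names: tuple[str, ...]
    trajectories: tuple[np.ndarray, ...]    # per fish: (n_segments, n_params)
    segment_times: np.ndarray


def generate_fig1_segments(
    seed: int,
    h1_values: Sequence[float] = (-1.0, -0.6, -0.2, 0.2, 0.6, 1.0),
    duration_s: float = 60.0,
    fs_out: float = 20.0,
    lfp_fs: float = 1000.0,
    config: dict | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Six single-channel fluorescence segments with a known H1 ramp.

    Each segment is simulated from a single source at its H1 value, kernel
    convolved at the population rate and decimated to ``fs_out``. Returns
    the segments (each (1, n_samples)) and a ground-truth dict.
    """
    h1_values = list(h1_values)
    if any(b < a for a, b in zip(h1_values, h1_values[1:])):
        raise ParameterError("h1_values must be sorted ascending")
    cfg = config or load_defaults()
    constants = ModelConstants.from_config(cfg)
    kspec = KernelSpec.from_config(cfg)
    pad_s = 1.5 * kspec.length_ms / 1000.0
    segments = []
    for i, v in enumerate(h1_values):
        m = single_source_model(
            SourceParams(h=[v, 0.0, 0.0, 0.0, 0.0]), constants
        )
        sim_s = (duration_s + pad_s) / 0.9 + 1.0
        y = simulate_lfp(m, sim_s, 1.0 / lfp_fs, seed=int(_rng(seed, i).integers(2**31)))
        fluo = apply_kernel(y, lfp_fs, kspec, fs_out)
        n_pad = int(round(pad_s * fs_out))
        n_keep = int(round(duration_s * fs_out))
        segments.append(fluo[:, n_pad : n_pad + n_keep])
    truth = {"parameter": "h1", "values": list(map(float, h1_values)),
             "seed": int(seed), "fs_hz": float(fs_out)}
    return segments, truth


def _stable_theta(pmap: ParameterMap, theta: np.ndarray) -> np.ndarray:
    """Shrink a parameter excursion toward zero until the model is stable."""
    from .neural_mass import N_POP_STATES, jacobian

    n = pmap.base.n_sources
    origin = np.zeros((n, N_POP_STATES))  # tanh model: fixed point at 0
    scale = 1.0
    for _ in range(12):
        m = pmap.apply(scale * theta)
        try:
            J = jacobian(m, origin)
        except Exception:
            scale *= 0.8
            continue
        if np.linalg.eigvals(J).real.max() < -1e-6:
            if scale < 1.0:
                logger.warning(
                    "unstable parameter excursion clipped to %.2f of its size",
                    scale,
                )
            return scale * theta
        scale *= 0.8
    logger.warning("excursion still unstable after clipping; using prior mean")
    return np.zeros_like(theta)


def generate_experiment(
    design: ExperimentDesign, config: dict | None = None
) -> SyntheticExperiment:
    """Generate a full synthetic experiment with drifting parameters.

    Parameters are frozen within each ~50 s segment (quasi-static
    first-level assumption) and follow ``basis x true_beta`` plus per-fish
    random effects across segments. The network state is carried across
    segment boundaries, so the concatenated trace is continuous despite the
    stepwise parameter changes; the result is kernel-convolved, decimated
    to the imaging rate and given additive white measurement noise.
    """
    cfg = config or load_defaults()
    constants = ModelConstants.from_config(cfg)
    kspec = KernelSpec.from_config(cfg)
    base = seizure_architecture(constants)
    pmap = ParameterMap(base, extrinsic=True)
    n_seg = int(round(design.duration_s / design.segment_s))
    seg_times = (np.arange(n_seg) + 0.5) * design.segment_s

    dt = min(0.5 / design.lfp_fs_hz, constants.t_e_ms / 1000.0 / 5.0 / np.exp(0.5))
    sub = int(round(1.0 / (design.lfp_fs_hz * dt)))
    dt = 1.0 / (design.lfp_fs_hz * sub)

    data = []
    trajectories = []
    basis = None
    beta = None
    for fish in range(design.n_fish):
        fish_basis = build_basis(
            seg_times, design.ptz_onset_s, fish_ids=[fish] * n_seg, config=cfg
        )
        if beta is None:
            basis = build_basis(
                seg_times, design.ptz_onset_s, fish_ids=[0] * n_seg, config=cfg
            )
            if design.true_beta is not None:
                beta = np.asarray(design.true_beta, dtype=float)
                if beta.shape != (len(basis.names), len(pmap.names)):
                    raise ParameterError(
                        f"true_beta must be {(len(basis.names), len(pmap.names))}"
                    )
            else:
                beta = default_true_beta(pmap, basis.names)
        # per-fish random offsets (the fish column of the true second level)
        fish_offset = design.fish_effect_sd * _rng(
            design.seed, "fish-effect", fish
        ).standard_normal(len(pmap.names))
        exp_cols = [i for i, nm in enumerate(fish_basis.names)
                    if not nm.startswith("fish_")]
        X = fish_basis.regressors[:, exp_cols]
        B = beta[[i for i, nm in enumerate(basis.names)
                  if not nm.startswith("fish_")], :]
        theta_traj = X @ B + fish_offset[None, :]

        n_seg_lfp = int(round(design.segment_s * design.lfp_fs_hz))
        total_lfp = n_seg * n_seg_lfp
        lfp = np.empty((base.n_sources, total_lfp))
        used_traj = np.empty_like(theta_traj)
        state = np.zeros((base.n_sources, 10))  # network fixed point
        burn_steps = int(round(5.0 * design.lfp_fs_hz))
        for s in range(n_seg):
            theta = _stable_theta(pmap, theta_traj[s])
            used_traj[s] = theta
            m = pmap.apply(theta)
            _, _, _, amp, nexp, _, _ = _nm_arrays(m)
            rng_s = _rng(design.seed, fish, s)
            n_in = n_seg_lfp + (burn_steps if s == 0 else 0)
            u = _pink_noise(rng_s, n_in, 1.0 / design.lfp_fs_hz, amp, nexp,
                            constants.noise_f_floor_hz)
            # zero-order hold onto the integrator step; the state carries
            # over between segments so no splice transients occur
            y, state = integrate_network(m, np.repeat(u, sub, axis=0), dt,
                                         x0=state)
            y = y[:, ::sub]
            if s == 0:
                y = y[:, burn_steps:]
            lfp[:, s * n_seg_lfp : (s + 1) * n_seg_lfp] = y
        fluo = apply_kernel(lfp, design.lfp_fs_hz, kspec, design.fs_hz)
        noise_rng = _rng(design.seed, "noise", fish)
        sd = fluo.std(axis=1, keepdims=True) / design.measurement_snr
        fluo = fluo + sd * noise_rng.standard_normal(fluo.shape)
        data.append(fluo)
        trajectories.append(used_traj)

    n_out = data[0].shape[1]
    time_s = np.arange(n_out) / design.fs_hz
    return SyntheticExperiment(
        design=design,
        time_s=time_s,
        data=tuple(data),
        channel_names=tuple(design.channel_names),
        basis=basis,
        true_beta=beta,
        param_names=pmap.names,
        trajectories=tuple(trajectories),
        segment_times=seg_times,
    )
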