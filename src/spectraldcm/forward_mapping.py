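"""Low-dimensional projection of intrinsic-parameter trajectories and
generative band-power maps.

Per-window posterior trajectories of one region's intrinsic parameters are
reduced by PCA -- separately for the five coupling gains and the two time
constants -- and the resulting two-dimensional score plane is mapped to
predicted delta/gamma log band power by running the single-source
generative model at each grid point. Because the model is generative, the
prediction grid may extend far beyond the Nyquist frequency of the data it
was fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import load_defaults
from .errors import ParameterError, SpectralDCMError
from .neural_mass import (
    CrossSpectrum,
    FrequencyGrid,
    ModelConstants,
    SourceParams,
    single_source_model,
    transfer_csd,
)

GAIN_PARAMS = ("h1", "h2", "h3", "h4", "h5")
TAU_PARAMS = ("t_e", "t_i")

__all__ = [
    "ParameterTrajectory",
    "BandDefinition",
    "PCAProjection",
    "BandPowerMap",
    "TrajectoryOverlay",
    "pca_project",
    "band_power",
    "band_power_map",
    "trajectory_overlay",
    "plot_band_map",
]


@dataclass(frozen=True)
class ParameterTrajectory:
    """Per-window posterior means of one region's intrinsic parameters."""

    window_times: np.ndarray          # (k,)
    values: np.ndarray                # (k, 7) ordered h1..h5, t_e, t_i
    param_names: tuple[str, ...] = GAIN_PARAMS + TAU_PARAMS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != np.asarray(self.window_times).size:
            raise ParameterError("values must be (n_windows, n_params)")
        if v.shape[1] != len(self.param_names):
            raise ParameterError("values width must match param_names")
        if not np.all(np.isfinite(v)):
            raise ParameterError("trajectory contains non-finite values")
        object.__setattr__(self, "values", v)

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.param_names.index(n) for n in names]
        return self.values[:, idx]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band in Hz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not (0 < self.lo_hz < self.hi_hz):
            raise ParameterError("need 0 < lo_hz < hi_hz")


@dataclass(frozen=True)
class PCAProjection:
    """Orthonormal components of one parameter group."""

    components: np.ndarray        # (n_components, d)
    scores: np.ndarray            # (k, n_components)
    variance_fractions: np.ndarray
    mean: np.ndarray              # (d,) centering
    param_names: tuple[str, ...]

    def reconstruct(self) -> np.ndarray:
        """Centered-input reconstruction from the retained components."""
        return self.scores @ self.components + self.mean[None, :]


def _pca(data: np.ndarray, n_components: int) -> tuple[np.ndarray, ...]:
    mean = data.mean(axis=0)
    xc = data - mean
    if np.allclose(xc, 0.0):
        raise ParameterError("trajectory is constant: PCA variance degenerate")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    comps = vt[:n_components]
    # sign convention: largest-magnitude loading positive
    for i in range(comps.shape[0]):
        pivot = np.argmax(np.abs(comps[i]))
        if comps[i, pivot] < 0:
            comps[i] = -comps[i]
    scores = xc @ comps.T
    return comps, scores, fractions[:n_components], mean


def pca_project(
    traj: ParameterTrajectory,
    groups: Mapping[str, Sequence[str]] | None = None,
    n_components: int = 1,
) -> dict[str, PCAProjection]:
    """PCA per parameter group (default: coupling gains, time constants)."""
    if traj.values.shape[0] < 3:
        raise ParameterError("need at least 3 windows for a PCA")
    groups = groups or {"gains": GAIN_PARAMS, "time_constants": TAU_PARAMS}
    out = {}
    for name, params in groups.items():
        data = traj.columns(params)
        ncomp = min(n_components, data.shape[1])
        comps, scores, fractions, mean = _pca(data, ncomp)
        out[name] = PCAProjection(
            components=comps,
            scores=scores,
            variance_fractions=fractions,
            mean=mean,
            param_names=tuple(params),
        )
    return out


def band_power(
    spectrum: CrossSpectrum, lo_hz: float, hi_hz: float, channel: int = 0
) -> float:
    """Integrated auto-power over [lo_hz, hi_hz) -- additive over a partition."""
    f = spectrum.grid.frequencies
    sel = (f >= lo_hz) & (f < hi_hz)
    df = spectrum.grid.resolution
    return float(spectrum.auto(channel)[sel].sum() * df)


def _mean_log_band_power(
    spectrum: CrossSpectrum, band: BandDefinition, channel: int = 0
) -> float:
    f = spectrum.grid.frequencies
    sel = (f >= band.lo_hz) & (f <= band.hi_hz)
    if not sel.any():
        raise ParameterError(f"band {band.name} outside the prediction grid")
    return float(np.mean(np.log(spectrum.auto(channel)[sel])))


@dataclass(frozen=True)
class BandPowerMap:
    """Predicted mean log band power over the two-component score plane."""

    scores_1: np.ndarray              # grid along the gain component
    scores_2: np.ndarray              # grid along the time-constant component
    surfaces: dict[str, np.ndarray]   # band name -> (n1, n2), NaN if unstable
    stable: np.ndarray                # (n1, n2) bool
    bands: tuple[BandDefinition, ...]


def band_power_map(
    base: SourceParams,
    pc_conn: np.ndarray,
    pc_tau: np.ndarray,
    grid_1: np.ndarray,
    grid_2: np.ndarray,
    bands: Sequence[BandDefinition] | None = None,
    constants: ModelConstants | None = None,
    config: dict | None = None,
) -> BandPowerMap:
    """Map (gain-score, tau-score) combinations to predicted band power.

    Each grid point adds ``s1 * pc_conn`` to the five gains and
    ``s2 * pc_tau`` to the two time-constant log-scalings of ``base``,
    predicts the steady-state spectrum on an extended grid and records the
    mean log power per band. Unstable points are flagged (NaN + mask),
    never silently filled.
    """
    cfg = (config or load_defaults())["forward_mapping"]
    bands = tuple(bands) if bands else (
        BandDefinition("delta", *cfg["delta_band_hz"]),
        BandDefinition("gamma", *cfg["gamma_band_hz"]),
    )
    pc_conn = np.asarray(pc_conn, dtype=float).reshape(-1)
    pc_tau = np.asarray(pc_tau, dtype=float).reshape(-1)
    if pc_conn.size != 5 or pc_tau.size != 2:
        raise ParameterError("pc_conn must have 5 loadings and pc_tau 2")
    grid_1 = np.asarray(grid_1, dtype=float)
    grid_2 = np.asarray(grid_2, dtype=float)
    fgrid = FrequencyGrid.regular(
        float(cfg["map_f_min_hz"]), float(cfg["map_f_max_hz"]),
        float(cfg["map_f_step_hz"]),
    )
    constants = constants or ModelConstants()

    def predict(s1: float, s2: float) -> CrossSpectrum | None:
        p = base.with_updates(
            h=base.h + s1 * pc_conn,
            t_e=base.t_e + s2 * pc_tau[0],
            t_i=base.t_i + s2 * pc_tau[1],
        )
        try:
            return transfer_csd(single_source_model(p, constants), fgrid)
        except SpectralDCMError:
            return None

    if predict(0.0, 0.0) is None:
        raise ParameterError("base model is unstable at the score-plane origin")
    surfaces = {b.name: np.full((grid_1.size, grid_2.size), np.nan) for b in bands}
    stable = np.zeros((grid_1.size, grid_2.size), dtype=bool)
    for i, s1 in enumerate(grid_1):
        for j, s2 in enumerate(grid_2):
            S = predict(float(s1), float(s2))
            if S is None:
                continue
            stable[i, j] = True
            for b in bands:
                surfaces[b.name][i, j] = _mean_log_band_power(S, b)
    return BandPowerMap(
        scores_1=grid_1, scores_2=grid_2, surfaces=surfaces,
        stable=stable, bands=bands,
    )


@dataclass(frozen=True)
class TrajectoryOverlay:
    """Time-ordered path of window scores through the band-power plane."""

    scores: np.ndarray        # (k, 2)
    window_times: np.ndarray  # (k,)

    @property
    def n_points(self) -> int:
        return self.scores.shape[0]


def trajectory_overlay(
    scores: np.ndarray,
    window_times: np.ndarray,
    surfaces: BandPowerMap | None = None,
) -> TrajectoryOverlay:
    """Order window scores by time for overlay on a band-power map."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    times = np.asarray(window_times, dtype=float).reshape(-1)
    if scores.shape[0] != times.size:
        raise ParameterError("scores and window_times must align")
    order = np.argsort(times, kind="stable")
    return TrajectoryOverlay(scores=scores[order], window_times=times[order])


def plot_band_map(
    bmap: BandPowerMap,
    overlay: TrajectoryOverlay | None = None,
    heat_band: str = "delta",
    isocline_band: str = "gamma",
    ax=None,
):
    """Heat map of one band with isoclines of another, optional trajectory."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    extent = [bmap.scores_2.min(), bmap.scores_2.max(),
              bmap.scores_1.min(), bmap.scores_1.max()]
    im = ax.imshow(bmap.surfaces[heat_band], origin="lower", extent=extent,
                   aspect="auto", cmap="gray")
    ax.figure.colorbar(im, ax=ax, label=f"log {heat_band} power")
    iso = bmap.surfaces.get(isocline_band)
    if iso is not None:
        ax.contour(bmap.scores_2, bmap.scores_1, iso, colors="purple",
                   linewidths=0.8)
    if overlay is not None:
        sc = ax.scatter(overlay.scores[:, 1], overlay.scores[:, 0],
                        c=overlay.window_times, cmap="viridis", s=12)
        ax.figure.colorbar(sc, ax=ax, label="time (s)")
    ax.set_xlabel("time-constant component score")
    ax.set_ylabel("coupling component score")
    return ax
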