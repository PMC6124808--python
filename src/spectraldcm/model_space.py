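"""Factorial architecture model space, Bayesian model reduction and
family-wise comparison.

The network comprises five bilateral region pairs ordered rostro-caudally.
Architectures cross three factors: a hub (one region pair reciprocally
connected to all other nodes, or none; 6 levels), presence of neighbouring
(rostro-caudal chain) connections, and presence of homotopic (left-right)
connections -- 6 x 2 x 2 = 24 models, with the all-off combination as the
null model.

Mask convention: ``mask[i, j] = 1`` denotes a connection from node j to
node i. "Forward" is caudal-to-rostral / into-the-hub; "backward" the
reverse; homotopic edges are carried (both directions) on the forward
mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .variational_inversion import InversionResult, PriorDensity

DEFAULT_REGIONS = ("Tect", "Crbl", "RHbr", "MHbr", "CHbr/RSc")

__all__ = [
    "DEFAULT_REGIONS",
    "ArchitectureFactor",
    "ArchitectureModel",
    "FamilyPartition",
    "node_names",
    "build_factorial_space",
    "full_masks",
    "reduce_model",
    "compare_families",
    "hub_partition",
    "short_range_partition",
    "space_table",
]


def node_names(regions: Sequence[str] = DEFAULT_REGIONS) -> list[str]:
    """Node ordering: left/right interleaved per rostro-caudal pair."""
    return [f"{r}_{side}" for r in regions for side in ("L", "R")]


@dataclass(frozen=True)
class ArchitectureFactor:
    """One cell of the factorial design."""

    hub: str | None
    neighbouring: bool
    homotopic: bool

    def label(self) -> str:
        hub = self.hub or "none"
        return (f"hub={hub};nbr={'on' if self.neighbouring else 'off'};"
                f"hom={'on' if self.homotopic else 'off'}")


@dataclass(frozen=True)
class ArchitectureModel:
    """A factor combination with its realised structural masks."""

    index: int
    factor: ArchitectureFactor
    mask_fwd: np.ndarray
    mask_bwd: np.ndarray

    def edge_list(self) -> list[tuple[str, int, int]]:
        edges = [("fwd", int(i), int(j)) for i, j in np.argwhere(self.mask_fwd)]
        edges += [("bwd", int(i), int(j)) for i, j in np.argwhere(self.mask_bwd)]
        return edges


def _pair_nodes(pair: int) -> tuple[int, int]:
    return 2 * pair, 2 * pair + 1


def build_factorial_space(
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> list[ArchitectureModel]:
    """Enumerate the 24 architecture hypotheses over 5 bilateral pairs.

    Hub masks connect both nodes of the hub pair reciprocally with every
    other node (forward into the hub, backward out). Neighbouring masks
    connect rostro-caudally adjacent regions on each side (forward toward
    the rostral end). Homotopic masks connect the left/right nodes of each
    pair. The all-off combination has no extrinsic connections.
    """
    regions = list(regions)
    if len(regions) != 5 or len(set(regions)) != 5:
        raise ParameterError("expected 5 uniquely named bilateral regions")
    n = 10
    models = []
    idx = 0
    for hub in (None, *regions):
        for neighbouring in (False, True):
            for homotopic in (False, True):
                fwd = np.zeros((n, n))
                bwd = np.zeros((n, n))
                if hub is not None:
                    hub_nodes = _pair_nodes(regions.index(hub))
                    for h in hub_nodes:
                        for o in range(n):
                            if o in hub_nodes:
                                continue
                            fwd[h, o] = 1.0   # other -> hub (forward)
                            bwd[o, h] = 1.0   # hub -> other (backward)
                if neighbouring:
                    for pair in range(4):
                        for side in range(2):
                            r = 2 * pair + side
                            c = 2 * (pair + 1) + side
                            fwd[r, c] = 1.0   # caudal -> rostral
                            bwd[c, r] = 1.0
                if homotopic:
                    for pair in range(5):
                        left, right = _pair_nodes(pair)
                        fwd[left, right] = 1.0
                        fwd[right, left] = 1.0
                models.append(ArchitectureModel(
                    index=idx,
                    factor=ArchitectureFactor(hub, neighbouring, homotopic),
                    mask_fwd=fwd,
                    mask_bwd=bwd,
                ))
                idx += 1
    return models


def full_masks(n: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Masks of the fully connected parent model (union of the space)."""
    off = 1.0 - np.eye(n)
    return off, off.copy()


def reduce_model(
    full: InversionResult,
    full_prior: PriorDensity,
    reduced_prior: PriorDensity,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Bayesian model reduction: evidence and posterior under a new prior.

    Given the full model's Gaussian posterior and prior, computes in closed
    form the free energy and posterior that inversion under
    ``reduced_prior`` would have produced, without refitting. Returns
    ``(F_reduced, (mean, cov))`` with F on the same scale as
    ``full.free_energy``.
    """
    if reduced_prior.n != full_prior.n:
        raise ParameterError("reduced prior must have the same dimension")
    P0, ld0 = _precision(full_prior.cov)
    Pr0, ldr0 = _precision(reduced_prior.cov)
    P, ldp = _precision(full.posterior_cov)
    mu0 = full_prior.mean
    mur0 = reduced_prior.mean
    mu = full.posterior_mean

    Pr = P + Pr0 - P0
    evals = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if evals.min() <= 0:
        raise ParameterError(
            "reduced posterior covariance is not positive definite"
        )
    br = P @ mu + Pr0 @ mur0 - P0 @ mu0
    mur = np.linalg.solve(Pr, br)
    _, ldr = np.linalg.slogdet(Pr)
    dF = 0.5 * (
        (-ldr0) - (-ld0) + (-ldp) - ldr
        + float(mur @ (Pr @ mur)) - float(mu @ (P @ mu))
        + float(mu0 @ (P0 @ mu0)) - float(mur0 @ (Pr0 @ mur0))
    )
    cov_r = np.linalg.inv(Pr)
    cov_r = 0.5 * (cov_r + cov_r.T)
    return full.free_energy + dF, (mur, cov_r)


def _precision(cov: np.ndarray, floor: float = 1e-12) -> tuple[float, float]:
    """Inverse and log-det of a covariance, flooring zero variances."""
    cov = np.array(cov, dtype=float)
    if cov.ndim == 1:
        cov = np.diag(cov)
    zero = np.diag(cov) <= 0
    if zero.any():
        cov[zero, :] = 0.0
        cov[:, zero] = 0.0
        cov[np.where(zero)[0], np.where(zero)[0]] = floor
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ParameterError("covariance must be positive definite")
    return np.linalg.inv(cov), float(ld)


@dataclass(frozen=True)
class FamilyPartition:
    """Named, disjoint, exhaustive grouping of model indices."""

    families: dict[str, tuple[int, ...]]
    n_models: int

    def __post_init__(self):
        seen: set[int] = set()
        for name, idxs in self.families.items():
            if len(idxs) == 0:
                raise ParameterError(f"family {name!r} is empty")
            if seen & set(idxs):
                raise ParameterError("families must be disjoint")
            seen |= set(idxs)
        if seen != set(range(self.n_models)):
            raise ParameterError(
                "families must partition all model indices exhaustively"
            )


def compare_families(
    F: np.ndarray, partition: FamilyPartition
) -> dict[str, float]:
    """Posterior family probabilities under a flat prior over models.

    Model posteriors are softmax(F); family probabilities are sums of
    member posteriors (invariant to adding a constant to every F).
    """
    F = np.asarray(F, dtype=float).reshape(-1)
    if not np.all(np.isfinite(F)):
        raise ParameterError("all free energies must be finite")
    if F.size != partition.n_models:
        raise ParameterError("F length does not match the partition")
    p = np.exp(F - F.max())
    p /= p.sum()
    return {name: float(p[list(idxs)].sum())
            for name, idxs in partition.families.items()}


def hub_partition(models: Sequence[ArchitectureModel]) -> FamilyPartition:
    """Six families by hub identity (including 'none')."""
    fams: dict[str, list[int]] = {}
    for m in models:
        fams.setdefault(m.factor.hub or "none", []).append(m.index)
    return FamilyPartition(
        families={k: tuple(v) for k, v in fams.items()}, n_models=len(models)
    )


def short_range_partition(models: Sequence[ArchitectureModel]) -> FamilyPartition:
    """Four families by the 2 x 2 short-range (neighbouring x homotopic) cell."""
    fams: dict[str, list[int]] = {}
    for m in models:
        key = (f"nbr={'on' if m.factor.neighbouring else 'off'};"
               f"hom={'on' if m.factor.homotopic else 'off'}")
        fams.setdefault(key, []).append(m.index)
    return FamilyPartition(
        families={k: tuple(v) for k, v in fams.items()}, n_models=len(models)
    )


def space_table(models: Sequence[ArchitectureModel]) -> pd.DataFrame:
    """Machine-readable summary: one row per model with its edge list."""
    rows = []
    for m in models:
        edges = ";".join(f"{kind}:{j}->{i}" for kind, i, j in m.edge_list())
        rows.append({
            "model": m.index,
            "hub": m.factor.hub or "none",
            "neighbouring": int(m.factor.neighbouring),
            "homotopic": int(m.factor.homotopic),
            "n_edges": int(m.mask_fwd.sum() + m.mask_bwd.sum()),
            "edges": edges,
        })
    return pd.DataFrame(rows)
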