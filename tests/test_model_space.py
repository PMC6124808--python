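import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectraldcm.errors import ParameterError
from spectraldcm.model_space import (
    FamilyPartition,
    build_factorial_space,
    compare_families,
    full_masks,
    hub_partition,
    node_names,
    reduce_model,
    short_range_partition,
    space_table,
)
from spectraldcm.neural_mass import CrossSpectrum, FrequencyGrid
from spectraldcm.variational_inversion import InversionResult, PriorDensity


def _dummy_result(mean, cov, F=0.0, prior=None):
    grid = FrequencyGrid(np.array([1.0]))
    dummy = CrossSpectrum(grid, np.ones((1, 1, 1)))
    n = len(mean)
    prior = prior or PriorDensity(np.zeros(n), np.eye(n))
    return InversionResult(
        posterior_mean=np.asarray(mean, float),
        posterior_cov=np.asarray(cov, float),
        free_energy=F, predicted=dummy, variance_explained=1.0,
        iterations=1, converged=True,
        names=tuple(f"p{i}" for i in range(n)),
        prior=prior, log_precision=0.0,
    )


class TestFactorialSpace:
    def test_exactly_24_distinct_models(self):
        models = build_factorial_space()
        assert len(models) == 24
        keys = {(m.mask_fwd.tobytes(), m.mask_bwd.tobytes()) for m in models}
        assert len(keys) == 24

    def test_null_model_has_no_edges(self):
        models = build_factorial_space()
        null = [m for m in models if m.factor.hub is None
                and not m.factor.neighbouring and not m.factor.homotopic]
        assert len(null) == 1
        assert null[0].mask_fwd.sum() == 0
        assert null[0].mask_bwd.sum() == 0

    def test_tect_hub_connects_hub_pair_to_all_others(self):
        models = build_factorial_space()
        m = next(mm for mm in models if mm.factor.hub == "Tect"
                 and not mm.factor.neighbouring and not mm.factor.homotopic)
        hub_nodes = {0, 1}
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                expect_f = i in hub_nodes and j not in hub_nodes
                expect_b = j in hub_nodes and i not in hub_nodes
                assert m.mask_fwd[i, j] == float(expect_f)
                assert m.mask_bwd[i, j] == float(expect_b)

    def test_neighbouring_connects_rostrocaudal_chain(self):
        models = build_factorial_space()
        m = next(mm for mm in models if mm.factor.hub is None
                 and mm.factor.neighbouring and not mm.factor.homotopic)
        # 4 adjacent pairs x 2 sides, one forward + one backward edge each
        assert m.mask_fwd.sum() == 8
        assert m.mask_bwd.sum() == 8
        assert m.mask_fwd[0, 2] == 1.0  # Crbl_L -> Tect_L (caudal to rostral)
        assert m.mask_bwd[2, 0] == 1.0

    def test_homotopic_connects_bilateral_pairs(self):
        models = build_factorial_space()
        m = next(mm for mm in models if mm.factor.hub is None
                 and not mm.factor.neighbouring and mm.factor.homotopic)
        assert m.mask_fwd.sum() == 10
        for pair in range(5):
            assert m.mask_fwd[2 * pair, 2 * pair + 1] == 1.0
            assert m.mask_fwd[2 * pair + 1, 2 * pair] == 1.0

    def test_malformed_regions_rejected(self):
        with pytest.raises(ParameterError):
            build_factorial_space(["A", "B", "C"])
        with pytest.raises(ParameterError):
            build_factorial_space(["A"] * 5)

    def test_node_names_interleave_sides(self):
        names = node_names()
        assert names[0] == "Tect_L"
        assert names[1] == "Tect_R"
        assert names[-1] == "CHbr/RSc_R"

    def test_space_table_lists_all_models(self):
        models = build_factorial_space()
        table = space_table(models)
        assert len(table) == 24
        assert set(table.columns) >= {"model", "hub", "neighbouring",
                                      "homotopic", "edges"}


class TestReduceModel:
    def test_identity_reduction_is_neutral(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        cov = A @ A.T / 10 + np.eye(4)
        prior = PriorDensity(np.zeros(4), np.eye(4) * 0.5)
        full = _dummy_result(rng.standard_normal(4), cov, F=-12.3, prior=prior)
        F, (mu, cov_r) = reduce_model(full, prior, prior)
        assert F == pytest.approx(full.free_energy, abs=1e-8)
        assert np.abs(mu - full.posterior_mean).max() < 1e-8

    def test_matches_conjugate_analytic_evidence(self):
        rng = np.random.default_rng(1)
        n_y, n_p = 12, 2
        X = rng.standard_normal((n_y, n_p))
        s2 = 0.5
        y = X @ np.array([0.7, -0.3]) + rng.standard_normal(n_y) * np.sqrt(s2)

        def evidence(V):
            C = X @ V @ X.T + s2 * np.eye(n_y)
            _, ld = np.linalg.slogdet(C)
            return float(-0.5 * n_y * np.log(2 * np.pi) - 0.5 * ld
                         - 0.5 * y @ np.linalg.solve(C, y))

        V_full = np.eye(n_p)
        P = X.T @ X / s2 + np.linalg.inv(V_full)
        S = np.linalg.inv(P)
        mu = S @ (X.T @ y / s2)
        full = _dummy_result(mu, S, F=evidence(V_full),
                             prior=PriorDensity(np.zeros(n_p), V_full))
        V_red = np.diag([1.0, 1e-8])
        F_red, _ = reduce_model(full, PriorDensity(np.zeros(n_p), V_full),
                                PriorDensity(np.zeros(n_p), V_red))
        assert F_red == pytest.approx(evidence(V_red), abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        prior = PriorDensity(np.zeros(2), np.eye(2))
        full = _dummy_result(np.zeros(2), np.eye(2), prior=prior)
        with pytest.raises(ParameterError):
            reduce_model(full, prior, PriorDensity(np.zeros(3), np.eye(3)))


class TestCompareFamilies:
    def test_flat_evidence_gives_uniform_families(self):
        models = build_factorial_space()
        probs = compare_families(np.zeros(24), hub_partition(models))
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        for p in probs.values():
            assert p == pytest.approx(1.0 / 6.0)

    def test_dominant_model_dominates_family(self):
        models = build_factorial_space()
        F = np.zeros(24)
        F[7] = 10.0
        part = short_range_partition(models)
        probs = compare_families(F, part)
        fam = next(k for k, idxs in part.families.items() if 7 in idxs)
        assert probs[fam] > 0.99

    @given(shift=st.floats(-500, 500))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance(self, shift):
        models = build_factorial_space()
        rng = np.random.default_rng(5)
        F = rng.standard_normal(24)
        part = hub_partition(models)
        p1 = compare_families(F, part)
        p2 = compare_families(F + shift, part)
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], abs=1e-9)

    def test_empty_family_rejected(self):
        with pytest.raises(ParameterError):
            FamilyPartition({"a": (), "b": tuple(range(3))}, n_models=3)

    def test_partition_must_be_exhaustive(self):
        with pytest.raises(ParameterError):
            FamilyPartition({"a": (0, 1)}, n_models=3)

    def test_non_finite_evidence_rejected(self):
        models = build_factorial_space()
        F = np.zeros(24)
        F[0] = np.nan
        with pytest.raises(ParameterError):
            compare_families(F, hub_partition(models))


def test_full_masks_cover_the_space():
    fwd, bwd = full_masks(10)
    for m in build_factorial_space():
        assert np.all(fwd >= m.mask_fwd)
        assert np.all(bwd >= m.mask_bwd)


def test_hub_recovery_from_generated_data(grid):
    """Data with a tectal hub: hub-present reductions outscore hub-absent."""
    from spectraldcm.neural_mass import (
        FrequencyGrid,
        NetworkModel,
        SourceParams,
        transfer_csd,
    )
    from spectraldcm.variational_inversion import (
        ParameterMap,
        default_prior,
        invert,
    )
    from spectraldcm.config import merge_config

    models = build_factorial_space()
    tect = next(m for m in models if m.factor.hub == "Tect"
                and not m.factor.neighbouring and not m.factor.homotopic)
    coarse = FrequencyGrid.regular(0.5, 10.0, 0.75)
    cfg = merge_config({"inversion": {"max_iterations": 12}})
    fwd_full, bwd_full = full_masks(10)
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        a_gain = 1.0 + 0.3 * rng.standard_normal()
        truth = NetworkModel(
            sources=tuple(SourceParams() for _ in range(10)),
            a_fwd=a_gain * tect.mask_fwd, a_bwd=a_gain * tect.mask_bwd,
            mask_fwd=tect.mask_fwd, mask_bwd=tect.mask_bwd,
        )
        data = transfer_csd(truth, coarse)
        base = NetworkModel(sources=tuple(SourceParams() for _ in range(10)),
                            mask_fwd=fwd_full, mask_bwd=bwd_full)
        pmap = ParameterMap(base, intrinsic=("noise_amp",), extrinsic=True)
        prior = default_prior(pmap, cfg)
        full = invert(base, data, prior=prior, pmap=pmap, config=cfg)
        pinned = 1e-8
        F = np.empty(24)
        var = np.diag(prior.cov).copy()
        for mm in models:
            v = var.copy()
            for p, name in enumerate(pmap.names):
                kind = name[:3]
                if kind in ("fwd", "bwd"):
                    i, j = map(int, name[4:-1].split(","))
                    mask = mm.mask_fwd if kind == "fwd" else mm.mask_bwd
                    if mask[i, j] == 0:
                        v[p] = pinned
            red = PriorDensity(prior.mean, np.diag(v))
            F[mm.index], _ = reduce_model(full, prior, red)
        probs = compare_families(F, hub_partition(models))
        hub_present = sum(v for k, v in probs.items() if k != "none")
        wins += probs["Tect"] == max(probs.values()) or hub_present > 0.5
    assert wins >= 4
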