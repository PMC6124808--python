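import numpy as np
import pytest

from spectraldcm.errors import ParameterError
from spectraldcm.neural_mass import (
    NetworkModel,
    SourceParams,
    single_source_model,
    transfer_csd,
)
from spectraldcm.variational_inversion import (
    ParameterMap,
    PriorDensity,
    default_prior,
    invert,
    invert_windows,
    variance_explained,
    vectorize_csd,
)

from conftest import make_source

INTR = ("h1", "h2", "h3", "h4", "h5", "t_e", "t_i", "noise_amp", "noise_exp")


@pytest.fixture(scope="module")
def setup(grid):
    base = single_source_model()
    pmap = ParameterMap(base, extrinsic=False)
    prior = default_prior(pmap)
    return base, pmap, prior


class TestParameterMap:
    def test_round_trip(self, setup):
        base, pmap, _ = setup
        theta = np.linspace(-0.3, 0.3, len(pmap))
        m = pmap.apply(theta)
        assert np.allclose(pmap.pack(m), theta)

    def test_extrinsic_edges_follow_masks(self):
        mask = np.array([[0.0, 1.0], [0.0, 0.0]])
        m = NetworkModel(sources=(SourceParams(),) * 2, mask_fwd=mask)
        pmap = ParameterMap(m)
        assert "fwd[0,1]" in pmap.names
        assert "fwd[1,0]" not in pmap.names

    def test_dimension_mismatch_rejected(self, setup):
        _, pmap, _ = setup
        with pytest.raises(ParameterError):
            pmap.apply(np.zeros(len(pmap) + 1))

    def test_unknown_field_rejected(self, setup):
        base, _, _ = setup
        with pytest.raises(ParameterError):
            ParameterMap(base, intrinsic=("h9",))


class TestPriorDensity:
    def test_asymmetric_covariance_rejected(self):
        cov = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ParameterError):
            PriorDensity(np.zeros(2), cov)

    def test_negative_eigenvalue_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ParameterError):
            PriorDensity(np.zeros(2), cov)

    def test_dimension_checked_in_invert(self, setup, base_csd):
        base, pmap, _ = setup
        bad = PriorDensity(np.zeros(3), np.eye(3))
        with pytest.raises(ParameterError):
            invert(base, base_csd, prior=bad, pmap=pmap)


class TestInvert:
    def test_self_inversion_recovers_prior_mean(self, setup, base_csd):
        base, pmap, prior = setup
        r = invert(base, base_csd, prior=prior, pmap=pmap)
        assert np.abs(r.posterior_mean - prior.mean).max() < 0.1
        assert r.variance_explained > 0.9

    def test_free_energy_trace_monotone(self, setup, grid):
        base, pmap, prior = setup
        data = transfer_csd(single_source_model(make_source(h1=0.5)), grid)
        r = invert(base, data, prior=prior, pmap=pmap)
        assert np.all(np.diff(r.f_trace) >= -1e-6)

    def test_two_point_ordinal_recovery(self, setup, grid):
        base, pmap, prior = setup
        ests = {}
        for v in (0.5, -0.5):
            data = transfer_csd(single_source_model(make_source(h1=v)), grid)
            r = invert(base, data, prior=prior, pmap=pmap)
            ests[v] = r.named_posterior()["s0.h1"]
        assert ests[0.5] > 0
        assert ests[0.5] > ests[-0.5]

    def test_bitwise_deterministic(self, setup, grid):
        base, pmap, prior = setup
        data = transfer_csd(single_source_model(make_source(h3=0.3)), grid)
        r1 = invert(base, data, prior=prior, pmap=pmap)
        r2 = invert(base, data, prior=prior, pmap=pmap)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.posterior_mean, r2.posterior_mean)

    def test_sign_recovery_battery(self, setup, grid):
        # 20 single-parameter perturbations at +-0.5 (known data scale)
        base, pmap, prior = setup
        cases = [(INTR[i % 9], 0.5 if (i // 9) % 2 == 0 else -0.5)
                 for i in range(20)]
        correct = 0
        for name, v in cases:
            kwargs = {name: v}
            data = transfer_csd(single_source_model(make_source(**kwargs)), grid)
            r = invert(base, data, prior=prior, pmap=pmap, data_scale=1.0)
            est = r.named_posterior()[f"s0.{name}"]
            correct += np.sign(est) == np.sign(v)
        assert correct >= 18

    def test_model_comparison_prefers_true_structure(self, grid):
        # data with a real forward connection: the model containing it wins
        mask = np.array([[0.0, 1.0], [0.0, 0.0]])
        wins = 0
        for seed in range(5):
            gain = 0.6 + 0.2 * seed
            truth = NetworkModel(
                sources=(SourceParams(), SourceParams()),
                a_fwd=gain * mask, mask_fwd=mask,
            )
            data = transfer_csd(truth, grid)
            with_conn = NetworkModel(sources=(SourceParams(),) * 2,
                                     mask_fwd=mask)
            without = NetworkModel(sources=(SourceParams(),) * 2)
            f1 = invert(with_conn, data).free_energy
            f0 = invert(without, data).free_energy
            wins += f1 > f0
        assert wins >= 4


class TestVarianceExplained:
    def test_perfect_prediction_is_one(self, setup, base_csd):
        base, pmap, prior = setup
        r = invert(base, base_csd, prior=prior, pmap=pmap)
        ve = variance_explained(r, base_csd)
        assert ve > 0.999

    def test_zero_prediction_clipped_with_warning(self, base_csd, caplog):
        from spectraldcm.variational_inversion import _variance_explained_vec

        obs = vectorize_csd(base_csd)
        with caplog.at_level("WARNING"):
            ve = _variance_explained_vec(np.zeros_like(obs), obs)
        assert ve == 0.0
        assert any("underperforms" in r.getMessage() for r in caplog.records)

    def test_zero_power_data_rejected(self, base_csd):
        obs = np.zeros(4)
        from spectraldcm.variational_inversion import _variance_explained_vec

        with pytest.raises(ParameterError):
            _variance_explained_vec(np.zeros(4), obs)

    def test_grid_mismatch_rejected(self, setup, base_csd, grid):
        from spectraldcm.neural_mass import FrequencyGrid

        base, pmap, prior = setup
        r = invert(base, base_csd, prior=prior, pmap=pmap)
        other = transfer_csd(base, FrequencyGrid.regular(1.0, 5.0, 1.0))
        with pytest.raises(ParameterError):
            variance_explained(r, other)


@pytest.fixture(scope="module")
def ramp_windows(grid):
    truths = np.linspace(-0.5, 0.5, 6)
    return truths, [
        transfer_csd(single_source_model(make_source(h1=v)), grid)
        for v in truths
    ]


class TestInvertWindows:
    def test_single_window_reduces_to_invert(self, setup, base_csd):
        base, pmap, prior = setup
        wi = invert_windows(base, [base_csd], prior=prior, pmap=pmap)
        single = invert(base, base_csd, prior=prior, pmap=pmap)
        assert wi.results[0].free_energy == single.free_energy

    def test_ramp_trajectory_recovered(self, setup, ramp_windows):
        from scipy.stats import spearmanr

        base, pmap, prior = setup
        truths, windows = ramp_windows
        wi = invert_windows(base, windows, prior=prior, pmap=pmap)
        ests = [r.named_posterior()["s0.h1"] for r in wi.results]
        assert spearmanr(ests, truths).statistic > 0.8

    def test_window_permutation_equivariance(self, setup, ramp_windows):
        base, pmap, prior = setup
        _, windows = ramp_windows
        wi = invert_windows(base, windows, prior=prior, pmap=pmap)
        perm = [3, 0, 5, 1, 4, 2]
        wi_p = invert_windows(base, [windows[i] for i in perm],
                              prior=prior, pmap=pmap)
        for j, i in enumerate(perm):
            assert wi_p.results[j].free_energy == wi.results[i].free_energy

    def test_empty_rejected(self, setup):
        base, pmap, prior = setup
        with pytest.raises(ParameterError):
            invert_windows(base, [], prior=prior, pmap=pmap)


def test_eigenmode_reduced_fit(grid):
    # optional data reduction: fit only the leading spectral eigenmode
    from spectraldcm.config import merge_config

    mask = np.array([[0.0, 1.0], [1.0, 0.0]])
    truth = NetworkModel(sources=(SourceParams(),) * 2,
                         a_fwd=0.5 * mask, mask_fwd=mask)
    data = transfer_csd(truth, grid)
    model = NetworkModel(sources=(SourceParams(),) * 2, mask_fwd=mask)
    cfg = merge_config({"inversion": {"fit_eigenmodes": 1,
                                      "max_iterations": 16}})
    r = invert(model, data, config=cfg)
    assert r.predicted.n_channels == 1  # mode space
    assert r.variance_explained > 0.9
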