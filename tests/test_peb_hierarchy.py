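import numpy as np
import pytest

from spectraldcm.errors import ConditioningError, ParameterError
from spectraldcm.neural_mass import CrossSpectrum, FrequencyGrid
from spectraldcm.peb_hierarchy import (
    TemporalBasis,
    build_basis,
    peb_compare_sets,
    peb_fit,
    pk_bump,
)
from spectraldcm.variational_inversion import InversionResult, PriorDensity


def make_result(mean, var=0.01):
    grid = FrequencyGrid(np.array([1.0]))
    dummy = CrossSpectrum(grid, np.ones((1, 1, 1)))
    mean = np.asarray(mean, float)
    n = mean.size
    return InversionResult(
        posterior_mean=mean, posterior_cov=np.eye(n) * var, free_energy=0.0,
        predicted=dummy, variance_explained=1.0, iterations=1, converged=True,
        names=tuple(f"p{i}" for i in range(n)),
        prior=PriorDensity(np.zeros(n), np.eye(n)), log_precision=0.0,
    )


@pytest.fixture(scope="module")
def full_basis():
    times = np.arange(30.0, 9000.0, 50.0)
    return build_basis(times, 1800.0, fish_ids=None)


class TestBuildBasis:
    def test_pre_onset_columns_are_zero(self, full_basis):
        pre = full_basis.window_times < 1800.0
        for col in ("tonic_step", "pk_monophasic", "ramp",
                    "dct1", "dct2", "dct3"):
            assert np.all(full_basis.column(col)[pre] == 0.0)

    def test_tonic_step_is_binary(self, full_basis):
        assert set(np.unique(full_basis.column("tonic_step"))) == {0.0, 1.0}

    def test_pk_peaks_30_minutes_after_onset(self, full_basis):
        pk = full_basis.column("pk_monophasic")
        t = full_basis.window_times
        t_peak = t[np.argmax(pk)]
        assert abs(t_peak - (1800.0 + 1800.0)) <= 50.0
        assert np.sum(pk == pk.max()) == 1  # unique maximum

    def test_pk_normalised_to_peak_one(self):
        s = np.linspace(0.0, 9000.0, 100001)
        bump = pk_bump(s, 1800.0, 10800.0)
        assert bump.max() == pytest.approx(1.0, abs=1e-6)
        assert abs(s[np.argmax(bump)] - 1800.0) < 1.0

    def test_ramp_linear_and_scaled(self, full_basis):
        ramp = full_basis.column("ramp")
        post = full_basis.window_times >= 1800.0
        assert ramp.max() == pytest.approx(1.0)
        d = np.diff(ramp[post])
        assert np.allclose(d, d[0])

    def test_dct_columns_mutually_orthogonal(self, full_basis):
        d1 = full_basis.column("dct1")
        d2 = full_basis.column("dct2")
        d3 = full_basis.column("dct3")
        assert abs(d1 @ d2) < 1e-10
        assert abs(d1 @ d3) < 1e-10
        assert abs(d2 @ d3) < 1e-10

    def test_fish_columns_are_disjoint_indicators(self):
        times = np.arange(0.0, 100.0, 10.0)
        basis = build_basis(times, 50.0, fish_ids=[0] * 5 + [1] * 5)
        f0 = basis.column("fish_0")
        f1 = basis.column("fish_1")
        assert np.all(f0 + f1 == 1.0)
        assert np.all(f0 * f1 == 0.0)

    def test_onset_outside_span_rejected(self):
        with pytest.raises(ParameterError):
            build_basis(np.arange(0.0, 100.0, 10.0), 500.0)


class TestPebFit:
    def test_intercept_only_recovers_precision_weighted_mean(self):
        k = 10
        results = [make_result([0.5, -0.2], var=1e-4) for _ in range(k)]
        basis = TemporalBasis(np.arange(k, dtype=float), np.ones((k, 1)),
                              ("intercept",), 0.0)
        g = peb_fit(results, basis, ["p0", "p1"])
        assert np.abs(g.beta[0] - np.array([0.5, -0.2])).max() < 1e-3

    def test_step_effect_recovered(self):
        t = np.arange(20.0)
        step = (t >= 10).astype(float)
        X = np.column_stack([np.ones(20), step, np.linspace(0, 1, 20)])
        basis = TemporalBasis(t, X, ("fish_0", "tonic_step", "ramp"), 10.0)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            results = [make_result([0.4 * step[i] + 0.05 * rng.standard_normal(),
                                    0.05 * rng.standard_normal()])
                       for i in range(20)]
            g = peb_fit(results, basis, ["p0", "p1"])
            b = g.effect("tonic_step", "p0")
            others = [abs(g.effect("ramp", "p0")),
                      abs(g.effect("tonic_step", "p1")),
                      abs(g.effect("ramp", "p1"))]
            hits += b > 0 and abs(b) > max(others)
        assert hits >= 4

    def test_paired_permutation_invariance(self):
        t = np.arange(12.0)
        X = np.column_stack([np.ones(12), t / 11.0])
        basis = TemporalBasis(t, X, ("intercept", "ramp"), 0.0)
        rng = np.random.default_rng(3)
        results = [make_result(rng.standard_normal(2) * 0.2) for _ in range(12)]
        g1 = peb_fit(results, basis, ["p0", "p1"])
        perm = rng.permutation(12)
        basis_p = TemporalBasis(t, X[perm], ("intercept", "ramp"), 0.0)
        g2 = peb_fit([results[i] for i in perm], basis_p, ["p0", "p1"])
        assert np.allclose(g1.beta, g2.beta, atol=1e-10)
        assert g1.F_group == pytest.approx(g2.F_group, abs=1e-6)

    def test_collinear_design_names_columns(self):
        t = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.ones(10)])
        basis = TemporalBasis(t, X, ("intercept", "copy"), 0.0)
        results = [make_result([0.1]) for _ in range(10)]
        with pytest.raises(ConditioningError, match="copy|intercept"):
            peb_fit(results, basis, ["p0"])

    def test_shrinkage_never_inflates_window_covariance(self):
        t = np.arange(15.0)
        X = np.column_stack([np.ones(15), (t >= 7).astype(float)])
        basis = TemporalBasis(t, X, ("intercept", "tonic_step"), 7.0)
        rng = np.random.default_rng(0)
        results = [make_result(rng.standard_normal(3) * 0.3, var=0.05)
                   for _ in range(15)]
        g = peb_fit(results, basis, ["p0", "p1", "p2"])
        for w, r in enumerate(results):
            assert (np.trace(g.window_covs[w])
                    <= np.trace(r.posterior_cov) + 1e-12)

    def test_sign_recovery_of_two_regressor_mixture(self):
        t = np.arange(24.0)
        step = (t >= 12).astype(float)
        ramp = t / 23.0
        X = np.column_stack([np.ones(24), step, ramp])
        basis = TemporalBasis(t, X, ("fish_0", "tonic_step", "ramp"), 12.0)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            b_step = rng.choice([-0.5, 0.5])
            b_ramp = rng.choice([-0.5, 0.5])
            results = [make_result(
                [b_step * step[i] + b_ramp * ramp[i]
                 + 0.08 * rng.standard_normal()]) for i in range(24)]
            g = peb_fit(results, basis, ["p0"])
            ok = (np.sign(g.effect("tonic_step", "p0")) == np.sign(b_step)
                  and np.sign(g.effect("ramp", "p0")) == np.sign(b_ramp))
            hits += ok
        assert hits >= 18

    def test_requires_at_least_two_windows(self):
        basis = TemporalBasis(np.array([0.0]), np.ones((1, 1)),
                              ("intercept",), 0.0)
        with pytest.raises(ParameterError):
            peb_fit([make_result([0.1])], basis, ["p0"])

    def test_empty_parameter_set_rejected(self):
        basis = TemporalBasis(np.arange(3.0), np.ones((3, 1)),
                              ("intercept",), 0.0)
        with pytest.raises(ParameterError):
            peb_fit([make_result([0.1])] * 3, basis, [])


class TestCompareSets:
    @pytest.fixture
    def basis(self):
        t = np.arange(20.0)
        X = np.column_stack([np.ones(20), (t >= 10).astype(float)])
        return TemporalBasis(t, X, ("fish_0", "tonic_step"), 10.0)

    def test_fluctuating_everywhere_beats_restrictions(self, basis):
        step = basis.column("tonic_step")
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            results = [make_result(0.5 * step[i] * np.ones(4)
                                   + 0.05 * rng.standard_normal(4))
                       for i in range(20)]
            fams = {"none": (), "p0": ("p0",), "p1": ("p1",),
                    "all": ("p0", "p1", "p2", "p3")}
            _, winner, _ = peb_compare_sets(results, basis, fams)
            hits += winner == "all"
        assert hits >= 4

    def test_null_data_selects_none(self, basis):
        rng = np.random.default_rng(9)
        results = [make_result(0.3 + 0.02 * rng.standard_normal(2))
                   for _ in range(20)]
        fams = {"none": (), "p0": ("p0",), "all": ("p0", "p1")}
        scores, winner, _ = peb_compare_sets(results, basis, fams)
        assert winner == "none"

    def test_scores_relative_to_winner(self, basis):
        rng = np.random.default_rng(2)
        results = [make_result(rng.standard_normal(2) * 0.1)
                   for _ in range(20)]
        fams = {"none": (), "all": ("p0", "p1")}
        scores, winner, _ = peb_compare_sets(results, basis, fams)
        assert scores[winner] == 0.0
        assert all(v <= 0 for v in scores.values())
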