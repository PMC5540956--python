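import numpy as np
import pytest

from perconet.errors import ParameterError, ShapeError
from perconet.lfr import LFRParams, generate_lfr
from perconet.simulate import (
    CorrelationTarget,
    add_rician_noise,
    adjacency_to_target,
    cholesky_factor,
    correlated_timeseries,
    generate_cohort,
    nearest_positive_definite,
    nearest_positive_semidefinite,
    read_cohort,
    write_cohort,
)


@pytest.fixture(scope="module")
def small_network():
    params = LFRParams(
        n_nodes=60, avg_degree=6.0, max_degree=10,
        min_community=10, max_community=20,
        mixing_topology=0.1, mixing_weight=0.1, seed=3,
    )
    net, _ = generate_lfr(params)
    return net


class TestNearestPositiveDefinite:
    def test_identity_is_fixed_point(self):
        out = nearest_positive_definite(np.eye(4))
        assert np.allclose(out.matrix, np.eye(4), atol=1e-12)

    def test_valid_correlation_matrix_unchanged(self):
        c = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
        out = nearest_positive_definite(c)
        assert np.allclose(out.matrix, c, atol=1e-8)

    def test_indefinite_2x2_pulled_to_boundary(self):
        out = nearest_positive_definite(np.array([[1.0, 1.2], [1.2, 1.0]]))
        vals = np.linalg.eigvalsh(out.matrix)
        assert vals.min() >= 0.25 * out.eig_floor
        assert out.matrix[0, 1] == pytest.approx(1.0, abs=1e-4)
        assert np.allclose(np.diag(out.matrix), 1.0)

    def test_agrees_with_statsmodels_reference(self):
        import warnings

        from statsmodels.stats.correlation_tools import corr_nearest
        from statsmodels.tools.sm_exceptions import IterationLimitWarning

        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.uniform(-1, 1, size=(6, 6))
            a = 0.5 * (a + a.T)
            np.fill_diagonal(a, 1.0)
            ours = nearest_positive_definite(a, eig_floor=1e-10).matrix
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", IterationLimitWarning)
                ref = corr_nearest(a, threshold=1e-10, n_fact=1000)
            assert np.linalg.norm(ours - ref, "fro") < 1e-4

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ShapeError):
            nearest_positive_definite(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestPsdProjection:
    def test_clips_eigenvalues_only(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])  # eigenvalues +-2
        out = nearest_positive_semidefinite(a, eig_floor=1e-8)
        vals = np.linalg.eigvalsh(out.matrix)
        assert vals.min() >= 0.0
        assert vals.max() == pytest.approx(2.0)

    def test_psd_input_unchanged(self):
        a = np.diag([1.0, 2.0, 3.0])
        out = nearest_positive_semidefinite(a)
        assert np.allclose(out.matrix, a, atol=1e-12)


class TestCorrelatedTimeseries:
    def test_cholesky_identity(self):
        c = nearest_positive_definite(
            np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
        )
        L = cholesky_factor(c)
        assert np.tril(L, -1).sum() != 0  # genuinely lower-triangular factor
        rel = np.linalg.norm(L @ L.T - c.matrix, "fro") / np.linalg.norm(
            c.matrix, "fro"
        )
        assert rel < 1e-10

    def test_identity_target_gives_uncorrelated_series(self):
        y = correlated_timeseries(CorrelationTarget(np.eye(4)), 100_000, 0.0, seed=0)
        r = np.corrcoef(y)
        off = r[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.01)

    def test_pairwise_correlation_matches_target(self):
        c = CorrelationTarget(np.array([[1.0, 0.8], [0.8, 1.0]]))
        y = correlated_timeseries(c, 100_000, 0.0, seed=1)
        assert np.corrcoef(y)[0, 1] == pytest.approx(0.8, abs=0.01)

    def test_baseline_shifts_mean(self):
        c = CorrelationTarget(np.eye(3))
        y = correlated_timeseries(c, 10_000, 100.0, seed=2)
        assert y.mean(axis=1) == pytest.approx(100.0, abs=3 / np.sqrt(10_000) * 100)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ParameterError):
            correlated_timeseries(CorrelationTarget(np.eye(2)), 2)


class TestRicianNoise:
    def test_infinite_snr_limit_returns_input(self):
        y = np.full((2, 1000), 100.0)
        out = add_rician_noise(y, snr=1e9, seed=0)
        assert np.allclose(out, y, rtol=1e-3)

    def test_noise_std_matches_snr_definition(self):
        y = np.full((1, 100_000), 100.0)
        out = add_rician_noise(y, snr=35.0, seed=1)
        sigma = 100.0 / 35.0
        assert out.std() == pytest.approx(sigma, rel=0.05)

    def test_zero_signal_follows_rayleigh_law(self):
        y = np.zeros((1, 200_000))
        sigma = 2.0
        out = add_rician_noise(y, snr=1.0, seed=2, sigma=sigma)
        assert out.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ParameterError):
            add_rician_noise(np.ones((1, 10)), snr=0.0)


class TestCohort:
    def test_panel_shape_and_determinism(self, small_network):
        p1 = generate_cohort(small_network, 3, 150, snr=35.0, seed=11)
        p2 = generate_cohort(small_network, 3, 150, snr=35.0, seed=11)
        assert p1.data.shape == (3, 60, 150)
        assert np.array_equal(p1.data, p2.data)
        p3 = generate_cohort(small_network, 3, 150, snr=35.0, seed=12)
        assert not np.array_equal(p1.data, p3.data)

    def test_subjects_are_independent_realizations(self, small_network):
        panel = generate_cohort(small_network, 2, 150, snr=35.0, seed=5)
        assert not np.array_equal(panel.data[0], panel.data[1])

    def test_noise_monotonicity(self, small_network):
        """Distance of the subject correlation matrix from the target is
        non-decreasing as SNR drops (common seeds, 10 replicates)."""
        target = adjacency_to_target(small_network)
        d = np.diag(target.matrix)
        r_target = target.matrix / np.sqrt(np.outer(d, d))
        dist = {snr: [] for snr in (1e9, 70.0, 35.0)}
        for rep in range(10):
            for snr in dist:
                panel = generate_cohort(
                    small_network, 1, 150, snr=snr, seed=100 + rep
                )
                r = np.corrcoef(panel.data[0])
                dist[snr].append(np.linalg.norm(r - r_target, "fro"))
        assert np.mean(dist[70.0]) >= np.mean(dist[1e9])
        assert np.mean(dist[35.0]) >= np.mean(dist[70.0])

    def test_group_average_beats_single_subject(self, small_network):
        """Across-subject averaging gets closer to the target correlation
        than single subjects in >= 90% of seeded replicates."""
        from perconet.connectivity import panel_to_group, pearson_matrix

        target = adjacency_to_target(small_network)
        d = np.diag(target.matrix)
        r_target = target.matrix / np.sqrt(np.outer(d, d))
        wins = 0
        for rep in range(10):
            panel = generate_cohort(small_network, 10, 150, snr=35.0, seed=rep)
            group = panel_to_group(panel).matrix
            g_err = np.linalg.norm(group - r_target, "fro")
            subj_errs = [
                np.linalg.norm(pearson_matrix(panel.data[k]).matrix - r_target, "fro")
                for k in range(panel.n_subjects)
            ]
            wins += g_err < min(subj_errs)
        assert wins >= 9

    def test_cohort_csv_round_trip(self, small_network, tmp_path):
        panel = generate_cohort(small_network, 2, 50, snr=70.0, seed=3)
        manifest = write_cohort(panel, tmp_path)
        back = read_cohort(manifest)
        assert back.data.shape == panel.data.shape
        assert np.allclose(back.data, panel.data, atol=1e-6)
        assert back.snr == panel.snr
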