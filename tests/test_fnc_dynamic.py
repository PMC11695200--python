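"""Sliding-window dFNC: tapers, window counts, k-means states, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

import dynconn as dc
from dynconn.fnc_dynamic import run_lengths


def brute_force_taper(width, sigma):
    """Direct-summation convolution oracle for the tapered window."""
    radius = max(1, int(np.ceil(3 * sigma)))
    grid = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (grid / sigma) ** 2)
    kernel /= kernel.sum()
    out = np.zeros(width)
    for i in range(width):
        for j, offset in enumerate(grid):
            # rectangle value at position (i - offset) within [0, width)
            if 0 <= i - offset < width:
                out[i] += kernel[j]
    return out / out.sum()


class TestTaper:
    def test_sigma_to_zero_limit_is_uniform(self):
        taper = dc.build_taper(20, 1e-6)
        assert np.abs(taper - 1 / 20).max() < 1e-9

    def test_symmetry_and_unimodality(self):
        taper = dc.build_taper(20, 3.0)
        np.testing.assert_allclose(taper, taper[::-1], atol=1e-15)
        assert taper[10] > taper[0]
        assert np.all(np.diff(taper[:10]) >= -1e-15)

    def test_matches_brute_force_convolution(self):
        for width, sigma in [(20, 3.0), (15, 2.0), (8, 1.0)]:
            np.testing.assert_allclose(
                dc.build_taper(width, sigma),
                brute_force_taper(width, sigma), atol=1e-12,
            )

    @pytest.mark.parametrize("width,sigma", [(1, 3.0), (10, 0.0)])
    def test_invalid_parameters(self, width, sigma):
        with pytest.raises(ValueError):
            dc.build_taper(width, sigma)


class TestWindowing:
    def test_window_count_boundary(self):
        spec = dc.WindowSpec(width=20)
        assert dc.n_windows(20, spec) == 1
        assert dc.n_windows(234, spec) == 215

    @given(
        t=st.integers(min_value=20, max_value=400),
        width=st.integers(min_value=2, max_value=20),
        step=st.integers(min_value=1, max_value=5),
    )
    @settings(deadline=None, max_examples=50)
    def test_window_count_formula(self, t, width, step):
        spec = dc.WindowSpec(width=width, step=step, gaussian_sigma=1.0)
        array = dc.windowed_fnc(
            np.random.default_rng(0).normal(size=(t, 3)), spec
        )
        assert array.n_windows == (t - width) // step + 1

    def test_stationary_series_mean_matches_full_series(self):
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        ts = rng.multivariate_normal([0, 0], cov, size=5000)
        spec = dc.WindowSpec(width=50, gaussian_sigma=1e-6, step=10)
        array = dc.windowed_fnc(ts, spec)
        mean_r = array.r_windows()[:, 0, 1].mean()
        full_r = dc.pearson_matrix(ts)[0, 1]
        assert mean_r == pytest.approx(full_r, abs=0.05)

    def test_degenerate_window_sets_pairs_to_zero(self, caplog):
        ts = np.column_stack([
            np.r_[np.ones(25), np.arange(25.0)],
            np.random.default_rng(1).normal(size=50),
        ])
        spec = dc.WindowSpec(width=20, gaussian_sigma=3.0)
        array = dc.windowed_fnc(ts, spec)
        assert array.z_windows[0, 0, 1] == 0.0


class TestClusterStates:
    @staticmethod
    def two_clouds(n=60, d=8, separation=50.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, d))
        b = rng.normal(size=(n, d)) + separation
        return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]

    @pytest.mark.parametrize("metric", ["cityblock", "sqeuclidean"])
    def test_separated_clouds_recovered_exactly(self, metric):
        x, truth = self.two_clouds()
        model = dc.cluster_states(x, k=2, distance=metric, seed=1, n_restarts=5)
        # perfect separation: each cluster is exactly one cloud
        first = model.labels[:60]
        assert len(set(first)) == 1
        assert set(model.labels[60:]) != set(first)

    def test_k1_centroid_is_pooled_mean(self, rng):
        x = rng.normal(size=(40, 5))
        model = dc.cluster_states(x, k=1, distance="sqeuclidean", seed=0,
                                  n_restarts=2)
        np.testing.assert_allclose(model.centroids[0], x.mean(axis=0),
                                   atol=1e-10)

    def test_duplication_invariance(self):
        x, _ = self.two_clouds(n=30)
        m1 = dc.cluster_states(x, k=2, seed=2, n_restarts=5)
        m2 = dc.cluster_states(np.vstack([x, x]), k=2, seed=2, n_restarts=5)
        c1 = m1.centroids[np.argsort(m1.centroids[:, 0])]
        c2 = m2.centroids[np.argsort(m2.centroids[:, 0])]
        np.testing.assert_allclose(c1, c2, atol=1e-10)
        assert sorted(np.bincount(m2.labels)[1:]) == \
            sorted(2 * np.bincount(m1.labels)[1:])

    def test_final_assignment_is_fixpoint(self, rng):
        x = rng.normal(size=(200, 6))
        model = dc.cluster_states(x, k=4, seed=3, n_restarts=3)
        d = cdist(x, model.centroids, metric="cityblock")
        # reassigning to the returned centroids reproduces the labels
        np.testing.assert_array_equal(d.argmin(axis=1) + 1, model.labels)
        assert model.inertia == pytest.approx(
            d[np.arange(len(x)), model.labels - 1].sum(), rel=1e-12
        )

    def test_sqeuclidean_matches_sklearn_objective(self, rng):
        x = rng.normal(size=(150, 5))
        ours = dc.cluster_states(x, k=3, distance="sqeuclidean", seed=4,
                                 n_restarts=10)
        ref = KMeans(n_clusters=3, n_init=10, random_state=4).fit(x)
        assert ours.inertia <= ref.inertia_ * 1.05

    def test_states_ordered_by_occupancy(self, rng):
        x = np.vstack([rng.normal(size=(80, 4)),
                       rng.normal(size=(20, 4)) + 30])
        model = dc.cluster_states(x, k=2, seed=5, n_restarts=5)
        counts = np.bincount(model.labels, minlength=3)[1:]
        assert counts[0] >= counts[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dc.cluster_states(np.ones((10, 3)), k=0)
        with pytest.raises(ValueError):
            dc.cluster_states(np.ones((3, 3)), k=5)
        with pytest.raises(ValueError):
            dc.cluster_states(np.ones((10, 3)), k=2, distance="cosine")


class TestStateMetrics:
    def test_hand_enumerated_example(self):
        m = dc.state_metrics(np.array([1, 1, 2, 2, 2]), k=2)
        np.testing.assert_allclose(m.fraction_time, [0.4, 0.6])
        np.testing.assert_allclose(m.mean_dwell_time, [2.0, 3.0])
        assert m.n_transitions == 1

    def test_constant_sequence(self):
        m = dc.state_metrics(np.full(30, 2), k=3)
        np.testing.assert_allclose(m.fraction_time, [0, 1, 0])
        assert m.n_transitions == 0
        assert m.mean_dwell_time[1] == 30
        assert np.isnan(m.mean_dwell_time[0])

    def test_alternating_sequence(self):
        m = dc.state_metrics(np.array([1, 2, 1, 2]), k=2)
        assert m.n_transitions == 3
        np.testing.assert_allclose(m.mean_dwell_time, [1.0, 1.0])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dc.state_metrics(np.array([]), k=2)

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=1,
                    max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_invariants(self, labels):
        m = dc.state_metrics(np.array(labels), k=4)
        assert m.fraction_time.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((m.fraction_time >= 0) & (m.fraction_time <= 1))
        assert 0 <= m.n_transitions <= len(labels) - 1
        # dwell times partition the sequence
        runs = run_lengths(np.array(labels))
        assert sum(length for _, length in runs) == len(labels)


class TestVariability:
    @staticmethod
    def array_from_r(r_values):
        """DFNCArray with a single pair following the given r sequence."""
        w = len(r_values)
        z = np.zeros((w, 2, 2))
        z[:, 0, 1] = z[:, 1, 0] = np.arctanh(np.asarray(r_values))
        return dc.DFNCArray(z_windows=z, window_starts=np.arange(w))

    def test_identical_windows_give_zero(self):
        array = self.array_from_r([0.3] * 10)
        np.testing.assert_allclose(dc.dfnc_variability(array), 0.0,
                                   atol=1e-15)

    def test_two_point_alternation_closed_form(self):
        w = 10
        array = self.array_from_r([0.5, -0.5] * (w // 2))
        expected = 0.5 * np.sqrt(w / (w - 1))
        assert dc.dfnc_variability(array)[0, 1] == pytest.approx(expected)

    def test_channel_scaling_invariance(self, rng):
        ts = rng.normal(size=(80, 4))
        spec = dc.WindowSpec(width=20)
        v1 = dc.dfnc_variability(dc.windowed_fnc(ts, spec))
        scaled = ts.copy()
        scaled[:, 2] *= 7.5
        v2 = dc.dfnc_variability(dc.windowed_fnc(scaled, spec))
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dc.dfnc_variability(self.array_from_r([0.1]))
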