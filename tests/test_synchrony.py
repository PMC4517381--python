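import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbnet import (
    ConnectionMatrix,
    ROISeries,
    SynchronyParams,
    coherence_band_pair,
    connection_matrix,
    granger_pair,
    mutual_information_pair,
    pearson_pair,
    symmetrize_directed,
    threshold_adjacency,
    windowed_connection_matrices,
)


def series(values, pid="p", roi="prefrontal", fs=10.0, start=0.0):
    return ROISeries(pid, roi, fs, start, np.asarray(values, dtype=float))


class TestPearson:
    def test_self_and_negated_self(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        assert pearson_pair(x, x) == pytest.approx(1.0)
        assert pearson_pair(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 4, sd_x = sd_y = sqrt(5) -> r = 4/5
        assert pearson_pair([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        r = pearson_pair(x, y)
        assert pearson_pair(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_pair(a * x + b, y) == pytest.approx(r, abs=1e-9)


class TestCoherence:
    def test_identical_signals_fully_coherent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        c = coherence_band_pair(x, x, band=(0.5, 4.0), fs=10.0)
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_bias_matches_segment_count(self):
        # Welch MSC of unrelated signals has expectation ~ 1/n_segments
        rng = np.random.default_rng(2)
        vals = [
            coherence_band_pair(
                rng.standard_normal(1152), rng.standard_normal(1152),
                band=(0.5, 4.5), n_segments=8, fs=10.0,
            )
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(1 / 8, abs=0.03)

    def test_single_segment_rejected(self):
        x = np.random.default_rng(0).standard_normal(256)
        with pytest.raises(ValueError, match="insufficient segments"):
            coherence_band_pair(x, x, band=(0.5, 4.0), n_segments=1, fs=10.0)

    def test_band_outside_nyquist_rejected(self):
        x = np.random.default_rng(0).standard_normal(256)
        with pytest.raises(ValueError, match="band"):
            coherence_band_pair(x, x, band=(0.5, 6.0), fs=10.0)


class TestMutualInformation:
    def test_identity_equals_marginal_entropy(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        mi = mutual_information_pair(x, x, n_bins=4)
        counts, _ = np.histogram(x, bins=4)
        p = counts / counts.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(h, abs=1e-12)

    def test_two_bin_closed_form(self):
        # joint table {(0,0): 1/2, (1,1): 1/2} -> MI = ln 2
        x = np.array([0.0, 1.0] * 50)
        assert mutual_information_pair(x, x, n_bins=2) == pytest.approx(np.log(2))

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(4)
        vals = [
            mutual_information_pair(
                rng.random(10_000), rng.random(10_000), n_bins=8
            )
            for _ in range(5)
        ]
        assert np.mean(vals) < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            mutual_information_pair([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_bins=1)


class TestGranger:
    def test_planted_lag_detected_directionally(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        y = np.roll(x, 1) + 0.1 * rng.standard_normal(2000)
        y[0] = rng.standard_normal()
        f_xy, f_yx = granger_pair(x, y, max_lag=1)
        assert f_xy > 10 * f_yx
        assert f_xy > 1.0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        stats = []
        for _ in range(5):
            f_xy, f_yx = granger_pair(
                rng.standard_normal(5000), rng.standard_normal(5000), max_lag=2
            )
            stats.extend([f_xy, f_yx])
        assert np.mean(stats) < 0.01

    def test_invalid_lag_and_degenerate_design(self):
        x = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="max_lag"):
            granger_pair(x, x, max_lag=0)
        with pytest.raises(ValueError, match="degenerate|zero variance|singular"):
            granger_pair(np.zeros(100), np.zeros(100), max_lag=1)


class TestConnectionMatrix:
    def test_copies_of_one_signal_fully_correlated(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        cm = connection_matrix([series(x, pid=f"p{i}") for i in range(3)])
        assert np.allclose(cm.values, 1.0)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((5, 300))
        cm = connection_matrix([series(row, pid=f"p{i}") for i, row in enumerate(data)])
        assert np.max(np.abs(cm.values - np.corrcoef(data))) < 1e-12
        assert np.array_equal(cm.values, cm.values.T)

    def test_nine_series_shape_and_symmetry(self, short_group):
        from mbnet import preprocess_group

        recordings, _ = short_group
        cm = connection_matrix(preprocess_group(recordings))
        assert cm.values.shape == (9, 9)
        assert np.array_equal(cm.values, cm.values.T)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            connection_matrix(
                [series(np.arange(10.0)), series(np.arange(12.0), pid="q")]
            )

    def test_granger_matrix_asymmetric_then_symmetrized(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(500)
        y = np.roll(x, 1) + 0.2 * rng.standard_normal(500)
        cm = connection_matrix(
            [series(x, pid="a"), series(y, pid="b")],
            SynchronyParams(measure="granger", max_lag=1),
        )
        assert cm.values[0, 1] != cm.values[1, 0]
        with pytest.raises(ValueError, match="symmetrize"):
            threshold_adjacency(cm, 0.1)
        sym = symmetrize_directed(cm, how="max")
        am = threshold_adjacency(sym, 0.1)
        assert am.values[0, 1] == 1


class TestThreshold:
    def test_strict_inequality_at_threshold(self):
        v = np.array(
            [[1.0, 0.6, 0.4], [0.6, 1.0, 0.5], [0.4, 0.5, 1.0]]
        )
        cm = ConnectionMatrix(labels=list("abc"), values=v, measure="pearson")
        am = threshold_adjacency(cm, 0.5)
        assert am.n_edges == 1
        assert am.values[0, 1] == 1

    def test_threshold_below_all_gives_complete_graph(self):
        rng = np.random.default_rng(10)
        v = np.corrcoef(rng.standard_normal((4, 50)))
        v = (v + v.T) / 2  # corrcoef is not bit-exactly symmetric
        cm = ConnectionMatrix(labels=list("abcd"), values=v, measure="pearson")
        am = threshold_adjacency(cm, -1.0)
        assert am.n_edges == 6

    def test_absolute_option_includes_negative_edges(self):
        v = np.array([[1.0, -0.8], [-0.8, 1.0]])
        cm = ConnectionMatrix(labels=list("ab"), values=v, measure="pearson")
        assert threshold_adjacency(cm, 0.5).n_edges == 0
        assert threshold_adjacency(cm, 0.5, absolute=True).n_edges == 1

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        tau1=st.floats(-1.0, 1.0),
        tau2=st.floats(-1.0, 1.0),
    )
    def test_monotone_in_threshold(self, seed, tau1, tau2):
        tau1, tau2 = sorted((tau1, tau2))
        rng = np.random.default_rng(seed)
        v = np.corrcoef(rng.standard_normal((5, 30)))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        cm = ConnectionMatrix(labels=list("abcde"), values=v, measure="pearson")
        high = threshold_adjacency(cm, tau2).values
        low = threshold_adjacency(cm, tau1).values
        assert np.all(low >= high)  # edge set at tau2 subset of tau1


class TestWindowed:
    def test_window_count(self):
        rng = np.random.default_rng(11)
        ss = [series(rng.standard_normal(1000), pid=f"p{i}") for i in range(3)]
        cms = windowed_connection_matrices(
            ss, SynchronyParams(window=(30.0, 10.0))
        )
        assert len(cms) == 8
        assert cms[0].window_start == 0.0
        assert cms[-1].window_start == pytest.approx(70.0)

    def test_stationary_identical_signals(self):
        x = np.sin(np.arange(1000) / 10)
        ss = [series(x, pid=f"p{i}") for i in range(3)]
        for cm in windowed_connection_matrices(ss, SynchronyParams(window=(30.0, 10.0))):
            off = cm.values[~np.eye(3, dtype=bool)]
            assert np.allclose(off, 1.0)

    def test_invalid_windows_rejected(self):
        x = np.random.default_rng(0).standard_normal(100)
        ss = [series(x, pid="a"), series(x + 1e-3, pid="b")]
        with pytest.raises(ValueError, match="step"):
            windowed_connection_matrices(ss, SynchronyParams(window=(3.0, 0.0)))
        with pytest.raises(ValueError, match="longer than series"):
            windowed_connection_matrices(ss, SynchronyParams(window=(20.0, 1.0)))
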