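import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgrqa import RecurrenceMatrix, binarize, distance_matrix, embed, \
    gen_ecg_record, resize_to_image, rqa_features, stack_channels
from ecgrqa.recurrence import RecurrencePlotTransformer

from oracles import distance_matrix_bf


@pytest.fixture
def seeded_states():
    rng = np.random.default_rng(4)
    from ecgrqa.phase_space import DataMatrix, EmbeddingParams
    states = rng.standard_normal((50, 3))
    return DataMatrix(states, EmbeddingParams(tau=1, M=3, N=52))


class TestDistanceMatrix:
    def test_3_4_5_triangle(self):
        from ecgrqa.phase_space import DataMatrix, EmbeddingParams
        dm = DataMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]),
                        EmbeddingParams(1, 2, 3))
        R = distance_matrix(dm)
        assert R.dist[0, 1] == R.dist[1, 0] == 5.0
        assert R.dist[0, 0] == R.dist[1, 1] == 0.0

    def test_matches_pairwise_loop_oracle(self, seeded_states):
        R = distance_matrix(seeded_states)
        assert np.allclose(R.dist, distance_matrix_bf(seeded_states.states),
                           atol=1e-12)
        assert np.allclose(R.dist, R.dist.T)
        assert np.all(np.diag(R.dist) == 0)

    def test_single_state_rejected(self):
        from ecgrqa.phase_space import DataMatrix, EmbeddingParams
        with pytest.raises(ValueError):
            distance_matrix(DataMatrix(np.ones((1, 2)),
                                       EmbeddingParams(1, 2, 2)))


class TestBinarize:
    def test_epsilon_zero_marks_only_coincident_states(self, seeded_states):
        b = binarize(distance_matrix(seeded_states), "epsilon", 0.0)
        assert np.array_equal(b.grid, np.eye(50, dtype=np.uint8))

    def test_epsilon_above_max_gives_all_ones(self, seeded_states):
        R = distance_matrix(seeded_states)
        b = binarize(R, "epsilon", R.dist.max() + 1.0)
        assert b.grid.all()
        assert b.recurrence_rate == 1.0

    def test_target_rr_achieved(self, seeded_states):
        R = distance_matrix(seeded_states)
        b = binarize(R, "target_rr", 0.10)
        assert abs(b.recurrence_rate - 0.10) < 0.02

    def test_monotone_in_epsilon(self, seeded_states):
        R = distance_matrix(seeded_states)
        qs = np.quantile(R.dist, [0.1, 0.3, 0.6])
        grids = [binarize(R, "epsilon", q).grid for q in qs]
        assert np.all(grids[0] <= grids[1])
        assert np.all(grids[1] <= grids[2])

    @given(p=st.floats(0.05, 0.5), q=st.floats(0.5, 0.95))
    @settings(max_examples=20, deadline=None)
    def test_rr_nondecreasing_in_target(self, p, q):
        rng = np.random.default_rng(4)
        from ecgrqa.phase_space import DataMatrix, EmbeddingParams
        dm = DataMatrix(rng.standard_normal((50, 3)),
                        EmbeddingParams(tau=1, M=3, N=52))
        R = distance_matrix(dm)
        rr_p = binarize(R, "target_rr", p).recurrence_rate
        rr_q = binarize(R, "target_rr", q).recurrence_rate
        assert rr_p <= rr_q + 1e-12

    def test_invalid_values(self, seeded_states):
        R = distance_matrix(seeded_states)
        with pytest.raises(ValueError):
            binarize(R, "epsilon", -1.0)
        with pytest.raises(ValueError):
            binarize(R, "target_rr", 1.5)
        with pytest.raises(ValueError):
            binarize(R, "nope", 0.1)

    def test_theiler_band_zeroed(self, seeded_states):
        R = distance_matrix(seeded_states)
        b = binarize(R, "target_rr", 0.2, theiler=1)
        i, j = np.indices(b.grid.shape)
        assert not b.grid[np.abs(i - j) <= 1].any()


class TestResize:
    def test_constant_matrix_maps_to_zeros(self):
        img = resize_to_image(RecurrenceMatrix(np.full((8, 8), 3.0)), 16)
        assert np.all(img == 0.0)

    def test_identity_when_already_target_size(self):
        rng = np.random.default_rng(0)
        d = rng.random((32, 32))
        img = resize_to_image(RecurrenceMatrix(d), 32)
        norm = (d - d.min()) / (d.max() - d.min())
        assert np.allclose(img, norm)

    def test_bilinear_corners_preserved(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        img = resize_to_image(RecurrenceMatrix(d), 4)
        assert img[0, 0] == pytest.approx(0.0)
        assert img[3, 3] == pytest.approx(0.0)
        assert img[0, 3] == pytest.approx(1.0)
        assert img[3, 0] == pytest.approx(1.0)

    @given(side=st.integers(2, 20), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_output_range_in_unit_interval(self, side, seed):
        rng = np.random.default_rng(seed)
        img = resize_to_image(RecurrenceMatrix(rng.random((side, side)) * 7),
                              24)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestStackChannels:
    def test_stack_shape(self):
        imgs = [np.zeros((32, 32))] * 15
        st_ = stack_channels(imgs, "r1", "HC")
        assert st_.tensor.shape == (15, 32, 32)
        assert st_.label == "HC"

    def test_single_channel(self):
        st_ = stack_channels([np.zeros((224, 224))])
        assert st_.tensor.shape == (1, 224, 224)

    def test_shape_mismatch_names_channel(self):
        imgs = [np.zeros((8, 8)), np.zeros((9, 9))]
        with pytest.raises(ValueError, match="v2"):
            stack_channels(imgs, channel_names=["v1", "v2"])

    def test_wrong_order_rejected(self):
        imgs = [np.zeros((8, 8))] * 2
        with pytest.raises(ValueError, match="order"):
            stack_channels(imgs, channel_names=["ii", "i"],
                           expected_order=["i", "ii"])


class TestPeriodicStructure:
    def test_sine_rp_has_diagonal_lines(self, sine_signal):
        """A periodic orbit at matched RR yields high determinism."""
        dm = embed(sine_signal[:600], tau=32, M=2)
        b = binarize(distance_matrix(dm), "target_rr", 0.1, theiler=1)
        fv = rqa_features(b)
        assert fv.DET > 0.9


class TestTransformer:
    def test_transform_shape_and_range(self):
        recs = [gen_ecg_record("HC", channels=3, duration=4.0, seed=s)
                for s in (0, 1)]
        rpt = RecurrencePlotTransformer(size=32, window_s=2.0, tau=8, M=3)
        out = rpt.fit(recs).transform(recs)
        assert out.shape == (2, 3, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_auto_params_estimated(self):
        recs = [gen_ecg_record("HC", channels=3, duration=6.0, seed=0)]
        rpt = RecurrencePlotTransformer(size=16, window_s=4.0, tau=None,
                                        M=None, m_max=5, max_lag=30)
        rpt.fit(recs)
        assert 1 <= rpt.tau_ <= 30
        assert 1 <= rpt.M_ <= 5
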