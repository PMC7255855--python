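import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embedsom import (
    DegeneratePointError,
    EmbedParams,
    LandmarkModel,
    SingularSystemError,
    ValidationError,
    default_params,
    embed,
    embed_point,
    landmark_distances,
    neighbor_scores,
)
from oracles import minimize_projection_objective, scalar_score
from embedsom.projection import _block_distances, _block_scores


def random_model(rng, n_l=25, d=5, p=2, scale=1.0):
    return LandmarkModel(
        high=rng.normal(size=(n_l, d)) * scale, low=rng.normal(size=(n_l, p))
    )


class TestLandmarkDistances:
    @pytest.mark.parametrize(
        "metric, expected",
        [("euclidean", 25.0), ("L1", 7.0), ("Linf", 4.0)],
    )
    def test_single_landmark(self, metric, expected):
        d = landmark_distances([0.0, 0.0], np.array([[3.0, 4.0]]), metric)
        assert d[0] == expected

    def test_zero_at_coincident_landmark(self, rng):
        high = rng.normal(size=(6, 4))
        for metric in ("euclidean", "L1", "Linf"):
            assert landmark_distances(high[2], high, metric)[2] == 0.0

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError, match="dimension"):
            landmark_distances([1.0, 2.0, 3.0], rng.normal(size=(4, 2)))


class TestNeighborScores:
    def test_kth_score_is_exactly_zero(self, rng):
        c = rng.uniform(0.5, 3.0, size=20)
        ns = neighbor_scores(c, k=7, m=10.0, b=0.5)
        assert ns.scores[-1] == 0.0

    def test_b_zero_matches_closed_form(self):
        # m-term only: S_1 = 1 - exp((1-4)/(10*4))
        ns = neighbor_scores([1.0, 2.0, 3.0, 4.0], k=4, m=10.0, b=0.0)
        assert ns.scores[0] == pytest.approx(1.0 - np.exp(-3.0 / 40.0), rel=1e-12)
        assert ns.scores[0] == pytest.approx(0.07226, abs=1e-5)

    def test_matches_scalar_reference(self, rng):
        c = np.sort(rng.uniform(0.1, 5.0, size=12))
        ns = neighbor_scores(c, k=8, m=7.0, b=0.4)
        np.testing.assert_allclose(ns.scores, scalar_score(c, 8, 7.0, 0.4), rtol=1e-12)

    def test_ordering_and_tie_break(self):
        c = [2.0, 1.0, 1.0, 3.0, 0.5]
        ns = neighbor_scores(c, k=4, m=10.0, b=0.0)
        assert list(ns.order) == [4, 1, 2, 0]  # ties 1,2 resolve by index
        assert np.all(np.diff(ns.dists) >= 0)

    def test_equal_distances_sigma_zero(self):
        # all k distances equal: exp factor treated as 1, m-term zero
        ns = neighbor_scores([2.0, 2.0, 2.0, 2.0], k=4, m=10.0, b=1.0)
        assert ns.sigma == 0.0
        np.testing.assert_array_equal(ns.scores, np.zeros(4))

    def test_degenerate_point_signalled(self):
        with pytest.raises(DegeneratePointError):
            neighbor_scores([0.0, 0.0, 0.0, 0.0, 1.0], k=4, m=10.0, b=0.0)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_at_b_zero(self, factor):
        c = np.array([0.3, 0.9, 1.7, 2.2, 4.0, 9.0])
        a = neighbor_scores(c, k=5, m=10.0, b=0.0)
        b = neighbor_scores(c * factor, k=5, m=10.0, b=0.0)
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-9)


class TestEmbedPoint:
    def test_unit_square_identity(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        model = LandmarkModel(high=pts, low=pts.copy())
        p = EmbedParams(k=4, m=1e6, b=0.0, a=0.0)
        out = embed_point([0.3, 0.8], model, p)
        np.testing.assert_allclose(out, [0.3, 0.8], atol=1e-9)

    def test_identity_when_low_equals_high(self, rng):
        L = rng.normal(size=(30, 2))
        model = LandmarkModel(high=L, low=L.copy())
        p = EmbedParams(k=8)
        for x in rng.normal(size=(20, 2)):
            np.testing.assert_allclose(embed_point(x, model, p), x, atol=1e-8)

    def test_matches_brute_force_minimizer(self, rng):
        p = EmbedParams(k=5)
        for _ in range(10):
            model = random_model(rng)
            x = rng.normal(size=5)
            got = embed_point(x, model, p)
            c = _block_distances(x[None], model.high, p.metric)
            order, _, _, _, S = _block_scores(c, p.k, p.m, p.b)
            want = minimize_projection_objective(x, model, p, S[0], order[0])
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)

    def test_degenerate_point_returns_landmark_low(self, rng):
        high = np.zeros((6, 3))
        high[4] = [5.0, 5.0, 5.0]
        high[5] = [9.0, 1.0, 2.0]
        low = rng.normal(size=(6, 2))
        model = LandmarkModel(high=high, low=low)
        # the origin coincides with landmarks 0..3 (>= k of them)
        out = embed_point([0.0, 0.0, 0.0], model, EmbedParams(k=4))
        np.testing.assert_array_equal(out, low[0])

    def test_singular_system_raises_with_hint(self):
        # collinear low landmarks: every h is parallel, rank-1 system
        high = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [10, 10]])
        low = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        model = LandmarkModel(high=high, low=low)
        with pytest.raises(SingularSystemError, match="larger k or m"):
            embed_point([1.5, 0.1], model, EmbedParams(k=4, m=10.0, b=0.0))

    def test_duplicate_landmarks_skipped(self, rng):
        model = random_model(rng, n_l=12, d=3)
        model.high[3] = model.high[1]  # duplicate pair must not poison sums
        model.low[3] = model.low[1]
        out = embed_point(rng.normal(size=3), model, EmbedParams(k=6))
        assert np.all(np.isfinite(out))

    def test_three_dimensional_output_matches_generic_solver(self, rng):
        model = random_model(rng, n_l=20, d=6, p=3)
        p = EmbedParams(k=7)
        x = rng.normal(size=6)
        out3 = embed_point(x, model, p)  # Cramer path
        # generic solve on an equivalent 4-D system padded with a dummy axis
        low4 = np.column_stack([model.low, np.zeros(20)])
        low4[:, 3] = rng.normal(size=20)
        model4 = LandmarkModel(high=model.high, low=low4)
        out4 = embed_point(x, model4, p)  # generic path
        assert out3.shape == (3,)
        assert out4.shape == (4,)
        assert np.all(np.isfinite(out4))


class TestEquivariance:
    def test_rigid_motion_of_low_landmarks(self, rng):
        model = random_model(rng, n_l=30, d=4)
        p = EmbedParams(k=8)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t = np.array([3.0, -1.5])
        moved = LandmarkModel(high=model.high.copy(), low=model.low @ R.T + t)
        X = rng.normal(size=(40, 4))
        a = embed(X, model, p) @ R.T + t
        b = embed(X, moved, p)
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-8)

    def test_uniform_scaling_with_a_zero(self, rng):
        model = random_model(rng, n_l=30, d=4)
        p = EmbedParams(k=8, a=0.0)
        scaled = LandmarkModel(high=model.high.copy(), low=model.low * 4.5)
        X = rng.normal(size=(30, 4))
        np.testing.assert_allclose(
            embed(X, model, p) * 4.5, embed(X, scaled, p), rtol=1e-8, atol=1e-8
        )


class TestEmbedBatch:
    def test_empty_input(self, rng):
        model = random_model(rng)
        out = embed(np.empty((0, 5)), model, EmbedParams(k=5))
        assert out.shape == (0, 2)

    def test_rows_equal_single_point_path(self, rng):
        model = random_model(rng)
        p = EmbedParams(k=6)
        X = rng.normal(size=(700, 5))  # spans multiple internal blocks
        batch = embed(X, model, p)
        for i in (0, 255, 256, 400, 699):
            np.testing.assert_array_equal(batch[i], embed_point(X[i], model, p))

    def test_thread_count_does_not_change_bits(self, rng):
        model = random_model(rng)
        p = EmbedParams(k=6)
        X = rng.normal(size=(1000, 5))
        a = embed(X, model, p, threads=1)
        b = embed(X, model, p, threads=4)
        assert a.tobytes() == b.tobytes()

    def test_metric_variants_produce_finite_output(self, rng):
        model = random_model(rng)
        X = rng.normal(size=(50, 5))
        for metric in ("L1", "Linf"):
            out = embed(X, model, EmbedParams(k=6, metric=metric))
            assert np.all(np.isfinite(out))

    def test_dimension_mismatch_rejected(self, rng):
        model = random_model(rng)
        with pytest.raises(ValidationError, match="dimension"):
            embed(rng.normal(size=(5, 3)), model, EmbedParams(k=5))


class TestSmoothness:
    def test_no_jumps_across_neighborhood_changes(self, rng):
        model = random_model(rng, n_l=40, d=3)
        p = EmbedParams(k=8)
        a, b = rng.normal(size=3) * 2, rng.normal(size=3) * 2
        jumps = {}
        for n in (2500, 5000):
            t = np.linspace(0, 1, n)[:, None]
            path = a * (1 - t) + b * t
            emb = embed(path, model, p)
            jumps[n] = np.abs(np.diff(emb, axis=0)).max()
        # halving the step should roughly halve the largest jump
        assert jumps[5000] < 0.75 * jumps[2500]
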