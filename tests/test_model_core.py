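"""Design-matrix construction and likelihood calculus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsnblr.model_core import (
    Dataset,
    OscillationOrders,
    ParameterVector,
    build_design,
    gradient,
    hessian,
    log_likelihood,
    predict_prob,
)
from conftest import fd_gradient, fd_hessian, random_instance


class TestBuildDesign:
    @pytest.mark.parametrize(
        "p,K,expected_m",
        [
            (6, (3, 2, 1, 1, 1, 1), 16),  # the published optimal-model shape
            (1, (1,), 3),
            (2, (0, 0), 3),               # plain logistic special case
            (3, (2, 0, 1), 7),
        ],
    )
    def test_column_count(self, rng, p, K, expected_m):
        X = rng.uniform(0, 10, size=(8, p))
        design = build_design(X, K)
        assert design.m == expected_m
        assert design.columns.shape == (8, expected_m)
        assert len(design.labels) == expected_m

    def test_cosine_columns_match_elementwise_oracle(self, rng):
        X = rng.uniform(-5, 5, size=(10, 2))
        design = build_design(X, (2, 1), names=("u", "v"))
        # independent scalar evaluation, element by element
        for i in range(10):
            for k, col in ((1, 2), (2, 3)):
                assert design.columns[i, col] == pytest.approx(
                    math.cos(k * X[i, 0]), abs=1e-15
                )
            assert design.columns[i, 5] == pytest.approx(
                math.cos(X[i, 1]), abs=1e-15
            )
        assert design.labels == (
            "(intercept)", "b_1:u", "a_1,1:u", "a_2,1:u", "b_2:v", "a_1,2:v",
        )

    def test_intercept_and_linear_columns(self, rng):
        X = rng.normal(size=(12, 2))
        design = build_design(X, (1, 2))
        assert np.all(design.columns[:, 0] == 1.0)
        np.testing.assert_array_equal(design.columns[:, 1], X[:, 0])
        np.testing.assert_array_equal(design.columns[:, 3], X[:, 1])
        cos_cols = design.columns[:, [2, 4, 5]]
        assert np.all((cos_cols >= -1.0) & (cos_cols <= 1.0))

    def test_rescaled_cosine_argument_spans_zero_to_pi(self, rng):
        X = rng.uniform(6.18, 589.11, size=(50, 1))
        design = build_design(X, (1,), rescale_cosine=True)
        lo, rate = design.cosine_scale[0]
        args = rate * (X[:, 0] - lo)
        assert args.min() == pytest.approx(0.0)
        assert args.max() == pytest.approx(np.pi)
        np.testing.assert_allclose(design.columns[:, 2], np.cos(args))

    def test_dimension_mismatch_and_nonfinite_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            build_design(X, (1, 1, 1))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            build_design(X, (1, 1))


class TestPredictProb:
    def test_zero_theta_gives_half(self, rng):
        design = build_design(rng.normal(size=(7, 2)), (1, 1))
        np.testing.assert_array_equal(
            predict_prob(design, np.zeros(design.m)), np.full(7, 0.5)
        )

    def test_saturation_without_overflow(self):
        design = build_design(np.array([[30.0], [-30.0], [1000.0]]), (0,))
        probs = predict_prob(design, np.array([0.0, 1.0]))
        assert probs[0] > 1 - 1e-12
        assert probs[1] < 1e-12
        assert np.all(np.isfinite(probs))
        assert np.all((probs > 0) & (probs < 1))

    def test_published_reduced_model_matches_scalar_evaluation(self):
        # the reduced two-predictor cosine model, evaluated at (x2, x6) = (50, 10)
        x2, x6 = 50.0, 10.0
        X = np.array([[x2, x6]])
        theta = ParameterVector(
            3.76, (-0.05, -0.04), ((-0.47, -0.51), (0.23, -0.01, -0.66))
        )
        design = build_design(X, (2, 3))
        eta = (
            3.76
            - 0.05 * x2 - 0.47 * math.cos(x2) - 0.51 * math.cos(2 * x2)
            - 0.04 * x6 + 0.23 * math.cos(x6) - 0.01 * math.cos(2 * x6)
            - 0.66 * math.cos(3 * x6)
        )
        expected = math.exp(eta) / (1.0 + math.exp(eta))
        assert predict_prob(design, theta)[0] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(0.1, 100.0),
    )
    def test_probabilities_strictly_inside_unit_interval(self, seed, scale):
        rng = np.random.default_rng(seed)
        design = build_design(rng.uniform(-scale, scale, size=(20, 2)), (1, 1))
        theta = rng.normal(scale=scale, size=design.m)
        probs = predict_prob(design, theta)
        assert np.all((probs > 0.0) & (probs < 1.0))


class TestLogLikelihood:
    def test_zero_theta_closed_form(self, rng):
        n = 23
        design = build_design(rng.normal(size=(n, 2)), (1, 0))
        y = rng.binomial(1, 0.5, size=n).astype(float)
        assert log_likelihood(y, design, np.zeros(design.m)) == pytest.approx(
            -n * np.log(2), abs=1e-12
        )

    def test_matches_bernoulli_product_oracle(self, rng):
        y, design, theta = random_instance(rng, n=5, K=(1, 1))
        pi = predict_prob(design, theta)
        oracle = math.log(
            math.prod(p**yi * (1 - p) ** (1 - yi) for p, yi in zip(pi, y))
        )
        assert log_likelihood(y, design, theta) == pytest.approx(oracle, abs=1e-12)

    def test_perfect_fit_limit_approaches_zero(self):
        design = build_design(np.full((6, 1), 1.0), (0,))
        y = np.ones(6)
        ll = log_likelihood(y, design, np.array([0.0, 500.0]))
        assert -1e-10 < ll <= 0.0

    def test_nonbinary_response_rejected(self, rng):
        design = build_design(rng.normal(size=(4, 1)), (0,))
        with pytest.raises(ValueError):
            log_likelihood(np.array([0.0, 1.0, 2.0, 0.0]), design, np.zeros(2))


class TestCalculus:
    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(20):
            y, design, theta = random_instance(rng)
            g = gradient(y, design, theta)
            fd = fd_gradient(y, design, theta)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_hessian_matches_finite_differences(self, rng):
        for _ in range(10):
            y, design, theta = random_instance(rng, n=20)
            H = hessian(y, design, theta)
            fd = fd_hessian(y, design, theta)
            scale = max(1.0, np.abs(H).max())
            assert np.abs(H - fd).max() / scale < 1e-4

    def test_intercept_score_vanishes_for_balanced_response_at_zero(self, rng):
        design = build_design(rng.normal(size=(10, 1)), (1,))
        y = np.array([0.0, 1.0] * 5)
        g = gradient(y, design, np.zeros(design.m))
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_hessian_at_zero_is_quarter_gram_matrix(self, rng):
        y, design, _ = random_instance(rng)
        H = hessian(y, design, np.zeros(design.m))
        expected = -0.25 * design.columns.T @ design.columns
        np.testing.assert_allclose(H, expected, rtol=1e-12)

    def test_hessian_exactly_symmetric_and_nsd(self, rng):
        y, design, theta = random_instance(rng)
        H = hessian(y, design, theta)
        assert np.array_equal(H, H.T)
        assert np.all(np.linalg.eigvalsh(H) <= 1e-10)


class TestParameterVector:
    @settings(max_examples=100, derandomize=True)
    @given(K=st.lists(st.integers(0, 4), min_size=1, max_size=5), seed=st.integers(0, 10**6))
    def test_flatten_unflatten_roundtrip(self, K, seed):
        orders = OscillationOrders(tuple(K))
        rng = np.random.default_rng(seed)
        flat = rng.normal(size=orders.n_params)
        theta = ParameterVector.unflatten(flat, orders)
        np.testing.assert_array_equal(theta.flatten(), flat)
        assert theta.orders.K == orders.K

    def test_index_map_is_bijective_and_ordered(self):
        theta = ParameterVector(1.0, (2.0, 3.0), ((4.0, 5.0), (6.0,)))
        imap = theta.index_map
        assert sorted(imap.values()) == list(range(theta.m))
        flat = theta.flatten()
        assert flat[imap["a0"]] == 1.0
        assert flat[imap["b2"]] == 3.0
        assert flat[imap["a2,1"]] == 5.0
        assert flat[imap["a1,2"]] == 6.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector.unflatten(np.zeros(4), (1, 1))


class TestDataset:
    def test_validation(self, rng):
        with pytest.raises(ValueError):
            Dataset(np.array([0.0, 2.0]), rng.normal(size=(2, 1)))
        with pytest.raises(ValueError):
            Dataset(np.array([0.0, 1.0]), np.array([[1.0], [np.nan]]))
        d = Dataset(np.array([0.0, 1.0]), rng.normal(size=(2, 3)))
        assert (d.n, d.p) == (2, 3)
        assert d.names == ("x1", "x2", "x3")

    def test_subset_preserves_column_order(self, rng):
        d = Dataset(np.array([0.0, 1.0, 1.0]), rng.normal(size=(3, 3)),
                    ("a", "b", "c"))
        sub = d.subset(["c", "a"])
        assert sub.names == ("a", "c")
        np.testing.assert_array_equal(sub.X, d.X[:, [0, 2]])
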