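"""Priors, conditional probability paths, and conditional vector fields."""

import numpy as np
import pytest

from molflows.interpolants import (
    CATEGORICAL_VARIANTS,
    ModalityState,
    VariantId,
    beta_schedule,
    conditional_vector_field,
    onehot_rows,
    project_to_simplex,
    sample_conditional_path,
    sample_prior,
)


class TestPriors:
    def test_ctmc_prior_is_all_mask(self):
        st = sample_prior(VariantId.CTMC, 5, 4, rng=0)
        assert st.indices.tolist() == [4, 4, 4, 4, 4]

    def test_simplex_prior_uniform_moments(self):
        n = 10_000
        st = sample_prior(VariantId.SIMPLEX, n, 3, rng=1)
        v = st.vectors
        assert np.allclose(v.sum(axis=1), 1.0, atol=1e-9)
        assert (v >= 0).all()
        # uniform simplex: mean 1/3, var = 1/3*2/3 / (D+1) = 2/36
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / n)
        assert np.abs(v.mean(axis=0) - 1 / 3).max() < 3 * se

    def test_euclidean_prior_centered(self):
        st = sample_prior(VariantId.EUCLIDEAN, 7, 3, rng=2)
        assert np.abs(st.vectors.mean(axis=0)).max() < 1e-9

    def test_continuous_prior_standard_normal(self):
        st = sample_prior(VariantId.CONTINUOUS, 20_000, 2, rng=3)
        assert abs(st.vectors.mean()) < 3 / np.sqrt(40_000)
        assert abs(st.vectors.std() - 1.0) < 0.02

    def test_degenerate_vocab_rejected(self):
        with pytest.raises(ValueError):
            sample_prior(VariantId.SIMPLEX, 3, 1, rng=0)


class TestConditionalPaths:
    def test_ctmc_endpoints_exact(self):
        x1 = ModalityState(indices=np.array([2, 0, 1]))
        at0 = sample_conditional_path(VariantId.CTMC, None, x1, 0.0, rng=0, mask_index=3)
        assert (at0.indices == 3).all()
        at1 = sample_conditional_path(VariantId.CTMC, None, x1, 1.0, rng=0, mask_index=3)
        assert (at1.indices == x1.indices).all()

    def test_ctmc_mixture_marginal(self):
        # P(x_t = x1) = t, checked against a 3-sigma binomial band
        n = 100_000
        x1 = ModalityState(indices=np.zeros(n, dtype=int))
        for t in (0.1, 0.5, 0.9):
            xt = sample_conditional_path(VariantId.CTMC, None, x1, t, rng=11, mask_index=2)
            freq = (xt.indices == 0).mean()
            assert abs(freq - t) < 3 * np.sqrt(t * (1 - t) / n)

    def test_linear_interpolant_midpoint(self):
        x0 = ModalityState(vectors=np.array([[0.0, 0.0]]))
        x1 = ModalityState(vectors=np.array([[0.0, 1.0]]))
        xt = sample_conditional_path(VariantId.CONTINUOUS, x0, x1, 0.5, rng=0)
        np.testing.assert_allclose(xt.vectors, [[0.0, 0.5]])

    def test_simplex_path_stays_on_simplex(self):
        rng = np.random.default_rng(5)
        x0 = sample_prior(VariantId.SIMPLEX, 50, 4, rng)
        x1 = ModalityState(vectors=onehot_rows(rng.integers(0, 4, 50), 4))
        for t in np.linspace(0, 1, 11):
            xt = sample_conditional_path(VariantId.SIMPLEX, x0, x1, t, rng)
            assert np.allclose(xt.vectors.sum(axis=1), 1.0, atol=1e-9)
            assert (xt.vectors >= -1e-12).all()

    def test_dirichlet_endpoint_argmax(self):
        # at t=1 the Dirichlet path concentrates: TV to delta(x1) after argmax < 0.05
        n = 10_000
        idx = np.full(n, 2)
        x1 = ModalityState(vectors=onehot_rows(idx, 5))
        xt = sample_conditional_path(VariantId.DIRICHLET, None, x1, 1.0, rng=6)
        assert np.allclose(xt.vectors.sum(axis=1), 1.0, atol=1e-6)
        mismatch = (xt.vectors.argmax(axis=1) != 2).mean()
        assert mismatch < 0.05

    def test_dirichlet_t0_is_uniform_prior(self):
        n = 10_000
        x1 = ModalityState(vectors=onehot_rows(np.zeros(n, dtype=int), 3))
        xt = sample_conditional_path(VariantId.DIRICHLET, None, x1, 0.0, rng=7)
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / n)
        assert np.abs(xt.vectors.mean(axis=0) - 1 / 3).max() < 3 * se

    @pytest.mark.parametrize("t", [-0.1, 1.1])
    def test_t_domain_error(self, t):
        x1 = ModalityState(indices=np.array([0]))
        with pytest.raises(ValueError):
            sample_conditional_path(VariantId.CTMC, None, x1, t, rng=0, mask_index=2)

    def test_non_onehot_endpoint_rejected(self):
        x0 = ModalityState(vectors=np.full((2, 3), 1 / 3))
        bad = ModalityState(vectors=np.array([[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            sample_conditional_path(VariantId.SIMPLEX, x0, bad, 0.5, rng=0)


class TestVectorFields:
    def test_linear_field_arithmetic(self):
        xt = ModalityState(vectors=np.array([[0.2]]))
        u = conditional_vector_field(VariantId.CONTINUOUS, xt, np.array([[1.0]]), 0.5)
        np.testing.assert_allclose(u, [[1.6]])

    @pytest.mark.parametrize("variant", [VariantId.CONTINUOUS, VariantId.SIMPLEX, VariantId.EUCLIDEAN])
    @pytest.mark.parametrize("t", [0.0, 0.3, 0.9])
    def test_fixed_point_zero_field(self, variant, t):
        x = np.random.default_rng(8).dirichlet(np.ones(4), size=6)
        u = conditional_vector_field(variant, ModalityState(vectors=x), x, t)
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_dirichlet_field_tangent_to_simplex(self, rng):
        x = rng.dirichlet(np.ones(5), size=40)
        p_hat = rng.dirichlet(np.ones(5), size=40)
        for t in (0.05, 0.2, 0.4):
            u = conditional_vector_field(VariantId.DIRICHLET, ModalityState(vectors=x), p_hat, t)
            assert np.abs(u.sum(axis=1)).max() < 1e-8

    def test_field_singular_at_t1(self):
        xt = ModalityState(vectors=np.array([[0.2, 0.8]]))
        with pytest.raises(ValueError):
            conditional_vector_field(VariantId.SIMPLEX, xt, np.array([[1.0, 0.0]]), 1.0)

    def test_beta_schedule_monotone_and_capped(self):
        ts = np.linspace(0, 1, 101)
        vals = [beta_schedule(t) for t in ts]
        assert vals[0] == 0.0 and vals[-1] == 100.0
        assert np.all(np.diff(vals) >= -1e-12)

    def test_project_to_simplex(self):
        v = np.array([[0.5, -1e-9, 0.5], [0.2, 0.3, 0.5]])
        out = project_to_simplex(v)
        assert (out >= 0).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
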