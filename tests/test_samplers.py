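"""Euler steps, CTMC jump transitions, and the generation loop."""

import numpy as np
import pytest

from molflows.denoiser import MemorizationDenoiser
from molflows.interpolants import VariantId
from molflows.samplers import SamplerConfig, ctmc_step, euler_step, generate, sample_sizes


class TestEulerStep:
    def test_arithmetic(self):
        assert euler_step(np.array(0.0), np.array(1.6), 0.1) == pytest.approx(0.16)

    def test_zero_field_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(euler_step(x, np.zeros(3), 0.3), x)

    def test_simplex_row_preserved_under_tangent_update(self, rng):
        x = rng.dirichlet(np.ones(4), size=10)
        target = rng.dirichlet(np.ones(4), size=10)
        t = 0.4
        u = (target - x) / (1 - t)
        out = euler_step(x, u, 0.25)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            euler_step(np.zeros(2), np.ones(2), 0.0)


class TestCtmcStep:
    def test_unmask_probability(self):
        # P(unmask) = dt/(1-t) = 0.2; 3-sigma binomial band over 1e5 tokens
        n = 100_000
        x = np.full(n, 3)  # all masked (D=3)
        p1 = np.tile([0.0, 0.0, 1.0], (n, 1))
        out = ctmc_step(x, p1, t=0.5, dt=0.1, rng=0)
        frac = (out == 2).mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)
        assert set(np.unique(out)) <= {2, 3}  # revealed class always from p1_hat

    def test_unmasked_tokens_absorbing(self):
        x = np.array([0, 1, 2])
        p1 = np.tile([0.0, 0.0, 1.0], (3, 1))
        out = ctmc_step(x, p1, t=0.5, dt=0.1, rng=1)
        assert (out == x).all()

    def test_final_step_resolves_all_masks(self):
        x = np.full(1000, 2)
        p1 = np.tile([0.25, 0.75], (1000, 1))
        out = ctmc_step(x, p1, t=0.9, dt=0.1, rng=2)
        assert (out < 2).all()

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            ctmc_step(np.array([2]), np.array([[0.6, 0.6]]), 0.5, 0.1, rng=0)

    @pytest.mark.parametrize("k_steps", [2, 4, 7, 10])
    def test_matches_exact_chain_enumeration(self, k_steps):
        """K-step sampler vs forward recursion of the two-state chain."""
        p1 = np.array([0.7, 0.3])
        # exact enumeration: state distribution over (class0, class1, mask)
        dist = np.array([0.0, 0.0, 1.0])
        grid = np.linspace(0, 1, k_steps + 1)
        for k in range(k_steps):
            t = grid[k]
            dt = grid[k + 1] - grid[k]
            p_un = 1.0 if k == k_steps - 1 else dt / (1 - t)
            moved = dist[2] * p_un
            dist = dist + np.array([moved * p1[0], moved * p1[1], -moved])
        assert dist[2] == pytest.approx(0.0, abs=1e-12)

        n = 100_000
        x = np.full(n, 2)
        rng = np.random.default_rng(3)
        for k in range(k_steps):
            x = ctmc_step(x, np.tile(p1, (n, 1)), grid[k], grid[k + 1] - grid[k], rng)
        for cls in (0, 1):
            frac = (x == cls).mean()
            assert abs(frac - dist[cls]) < 3 * np.sqrt(dist[cls] * (1 - dist[cls]) / n)


class TestSampleSizes:
    def test_point_mass(self):
        assert sample_sizes({5: 1.0}, 3, rng=0) == [5, 5, 5]

    def test_two_point_frequencies(self):
        n = 10_000
        sizes = np.array(sample_sizes({4: 0.5, 6: 0.5}, n, rng=1))
        assert abs((sizes == 4).mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_empty_request(self):
        assert sample_sizes({4: 1.0}, 0, rng=0) == []

    def test_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            sample_sizes({4: 0.0}, 1, rng=0)


class TestGenerate:
    @pytest.mark.parametrize(
        "variant",
        [VariantId.CONTINUOUS, VariantId.SIMPLEX, VariantId.DIRICHLET, VariantId.CTMC],
    )
    def test_perfect_memorization(self, fixture_mols, variant):
        target = fixture_mols["methane"].copy()
        target.positions = target.positions - target.positions.mean(axis=0)
        denoiser = MemorizationDenoiser(target)
        if variant is VariantId.CTMC:
            denoiser.vocabs = target.vocabs.with_mask()
        cfg = SamplerConfig(variant=variant, n_steps=20, rng_seed=0)
        mols = generate(denoiser, 4, {target.n_atoms: 1.0}, cfg)
        for g in mols:
            assert (g.atom_types == target.atom_types).all()
            assert (g.charges == target.charges).all()
            assert (g.bond_orders == target.bond_orders).all()
            np.testing.assert_allclose(g.positions, target.positions, atol=1e-8)

    def test_empty_batch(self, fixture_mols):
        denoiser = MemorizationDenoiser(fixture_mols["methane"])
        assert generate(denoiser, 0, {5: 1.0}, SamplerConfig(n_steps=5)) == []

    def test_fixed_seed_repeatability(self, fixture_mols):
        target = fixture_mols["methane"]
        denoiser = MemorizationDenoiser(target)
        denoiser.vocabs = target.vocabs.with_mask()
        cfg = SamplerConfig(variant=VariantId.CTMC, n_steps=10, rng_seed=42, record_trajectories=True)
        a_mols, a_trajs = generate(denoiser, 3, {5: 1.0}, cfg)
        b_mols, b_trajs = generate(denoiser, 3, {5: 1.0}, cfg)
        for ga, gb in zip(a_mols, b_mols):
            assert (ga.atom_types == gb.atom_types).all()
            np.testing.assert_array_equal(ga.positions, gb.positions)
        for ta, tb in zip(a_trajs, b_trajs):
            np.testing.assert_array_equal(ta.states["atoms"], tb.states["atoms"])

    def test_ctmc_trajectory_purely_discrete(self, fixture_mols):
        target = fixture_mols["methane"]
        denoiser = MemorizationDenoiser(target)
        denoiser.vocabs = target.vocabs.with_mask()
        cfg = SamplerConfig(variant=VariantId.CTMC, n_steps=25, rng_seed=5, record_trajectories=True)
        _, trajs = generate(denoiser, 2, {5: 1.0}, cfg)
        da = target.vocabs.atoms.n_real
        for traj in trajs:
            states = traj.states["atoms"]
            assert states.dtype.kind == "i"
            assert states.max() <= da  # real classes plus the mask index
            assert traj.grid[0] == 0.0 and traj.grid[-1] == 1.0

    def test_trajectory_grid_matches_config(self, fixture_mols):
        target = fixture_mols["methane"]
        denoiser = MemorizationDenoiser(target)
        cfg = SamplerConfig(variant=VariantId.SIMPLEX, n_steps=8, rng_seed=1, record_trajectories=True)
        _, trajs = generate(denoiser, 1, {5: 1.0}, cfg)
        np.testing.assert_allclose(trajs[0].grid, np.linspace(0, 1, 9))
        assert trajs[0].states["atoms"].shape == (5, 9)
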