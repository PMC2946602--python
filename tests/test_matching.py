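"""Single-surface matching: energy composition, gradients, recovery, limits."""

import numpy as np
import pytest

from surfatlas import (
    CurrentsKernel,
    KernelSpec,
    MatchConfig,
    TriMesh,
    currents_energy,
    default_sigma_w,
    default_tau,
    deform_mesh,
    make_icosphere,
    match_surface,
    matching_energy,
    matching_gradient,
    sample_momentum,
    solve_gram,
    v_norm,
)


@pytest.fixture
def ck12(ico12):
    return CurrentsKernel(sigma_w=default_sigma_w(ico12))


class TestMatchingEnergy:
    def test_zero_alpha_identical_target(self, ico12, spec12, ck12):
        e, (reg, mis) = matching_energy(
            ico12, ico12, spec12, ck12, np.zeros((12, 3)), MatchConfig()
        )
        assert reg == 0.0
        assert abs(e) < 1e-12

    def test_zero_alpha_reduces_to_currents_term(self, ico12, spec12, ck12):
        target = make_icosphere(0, radius=1.2)
        cfg = MatchConfig(sigma2=2.0)
        e, (reg, mis) = matching_energy(ico12, target, spec12, ck12, np.zeros((12, 3)), cfg)
        assert reg == 0.0
        assert e == pytest.approx(currents_energy(target, ico12, ck12) / 2.0, rel=1e-12)

    def test_composition_of_module_oracles(self, ico12, spec12, ck12, rng):
        target = make_icosphere(0, radius=1.15)
        cfg = MatchConfig(sigma2=1.7, steps=20)
        a = sample_momentum(ico12, spec12, 0.1, rng)
        e, _ = matching_energy(ico12, target, spec12, ck12, a, cfg)
        expected = v_norm(ico12, spec12, a) + (
            currents_energy(target, deform_mesh(ico12, spec12, a, 20), ck12) / 1.7
        )
        assert e == pytest.approx(expected, rel=1e-12)


class TestMatchingGradient:
    def test_zero_at_global_minimum(self, ico12, spec12, ck12):
        g = matching_gradient(
            ico12, ico12, spec12, ck12, np.zeros((12, 3)), MatchConfig()
        )
        assert np.abs(g).max() < 1e-10

    def test_euclidean_gradient_matches_finite_differences(self, rng):
        # 8-vertex instance: two stacked tetrahedra sharing no vertices
        v = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
             [2, 2, 2.5], [2, 0, 0.5], [0, 2, 0.5], [0, 0, 2.5]],
            dtype=float,
        )
        f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3],
                      [4, 6, 5], [4, 5, 7], [4, 7, 6], [5, 6, 7]])
        mesh = TriMesh(v, f)
        spec = KernelSpec(tau=default_tau(mesh))
        ck = CurrentsKernel(sigma_w=default_sigma_w(mesh))
        target = TriMesh(1.1 * v, f)
        cfg = MatchConfig(sigma2=1.0, steps=20)
        a = sample_momentum(mesh, spec, 0.1, rng)
        g = matching_gradient(mesh, target, spec, ck, a, cfg, preconditioned=False)
        h = 1e-5
        gfd = np.zeros_like(g)
        for l in range(8):
            for j in range(3):
                ap = a.copy(); ap[l, j] += h
                am = a.copy(); am[l, j] -= h
                gfd[l, j] = (
                    matching_energy(mesh, target, spec, ck, ap, cfg)[0]
                    - matching_energy(mesh, target, spec, ck, am, cfg)[0]
                ) / (2 * h)
        assert np.abs(g - gfd).max() < 1e-4 * np.abs(gfd).max()

    def test_preconditioned_is_gram_solve_of_euclidean(self, ico12, spec12, ck12, rng):
        target = make_icosphere(0, radius=1.1)
        cfg = MatchConfig(steps=20)
        a = sample_momentum(ico12, spec12, 0.08, rng)
        from surfatlas.kernels import scalar_gram

        g_pre = matching_gradient(ico12, target, spec12, ck12, a, cfg)
        g_euc = matching_gradient(ico12, target, spec12, ck12, a, cfg, preconditioned=False)
        eta = g_euc - 2.0 * (scalar_gram(ico12.vertices, spec12) @ a)  # strip the 2Γα part
        back = solve_gram(ico12, spec12, eta, ridge=cfg.resolved_ridge(spec12), tol=cfg.solve_tol)
        np.testing.assert_allclose(g_pre, 2.0 * a + back, rtol=1e-6, atol=1e-10)
        # the preconditioned direction has nonnegative gram norm
        assert np.sum(g_pre * g_euc) >= 0


class TestMatchSurface:
    def test_identical_target_stays_at_zero(self, ico12, spec12, ck12):
        res = match_surface(ico12, ico12, spec12, ck12)
        assert not np.any(res.alpha)
        assert res.converged

    def test_self_recovery_small_instance(self, ico12, spec12, ck12, rng):
        astar = sample_momentum(ico12, spec12, 0.12, rng)
        target = deform_mesh(ico12, spec12, astar, 20)
        cfg = MatchConfig(sigma2=0.01, max_iters=100, steps=20)
        init = currents_energy(target, ico12, ck12) / cfg.sigma2
        res = match_surface(ico12, target, spec12, ck12, None, cfg)
        assert res.final_mismatch < 0.02 * init
        rec = deform_mesh(ico12, spec12, res.alpha, 20)
        err = np.linalg.norm(rec.vertices - target.vertices, axis=1).max()
        assert err < 0.05 * ico12.diameter

    def test_energy_trace_non_increasing(self, ico12, spec12, ck12, rng):
        target = deform_mesh(ico12, spec12, sample_momentum(ico12, spec12, 0.1, rng), 20)
        res = match_surface(ico12, target, spec12, ck12, None, MatchConfig(max_iters=30))
        assert all(b <= a for a, b in zip(res.energy_trace, res.energy_trace[1:]))

    def test_large_sigma2_recovers_prior_mode(self, ico12, spec12, ck12, rng):
        target = deform_mesh(ico12, spec12, sample_momentum(ico12, spec12, 0.1, rng), 20)
        cfg = MatchConfig(sigma2=1e8, max_iters=50)
        res = match_surface(ico12, target, spec12, ck12, None, cfg)
        assert np.linalg.norm(res.alpha) < 1e-6 * ico12.diameter

    def test_translation_equivariance_of_trace(self, ico12, spec12, ck12, rng):
        target = deform_mesh(ico12, spec12, sample_momentum(ico12, spec12, 0.1, rng), 20)
        cfg = MatchConfig(max_iters=10)
        r0 = match_surface(ico12, target, spec12, ck12, None, cfg)
        shift = np.array([3.0, -1.0, 2.0])
        r1 = match_surface(
            TriMesh(ico12.vertices + shift, ico12.faces),
            TriMesh(target.vertices + shift, target.faces),
            spec12, ck12, None, cfg,
        )
        np.testing.assert_allclose(r0.energy_trace, r1.energy_trace, rtol=1e-8, atol=1e-12)
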