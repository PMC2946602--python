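"""Template update: vertex gradients, the two-level chain rule, descent."""

import numpy as np
import pytest

from surfatlas import (
    CurrentsKernel,
    KernelSpec,
    MStepConfig,
    TriMesh,
    default_sigma_w,
    default_tau,
    deform_mesh,
    make_icosphere,
    norm_grad_points,
    sample_momentum,
    template_energy,
    template_gradient,
    update_template,
    v_norm,
)


def eight_vertex_mesh():
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
         [2, 2, 2.5], [2, 0, 0.5], [0, 2, 0.5], [0, 0, 2.5]],
        dtype=float,
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3],
                  [4, 6, 5], [4, 5, 7], [4, 7, 6], [5, 6, 7]])
    return TriMesh(v, f)


class TestNormGradPoints:
    def test_zero_alpha(self, ico12, spec12):
        assert not np.any(norm_grad_points(ico12, spec12, np.zeros((12, 3))))

    def test_single_vertex_no_pairwise_term(self):
        m = TriMesh.__new__(TriMesh)
        object.__setattr__(m, "vertices", np.zeros((1, 3)))
        object.__setattr__(m, "faces", np.empty((0, 3), dtype=int))
        g = norm_grad_points(m, KernelSpec(tau=1.0), np.array([[1.0, 2.0, 3.0]]))
        assert not np.any(g)

    def test_matches_finite_differences(self, rng):
        v = rng.standard_normal((6, 3))
        mesh = TriMesh(v, [[0, 1, 2]])
        spec = KernelSpec(tau=1.2)
        a = rng.standard_normal((6, 3))
        g = norm_grad_points(mesh, spec, a)
        h = 1e-6
        gfd = np.zeros_like(g)
        for k in range(6):
            for j in range(3):
                vp = v.copy(); vp[k, j] += h
                vm = v.copy(); vm[k, j] -= h
                gfd[k, j] = (
                    v_norm(TriMesh(vp, mesh.faces), spec, a)
                    - v_norm(TriMesh(vm, mesh.faces), spec, a)
                ) / (2 * h)
        assert np.abs(g - gfd).max() < 1e-7 * max(np.abs(gfd).max(), 1.0)


class TestTemplateEnergy:
    def test_all_zero_perfect_fit(self, ico12, spec12):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        z = np.zeros((12, 3))
        e = template_energy(ico12, spec12, ck, z, [z, z], [ico12, ico12], MStepConfig())
        assert abs(e) < 1e-12

    def test_no_observations_reduces_to_prior(self, ico12, spec12, rng):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        mu = sample_momentum(ico12, spec12, 0.1, rng)
        e = template_energy(ico12, spec12, ck, mu, [], [], MStepConfig())
        assert e == pytest.approx(v_norm(ico12, spec12, mu), rel=1e-12)

    def test_composition_of_module_oracles(self, ico12, spec12, rng):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        cfg = MStepConfig(lam=2.0, steps=20)
        mu = sample_momentum(ico12, spec12, 0.05, rng)
        alphas = [sample_momentum(ico12, spec12, 0.05, rng) for _ in range(2)]
        targets = [make_icosphere(0, 1.1), make_icosphere(0, 0.9)]
        e = template_energy(ico12, spec12, ck, mu, alphas, targets, cfg, sigma2=1.5)
        T = deform_mesh(ico12, spec12, mu, 20)
        from surfatlas import currents_energy

        expected = v_norm(ico12, spec12, mu)
        for a, t in zip(alphas, targets):
            expected += (
                v_norm(T, spec12, a)
                + currents_energy(t, deform_mesh(T, spec12, a, 20), ck) / 1.5
            ) / 2.0
        assert e == pytest.approx(expected, rel=1e-12)


class TestTemplateGradient:
    def test_zero_at_perfect_fit(self, ico12, spec12):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        z = np.zeros((12, 3))
        g = template_gradient(ico12, spec12, ck, z, [z], [ico12], MStepConfig())
        assert np.abs(g).max() < 1e-10

    def test_two_level_chain_rule_matches_finite_differences(self, rng):
        """Full chain through both flows vs brute-force differences of Ẽ(μ)."""
        mesh = eight_vertex_mesh()
        spec = KernelSpec(tau=default_tau(mesh))
        ck = CurrentsKernel(sigma_w=default_sigma_w(mesh))
        cfg = MStepConfig(lam=1.0, steps=20)
        mu = sample_momentum(mesh, spec, 0.05, rng)
        alphas = [sample_momentum(mesh, spec, 0.07, rng) for _ in range(2)]
        targets = [
            TriMesh(1.1 * mesh.vertices, mesh.faces),
            TriMesh(0.95 * mesh.vertices + 0.05, mesh.faces),
        ]
        g = template_gradient(
            mesh, spec, ck, mu, alphas, targets, cfg, preconditioned=False
        )
        h = 1e-6
        gfd = np.zeros_like(g)
        for k in range(8):
            for j in range(3):
                mp = mu.copy(); mp[k, j] += h
                mm = mu.copy(); mm[k, j] -= h
                gfd[k, j] = (
                    template_energy(mesh, spec, ck, mp, alphas, targets, cfg)
                    - template_energy(mesh, spec, ck, mm, alphas, targets, cfg)
                ) / (2 * h)
        assert np.abs(g - gfd).max() < 1e-4 * np.abs(gfd).max()

    def test_prior_only_limit(self, ico12, spec12, rng):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        mu = sample_momentum(ico12, spec12, 0.1, rng)
        g = template_gradient(
            ico12, spec12, ck, mu, [], [], MStepConfig(), preconditioned=True
        )
        np.testing.assert_allclose(g, 2.0 * mu, rtol=1e-10, atol=1e-12)


class TestUpdateTemplate:
    def test_stationary_at_perfect_fit(self, ico12, spec12):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        z = np.zeros((12, 3))
        mu, template, trace = update_template(ico12, spec12, ck, [z], [ico12], None, MStepConfig())
        assert not np.any(mu)
        np.testing.assert_array_equal(template.vertices, ico12.vertices)

    def test_moves_template_toward_observation(self, ico12, spec12):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        target = make_icosphere(0, radius=1.2)
        z = np.zeros((12, 3))
        from surfatlas import currents_energy

        before = currents_energy(target, ico12, ck)
        mu, template, trace = update_template(
            ico12, spec12, ck, [z], [target], None, MStepConfig(max_iters=10)
        )
        assert currents_energy(target, template, ck) < before
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_large_lambda_pins_template(self, ico12, spec12):
        ck = CurrentsKernel(sigma_w=default_sigma_w(ico12))
        target = make_icosphere(0, radius=1.3)
        z = np.zeros((12, 3))
        mu, _, _ = update_template(
            ico12, spec12, ck, [z], [target], None, MStepConfig(lam=1e8, max_iters=10)
        )
        assert np.linalg.norm(mu) < 1e-4 * ico12.diameter
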