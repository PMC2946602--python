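"""Adjoint (costate) machinery for gradients through the geodesic flow.

Differentiating the shooting system along a trajectory gives a linear system
d(δx, δa)/dt = J(t)(δx, δa) whose blocks involve γ, γ' and γ''.  The costate
(η_x, η_α) solves d(η_x, η_α)/dt = −J(t)*(η_x, η_α) backward from t = 1; with
terminal condition (v, 0), η_α(0) is the pullback (dx(1)/dα)*·v and η_x(0) is
(dx(1)/dx(0))*·v.  J is never materialized — only matrix-free applications of
J and J* (O(L²) each) are provided, and the continuous adjoint is discretized
with the same fixed-step RK4 as the forward pass, interpolating the stored
trajectory linearly at stage times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, _pairwise_r2
from .shooting import Trajectory

__all__ = [
    "AdjointState",
    "jacobian_apply",
    "backward_sweep",
    "grad_wrt_momentum",
    "grad_wrt_points",
]


@dataclass(frozen=True)
class AdjointState:
    """Costate pair at one time: eta_x adjoint to positions, eta_a to momenta."""

    eta_x: np.ndarray
    eta_a: np.ndarray
    t: float


def _pairdot_diff(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Matrix P with P[k, l] = (u_k − u_l)·(v_k − v_l), via matmuls."""
    S = u @ v.T
    s = np.einsum("kj,kj->k", u, v)
    return s[:, None] + s[None, :] - S - S.T


def _diffsum(W: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Σ_l W_kl (y_k − y_l), row-sum form (no (L, L, 3) temporary)."""
    return W.sum(axis=1)[:, None] * y - W @ y


def _jac_apply_state(
    x: np.ndarray,
    a: np.ndarray,
    spec: KernelSpec,
    dx: np.ndarray,
    da: np.ndarray,
    transpose: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply J(x, a) or J(x, a)* to (dx, da), matrix-free (all BLAS level 3)."""
    from .shooting import _fast_r2

    G = np.asarray(spec.gamma(_fast_r2(x)))
    G1 = G * (-0.5 / spec.tau**2)
    G2 = G * (0.25 / spec.tau**4)
    aa = a @ a.T  # a_k · a_l (symmetric)

    if not transpose:
        # linearization of dx_k/dt = Σ γ_kl a_l:
        #   u_k = Σ_l γ_kl δa_l + 2 Σ_l γ'_kl [e_kl·(δx_k − δx_l)] a_l
        P = _pairdot_diff(x, dx)  # e_kl·(δx_k − δx_l)
        u = G @ da + (2.0 * G1 * P) @ a
        # linearization of da_k/dt = −2 Σ γ'_kl (a_l·a_k) e_kl
        t12 = a @ da.T + da @ a.T  # a_k·δa_l + δa_k·a_l
        v = -2.0 * _diffsum(G1 * t12, x)
        v -= 2.0 * _diffsum(G1 * aa, dx)
        v -= 4.0 * _diffsum(G2 * aa * P, x)
        return u, v

    # transpose: (p, q) = J*(η_x, η_a) with η_x = dx, η_a = da
    ex, ea = dx, da
    exa = ex @ a.T  # η_x,k · a_l
    # dea_e[k, l] = (η_a,l − η_a,k)·(x_k − x_l)
    T = x @ ea.T
    t = np.einsum("kj,kj->k", x, ea)
    dea_e = T + T.T - t[:, None] - t[None, :]
    p = 2.0 * _diffsum(G1 * (exa + exa.T), x)
    W = G1 * aa
    p += 2.0 * (W @ ea - W.sum(axis=1)[:, None] * ea)  # Σ W_kl (η_a,l − η_a,k)
    p += 4.0 * _diffsum(G2 * aa * dea_e, x)
    q = G @ ex + (2.0 * G1 * dea_e) @ a
    return p, q


def jacobian_apply(
    traj: Trajectory,
    t_index: int,
    dx: np.ndarray,
    da: np.ndarray,
    transpose: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """J(t_i)·(dx, da) or J(t_i)*·(dx, da) at a stored trajectory step."""
    x = traj.positions[t_index]
    a = traj.momenta[t_index]
    return _jac_apply_state(x, a, traj.spec, np.asarray(dx, float), np.asarray(da, float), transpose)


def backward_sweep(
    traj: Trajectory, eta_x_end: np.ndarray, eta_a_end: np.ndarray
) -> AdjointState:
    """Integrate d(η_x, η_α)/dt = −J(t)*(η_x, η_α) from t=1 back to t=0.

    RK4 with the same step count as the forward pass; (x, a) at the half-step
    stage times are linear interpolants of the stored trajectory.
    """
    spec = traj.spec
    steps = traj.steps
    h = 1.0 / steps
    ex = np.array(eta_x_end, dtype=float)
    ea = np.array(eta_a_end, dtype=float)

    def rhs(x, a, ex, ea):
        p, q = _jac_apply_state(x, a, spec, ex, ea, transpose=True)
        return -p, -q

    for i in range(steps, 0, -1):
        x1, a1 = traj.positions[i], traj.momenta[i]
        x0, a0 = traj.positions[i - 1], traj.momenta[i - 1]
        xm, am = 0.5 * (x0 + x1), 0.5 * (a0 + a1)
        # integrating backward: step -h from t_i to t_{i-1}
        k1x, k1a = rhs(x1, a1, ex, ea)
        k2x, k2a = rhs(xm, am, ex - 0.5 * h * k1x, ea - 0.5 * h * k1a)
        k3x, k3a = rhs(xm, am, ex - 0.5 * h * k2x, ea - 0.5 * h * k2a)
        k4x, k4a = rhs(x0, a0, ex - h * k3x, ea - h * k3a)
        ex = ex - (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        ea = ea - (h / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
        if not (np.all(np.isfinite(ex)) and np.all(np.isfinite(ea))):
            raise FloatingPointError(f"adjoint sweep blew up between steps {i} and {i - 1}")
    return AdjointState(eta_x=ex, eta_a=ea, t=0.0)


def grad_wrt_momentum(traj: Trajectory, v: np.ndarray) -> np.ndarray:
    """(dx(1)/dα)*·v = η_α(0), from the sweep with terminal (η_x, η_α) = (v, 0)."""
    v = np.asarray(v, dtype=float)
    state = backward_sweep(traj, v, np.zeros_like(v))
    return state.eta_a


def grad_wrt_points(traj: Trajectory, v: np.ndarray) -> np.ndarray:
    """(dx(1)/dx(0))*·v = η_x(0) at fixed initial momentum; same sweep, other leg."""
    v = np.asarray(v, dtype=float)
    state = backward_sweep(traj, v, np.zeros_like(v))
    return state.eta_x
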