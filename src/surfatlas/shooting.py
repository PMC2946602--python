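"""Geodesic shooting: the discrete EPDiff point-set system.

With a radial kernel γ and γ_kl = γ(‖x_k−x_l‖²), the vertices x_k and their
momenta a_k evolve on [0, 1] by

    dx_k/dt =  Σ_l γ_kl a_l
    da_k/dt = −2 Σ_l γ'_kl (a_l·a_k)(x_k − x_l).

This is the Hamiltonian system of H(x, a) = ½ Σ_{k,l} γ_kl (a_k·a_l), so H is
conserved along exact solutions; the drift of H under the fixed-step RK4
integrator is the standard accuracy diagnostic.  The initial momentum alone
parameterizes the deformation: the deformed surface T_α keeps the template's
topology and carries its vertices to x(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, _pairwise_r2
from .mesh_io import TriMesh

__all__ = ["Trajectory", "shoot", "hamiltonian", "deform_mesh", "epdiff_rhs"]


@dataclass(frozen=True)
class Trajectory:
    """Dense time-discretized solution of the shooting ODE.

    positions[i], momenta[i] hold x(t_i), a(t_i) at the uniform grid
    t_i = i/steps on [0, 1].  Stored densely because the backward adjoint
    sweep needs the state at every step.
    """

    times: np.ndarray  # (T+1,)
    positions: np.ndarray  # (T+1, L, 3)
    momenta: np.ndarray  # (T+1, L, 3)
    spec: KernelSpec

    @property
    def steps(self) -> int:
        return len(self.times) - 1

    def state(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(x, a) at arbitrary t by linear interpolation between stored steps."""
        s = np.clip(t, 0.0, 1.0) * self.steps
        i = min(int(np.floor(s)), self.steps - 1)
        w = s - i
        x = (1 - w) * self.positions[i] + w * self.positions[i + 1]
        a = (1 - w) * self.momenta[i] + w * self.momenta[i + 1]
        return x, a


def _fast_r2(x: np.ndarray) -> np.ndarray:
    """Pairwise squared distances via matmul (BLAS); clipped at zero."""
    sq = np.einsum("kj,kj->k", x, x)
    r2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    return np.maximum(r2, 0.0)


def epdiff_rhs(
    x: np.ndarray, a: np.ndarray, spec: KernelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side (dx/dt, da/dt) of the point-set EPDiff system.

    The pairwise sums Σ_l W_kl (x_k − x_l) are evaluated as
    rowsum(W)·x_k − (W @ x), keeping everything in matrix products.
    """
    G = np.asarray(spec.gamma(_fast_r2(x)))
    G1 = G * (-0.5 / spec.tau**2)
    dx = G @ a
    W = G1 * (a @ a.T)  # γ'_kl (a_k·a_l)
    da = -2.0 * (W.sum(axis=1)[:, None] * x - W @ x)
    return dx, da


def shoot(mesh: TriMesh, spec: KernelSpec, alpha: np.ndarray, steps: int = 20) -> Trajectory:
    """Integrate the shooting system from (x(0)=vertices, a(0)=alpha) to t=1.

    Classical fixed-step RK4; deterministic.  Aborts with the step index if
    the state becomes non-finite (momentum far too large for the kernel
    width, typically).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (mesh.n_vertices, 3):
        raise ValueError("alpha must be an (L, 3) field on the mesh vertices")
    h = 1.0 / steps
    L = mesh.n_vertices
    xs = np.empty((steps + 1, L, 3))
    as_ = np.empty((steps + 1, L, 3))
    xs[0], as_[0] = mesh.vertices, alpha
    x, a = mesh.vertices.copy(), alpha.copy()
    for i in range(steps):
        k1x, k1a = epdiff_rhs(x, a, spec)
        k2x, k2a = epdiff_rhs(x + 0.5 * h * k1x, a + 0.5 * h * k1a, spec)
        k3x, k3a = epdiff_rhs(x + 0.5 * h * k2x, a + 0.5 * h * k2a, spec)
        k4x, k4a = epdiff_rhs(x + h * k3x, a + h * k3a, spec)
        x = x + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        a = a + (h / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(a))):
            raise FloatingPointError(f"shooting blew up at step {i + 1}/{steps}")
        xs[i + 1], as_[i + 1] = x, a
    return Trajectory(
        times=np.linspace(0.0, 1.0, steps + 1), positions=xs, momenta=as_, spec=spec
    )


def hamiltonian(traj: Trajectory, t_index: int) -> float:
    """H(t_i) = ½ Σ_{k,l} γ(‖x_k(t)−x_l(t)‖²)(a_k(t)·a_l(t))."""
    x = traj.positions[t_index]
    a = traj.momenta[t_index]
    G = traj.spec.gamma(_pairwise_r2(x))
    return 0.5 * float(np.einsum("kl,kj,lj->", G, a, a))


def deform_mesh(
    mesh: TriMesh, spec: KernelSpec, alpha: np.ndarray, steps: int = 20
) -> TriMesh:
    """The deformed surface T_α: vertices x(1), topology copied from ``mesh``."""
    if not np.any(alpha):
        return mesh.with_vertices(mesh.vertices.copy())
    traj = shoot(mesh, spec, alpha, steps)
    return mesh.with_vertices(traj.positions[-1])
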