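"""Gaussian deformation kernel, the Gram matrix Γ_T and momentum algebra.

The deformation kernel is radial, K(x, y) = γ(‖x−y‖²) with
γ(r²) = cst · exp(−r² / (2τ²)).  Its first two derivatives with respect to r²
enter the geodesic equations and their linearization.  The Gram matrix on a
mesh with L vertices is the 3L×3L block matrix with blocks γ(‖x_k−x_l‖²)·I₃;
because each block is a scalar multiple of the identity, Γ_T = G ⊗ I₃ with G
the L×L scalar gram, and all solves and factorizations are carried out on G.

Γ_T defines the squared momentum norm ‖α‖²_T = αᵀ Γ_T α, which is both the
deformation-energy regularizer and the inverse covariance of the Gaussian
prior on initial momenta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .mesh_io import TriMesh

__all__ = [
    "KernelSpec",
    "gamma_eval",
    "scalar_gram",
    "gram_matrix",
    "v_norm",
    "solve_gram",
    "default_tau",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel γ(r²) = amplitude · exp(−r²/(2 tau²)).

    tau is the kernel width in the mesh's length units; it sets the spatial
    scale over which momentum vectors on different vertices interact.
    amplitude is the dimensionless constant γ(0); it trades off against the
    overall momentum scale, so the default 1.0 loses no generality.
    """

    tau: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def gamma(self, r2: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude * np.exp(-np.asarray(r2) / (2.0 * self.tau**2))

    def gamma1(self, r2: np.ndarray | float) -> np.ndarray | float:
        """dγ/d(r²)."""
        return self.gamma(r2) * (-0.5 / self.tau**2)

    def gamma2(self, r2: np.ndarray | float) -> np.ndarray | float:
        """d²γ/d(r²)²."""
        return self.gamma(r2) * (0.25 / self.tau**4)


def default_tau(mesh: TriMesh, fraction: float = 0.2) -> float:
    """Kernel width as a fraction of the mesh bounding-box diagonal."""
    return fraction * mesh.diameter


def gamma_eval(spec: KernelSpec, r2: float, order: int = 0) -> float:
    """γ(r²) or its first/second derivative with respect to r²."""
    if np.any(np.asarray(r2) < 0):
        raise ValueError("r2 must be nonnegative")
    if order == 0:
        return float(spec.gamma(r2))
    if order == 1:
        return float(spec.gamma1(r2))
    if order == 2:
        return float(spec.gamma2(r2))
    raise ValueError("order must be 0, 1, or 2")


def _pairwise_r2(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    y = x if y is None else y
    d = x[:, None, :] - y[None, :, :]
    return np.einsum("klj,klj->kl", d, d)


def scalar_gram(points: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """L×L matrix G with G[k, l] = γ(‖x_k − x_l‖²)."""
    return np.asarray(spec.gamma(_pairwise_r2(np.asarray(points, dtype=float))))


def gram_matrix(mesh: TriMesh, spec: KernelSpec) -> np.ndarray:
    """The full 3L×3L block Gram matrix Γ_T = G ⊗ I₃."""
    return np.kron(scalar_gram(mesh.vertices, spec), np.eye(3))


def v_norm(mesh: TriMesh, spec: KernelSpec, alpha: np.ndarray) -> float:
    """Squared momentum norm ‖α‖²_T = Σ_{k,l} γ(‖x_k−x_l‖²)(α_k·α_l).

    ``alpha`` is an (L, 3) field bound to the mesh's vertices.
    """
    alpha = _check_field(mesh, alpha)
    G = scalar_gram(mesh.vertices, spec)
    return float(np.einsum("kl,kj,lj->", G, alpha, alpha))


def _check_field(mesh: TriMesh, field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_vertices, 3):
        raise ValueError(
            f"momentum field shape {field.shape} does not match mesh (L={mesh.n_vertices})"
        )
    return field


def solve_gram(
    mesh: TriMesh,
    spec: KernelSpec,
    rhs: np.ndarray,
    ridge: float | None = None,
    tol: float = 1e-10,
    maxit: int | None = None,
) -> np.ndarray:
    """Solve (Γ_T + ridge·I) z = rhs by conjugate gradient.

    Γ_T is typically very badly conditioned for the Gaussian kernel, so a
    small ridge (default 1e-7·γ(0), unit-free) is added to the diagonal.
    Thanks to the Kronecker structure the three coordinate columns are solved
    against the scalar L×L gram.  Raises on non-convergence, reporting the
    achieved residual.
    """
    rhs = _check_field(mesh, rhs)
    if ridge is None:
        ridge = 1e-7 * spec.amplitude
    L = mesh.n_vertices
    if maxit is None:
        maxit = 10 * 3 * L
    if not np.any(rhs):
        return np.zeros_like(rhs)
    A = scalar_gram(mesh.vertices, spec) + ridge * np.eye(L)
    op = LinearOperator((L, L), matvec=lambda v: A @ v, dtype=float)
    out = np.empty_like(rhs)
    for j in range(3):
        b = rhs[:, j]
        if not np.any(b):
            out[:, j] = 0.0
            continue
        z, info = cg(op, b, rtol=tol, atol=0.0, maxiter=maxit)
        if info > 0:
            res = float(np.linalg.norm(A @ z - b) / np.linalg.norm(b))
            raise RuntimeError(
                f"gram solve: CG did not converge in {maxit} iterations "
                f"(relative residual {res:.3e})"
            )
        out[:, j] = z
    return out
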