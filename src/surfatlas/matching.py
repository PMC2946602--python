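"""Single-surface matching by initial momentum (the MAE step).

For a template T with momentum field α and an observed surface S, the
matching energy is

    E(α) = ‖α‖²_T + (1/σ²) ‖S − T_α‖²_obs,

the maximum-a-posteriori objective of the generative model for one
observation: the first term is the Gaussian-prior penalty on the deformation,
the second the currents mismatch of the shot surface.  It is minimized by
gradient descent in the Γ_T inner product — the update direction is the
kernel-preconditioned gradient 2α + (1/σ²) Γ_T⁻¹ η_α(0) — with a backtracking
(Armijo) line search so accepted iterates strictly decrease E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .adjoint import grad_wrt_momentum
from .currents import CurrentsKernel, currents_energy, currents_grad
from .kernels import KernelSpec, scalar_gram, solve_gram, v_norm
from .mesh_io import TriMesh
from .shooting import shoot

__all__ = [
    "MatchConfig",
    "MatchResult",
    "matching_energy",
    "matching_gradient",
    "match_surface",
]

ARMIJO_C = 1e-4
LS_SHRINK = 0.5


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of one matching problem.

    sigma2 is the observation-noise variance σ² weighting the currents term;
    steps the RK4 step count of each shoot; grad_tol a relative stopping
    threshold on the preconditioned gradient; energy_tol the relative
    per-iteration energy decrease below which we stop.
    """

    sigma2: float = 1.0
    max_iters: int = 100
    grad_tol: float = 1e-6
    energy_tol: float = 1e-6
    ls_max_halvings: int = 25
    steps: int = 20
    #: ridge for the Γ_T-preconditioner solve.  Larger than the generic gram
    #: ridge: the preconditioner only needs to be SPD (the line search guards
    #: descent), and a looser solve keeps CG iteration counts bounded on
    #: badly conditioned fine-mesh grams.
    ridge: float | None = None
    solve_tol: float = 1e-8

    def resolved_ridge(self, spec) -> float:
        return self.ridge if self.ridge is not None else 1e-5 * spec.amplitude

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class MatchResult:
    alpha: np.ndarray
    energy_trace: list = field(default_factory=list)
    converged: bool = False
    final_mismatch: float = float("nan")
    final_reg: float = float("nan")
    n_iters: int = 0


def matching_energy(
    template: TriMesh,
    target: TriMesh,
    spec: KernelSpec,
    ck: CurrentsKernel,
    alpha: np.ndarray,
    cfg: MatchConfig,
) -> tuple[float, tuple[float, float]]:
    """E(α) and its (regularization, weighted mismatch) parts."""
    reg = v_norm(template, spec, alpha)
    if np.any(alpha):
        deformed = template.with_vertices(
            shoot(template, spec, alpha, cfg.steps).positions[-1]
        )
    else:
        deformed = template
    mis = currents_energy(target, deformed, ck) / cfg.sigma2
    return reg + mis, (reg, mis)


def matching_gradient(
    template: TriMesh,
    target: TriMesh,
    spec: KernelSpec,
    ck: CurrentsKernel,
    alpha: np.ndarray,
    cfg: MatchConfig,
    *,
    preconditioned: bool = True,
) -> np.ndarray:
    """Gradient of E(α).

    The Euclidean gradient is 2 Γ_T α + (1/σ²) η_α(0), where η_α(0) is the
    adjoint pullback of the currents gradient at the deformed surface.  The
    preconditioned form 2α + (1/σ²) Γ_T⁻¹ η_α(0) is the gradient in the Γ_T
    inner product, used as descent direction.
    """
    alpha = np.asarray(alpha, dtype=float)
    traj = shoot(template, spec, alpha, cfg.steps)
    deformed = template.with_vertices(traj.positions[-1])
    du = currents_grad(target, deformed, ck)
    eta_a0 = grad_wrt_momentum(traj, du)
    if preconditioned:
        z = solve_gram(template, spec, eta_a0, ridge=cfg.resolved_ridge(spec), tol=cfg.solve_tol)
        return 2.0 * alpha + z / cfg.sigma2
    G = scalar_gram(template.vertices, spec)
    return 2.0 * (G @ alpha) + eta_a0 / cfg.sigma2


def _descent(
    energy_fn,
    grad_fns,
    x0: np.ndarray,
    cfg,
    scale: float,
) -> tuple[np.ndarray, list, bool, int]:
    """Backtracking gradient descent shared by the MAE and M steps.

    grad_fns(x) returns (preconditioned direction gradient, Euclidean
    gradient); Armijo sufficient decrease uses their inner product, which is
    the squared Γ-norm of the gradient (nonnegative up to ridge effects).
    """
    x = np.array(x0, dtype=float)
    e = energy_fn(x)
    trace = [e]
    converged = False
    it = 0
    eps_prev = 1.0
    for it in range(1, cfg.max_iters + 1):
        g_pre, g_euc = grad_fns(x)
        slope = float(np.sum(g_pre * g_euc))  # directional derivative along −g_pre
        gnorm = float(np.sqrt(np.sum(g_pre * g_pre)))
        if gnorm <= cfg.grad_tol * max(scale, abs(e)):
            converged = True
            break
        if slope <= 0:
            # ridge/roundoff made the preconditioned direction non-descent
            g_pre = g_euc
            slope = float(np.sum(g_euc * g_euc))
            if slope == 0.0:
                converged = True
                break
        # warm-started backtracking: start from twice the last accepted step
        # (capped at 1) so a well-scaled step needs one energy evaluation
        eps = min(1.0, eps_prev / LS_SHRINK)
        accepted = False
        for _ in range(cfg.ls_max_halvings + 1):
            e_new = energy_fn(x - eps * g_pre)
            if e_new <= e - ARMIJO_C * eps * slope:
                accepted = True
                break
            eps *= LS_SHRINK
        if not accepted:
            if it == 1 and not np.any(x0) and gnorm > 1e3 * cfg.grad_tol * max(scale, abs(e)):
                # a failed very first step from a cold start with a sizeable
                # gradient signals a gradient bug or an oversized ridge
                warnings.warn("line search failed at iteration 0", stacklevel=2)
            break
        x = x - eps * g_pre
        eps_prev = eps
        e_prev, e = e, e_new
        trace.append(e)
        if e_prev - e <= cfg.energy_tol * max(abs(e_prev), 1e-300):
            converged = True
            break
    return x, trace, converged, it


def match_surface(
    template: TriMesh,
    target: TriMesh,
    spec: KernelSpec,
    ck: CurrentsKernel,
    alpha0: np.ndarray | None = None,
    cfg: MatchConfig | None = None,
) -> MatchResult:
    """Minimize E(α) from alpha0 (default zero).  Deterministic.

    Accepted iterates strictly decrease the energy; stops on a small
    preconditioned gradient, a small relative energy decrease, a failed line
    search, or max_iters.
    """
    cfg = cfg or MatchConfig()
    if alpha0 is None:
        alpha0 = np.zeros((template.n_vertices, 3))

    def energy(a):
        return matching_energy(template, target, spec, ck, a, cfg)[0]

    def grads(a):
        traj = shoot(template, spec, a, cfg.steps)
        deformed = template.with_vertices(traj.positions[-1])
        du = currents_grad(target, deformed, ck)
        eta_a0 = grad_wrt_momentum(traj, du)
        g_euc = 2.0 * (scalar_gram(template.vertices, spec) @ a) + eta_a0 / cfg.sigma2
        z = solve_gram(template, spec, eta_a0, ridge=cfg.resolved_ridge(spec), tol=cfg.solve_tol)
        g_pre = 2.0 * a + z / cfg.sigma2
        return g_pre, g_euc

    scale = template.diameter
    alpha, trace, converged, n_it = _descent(energy, grads, alpha0, cfg, scale)
    _, (reg, mis) = matching_energy(template, target, spec, ck, alpha, cfg)
    return MatchResult(
        alpha=alpha,
        energy_trace=trace,
        converged=converged,
        final_mismatch=mis,
        final_reg=reg,
        n_iters=n_it,
    )
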