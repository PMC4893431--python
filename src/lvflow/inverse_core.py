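"""Doppler-constrained Navier-Stokes inversion.

The measured quantity is a single beam-projected velocity component
𝒟 = a·v (the beam is fixed along x, so 𝒟 is the first component).  Taking
the beam projection of the momentum equation and adding incompressibility
gives, per frame, a linear system for the two unknown components (v2, v3):

    [ diag(∂𝒟/∂y)  diag(∂𝒟/∂z) ] [v2]   [ -𝒟·∂x𝒟 - ∂t𝒟 + ν∇²𝒟 - (1/ρ)∂x p ]
    [     𝔻y            𝔻z      ] [v3] = [            -∂x𝒟                ]

with Dirichlet wall-motion data on the wall boundary, homogeneous Neumann
conditions at the valve openings, and the pressure recovered from the
current velocity iterate through a Neumann-Poisson problem
∇²p = -ρ ∇·((v·∇)v).  Because the Doppler-gradient diagonal blocks vanish
wherever ∇𝒟 does, the system is solved as a Tikhonov-regularized sequence
of least-squares corrections

    v^{n+1} = v^n + (SᵀS + λ²I)⁻¹ Sᵀ (f^{n+1} - S v^n),

iterated with the pressure until the relative update falls below the
stopping tolerance.  A vorticity-constrained elliptic solve provides the
initial iterate, and a closed-form per-node solution is available when a
second, linearly independent beam is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import DopplerField, PressureField, VelocityField
from .grid_ops import (
    MaskedDomain,
    build_neumann_laplacian,
    masked_operator_set,
    normal_derivative_rows,
)
from .phantom import FluidProperties, WallValues

__all__ = [
    "ReconstructionConfig",
    "AssembledSystem",
    "ReconstructionResult",
    "doppler_time_derivative",
    "solve_pressure",
    "assemble_system",
    "minimize_step",
    "reconstruct_frame",
    "reconstruct_cycle",
    "initial_guess",
    "estimate_d_vector",
    "dual_beam_solve",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tunable parameters of the inverse solver.

    ``lambda2`` is the dimensionless Tikhonov weight λ² applied relative to
    the mean diagonal of SᵀS (see ``regularization``); its default is
    calibrated, like the original operating point of the method, at the
    interior minimum of the cycle-error-versus-λ² sweep on the reference
    Hill-vortex phantom.  ``stop_tol`` is the relative-update stopping
    threshold (default 1e-2); ``d_vector`` the in-plane direction
    d = (d1, d2, 0) whose vorticity component is assumed negligible for
    the initial guess.
    """

    lambda2: float = 1e-2
    stop_tol: float = 1e-2
    max_iter: int = 50
    linear_solver_tol: float = 1e-8
    fluid: FluidProperties = field(default_factory=FluidProperties)
    d_vector: tuple[float, float] = (1.0, 0.0)
    init_mode: str = "vorticity"          # or "zeros"
    scheme: str = "one_sided"             # masked-stencil closure
    solver: str = "auto"                  # "auto" | "direct" | "cg"
    direct_threshold: int = 60000         # max 2n for the sparse direct path
    pressure_maxiter: int = 20000
    pressure_bc: str = "consistent"        # or "homogeneous"
    pressure_update: str = "frozen"       # or "every_iteration"
    regularization: str = "scaled"        # λ² times mean diag(SᵀS); or "absolute"
    det_rel_threshold: float = 0.02       # dual-beam near-singular cutoff
    max_singular_fraction: float = 0.25
    estimate_d: bool = False              # fit d from the initial vorticity
    time_coupling_passes: int = 2         # cycle passes for transverse ∂v/∂t

    def __post_init__(self) -> None:
        if not self.lambda2 > 0:
            raise ValueError("lambda2 must be positive")
        if not 0 < self.stop_tol < 1:
            raise ValueError("stop_tol must lie in (0, 1)")
        if self.d_vector[0] == 0 and self.d_vector[1] == 0:
            raise ValueError("d_vector must be nonzero")
        if self.init_mode not in ("vorticity", "zeros"):
            raise ValueError("init_mode must be 'vorticity' or 'zeros'")
        if self.pressure_bc not in ("consistent", "homogeneous"):
            raise ValueError("pressure_bc must be 'consistent' or 'homogeneous'")
        if self.pressure_update not in ("frozen", "every_iteration"):
            raise ValueError(
                "pressure_update must be 'frozen' or 'every_iteration'")
        if self.regularization not in ("scaled", "absolute"):
            raise ValueError("regularization must be 'scaled' or 'absolute'")


def doppler_time_derivative(series: list[DopplerField]) -> list[np.ndarray]:
    """∂𝒟/∂t per frame by central differences, periodic across the cycle."""
    if len(series) < 3:
        raise ValueError("need at least 3 frames for a time derivative")
    dt = series[0].frame_dt
    if dt <= 0:
        raise ValueError("frame_dt must be set on the Doppler fields")
    vals = [d.values for d in series]
    n = len(vals)
    return [
        (vals[(k + 1) % n] - vals[(k - 1) % n]) / (2.0 * dt) for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Pressure Poisson problem
# ---------------------------------------------------------------------------


def solve_neumann_poisson(
    domain: MaskedDomain,
    rhs_full: np.ndarray,
    flux: list[np.ndarray] | None = None,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> np.ndarray:
    """Solve ∇²p = rhs on the mask with Neumann data ∂p/∂n = g·n.

    ``flux`` optionally gives the three components of the prescribed
    pressure-gradient vector g on the full grid (``None`` = homogeneous
    data).  Finite-volume weak form: the graph Laplacian with transverse
    face weights on the left, trapezoid cell weights times the right-hand
    side minus the boundary-face flux integral on the right.  The singular
    (constant) direction is handled by projecting the right-hand side onto
    the compatible subspace; the solution is gauge-fixed to zero mean.
    Returns the compact inside-node pressure vector.
    """
    key = "neumann_laplacian"
    cached = domain._op_cache.get(key)
    if cached is None:
        from .grid_ops import neumann_surface_weights

        cached = (*build_neumann_laplacian(domain),
                  neumann_surface_weights(domain))
        domain._op_cache[key] = cached
    A, w, s = cached
    f = rhs_full[domain.inside_idx]
    b = w * f
    if flux is not None:
        h = domain.grid.h
        for axis in range(3):
            g_ax = np.asarray(flux[axis]).ravel(order="F")[domain.inside_idx]
            b -= (1.0 / h) * s[axis] * g_ax
    b = b - b.mean()  # compatibility: project onto range of the Laplacian
    n = b.size
    if n == 1:
        return np.zeros(1)
    Apos = (-A).tocsr()
    diag = Apos.diagonal()
    diag[diag == 0] = 1.0
    M = sp.diags(1.0 / diag)
    p_in, info = spla.cg(Apos, -b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(Apos @ p_in + b) / max(np.linalg.norm(b), 1e-300)
        raise RuntimeError(
            f"pressure solve did not converge (info={info}, "
            f"relative residual {res:.2e})"
        )
    return p_in - p_in.mean()


def solve_pressure(
    v: VelocityField,
    domain: MaskedDomain,
    fluid: FluidProperties,
    config: ReconstructionConfig | None = None,
    ddot1: np.ndarray | None = None,
    accel23: tuple[np.ndarray, np.ndarray] | None = None,
) -> PressureField:
    """Pressure Poisson solve  ∇²p = -ρ ∇·((v·∇)v)  on the mask.

    Boundary data per ``config.pressure_bc``:

    * ``"consistent"`` (default) — the Neumann datum is the normal
      component of the momentum balance, ∂p/∂n = ρ(ν∇²v − ∂tv − (v·∇)v)·n,
      evaluated from the current iterate (the measured ∂t𝒟 stands in for
      the first component of ∂tv when provided; the unknown transverse
      acceleration is neglected).  This is the standard consistent closure
      of pressure-Poisson solvers and remains meaningful for data whose
      forward model did not itself impose a zero-flux pressure wall.
    * ``"homogeneous"`` — the zero-flux condition ∂p/∂n = 0.

    Raises if the inner conjugate-gradient solve does not reach the
    requested tolerance.
    """
    config = config or ReconstructionConfig()
    ops = masked_operator_set(domain, config.scheme)
    g = domain.grid
    vc = [g.ravel(v.v[i]) for i in range(3)]
    adv = []
    for i in range(3):
        comp = g.ravel(v.v[i])
        adv.append(vc[0] * (ops.Dx @ comp) + vc[1] * (ops.Dy @ comp)
                   + vc[2] * (ops.Dz @ comp))
    if config.pressure_bc == "consistent":
        nu = fluid.nu
        flux = [fluid.rho * (nu * (ops.L @ vc[i]) - adv[i]) for i in range(3)]
        if ddot1 is not None:
            flux[0] -= fluid.rho * g.ravel(np.asarray(ddot1))
        if accel23 is not None:
            flux[1] -= fluid.rho * g.ravel(np.asarray(accel23[0]))
            flux[2] -= fluid.rho * g.ravel(np.asarray(accel23[1]))
        p_in = _gradient_matching_pressure(domain, flux, config)
    else:
        div = ops.Dx @ adv[0] + ops.Dy @ adv[1] + ops.Dz @ adv[2]
        rhs_full = -fluid.rho * div
        p_in = solve_neumann_poisson(
            domain, rhs_full, flux=None,
            rtol=config.linear_solver_tol, maxiter=config.pressure_maxiter,
        )
    return PressureField(g, domain.expand(p_in), frame_time=v.frame_time)


def _gradient_matching_pressure(
    domain: MaskedDomain,
    flux: list[np.ndarray],
    config: ReconstructionConfig,
) -> np.ndarray:
    """Discrete Helmholtz projection: the pressure whose face gradients
    best match the momentum-balance vector G in the weighted least-squares
    sense, min_p Σ_faces w ((p_j − p_i)/h − G·e)².  The normal equations
    are the finite-volume Neumann Laplacian; the face data impose the
    consistent Neumann condition weakly."""
    from .grid_ops import face_gradient_system

    key = "face_gradient"
    cached = domain._op_cache.get(key)
    if cached is None:
        A, w, ax, i_arr, j_arr = face_gradient_system(domain)
        N = (A.T @ sp.diags(w) @ A).tocsr()
        diag = N.diagonal()
        diag[diag == 0] = 1.0
        M = sp.diags(1.0 / diag)
        cached = (A, w, ax, i_arr, j_arr, N, M)
        domain._op_cache[key] = cached
    A, w, ax, i_arr, j_arr, N, M = cached
    if A.shape[0] == 0:
        return np.zeros(domain.n_inside)
    g_face = np.empty(A.shape[0])
    for axis in range(3):
        sel = ax == axis
        G_in = np.asarray(flux[axis]).ravel(order="F")[domain.inside_idx]
        g_face[sel] = 0.5 * (G_in[i_arr[sel]] + G_in[j_arr[sel]])
    b = A.T @ (w * g_face)
    b = b - b.mean()
    p_in, info = spla.cg(
        N, b, rtol=config.linear_solver_tol, atol=0.0,
        maxiter=config.pressure_maxiter, M=M,
    )
    if info != 0:
        res = np.linalg.norm(N @ p_in - b) / max(np.linalg.norm(b), 1e-300)
        raise RuntimeError(
            f"pressure solve did not converge (info={info}, "
            f"relative residual {res:.2e})"
        )
    return p_in - p_in.mean()


# ---------------------------------------------------------------------------
# Discrete system assembly
# ---------------------------------------------------------------------------


@dataclass
class AssembledSystem:
    """The 2n×2n Doppler/continuity system restricted to inside nodes.

    ``S`` already has its wall rows replaced by identity (Dirichlet) rows
    and its valve rows by one-sided n·∇ stencils; ``rhs(pressure)`` builds
    the matching right-hand side, whose only iteration-dependent part is
    the pressure-gradient term of the momentum row.
    """

    S: sp.csr_matrix
    f_const: np.ndarray          # boundary values filled in, pressure absent
    interior: np.ndarray         # bool per inside node: momentum row kept
    domain: MaskedDomain
    config: ReconstructionConfig
    _dxp_restrict: sp.csr_matrix = None
    _factor_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.domain.n_inside

    def rhs(self, pressure: PressureField | None) -> np.ndarray:
        f = self.f_const.copy()
        if pressure is not None:
            rho = self.config.fluid.rho
            dxp = self._dxp_restrict @ pressure.grid.ravel(pressure.p)
            f[: self.n][self.interior] -= (1.0 / rho) * dxp[self.interior]
        return f


def _compact(mat: sp.spmatrix, idx: np.ndarray) -> sp.csr_matrix:
    return mat.tocsr()[idx, :][:, idx]


def _boundary_rows(
    domain: MaskedDomain, wall_vals: np.ndarray, pos: np.ndarray,
    scheme: str,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Dirichlet/Neumann replacement rows for one component.

    Returns ``(R, g, is_bc)`` with ``R`` an n×n matrix holding identity
    rows at wall nodes and n·∇ stencils at valve nodes, ``g`` the matching
    data (wall values; zeros at valves), and ``is_bc`` marking which
    compact rows were replaced.
    """
    n = domain.n_inside
    wall_c = pos[domain.wall_idx]
    valve_c = pos[domain.valve_idx]
    is_bc = np.zeros(n, dtype=bool)
    is_bc[wall_c] = True
    is_bc[valve_c] = True
    g = np.zeros(n)
    g[wall_c] = wall_vals
    R = sp.coo_matrix(
        (np.ones(wall_c.size), (wall_c, wall_c)), shape=(n, n)
    ).tocsr()
    if valve_c.size:
        Nrows = normal_derivative_rows(domain, domain.valve_idx, scheme)
        Nc = Nrows[:, domain.inside_idx]
        lift = sp.coo_matrix(
            (np.ones(valve_c.size), (valve_c, np.arange(valve_c.size))),
            shape=(n, valve_c.size),
        ).tocsr()
        R = R + lift @ Nc
    return R, g, is_bc


def assemble_system(
    doppler: DopplerField,
    ddot: np.ndarray,
    domain: MaskedDomain,
    wall_values: WallValues,
    config: ReconstructionConfig,
) -> AssembledSystem:
    """Build S and the pressure-independent part of f for one frame."""
    ops = masked_operator_set(domain, config.scheme)
    g = domain.grid
    idx = domain.inside_idx
    n = idx.size
    pos = np.full(g.n_nodes, -1, dtype=np.int64)
    pos[idx] = np.arange(n)
    if not np.all(pos[wall_values.idx] >= 0):
        raise ValueError("wall values reference nodes outside the mask")
    if wall_values.idx.size != domain.wall_idx.size or not np.array_equal(
        np.sort(wall_values.idx), np.sort(domain.wall_idx)
    ):
        raise ValueError("wall values must cover exactly the wall nodes")
    order = np.argsort(wall_values.idx)
    widx = wall_values.idx[order]
    w2 = wall_values.v2[order]
    w3 = wall_values.v3[order]
    assert np.array_equal(widx, np.sort(domain.wall_idx))

    C = g.ravel(doppler.values)
    nu = config.fluid.nu
    dxC = ops.Dx @ C
    dyC = ops.Dy @ C
    dzC = ops.Dz @ C
    lapC = ops.L @ C
    ddot_c = g.ravel(np.asarray(ddot)) if ddot is not None else np.zeros_like(C)

    Cy = sp.diags(dyC[idx])
    Cz = sp.diags(dzC[idx])
    Dyc = _compact(ops.Dy, idx)
    Dzc = _compact(ops.Dz, idx)

    f1 = (-C * dxC - ddot_c + nu * lapC)[idx]
    f2 = (-dxC)[idx]

    # wall ordering consistent with _boundary_rows (sorted wall_idx)
    wall_sorted = np.sort(domain.wall_idx)
    R2, g2, is_bc = _boundary_rows(domain, w2, pos, config.scheme)
    R3, g3, _ = _boundary_rows(domain, w3, pos, config.scheme)
    del wall_sorted

    keep = sp.diags((~is_bc).astype(float))
    S = sp.bmat(
        [
            [keep @ Cy + R2, keep @ Cz],
            [keep @ Dyc, keep @ Dzc + R3],
        ],
        format="csr",
    )
    f1 = np.where(is_bc, g2, f1)
    f2 = np.where(is_bc, g3, f2)
    f_const = np.concatenate([f1, f2])
    dxp_restrict = ops.Dx.tocsr()[idx, :]
    return AssembledSystem(
        S=S,
        f_const=f_const,
        interior=~is_bc,
        domain=domain,
        config=config,
        _dxp_restrict=dxp_restrict,
    )


# ---------------------------------------------------------------------------
# Regularized minimization step
# ---------------------------------------------------------------------------


def effective_lambda2(system: AssembledSystem,
                      config: ReconstructionConfig) -> float:
    """Tikhonov weight actually applied to the normal equations.

    With ``regularization="scaled"`` (default) the dimensionless ``lambda2``
    is multiplied by the mean diagonal of SᵀS, making the damping relative
    to the operator's energy and independent of units and grid spacing —
    the penalty and data terms of the underlying functional otherwise carry
    incompatible physical units.  ``"absolute"`` applies ``lambda2`` as is.
    """
    if config.regularization == "absolute":
        return config.lambda2
    scale = system._factor_cache.get("sts_diag_mean")
    if scale is None:
        S = system.S
        scale = float(np.asarray(S.multiply(S).sum(axis=0)).mean())
        system._factor_cache["sts_diag_mean"] = scale
    return config.lambda2 * scale


def _solve_normal_equations(
    system: AssembledSystem, g: np.ndarray, config: ReconstructionConfig
) -> np.ndarray:
    """Solve (SᵀS + λ²I) δ = g, caching factorizations per λ²."""
    S = system.S
    lam2 = effective_lambda2(system, config)
    two_n = S.shape[0]
    mode = config.solver
    if mode == "auto":
        mode = "direct" if two_n <= config.direct_threshold else "cg"
    if mode == "direct":
        key = ("direct", lam2)
        fact = system._factor_cache.get(key)
        if fact is None:
            A = (S.T @ S + lam2 * sp.identity(two_n)).tocsc()
            fact = spla.splu(A)
            system._factor_cache[key] = fact
        return fact.solve(g)
    if mode == "cg":
        key = ("precond", lam2)
        M = system._factor_cache.get(key)
        StS_diag = np.asarray(S.multiply(S).sum(axis=0)).ravel() + lam2
        if M is None:
            M = sp.diags(1.0 / StS_diag)
            system._factor_cache[key] = M

        def mv(x):
            return S.T @ (S @ x) + lam2 * x

        A = spla.LinearOperator((two_n, two_n), matvec=mv)
        delta, info = spla.cg(
            A, g, rtol=config.linear_solver_tol, atol=0.0, M=M,
            maxiter=50 * two_n,
        )
        if info != 0:
            raise RuntimeError(
                f"normal-equation CG failed (info={info}); consider a larger "
                f"lambda2 than {lam2:g} or the direct solver"
            )
        return delta
    raise ValueError(f"unknown solver mode {config.solver!r}")


def minimize_step(
    system: AssembledSystem,
    v_prev: np.ndarray,
    config: ReconstructionConfig | None = None,
    pressure: PressureField | None = None,
    f: np.ndarray | None = None,
) -> np.ndarray:
    """One Tikhonov-regularized correction
    v_new = v_prev + (SᵀS + λ²I)⁻¹ Sᵀ (f − S v_prev)."""
    config = config or system.config
    if f is None:
        f = system.rhs(pressure)
    r = f - system.S @ v_prev
    delta = _solve_normal_equations(system, system.S.T @ r, config)
    return v_prev + delta


# ---------------------------------------------------------------------------
# Vorticity-constrained initial guess
# ---------------------------------------------------------------------------


def initial_guess(
    doppler: DopplerField,
    domain: MaskedDomain,
    wall_values: WallValues,
    config: ReconstructionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Elliptic initial guess assuming the vorticity component along
    d = (d1, d2, 0) vanishes.

    Combining d·ω = 0 (with v1 = 𝒟) with incompressibility gives, after
    cross-differentiation, the block-triangular elliptic system

        (d1·Lyz − d2·DxDy) v3 = −(d2·DyDz + d1·DzDx) 𝒟
         d1·Lyz v2            =  (d2·Lzz − d1·DxDy) 𝒟 − d2·DzDx v3

    solved with the wall Dirichlet / valve Neumann rows substituted.
    Returns full-grid (v2, v3) arrays, zero outside the mask.
    """
    d1, d2 = config.d_vector
    if d1 == 0:
        raise ValueError("d_vector[0] = 0 makes the v2 operator singular")
    scale = float(np.hypot(d1, d2))
    d1, d2 = d1 / scale, d2 / scale
    ops = masked_operator_set(domain, config.scheme)
    g = domain.grid
    idx = domain.inside_idx
    n = idx.size
    pos = np.full(g.n_nodes, -1, dtype=np.int64)
    pos[idx] = np.arange(n)
    Dxc = _compact(ops.Dx, idx)
    Dyc = _compact(ops.Dy, idx)
    Dzc = _compact(ops.Dz, idx)
    Lyzc = _compact(ops.Lyz, idx)
    Lzzc = _compact(ops.Lzz, idx)
    Cc = g.ravel(doppler.values)[idx]

    order = np.argsort(wall_values.idx)
    w2 = wall_values.v2[order]
    w3 = wall_values.v3[order]

    A3 = (d1 * Lyzc - d2 * (Dxc @ Dyc)).tocsr()
    b3 = -(d2 * (Dyc @ Dzc) + d1 * (Dzc @ Dxc)) @ Cc
    R3, g3, is_bc = _boundary_rows(domain, w3, pos, config.scheme)
    keep = sp.diags((~is_bc).astype(float))
    A3 = (keep @ A3 + R3).tocsr()
    b3 = np.where(is_bc, g3, b3)
    v3 = spla.spsolve(A3.tocsc(), b3)

    A2 = (d1 * Lyzc).tocsr()
    b2 = (d2 * Lzzc - d1 * (Dxc @ Dyc)) @ Cc - d2 * (Dzc @ Dxc) @ v3
    R2, g2, _ = _boundary_rows(domain, w2, pos, config.scheme)
    A2 = (keep @ A2 + R2).tocsr()
    b2 = np.where(is_bc, g2, b2)
    v2 = spla.spsolve(A2.tocsc(), b2)

    if not (np.all(np.isfinite(v2)) and np.all(np.isfinite(v3))):
        raise RuntimeError("initial-guess elliptic solve produced non-finite "
                           "values (singular operator?)")
    return domain.expand(v2), domain.expand(v3)


def estimate_d_vector(
    doppler: DopplerField,
    domain: MaskedDomain,
    wall_values: WallValues,
    config: ReconstructionConfig,
) -> tuple[float, float]:
    """Heuristic for d: least-squares direction minimizing d·ω⁰ using the
    vorticity of a first initial guess computed with d = (1, 0)."""
    from .metrics import vorticity

    base = replace(config, d_vector=(1.0, 0.0))
    v2, v3 = initial_guess(doppler, domain, wall_values, base)
    vf = VelocityField(
        domain.grid, np.stack([doppler.values, v2, v3]),
        frame_time=doppler.frame_time,
    )
    w = vorticity(vf, domain, config.scheme)
    m = domain.inside
    W = np.column_stack([w.v[0][m], w.v[1][m]])
    G = W.T @ W
    vals, vecs = np.linalg.eigh(G)
    d = vecs[:, 0]
    if abs(d[0]) < 1e-6:
        return (1.0, 0.0)
    if d[0] < 0:
        d = -d
    return (float(d[0]), float(d[1]))


# ---------------------------------------------------------------------------
# Frame reconstruction loop
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    velocity: VelocityField
    pressure: PressureField
    history: list[float]
    converged: bool
    n_iter: int
    initial: tuple[np.ndarray, np.ndarray]


def reconstruct_frame(
    series: list[DopplerField],
    frame_index: int,
    domain: MaskedDomain,
    wall_values: WallValues,
    config: ReconstructionConfig | None = None,
    accel23: tuple[np.ndarray, np.ndarray] | None = None,
) -> ReconstructionResult:
    """Reconstruct (v2, v3, p) for one frame of a Doppler time series.

    Alternates the pressure Poisson solve (from the current iterate), the
    right-hand-side update and the regularized correction until the
    relative update ‖v^{n+1}−v^n‖/‖v^n‖ drops below ``stop_tol`` (absolute
    norm when the iterate is zero) or ``max_iter`` is reached; in the
    latter case the fields are still returned with ``converged=False``.
    """
    config = config or ReconstructionConfig()
    doppler = series[frame_index]
    ddots = doppler_time_derivative(series)
    ddot = ddots[frame_index]
    if config.estimate_d:
        d = estimate_d_vector(doppler, domain, wall_values, config)
        config = replace(config, d_vector=d)
    system = assemble_system(doppler, ddot, domain, wall_values, config)
    n = system.n
    g = domain.grid
    if config.init_mode == "vorticity":
        v2_0, v3_0 = initial_guess(doppler, domain, wall_values, config)
    else:
        v2_0 = np.zeros(g.shape)
        v3_0 = np.zeros(g.shape)
    v = np.concatenate([domain.compact(v2_0), domain.compact(v3_0)])
    history: list[float] = []
    converged = False
    pressure = None
    for it in range(config.max_iter):
        if pressure is None or config.pressure_update == "every_iteration":
            vel = VelocityField(
                g,
                np.stack(
                    [doppler.values, domain.expand(v[:n]), domain.expand(v[n:])]
                ),
                frame_time=doppler.frame_time,
            )
            pressure = solve_pressure(
                vel, domain, config.fluid, config, ddot1=ddot,
                accel23=accel23,
            )
        v_new = minimize_step(system, v, config, pressure=pressure)
        norm = np.linalg.norm(v)
        diff = np.linalg.norm(v_new - v)
        ratio = diff / norm if norm > 0 else diff
        history.append(float(ratio))
        v = v_new
        if ratio < config.stop_tol:
            converged = True
            break
    velocity = VelocityField(
        g,
        np.stack([doppler.values, domain.expand(v[:n]), domain.expand(v[n:])]),
        frame_time=doppler.frame_time,
    )
    return ReconstructionResult(
        velocity=velocity,
        pressure=pressure,
        history=history,
        converged=converged,
        n_iter=len(history),
        initial=(v2_0, v3_0),
    )


def reconstruct_cycle(
    series: list[DopplerField],
    domains: list[MaskedDomain],
    wall_values: list[WallValues],
    config: ReconstructionConfig | None = None,
) -> list[ReconstructionResult]:
    """Reconstruct every frame of a cardiac cycle with time coupling.

    The pressure datum requires the full local acceleration ∂v/∂t, of which
    only the beam component is measured.  The first pass reconstructs each
    frame with the transverse acceleration set to zero; each further pass
    (``config.time_coupling_passes`` in total) re-estimates ∂v₂/∂t and
    ∂v₃/∂t by periodic central differences across the previous pass's
    reconstructions and repeats the frame solves with the completed
    pressure datum.
    """
    config = config or ReconstructionConfig()
    n = len(series)
    if not (len(domains) == len(wall_values) == n):
        raise ValueError("series, domains and wall values must align")
    results = [
        reconstruct_frame(series, k, domains[k], wall_values[k], config)
        for k in range(n)
    ]
    dt = series[0].frame_dt
    for _ in range(max(config.time_coupling_passes - 1, 0)):
        v2s = [r.velocity.v2 for r in results]
        v3s = [r.velocity.v3 for r in results]
        results = []
        for k in range(n):
            a2 = (v2s[(k + 1) % n] - v2s[(k - 1) % n]) / (2 * dt)
            a3 = (v3s[(k + 1) % n] - v3s[(k - 1) % n]) / (2 * dt)
            results.append(
                reconstruct_frame(
                    series, k, domains[k], wall_values[k], config,
                    accel23=(a2, a3),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Dual-beam closed form
# ---------------------------------------------------------------------------


def dual_beam_solve(
    doppler1: DopplerField,
    doppler2: DopplerField,
    pressure: PressureField,
    domain: MaskedDomain,
    fluid: FluidProperties,
    ddot1: np.ndarray | None = None,
    ddot2: np.ndarray | None = None,
    config: ReconstructionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise two-beam inversion (no boundary data required).

    With the primary beam along x and a second, linearly independent beam
    a₂, the in-plane Doppler gradients form a 2×2 matrix per node whose
    inversion yields (v2, v3) explicitly.  Near-singular nodes (relative
    |det| below ``det_rel_threshold``) are solved with a Tikhonov
    pseudo-inverse; if their fraction exceeds ``max_singular_fraction``
    the inversion is rejected.  Returns full-grid (v2, v3, singular_mask).
    """
    config = config or ReconstructionConfig()
    a1 = doppler1.beam
    a2 = doppler2.beam
    if np.linalg.norm(a1 - np.array([1.0, 0.0, 0.0])) > 1e-8:
        raise ValueError("the primary beam must be the x unit vector")
    if np.linalg.norm(np.cross(a1, a2)) < 1e-8:
        raise ValueError("beams must be linearly independent")
    ops = masked_operator_set(domain, config.scheme)
    g = domain.grid
    idx = domain.inside_idx
    nu = fluid.nu
    C1 = g.ravel(doppler1.values)
    C2 = g.ravel(doppler2.values)
    p = g.ravel(pressure.p)
    d1t = g.ravel(np.asarray(ddot1)) if ddot1 is not None else 0.0
    d2t = g.ravel(np.asarray(ddot2)) if ddot2 is not None else 0.0
    a2gradp = a2[0] * (ops.Dx @ p) + a2[1] * (ops.Dy @ p) + a2[2] * (ops.Dz @ p)
    r1 = (-C1 * (ops.Dx @ C1) - d1t + nu * (ops.L @ C1)
          - (1.0 / fluid.rho) * (ops.Dx @ p))[idx]
    r2 = (-C1 * (ops.Dx @ C2) - d2t + nu * (ops.L @ C2)
          - (1.0 / fluid.rho) * a2gradp)[idx]
    m11 = (ops.Dy @ C1)[idx]
    m12 = (ops.Dz @ C1)[idx]
    m21 = (ops.Dy @ C2)[idx]
    m22 = (ops.Dz @ C2)[idx]
    det = m11 * m22 - m12 * m21
    scale = np.percentile(np.abs(det), 90)
    if scale == 0.0:
        raise RuntimeError("Doppler gradient matrix is singular everywhere")
    singular = np.abs(det) < config.det_rel_threshold * scale
    frac = singular.mean()
    if frac > config.max_singular_fraction:
        raise RuntimeError(
            f"{frac:.0%} of nodes have a near-singular beam-gradient matrix"
        )
    v2 = np.empty_like(det)
    v3 = np.empty_like(det)
    ok = ~singular
    v2[ok] = (m22[ok] * r1[ok] - m12[ok] * r2[ok]) / det[ok]
    v3[ok] = (-m21[ok] * r1[ok] + m11[ok] * r2[ok]) / det[ok]
    if singular.any():
        tau = (config.det_rel_threshold * scale) ** 2
        s = singular
        # 2x2 Tikhonov pseudo-inverse (MᵀM + τI)⁻¹ Mᵀ r
        g11 = m11[s] ** 2 + m21[s] ** 2 + tau
        g12 = m11[s] * m12[s] + m21[s] * m22[s]
        g22 = m12[s] ** 2 + m22[s] ** 2 + tau
        h1 = m11[s] * r1[s] + m21[s] * r2[s]
        h2 = m12[s] * r1[s] + m22[s] * r2[s]
        gdet = g11 * g22 - g12**2
        v2[s] = (g22 * h1 - g12 * h2) / gdet
        v3[s] = (-g12 * h1 + g11 * h2) / gdet
    return (
        domain.expand(v2),
        domain.expand(v3),
        domain.expand(singular.astype(float)).astype(bool),
    )
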