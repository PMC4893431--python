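"""Synthetic ground-truth flows in a moving left-ventricle-like domain.

This module stands in for a fluid-structure-interaction forward simulation:
it produces time series of (a) analytically divergence-free 3-D velocity
fields, (b) ellipsoidal LV-like masks with two valve openings whose volume
follows a prescribed cardiac cycle, (c) beam-projected Doppler scalar data,
and (d) wall boundary velocities — everything the inverse reconstruction
needs, with the ground truth known exactly.

The default phantom is a Hill spherical vortex whose axis is tilted with
respect to the ultrasound beam (x) axis, mimicking the oblique transmitral
inflow jet; its interior velocity is a polynomial, so it is divergence-free
to machine precision even discretely.  A genuinely trigonometric field
(``taylor_green_3d``), a vortex-ring/jet field built from a vector
potential (``inflow_jet_with_ring``), and a decaying Beltrami flow that
satisfies the full unsteady Navier-Stokes equations exactly
(``abc_beltrami``) are also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .fields import DopplerField, VelocityField
from .grid_ops import MaskedDomain, StructuredGrid

__all__ = [
    "FluidProperties",
    "PhantomSpec",
    "WallValues",
    "generate_flow_series",
    "project_doppler",
    "wall_speed",
    "wall_boundary_values",
    "exact_wall_values",
    "volume_schedule",
    "ellipsoid_area",
    "default_grid",
    "evaluate_phantom_pressure",
    "hill_vortex_velocity",
    "hill_vortex_pressure",
    "taylor_green_velocity",
    "abc_beltrami_velocity",
    "abc_beltrami_pressure",
    "SpeckleMotion",
    "make_speckle_sequence",
]

PHANTOM_KINDS = (
    "hill_vortex",
    "taylor_green_3d",
    "inflow_jet_with_ring",
    "abc_beltrami",
)


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (kg/m³) and dynamic viscosity (Pa·s)."""

    rho: float = 1050.0
    mu: float = 0.00316

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m²/s)."""
        return self.mu / self.rho


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of one synthetic cardiac-cycle experiment.

    Geometry is an ellipsoid with semi-axes ``semi_axes`` (metres, long
    axis along x) whose short axes scale with the volume curve; two pipe
    extensions with elliptic (mitral) and circular (aortic) cross-sections
    attach at the basal (+x) cap and end in valve-labelled caps.
    """

    kind: str = "hill_vortex"
    peak_speed: float = 0.5            # m/s, cycle-peak flow amplitude
    amplitude_modulation: float = 0.0  # relative sinusoidal modulation
    drift_amplitude: float = 0.008     # m, oscillatory vortex translation
    semi_axes: tuple[float, float, float] = (0.045, 0.0252, 0.0252)  # at EDV
    mitral_center: tuple[float, float] = (0.011, 0.0)   # (y, z) on basal cap
    mitral_radii: tuple[float, float] = (0.0115, 0.009)  # elliptic (ry, rz)
    aortic_center: tuple[float, float] = (-0.011, 0.0)
    aortic_radius: float = 0.009
    pipe_length: float = 0.012         # m beyond the basal cap
    heart_rate: float = 60.0           # beats per minute
    diastole_fraction: float = 0.6
    stroke_volume: float = 70e-6       # m³
    end_diastolic_volume: float = 120e-6  # m³
    n_frames: int = 10
    vortex_axis_tilt: float = math.radians(25.0)  # tilt of flow axis in x-y
    doppler_noise: float = 0.0         # rms noise (m/s) added to projections
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not 0.0 < self.diastole_fraction < 1.0:
            raise ValueError("diastole fraction must lie in (0, 1)")
        if self.stroke_volume >= self.end_diastolic_volume:
            raise ValueError("stroke volume must be below end-diastolic volume")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames for time derivatives")

    @property
    def period(self) -> float:
        """Cardiac period T (s)."""
        return 60.0 / self.heart_rate

    @property
    def frame_times(self) -> np.ndarray:
        """Frame centres ((m+1/2)·T/n over the cycle, matching t/T rows)."""
        return (np.arange(self.n_frames) + 0.5) * self.period / self.n_frames

    @property
    def frame_dt(self) -> float:
        return self.period / self.n_frames

    def amplitude(self, t) -> np.ndarray:
        """Flow speed scale at time t (m/s).

        A nonzero ``amplitude_modulation`` makes the field pulsate; note
        that a pulsating vortex is not an exact Navier-Stokes solution (the
        rotational part of ∂v/∂t has no absorbing pressure), so modulation
        is an optional stress condition, off by default.  The default
        cardiac-cycle dynamics come from ``drift_amplitude`` instead: a
        periodic translation of the vortex along its axis, which is an
        exact (Galilean-boosted, accelerating-frame) Navier-Stokes solution
        with the inertial force absorbed in the pressure.
        """
        m = self.amplitude_modulation
        return self.peak_speed * (
            1.0 + m * np.sin(2 * np.pi * np.asarray(t) / self.period)
        ) / (1.0 + m)

    def vortex_axis(self) -> np.ndarray:
        return np.array(
            [math.cos(self.vortex_axis_tilt), math.sin(self.vortex_axis_tilt), 0.0]
        )

    def drift_offset(self, t) -> np.ndarray:
        """Vortex-centre displacement x_c(t) (m)."""
        s = np.sin(2 * np.pi * np.asarray(t) / self.period)
        return self.drift_amplitude * s * self.vortex_axis()

    def drift_velocity(self, t) -> np.ndarray:
        """Frame translation speed dx_c/dt (m/s)."""
        w = 2 * np.pi / self.period
        return self.drift_amplitude * w * np.cos(w * np.asarray(t)) * \
            self.vortex_axis()

    def drift_acceleration(self, t) -> np.ndarray:
        w = 2 * np.pi / self.period
        return -self.drift_amplitude * w**2 * np.sin(w * np.asarray(t)) * \
            self.vortex_axis()


# ---------------------------------------------------------------------------
# Cardiac volume / area schedules
# ---------------------------------------------------------------------------


def volume_schedule(spec: PhantomSpec, t) -> np.ndarray:
    """Smooth periodic LV volume V(t): filling for the diastolic fraction
    of the cycle, then ejection; C¹ and periodic, amplitude = stroke volume."""
    t = np.asarray(t, dtype=float) % spec.period
    Td = spec.diastole_fraction * spec.period
    Ts = spec.period - Td
    esv = spec.end_diastolic_volume - spec.stroke_volume
    fill = esv + spec.stroke_volume * 0.5 * (1 - np.cos(np.pi * t / Td))
    eject = esv + spec.stroke_volume * 0.5 * (1 + np.cos(np.pi * (t - Td) / Ts))
    return np.where(t < Td, fill, eject)


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation of the ellipsoid surface area (p = 1.6075)."""
    p = 1.6075
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


def _semi_axes_at(spec: PhantomSpec, t: float) -> tuple[float, float, float]:
    """Short semi-axes scale as sqrt(V/EDV); the long axis is kept fixed."""
    a, b0, c0 = spec.semi_axes
    s = math.sqrt(float(volume_schedule(spec, t)) / spec.end_diastolic_volume)
    return a, b0 * s, c0 * s


# ---------------------------------------------------------------------------
# Analytic divergence-free flows
# ---------------------------------------------------------------------------


def hill_vortex_velocity(
    points: np.ndarray,
    radius: float,
    speed: float,
    axis: np.ndarray,
    center: np.ndarray,
) -> np.ndarray:
    """Interior Hill spherical-vortex velocity at ``points`` (n, 3).

    The classical interior solution (a degree-2 polynomial, hence exactly
    divergence-free) with vortex axis ``axis`` and sphere radius ``radius``;
    evaluated everywhere, not only inside the sphere.
    """
    e = np.asarray(axis, float)
    e = e / np.linalg.norm(e)
    r = np.asarray(points, float) - np.asarray(center, float)
    xi = r @ e
    rho_vec = r - np.outer(xi, e)
    rho2 = (rho_vec**2).sum(axis=1)
    u_ax = 1.5 * speed * (1.0 - (2 * rho2 + xi**2) / radius**2)
    return np.outer(u_ax, e) + (1.5 * speed / radius**2) * xi[:, None] * rho_vec


def hill_vortex_pressure(
    points: np.ndarray,
    radius: float,
    speed: float,
    axis: np.ndarray,
    center: np.ndarray,
    fluid: "FluidProperties",
) -> np.ndarray:
    """Exact Navier-Stokes pressure of the interior Hill vortex (Pa).

    The steady advection term of the interior polynomial field is a perfect
    gradient and its Laplacian is a constant vector, so the field solves
    the steady Navier-Stokes equations with the polynomial pressure
    returned here (arbitrary additive constant)."""
    e = np.asarray(axis, float)
    e = e / np.linalg.norm(e)
    r = np.asarray(points, float) - np.asarray(center, float)
    xi = (r @ e) / radius
    rho2 = ((r - np.outer(r @ e, e)) ** 2).sum(axis=1) / radius**2
    phi = 9.0 / 8.0 * (-(xi**4) + 2 * xi**2 + rho2**2 - rho2)
    visc = -15.0 * fluid.nu * speed * xi / radius
    return fluid.rho * (speed**2 * phi + visc)


def taylor_green_velocity(
    points: np.ndarray, k: float, speed: float, center: np.ndarray
) -> np.ndarray:
    """3-D Taylor-Green-type trigonometric divergence-free field."""
    r = np.asarray(points, float) - np.asarray(center, float)
    X, Y, Z = (k * r[:, i] for i in range(3))
    v1 = np.sin(X) * np.cos(Y) * np.cos(Z)
    v2 = -0.5 * np.cos(X) * np.sin(Y) * np.cos(Z)
    v3 = -0.5 * np.cos(X) * np.cos(Y) * np.sin(Z)
    return speed * np.column_stack([v1, v2, v3])


def abc_beltrami_velocity(
    points: np.ndarray,
    t: float,
    k: float,
    speed: float,
    nu: float,
    abc: tuple[float, float, float] = (1.0, 0.7, 0.4),
) -> np.ndarray:
    """Decaying ABC (Beltrami) flow — an exact unsteady Navier-Stokes
    solution with pressure ``-ρ|v|²/2`` (up to a constant)."""
    A, B, C = abc
    r = np.asarray(points, float)
    X, Y, Z = (k * r[:, i] for i in range(3))
    decay = math.exp(-nu * k**2 * t)
    v1 = A * np.sin(Z) + C * np.cos(Y)
    v2 = B * np.sin(X) + A * np.cos(Z)
    v3 = C * np.sin(Y) + B * np.cos(X)
    return speed * decay * np.column_stack([v1, v2, v3])


def abc_beltrami_pressure(
    points: np.ndarray,
    t: float,
    k: float,
    speed: float,
    nu: float,
    rho: float,
    abc: tuple[float, float, float] = (1.0, 0.7, 0.4),
) -> np.ndarray:
    v = abc_beltrami_velocity(points, t, k, speed, nu, abc)
    return -0.5 * rho * (v**2).sum(axis=1)


@lru_cache(maxsize=8)
def _jet_ring_lambdified(sigma: float, ell: float):
    """Curl of a smooth azimuthal vector potential about the x-axis,
    derived symbolically once and lambdified (exactly divergence-free)."""
    import sympy as sym

    x, y, z = sym.symbols("x y z", real=True)
    g = sym.exp(-((y**2 + z**2) / sigma**2 + x**2 / ell**2))
    Ax, Ay, Az = sym.Integer(0), -z * g, y * g
    v1 = sym.diff(Az, y) - sym.diff(Ay, z)
    v2 = sym.diff(Ax, z) - sym.diff(Az, x)
    v3 = sym.diff(Ay, x) - sym.diff(Ax, y)
    return sym.lambdify((x, y, z), (v1, v2, v3), "numpy")


def _jet_ring_velocity(
    points: np.ndarray, spec: PhantomSpec, speed: float
) -> np.ndarray:
    """Localized jet-with-vortex-ring field through the mitral opening."""
    a, b0, _ = spec.semi_axes
    sigma = 0.8 * spec.mitral_radii[0]
    ell = 0.5 * a
    fn = _jet_ring_lambdified(sigma, ell)
    r = np.asarray(points, float).copy()
    r[:, 0] -= 0.3 * a           # ring centred below the base
    r[:, 1] -= spec.mitral_center[0]
    r[:, 2] -= spec.mitral_center[1]
    v = np.column_stack(fn(r[:, 0], r[:, 1], r[:, 2]))
    # resolution-independent normalization from a fixed coarse sample
    key = (sigma, ell)
    scale = _jet_ring_scale(key)
    return speed / scale * v


@lru_cache(maxsize=8)
def _jet_ring_scale(key: tuple[float, float]) -> float:
    sigma, ell = key
    fn = _jet_ring_lambdified(sigma, ell)
    s = np.linspace(-2 * ell, 2 * ell, 25)
    X, Y, Z = np.meshgrid(s, s, s, indexing="ij")
    v = np.stack(fn(X.ravel(), Y.ravel(), Z.ravel()))
    return float(np.sqrt((v**2).sum(axis=0)).max())


def _evaluate_flow(spec: PhantomSpec, points: np.ndarray, t: float,
                   fluid: FluidProperties | None = None) -> np.ndarray:
    amp = float(spec.amplitude(t))
    if amp == 0.0:
        return np.zeros_like(np.asarray(points, dtype=float))
    a, b0, c0 = spec.semi_axes
    center = np.zeros(3)
    if spec.kind == "hill_vortex":
        # the vortex sphere spans the chamber (radius = long semi-axis) so
        # the interior polynomial stays within physiologic speeds in the
        # mask; the centre oscillates along the tilted axis (exact
        # accelerating-frame Navier-Stokes solution)
        xc = spec.drift_offset(t)
        c = spec.drift_velocity(t)
        return hill_vortex_velocity(
            points, a, amp, spec.vortex_axis(), center + xc
        ) + c
    if spec.kind == "taylor_green_3d":
        return taylor_green_velocity(points, np.pi / (2 * b0), amp, center)
    if spec.kind == "inflow_jet_with_ring":
        return _jet_ring_velocity(points, spec, amp)
    if spec.kind == "abc_beltrami":
        nu = (fluid or FluidProperties()).nu
        return abc_beltrami_velocity(points, t, np.pi / (2 * b0), amp, nu)
    raise ValueError(spec.kind)


def evaluate_phantom_pressure(
    spec: PhantomSpec, points: np.ndarray, t: float,
    fluid: FluidProperties | None = None,
) -> np.ndarray:
    """Exact pressure of the phantom flow where known (Pa).

    Available for the drifting Hill vortex (polynomial pressure plus the
    accelerating-frame term −ρ ẍ_c·x) and the Beltrami flow (−ρ|v|²/2).
    """
    fluid = fluid or FluidProperties()
    amp = float(spec.amplitude(t))
    if amp == 0.0:
        return np.zeros(np.asarray(points).shape[0])
    a, b0, _ = spec.semi_axes
    if spec.kind == "hill_vortex":
        if spec.amplitude_modulation != 0.0:
            raise ValueError(
                "a pulsating Hill vortex has no exact pressure")
        xc = spec.drift_offset(t)
        acc = spec.drift_acceleration(t)
        p = hill_vortex_pressure(
            points, a, amp, spec.vortex_axis(), xc, fluid
        )
        return p - fluid.rho * (np.asarray(points) @ acc)
    if spec.kind == "abc_beltrami":
        return abc_beltrami_pressure(
            points, t, np.pi / (2 * b0), amp, fluid.nu, fluid.rho
        )
    raise ValueError(f"no exact pressure for phantom kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Masks and frame generation
# ---------------------------------------------------------------------------


def _pipe_extent(spec: PhantomSpec) -> float:
    return spec.semi_axes[0] + spec.pipe_length


def default_grid(spec: PhantomSpec, n: int = 32, margin_cells: int = 3
                 ) -> StructuredGrid:
    """Cubic n³ grid enclosing the phantom with the given margin."""
    a, b0, c0 = spec.semi_axes
    xmax = _pipe_extent(spec)
    half = max(a, xmax, b0, c0)
    # symmetric cube around the origin covering [-half, xmax] in x
    lo, hi = -a, xmax
    side = max(hi - lo, 2 * b0, 2 * c0)
    h = side / (n - 1 - 2 * margin_cells)
    length = h * (n - 1)
    cx = 0.5 * (lo + hi)
    origin = (cx - length / 2, -length / 2, -length / 2)
    return StructuredGrid(n, n, n, h, origin)


def _frame_mask(spec: PhantomSpec, grid: StructuredGrid, t: float) -> np.ndarray:
    a, b, c = _semi_axes_at(spec, t)
    X, Y, Z = grid.meshgrid()
    inside = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    xmax = _pipe_extent(spec)
    in_pipe_x = (X >= 0.0) & (X <= xmax)
    my, mz = spec.mitral_center
    ry, rz = spec.mitral_radii
    mitral = ((Y - my) / ry) ** 2 + ((Z - mz) / rz) ** 2 <= 1.0
    ay, az = spec.aortic_center
    aortic = (Y - ay) ** 2 + (Z - az) ** 2 <= spec.aortic_radius**2
    inside |= in_pipe_x & (mitral | aortic)
    return inside


def _valve_predicate(spec: PhantomSpec, grid: StructuredGrid):
    xmax = _pipe_extent(spec)
    my, mz = spec.mitral_center
    ry, rz = spec.mitral_radii
    ay, az = spec.aortic_center

    def pred(points: np.ndarray) -> np.ndarray:
        x, y, z = points.T
        cap = x > xmax - 1.5 * grid.h
        mitral = ((y - my) / ry) ** 2 + ((z - mz) / rz) ** 2 <= 1.0
        aortic = (y - ay) ** 2 + (z - az) ** 2 <= spec.aortic_radius**2
        return cap & (mitral | aortic)

    return pred


def generate_flow_series(
    spec: PhantomSpec,
    grid: StructuredGrid,
    fluid: FluidProperties | None = None,
) -> list[tuple[MaskedDomain, VelocityField]]:
    """Generate ``n_frames`` (mask, ground-truth velocity) pairs.

    Velocities are evaluated on the full grid (so time derivatives near the
    moving boundary are well defined); masks carry wall/valve labels and
    outward normals.  Raises if the phantom does not fit in the grid with a
    two-cell margin.
    """
    _check_fit(spec, grid)
    pred = _valve_predicate(spec, grid)
    pts = grid.points()
    frames = []
    for t in spec.frame_times:
        inside = _frame_mask(spec, grid, t)
        dom = MaskedDomain.from_mask(grid, inside, valve_predicate=pred)
        v = _evaluate_flow(spec, pts, float(t), fluid)
        varr = np.stack(
            [grid.unravel(v[:, i]) for i in range(3)]
        )
        frames.append((dom, VelocityField(grid, varr, frame_time=float(t))))
    return frames


def _check_fit(spec: PhantomSpec, grid: StructuredGrid) -> None:
    a, b0, c0 = spec.semi_axes
    m = 2 * grid.h
    x, y, z = grid.axes()
    if (
        x[0] > -a - m or x[-1] < _pipe_extent(spec) + m
        or y[0] > -b0 - m or y[-1] < b0 + m
        or z[0] > -c0 - m or z[-1] < c0 + m
    ):
        raise ValueError(
            "phantom domain does not fit inside the grid with a 2-cell margin"
        )


def project_doppler(
    v: VelocityField,
    beam: np.ndarray,
    frame_dt: float = 0.0,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DopplerField:
    """Beam projection 𝒟 = a·v, optionally with additive Gaussian noise."""
    beam = np.asarray(beam, dtype=float)
    if abs(np.linalg.norm(beam) - 1.0) > 1e-8:
        raise ValueError("beam direction must be a unit vector")
    values = np.tensordot(beam, v.v, axes=(0, 0))
    if noise > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        values = values + noise * rng.standard_normal(values.shape)
    return DopplerField(
        v.grid, values, beam=beam, frame_time=v.frame_time, frame_dt=frame_dt
    )


# ---------------------------------------------------------------------------
# Wall boundary data
# ---------------------------------------------------------------------------


def wall_speed(volume_series: np.ndarray, area_series: np.ndarray,
               dt: float) -> np.ndarray:
    """Average outward boundary speed v̄(t) = (dV/dt)/A(t).

    dV/dt by central differences with periodic closure across the cycle.
    """
    V = np.asarray(volume_series, dtype=float)
    A = np.asarray(area_series, dtype=float)
    if V.size < 3:
        raise ValueError("need at least 3 frames")
    if np.any(A <= 0):
        raise ValueError("areas must be positive")
    dVdt = (np.roll(V, -1) - np.roll(V, 1)) / (2.0 * dt)
    return dVdt / A


@dataclass
class WallValues:
    """Dirichlet data (v2, v3) at wall boundary nodes (flat indices)."""

    idx: np.ndarray
    v2: np.ndarray
    v3: np.ndarray


def wall_boundary_values(domain: MaskedDomain, vbar: float) -> WallValues:
    """Wall velocity v̄·n per wall node; returns its y and z components.

    Valve nodes are not included — they carry the homogeneous Neumann
    condition in the reconstruction instead.
    """
    idx = domain.wall_idx
    n = domain.wall_normals()
    return WallValues(idx=idx, v2=vbar * n[:, 1], v3=vbar * n[:, 2])


def exact_wall_values(domain: MaskedDomain, v: VelocityField) -> WallValues:
    """Ground-truth wall Dirichlet data sampled from a phantom field."""
    idx = domain.wall_idx
    return WallValues(
        idx=idx,
        v2=v.grid.ravel(v.v2)[idx],
        v3=v.grid.ravel(v.v3)[idx],
    )


# ---------------------------------------------------------------------------
# Speckle image sequences for tracking tests
# ---------------------------------------------------------------------------


@dataclass
class SpeckleMotion:
    """Per-frame affine maps x_t = M_t x + c_t from reference coordinates.

    ``maps[t]`` is a tuple (M, c); frame 0 is the identity.  Points are in
    (x, y) = (column, row) pixel coordinates.
    """

    maps: list[tuple[np.ndarray, np.ndarray]]

    @classmethod
    def translation(cls, v: tuple[float, float], n_frames: int) -> "SpeckleMotion":
        v = np.asarray(v, dtype=float)
        I = np.eye(2)
        return cls([(I.copy(), t * v) for t in range(n_frames)])

    @classmethod
    def affine(cls, A: np.ndarray, b: tuple[float, float], n_frames: int,
               center: tuple[float, float] = (0.0, 0.0)) -> "SpeckleMotion":
        """Repeated application of the affine step ``x -> A(x-c) + c + b``."""
        A = np.asarray(A, dtype=float)
        b = np.asarray(b, dtype=float)
        c = np.asarray(center, dtype=float)
        maps = [(np.eye(2), np.zeros(2))]
        for _ in range(1, n_frames):
            M, d = maps[-1]
            maps.append((A @ M, A @ (d - c) + c + b))
        return cls(maps)

    def apply(self, t: int, points: np.ndarray) -> np.ndarray:
        M, c = self.maps[t]
        return points @ M.T + c


def make_speckle_sequence(
    motion: SpeckleMotion,
    image_size: tuple[int, int],
    points0: np.ndarray,
    noise: float = 0.0,
    seed: int = 0,
    correlation_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Speckle-textured image sequence advected by ``motion``.

    Returns ``(frames, tracks)`` with ``frames`` of shape (T, H, W) and
    ``tracks`` the ground-truth point positions (T, n, 2) in (x, y) pixel
    coordinates.  The texture is multiplicative: a strictly positive
    reference pattern warped by each frame's affine map, times a per-frame
    ``(1 + noise·η)`` field.  Raises if any ground-truth point leaves the
    image.
    """
    H, W = image_size
    rng = np.random.default_rng(seed)
    pad = 16
    base = rng.standard_normal((H + 2 * pad, W + 2 * pad))
    base = gaussian_filter(base, correlation_px)
    base = 1.0 + 0.5 * base / np.abs(base).max()
    n_frames = len(motion.maps)
    pts0 = np.asarray(points0, dtype=float)
    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    xy = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    frames = np.empty((n_frames, H, W))
    tracks = np.empty((n_frames, pts0.shape[0], 2))
    for t in range(n_frames):
        M, c = motion.maps[t]
        inv = np.linalg.inv(M)
        ref = (xy - c) @ inv.T
        coords = np.stack(
            [ref[:, 1].reshape(H, W) + pad, ref[:, 0].reshape(H, W) + pad]
        )
        img = map_coordinates(base, coords, order=3, mode="reflect")
        if noise > 0.0:
            eta = gaussian_filter(rng.standard_normal((H, W)), 1.0)
            img = img * (1.0 + noise * eta)
        frames[t] = img
        tracks[t] = motion.apply(t, pts0)
        if (
            tracks[t][:, 0].min() < 0 or tracks[t][:, 0].max() > W - 1
            or tracks[t][:, 1].min() < 0 or tracks[t][:, 1].max() > H - 1
        ):
            raise ValueError("motion carries ground-truth points outside image")
    return frames, tracks
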