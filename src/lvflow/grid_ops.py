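"""Uniform structured grids and sparse finite-difference operators.

The computational domain is a uniform ``nx × ny × nz`` lattice with spacing
``h`` (equal in all three axes).  Every field is stored either as a 3-D array
of shape ``(nx, ny, nz)`` or as a flat vector in the fixed node ordering

    flat(i, j, k) = i + nx * (j + ny * k)          (x fastest, then y, then z)

which corresponds to ``array.ravel(order="F")``.  All sparse operators in
this module use that ordering.

Two operator families are provided:

* :func:`build_operators` — the plain Kronecker-product central-difference
  operators on the full grid box (zero-padded at the grid ends, i.e. the
  stencil simply drops the missing neighbour).  These are exact on the
  interior and are the building blocks of the discrete inverse model.
* masked operators (:func:`masked_operator_set`, :func:`apply_masked`) —
  restrictions to an irregular inside region (the moving ventricle).  Where
  a central stencil would reach outside the region the stencil is closed
  either with a one-sided difference of the same formal order (default) or
  with mirrored ghost values; the choice is a config switch because the
  governing equations are posed on the physical domain, not the grid box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

__all__ = [
    "StructuredGrid",
    "OperatorSet",
    "MaskedDomain",
    "MaskedOperatorSet",
    "build_operators",
    "masked_operator_set",
    "apply_masked",
    "build_neumann_laplacian",
    "normal_derivative_rows",
    "WALL",
    "VALVE",
]

WALL = 0
VALVE = 1

_SCHEMES = ("one_sided", "mirror")


@dataclass(frozen=True)
class StructuredGrid:
    """Uniform lattice of ``nx*ny*nz`` nodes with spacing ``h`` (metres)."""

    nx: int
    ny: int
    nz: int
    h: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("central differences need nx, ny, nz >= 3")
        if not self.h > 0:
            raise ValueError("grid spacing h must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny * self.nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return (
            o[0] + self.h * np.arange(self.nx),
            o[1] + self.h * np.arange(self.ny),
            o[2] + self.h * np.arange(self.nz),
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinates as three ``(nx, ny, nz)`` arrays."""
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")

    def points(self) -> np.ndarray:
        """All node coordinates, shape ``(n_nodes, 3)`` in flat ordering."""
        X, Y, Z = self.meshgrid()
        return np.column_stack(
            [X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")]
        )

    def flat_index(self) -> np.ndarray:
        """``(nx, ny, nz)`` array whose entry [i,j,k] is the flat node id."""
        return np.arange(self.n_nodes).reshape(self.shape, order="F")

    def ravel(self, field3d: np.ndarray) -> np.ndarray:
        return np.asarray(field3d).ravel(order="F")

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat).reshape(self.shape, order="F")


def _d1_1d(n: int, h: float) -> sp.csr_matrix:
    """Central first-derivative matrix with zero-padded ends (tridiagonal)."""
    e = np.ones(n - 1) / (2.0 * h)
    return sp.diags([-e, e], offsets=[-1, 1], format="csr")


def _d2_1d(n: int, h: float) -> sp.csr_matrix:
    """Central second-derivative matrix with zero-padded ends."""
    main = np.full(n, -2.0 / h**2)
    off = np.ones(n - 1) / h**2
    return sp.diags([off, main, off], offsets=[-1, 0, 1], format="csr")


@dataclass(frozen=True)
class OperatorSet:
    """Full-grid Kronecker-structured central-difference operators.

    ``Dx = I_nz ⊗ I_ny ⊗ D_nx`` etc.; ``L = Lx + Ly + Lz`` and the in-plane
    Laplacian ``Lyz = Ly + Lz`` used by the vorticity-constrained initial
    guess.  All matrices are N×N CSR with at most 7 nonzeros per row.
    """

    grid: StructuredGrid
    Dx: sp.csr_matrix
    Dy: sp.csr_matrix
    Dz: sp.csr_matrix
    L: sp.csr_matrix
    Lx: sp.csr_matrix
    Lyz: sp.csr_matrix


def build_operators(grid: StructuredGrid) -> OperatorSet:
    """Assemble the sparse Kronecker-product difference operators."""
    nx, ny, nz, h = grid.nx, grid.ny, grid.nz, grid.h
    Ix, Iy, Iz = (sp.identity(n, format="csr") for n in (nx, ny, nz))
    Dx = sp.kron(Iz, sp.kron(Iy, _d1_1d(nx, h)), format="csr")
    Dy = sp.kron(Iz, sp.kron(_d1_1d(ny, h), Ix), format="csr")
    Dz = sp.kron(_d1_1d(nz, h), sp.kron(Iy, Ix), format="csr")
    Lx = sp.kron(Iz, sp.kron(Iy, _d2_1d(nx, h)), format="csr")
    Ly = sp.kron(Iz, sp.kron(_d2_1d(ny, h), Ix), format="csr")
    Lz = sp.kron(_d2_1d(nz, h), sp.kron(Iy, Ix), format="csr")
    Lyz = (Ly + Lz).tocsr()
    L = (Lx + Lyz).tocsr()
    return OperatorSet(grid=grid, Dx=Dx, Dy=Dy, Dz=Dz, L=L, Lx=Lx, Lyz=Lyz)


# ---------------------------------------------------------------------------
# Masked domains
# ---------------------------------------------------------------------------


@dataclass
class MaskedDomain:
    """An irregular inside region of the grid with a labelled boundary.

    Boundary nodes are inside nodes with at least one outside 6-neighbour
    (nodes on the grid box edge count their missing neighbours as outside).
    Each boundary node carries a label — ``WALL`` for the moving myocardial
    wall (Dirichlet velocity data) or ``VALVE`` for the inlet/outlet
    openings (homogeneous Neumann) — and an outward unit normal estimated
    from the gradient of a Gaussian-smoothed indicator function.
    """

    grid: StructuredGrid
    inside: np.ndarray  # bool (nx, ny, nz)
    boundary_idx: np.ndarray = field(default=None)  # flat indices
    boundary_label: np.ndarray = field(default=None)  # int per boundary node
    normals: np.ndarray = field(default=None)  # (n_boundary, 3) outward unit
    _op_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_mask(
        cls,
        grid: StructuredGrid,
        inside: np.ndarray,
        valve_predicate=None,
        normal_sigma: float = 1.5,
    ) -> "MaskedDomain":
        """Build a domain from a boolean mask.

        ``valve_predicate(points) -> bool array`` marks which boundary nodes
        belong to a valve opening; all other boundary nodes are wall.
        """
        inside = np.ascontiguousarray(inside, dtype=bool)
        if inside.shape != grid.shape:
            raise ValueError("mask shape does not match grid")
        if not inside.any():
            raise ValueError("mask is empty")
        boundary3d = _boundary_mask(inside)
        flat = grid.flat_index()
        boundary_idx = np.sort(flat[boundary3d])
        normals = _estimate_normals(grid, inside, boundary_idx, normal_sigma)
        labels = np.full(boundary_idx.size, WALL, dtype=np.int8)
        if valve_predicate is not None:
            pts = grid.points()[boundary_idx]
            labels[np.asarray(valve_predicate(pts), dtype=bool)] = VALVE
        return cls(
            grid=grid,
            inside=inside,
            boundary_idx=boundary_idx,
            boundary_label=labels,
            normals=normals,
        )

    @property
    def inside_idx(self) -> np.ndarray:
        """Flat indices of inside nodes (sorted)."""
        return np.flatnonzero(self.inside.ravel(order="F"))

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def wall_idx(self) -> np.ndarray:
        return self.boundary_idx[self.boundary_label == WALL]

    @property
    def valve_idx(self) -> np.ndarray:
        return self.boundary_idx[self.boundary_label == VALVE]

    def wall_normals(self) -> np.ndarray:
        return self.normals[self.boundary_label == WALL]

    def compact(self, field3d: np.ndarray) -> np.ndarray:
        """Restrict a full-grid field to the inside-node vector."""
        return self.grid.ravel(field3d)[self.inside_idx]

    def expand(self, compact: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an inside-node vector back to a full 3-D array."""
        out = np.full(self.grid.n_nodes, fill, dtype=float)
        out[self.inside_idx] = compact
        return self.grid.unravel(out)

    def to_label_array(self) -> np.ndarray:
        """Integer mask: 0 outside, 1 inside, 2 wall boundary, 3 valve."""
        arr = self.inside.astype(np.int8).ravel(order="F")
        arr[self.wall_idx] = 2
        arr[self.valve_idx] = 3
        return self.grid.unravel(arr)

    @classmethod
    def from_label_array(
        cls, grid: StructuredGrid, labels: np.ndarray, normal_sigma: float = 1.5
    ) -> "MaskedDomain":
        labels = np.asarray(labels)
        inside = labels > 0
        dom = cls.from_mask(grid, inside, normal_sigma=normal_sigma)
        flat_labels = grid.ravel(labels)
        dom.boundary_label = np.where(
            flat_labels[dom.boundary_idx] == 3, VALVE, WALL
        ).astype(np.int8)
        return dom


def _boundary_mask(inside: np.ndarray) -> np.ndarray:
    """Inside nodes with an outside 6-neighbour (grid edge counts outside)."""
    padded = np.pad(inside, 1, constant_values=False)
    has_outside = np.zeros_like(inside)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for shift in (-1, 1):
            nb = np.roll(padded, shift, axis=axis)[core]
            has_outside |= ~nb
    return inside & has_outside


def _estimate_normals(
    grid: StructuredGrid,
    inside: np.ndarray,
    boundary_idx: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Outward unit normals from the gradient of a smoothed indicator."""
    chi = gaussian_filter(inside.astype(float), sigma=sigma, mode="constant")
    grads = np.gradient(chi, grid.h)
    g = np.column_stack([grid.ravel(gc)[boundary_idx] for gc in grads])
    normals = -g  # indicator increases inward
    norms = np.linalg.norm(normals, axis=1)
    # fallback for degenerate nodes: point along the axis of an outside neighbour
    bad = norms < 1e-12
    if bad.any():
        fi = grid.flat_index()
        strides = {0: 1, 1: grid.nx, 2: grid.nx * grid.ny}
        flat_in = inside.ravel(order="F")
        for row in np.flatnonzero(bad):
            node = boundary_idx[row]
            i, j, k = np.unravel_index(node, grid.shape, order="F")
            fallback = np.zeros(3)
            for axis, (idx, n) in enumerate(
                [(i, grid.nx), (j, grid.ny), (k, grid.nz)]
            ):
                for s in (-1, 1):
                    pos = idx + s
                    if pos < 0 or pos >= n:
                        fallback[axis] += s
                    elif not flat_in[node + s * strides[axis]]:
                        fallback[axis] += s
            if np.linalg.norm(fallback) == 0:
                fallback[0] = 1.0
            normals[row] = fallback
            norms[row] = np.linalg.norm(fallback)
    return normals / norms[:, None]


# ---------------------------------------------------------------------------
# Masked operators
# ---------------------------------------------------------------------------


def _iter_lines(
    grid: StructuredGrid, inside: np.ndarray, axis: int
) -> Iterator[np.ndarray]:
    """Yield flat-index arrays of consecutive inside runs along ``axis``."""
    flat = grid.flat_index()
    m = np.moveaxis(inside, axis, -1)
    f = np.moveaxis(flat, axis, -1)
    n = m.shape[-1]
    lines = m.reshape(-1, n)
    fidx = f.reshape(-1, n)
    for line, ids in zip(lines, fidx):
        if not line.any():
            continue
        d = np.diff(line.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        stops = list(np.flatnonzero(d == -1) + 1)
        if line[0]:
            starts.insert(0, 0)
        if line[-1]:
            stops.append(n)
        for a, b in zip(starts, stops):
            yield ids[a:b]


class _CooBuilder:
    def __init__(self) -> None:
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []

    def add(self, rows, cols, vals) -> None:
        rows = np.atleast_1d(np.asarray(rows))
        cols = np.atleast_1d(np.asarray(cols))
        vals = np.broadcast_to(np.atleast_1d(np.asarray(vals, float)), cols.shape)
        self.rows.append(rows)
        self.cols.append(cols)
        self.vals.append(vals)

    def tocsr(self, n: int) -> sp.csr_matrix:
        if not self.rows:
            return sp.csr_matrix((n, n))
        return sp.coo_matrix(
            (
                np.concatenate(self.vals),
                (np.concatenate(self.rows), np.concatenate(self.cols)),
            ),
            shape=(n, n),
        ).tocsr()


def _masked_d1(grid: StructuredGrid, inside: np.ndarray, axis: int, scheme: str
               ) -> sp.csr_matrix:
    h = grid.h
    b = _CooBuilder()
    for run in _iter_lines(grid, inside, axis):
        ell = run.size
        if ell >= 3:
            mid = run[1:-1]
            b.add(mid, run[2:], 1.0 / (2 * h))
            b.add(mid, run[:-2], -1.0 / (2 * h))
        if scheme == "one_sided":
            if ell >= 3:
                b.add([run[0]] * 3, run[:3], np.array([-3, 4, -1]) / (2 * h))
                b.add([run[-1]] * 3, run[-3:], np.array([1, -4, 3]) / (2 * h))
            elif ell == 2:
                b.add([run[0]] * 2, run, np.array([-1, 1]) / h)
                b.add([run[1]] * 2, run, np.array([-1, 1]) / h)
        # mirror scheme: even reflection -> zero derivative at run ends
    return b.tocsr(grid.n_nodes)


def _masked_d2(grid: StructuredGrid, inside: np.ndarray, axis: int, scheme: str
               ) -> sp.csr_matrix:
    h2 = grid.h**2
    b = _CooBuilder()
    for run in _iter_lines(grid, inside, axis):
        ell = run.size
        if ell >= 3:
            mid = run[1:-1]
            b.add(mid, run[1:-1], -2.0 / h2)
            b.add(mid, run[2:], 1.0 / h2)
            b.add(mid, run[:-2], 1.0 / h2)
        if scheme == "one_sided":
            if ell >= 4:
                b.add([run[0]] * 4, run[:4], np.array([2, -5, 4, -1]) / h2)
                b.add([run[-1]] * 4, run[-4:], np.array([-1, 4, -5, 2]) / h2)
            elif ell == 3:
                stencil = np.array([1, -2, 1]) / h2
                b.add([run[0]] * 3, run, stencil)
                b.add([run[-1]] * 3, run, stencil)
        elif scheme == "mirror":
            if ell >= 2:
                b.add([run[0]] * 2, run[:2], np.array([-2, 2]) / h2)
                b.add([run[-1]] * 2, run[-2:], np.array([2, -2]) / h2)
    return b.tocsr(grid.n_nodes)


@dataclass(frozen=True)
class MaskedOperatorSet:
    """Difference operators closed at the discrete boundary of a mask.

    Matrices are N×N (full-grid indexing) but only rows of inside nodes are
    populated, and those rows reference inside nodes only, so restriction to
    the inside-node block is lossless.
    """

    domain: MaskedDomain
    scheme: str
    Dx: sp.csr_matrix
    Dy: sp.csr_matrix
    Dz: sp.csr_matrix
    Lxx: sp.csr_matrix
    Lyy: sp.csr_matrix
    Lzz: sp.csr_matrix

    @property
    def L(self) -> sp.csr_matrix:
        return (self.Lxx + self.Lyy + self.Lzz).tocsr()

    @property
    def Lyz(self) -> sp.csr_matrix:
        return (self.Lyy + self.Lzz).tocsr()


def masked_operator_set(
    domain: MaskedDomain, scheme: str = "one_sided"
) -> MaskedOperatorSet:
    """Build (and cache on the domain) the masked operator family."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown closure scheme {scheme!r}; use one of {_SCHEMES}")
    cached = domain._op_cache.get(scheme)
    if cached is not None:
        return cached
    g, m = domain.grid, domain.inside
    ops = MaskedOperatorSet(
        domain=domain,
        scheme=scheme,
        Dx=_masked_d1(g, m, 0, scheme),
        Dy=_masked_d1(g, m, 1, scheme),
        Dz=_masked_d1(g, m, 2, scheme),
        Lxx=_masked_d2(g, m, 0, scheme),
        Lyy=_masked_d2(g, m, 1, scheme),
        Lzz=_masked_d2(g, m, 2, scheme),
    )
    domain._op_cache[scheme] = ops
    return ops


_OP_NAMES = {
    "dx": "Dx",
    "dy": "Dy",
    "dz": "Dz",
    "lap": "L",
    "laplacian": "L",
    "lyz": "Lyz",
    "lx": "Lxx",
    "lxx": "Lxx",
    "lyy": "Lyy",
    "lzz": "Lzz",
}


def apply_masked(
    op: str,
    field3d: np.ndarray,
    domain: MaskedDomain,
    scheme: str = "one_sided",
) -> np.ndarray:
    """Apply a named derivative operator restricted to the inside region.

    Returns a full ``(nx, ny, nz)`` array that is zero outside the mask.
    ``op`` is one of ``dx, dy, dz, lap, lyz, lx, lxx, lyy, lzz``.
    """
    try:
        attr = _OP_NAMES[op.lower()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown operator name {op!r}") from None
    ops = masked_operator_set(domain, scheme)
    mat = getattr(ops, attr)
    res = mat @ domain.grid.ravel(np.asarray(field3d, dtype=float))
    res[~domain.inside.ravel(order="F")] = 0.0
    return domain.grid.unravel(res)


# ---------------------------------------------------------------------------
# Neumann Laplacian and boundary stencils for the pressure / system solves
# ---------------------------------------------------------------------------


def build_neumann_laplacian(
    domain: MaskedDomain,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Symmetric zero-flux Laplacian on the inside nodes.

    Returns ``(A, w)`` where ``A`` is the (negative semidefinite) graph
    Laplacian over inside-node adjacency scaled by ``1/h²`` in compact
    inside-node indexing, and ``w`` are trapezoid-style quadrature weights
    for the right-hand side (half weight at run ends along each axis).  The
    pair discretizes the Poisson problem with homogeneous Neumann data; the
    nullspace is the constant vector.
    """
    grid = domain.grid
    n_in = domain.n_inside
    pos = np.full(grid.n_nodes, -1, dtype=np.int64)
    pos[domain.inside_idx] = np.arange(n_in)
    h2 = grid.h**2
    # per-axis trapezoid weights: 1 in the run interior, 1/2 at run ends
    w_axis = np.ones((3, n_in))
    runs = {axis: list(_iter_lines(grid, domain.inside, axis)) for axis in range(3)}
    for axis in range(3):
        for run in runs[axis]:
            c = pos[run]
            w_axis[axis, c[0]] = 0.5
            w_axis[axis, c[-1]] = 0.5
    # finite-volume edge weights: each face carries the transverse cell area
    rows, cols, vals = [], [], []
    for axis in range(3):
        o1, o2 = [a for a in range(3) if a != axis]
        trans = w_axis[o1] * w_axis[o2]
        for run in runs[axis]:
            if run.size < 2:
                continue
            c = pos[run]
            a, bb = c[:-1], c[1:]
            ew = 0.5 * (trans[a] + trans[bb]) / h2
            rows += [a, bb, a, bb]
            cols += [bb, a, a, bb]
            vals += [ew, ew, -ew, -ew]
    if rows:
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_in, n_in),
        ).tocsr()
    else:
        A = sp.csr_matrix((n_in, n_in))
    w = w_axis.prod(axis=0)
    return A, w


def neumann_surface_weights(domain: MaskedDomain) -> np.ndarray:
    """Signed boundary-face areas for inhomogeneous Neumann data.

    Returns ``s`` of shape (3, n_inside): ``s[axis, i]`` is the transverse
    face weight (in units of h²/h³ = 1/h after scaling) of the outward
    boundary face of node ``i`` along ``axis``, positive at run ends in the
    +axis direction, negative at run starts, zero in run interiors.  The
    weak-form right-hand side of the Poisson problem with flux data g is
    ``w·f − (1/h)·Σ_axis s[axis]·g_axis``.
    """
    grid = domain.grid
    n_in = domain.n_inside
    pos = np.full(grid.n_nodes, -1, dtype=np.int64)
    pos[domain.inside_idx] = np.arange(n_in)
    runs = {axis: list(_iter_lines(grid, domain.inside, axis)) for axis in range(3)}
    w_axis = np.ones((3, n_in))
    for axis in range(3):
        for run in runs[axis]:
            c = pos[run]
            w_axis[axis, c[0]] = 0.5
            w_axis[axis, c[-1]] = 0.5
    s = np.zeros((3, n_in))
    for axis in range(3):
        o1, o2 = [a for a in range(3) if a != axis]
        trans = w_axis[o1] * w_axis[o2]
        for run in runs[axis]:
            c = pos[run]
            s[axis, c[0]] -= trans[c[0]]
            s[axis, c[-1]] += trans[c[-1]]
    return s


def face_gradient_system(
    domain: MaskedDomain,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Face-difference operator for gradient-matching (Helmholtz) solves.

    Returns ``(A, w, axis, i, j)`` where ``A`` maps compact inside-node
    values to per-face differences ``(p_j - p_i)/h`` over all pairs of
    6-adjacent inside nodes, ``w`` are transverse face-area weights,
    ``axis`` the face orientation, and ``i, j`` the compact node ids of
    each face's endpoints.  ``AᵀWA`` equals the finite-volume Neumann
    Laplacian of :func:`build_neumann_laplacian` (up to sign).
    """
    grid = domain.grid
    n_in = domain.n_inside
    pos = np.full(grid.n_nodes, -1, dtype=np.int64)
    pos[domain.inside_idx] = np.arange(n_in)
    runs = {axis: list(_iter_lines(grid, domain.inside, axis)) for axis in range(3)}
    w_axis = np.ones((3, n_in))
    for axis in range(3):
        for run in runs[axis]:
            c = pos[run]
            w_axis[axis, c[0]] = 0.5
            w_axis[axis, c[-1]] = 0.5
    ii, jj, ww, ax = [], [], [], []
    for axis in range(3):
        o1, o2 = [a for a in range(3) if a != axis]
        trans = w_axis[o1] * w_axis[o2]
        for run in runs[axis]:
            c = pos[run]
            if c.size < 2:
                continue
            a_, b_ = c[:-1], c[1:]
            ii.append(a_)
            jj.append(b_)
            ww.append(0.5 * (trans[a_] + trans[b_]))
            ax.append(np.full(a_.size, axis, dtype=np.int8))
    if not ii:
        return (sp.csr_matrix((0, n_in)), np.zeros(0),
                np.zeros(0, np.int8), np.zeros(0, np.int64), np.zeros(0, np.int64))
    i_arr = np.concatenate(ii)
    j_arr = np.concatenate(jj)
    w_arr = np.concatenate(ww)
    ax_arr = np.concatenate(ax)
    nf = i_arr.size
    rows = np.repeat(np.arange(nf), 2)
    cols = np.column_stack([j_arr, i_arr]).ravel()
    vals = np.tile([1.0 / grid.h, -1.0 / grid.h], nf)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(nf, n_in)).tocsr()
    return A, w_arr, ax_arr, i_arr, j_arr


def normal_derivative_rows(
    domain: MaskedDomain, nodes: np.ndarray, scheme: str = "one_sided"
) -> sp.csr_matrix:
    """One-sided stencils for ``n·∇`` at the given boundary nodes.

    Returns a ``(len(nodes), N)`` sparse matrix in full-grid column
    indexing.  Per axis with a non-negligible normal component the
    derivative is taken one-sidedly into the domain interior (second order
    where two interior neighbours exist, first order otherwise).
    """
    grid = domain.grid
    flat_in = domain.inside.ravel(order="F")
    strides = (1, grid.nx, grid.nx * grid.ny)
    dims = grid.shape
    node_to_row = {int(n): r for r, n in enumerate(domain.boundary_idx)}
    rows, cols, vals = [], [], []
    for r, node in enumerate(np.asarray(nodes)):
        node = int(node)
        nrm = domain.normals[node_to_row[node]]
        ijk = np.unravel_index(node, dims, order="F")
        any_term = False
        for axis in range(3):
            na = nrm[axis]
            if abs(na) < 1e-10:
                continue
            # step into the interior is opposite the outward normal
            s = -1 if na > 0 else 1
            p1 = ijk[axis] + s
            p2 = ijk[axis] + 2 * s
            n1 = node + s * strides[axis]
            n2 = node + 2 * s * strides[axis]
            ok1 = 0 <= p1 < dims[axis] and flat_in[n1]
            ok2 = 0 <= p2 < dims[axis] and flat_in[n2]
            sgn = -s  # derivative in +axis direction
            if ok1 and ok2 and scheme == "one_sided":
                st = sgn * np.array([3.0, -4.0, 1.0]) / (2 * grid.h)
                rows += [r, r, r]
                cols += [node, n1, n2]
                vals += list(na * st)
                any_term = True
            elif ok1:
                st = sgn * np.array([1.0, -1.0]) / grid.h
                rows += [r, r]
                cols += [node, n1]
                vals += list(na * st)
                any_term = True
        if not any_term:
            # isolated node: pin it (identity row, homogeneous data)
            rows.append(r)
            cols.append(node)
            vals.append(1.0)
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(np.asarray(nodes)), grid.n_nodes)
    ).tocsr()
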