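"""LV contour tracking and 3-D surface lofting.

Tracking points on a 2-D echo image are advanced frame-to-frame by
minimizing a jointly quadratic energy: a Lucas-Kanade data term (optical
flow over a pixel neighbourhood around each point) plus a global-
deformation regularizer that penalizes deviation of the new point
configuration from the best-fit affine transform of the initial
configuration.  Tracked points are interpolated into closed periodic
cubic-spline contours, and two orthogonal contour stacks (sharing the long
axis) are lofted into a 3-D voxel mask with pipe-type valve openings.

Image convention: arrays are indexed ``[row, col]``; points are ``(x, y)``
= (column, row) pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid_ops import MaskedDomain, StructuredGrid

__all__ = [
    "ContourTrack",
    "ClosedContour",
    "track_frame",
    "track_sequence",
    "interpolate_contour",
    "loft_surface",
    "ValvePipeSpec",
    "extract_plane_contour",
]


@dataclass
class ContourTrack:
    """State of a 2-D point-tracking problem.

    ``points``: current (n, 2) positions in (x, y) pixel coordinates;
    ``window``: odd neighbourhood size k (a k×k patch per point);
    ``lambda_tilde``: weight of the global-affine-deviation term;
    ``sigma``: Gaussian presmoothing of the images before differencing.
    The initial configuration (for the affine design matrix) is stored at
    construction.
    """

    points: np.ndarray
    window: int = 9
    lambda_tilde: float = 1.0
    sigma: float = 1.0
    n_refine: int = 3
    initial_points: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if self.points.shape[0] < 3:
            raise ValueError("need at least 3 tracking points (affine fit)")
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if self.initial_points is None:
            self.initial_points = self.points.copy()

    def design_matrix(self) -> np.ndarray:
        """The n×3 affine design matrix [x_i(0), y_i(0), 1]."""
        n = self.initial_points.shape[0]
        return np.column_stack([self.initial_points, np.ones(n)])

    def affine_projector(self) -> np.ndarray:
        """Hat matrix P = X(XᵀX)⁻¹Xᵀ projecting point configurations onto
        affine images of the initial configuration."""
        X = self.design_matrix()
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("initial points are collinear; affine fit is "
                             "rank-deficient")
        return X @ np.linalg.solve(X.T @ X, X.T)


def _sample(img: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    return map_coordinates(
        img, [pts_xy[:, 1], pts_xy[:, 0]], order=1, mode="nearest"
    )


def track_frame(
    image0: np.ndarray,
    image1: np.ndarray,
    track: ContourTrack,
) -> np.ndarray:
    """Track all points from ``image0`` to ``image1``.

    Minimizes, jointly over the 2n displacement unknowns, the sum of the
    per-point Lucas-Kanade quadratic data terms and λ̃ times the squared
    deviation of the displaced configuration from its best-fit affine
    transform; the exact minimizer of the quadratic is found by one dense
    linear solve per refinement sweep (the image is re-warped between
    sweeps to reduce linearization error).  Returns the new (n, 2) points.
    """
    image0 = np.asarray(image0, dtype=float)
    image1 = np.asarray(image1, dtype=float)
    if image0.shape != image1.shape:
        raise ValueError("images must have the same shape")
    I0 = gaussian_filter(image0, track.sigma)
    I1 = gaussian_filter(image1, track.sigma)
    gy, gx = np.gradient(I1)
    n = track.points.shape[0]
    P = track.affine_projector()
    k = track.window // 2
    off = np.arange(-k, k + 1, dtype=float)
    OX, OY = np.meshgrid(off, off)
    offsets = np.column_stack([OX.ravel(), OY.ravel()])

    pts = track.points.copy()
    disp = np.zeros((n, 2))
    for _ in range(max(track.n_refine, 1)):
        A = np.zeros((2 * n, 2 * n))
        b = np.zeros(2 * n)
        for i in range(n):
            nb = pts[i] + disp[i] + offsets
            Ix = _sample(gx, nb)
            Iy = _sample(gy, nb)
            It = _sample(I1, nb) - _sample(I0, pts[i] + offsets)
            G = np.array(
                [[(Ix * Ix).sum(), (Ix * Iy).sum()],
                 [(Ix * Iy).sum(), (Iy * Iy).sum()]]
            )
            A[2 * i: 2 * i + 2, 2 * i: 2 * i + 2] += G
            b[2 * i: 2 * i + 2] -= np.array(
                [(Ix * It).sum(), (Iy * It).sum()]
            )
        # regularizer: λ̃ ‖(I-P)(x + v)‖² over both coordinates
        Q = np.eye(n) - P
        QtQ = Q.T @ Q
        for c in range(2):
            idx = 2 * np.arange(n) + c
            A[np.ix_(idx, idx)] += track.lambda_tilde * QtQ
            b[idx] -= track.lambda_tilde * (QtQ @ (pts[:, c] + disp[:, c]))
        try:
            delta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular tracking system (a point neighbourhood has no "
                "texture); set lambda_tilde > 0 to regularize"
            ) from exc
        disp = disp + delta.reshape(n, 2)
    new_pts = pts + disp
    H, W = image1.shape
    new_pts[:, 0] = np.clip(new_pts[:, 0], 0, W - 1)
    new_pts[:, 1] = np.clip(new_pts[:, 1], 0, H - 1)
    return new_pts


def track_sequence(
    frames: np.ndarray, track: ContourTrack
) -> np.ndarray:
    """Track through a (T, H, W) sequence; returns (T, n, 2) positions."""
    out = [track.points.copy()]
    for t in range(len(frames) - 1):
        track.points = track_frame(frames[t], frames[t + 1], track)
        out.append(track.points.copy())
    return np.stack(out)


# ---------------------------------------------------------------------------
# Closed-contour interpolation
# ---------------------------------------------------------------------------


@dataclass
class ClosedContour:
    """Periodic cubic-spline curve through ordered points.

    ``sample(s)`` evaluates the curve at parameters in [0, 1]; the spline
    passes through the input points at the knot parameters (chord-length
    by default).
    """

    points: np.ndarray
    knots: np.ndarray
    _spline: CubicSpline = field(default=None, repr=False)

    def sample(self, s: np.ndarray) -> np.ndarray:
        return self._spline(np.asarray(s) % 1.0)


def interpolate_contour(
    points: np.ndarray,
    n_samples: int | None = None,
    knots: np.ndarray | None = None,
) -> ClosedContour | np.ndarray:
    """Closed periodic cubic spline through ordered contour points.

    ``knots`` are the curve parameters s_i of the input points (chord-
    length parameterization normalized to [0, 1) when omitted).  With
    ``n_samples`` given, returns the (n_samples, 2) sampled polyline;
    otherwise returns the :class:`ClosedContour`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 ordered (x, y) points")
    if np.any(np.all(pts == np.roll(pts, 1, axis=0), axis=1)):
        raise ValueError("repeated consecutive points")
    closed = np.vstack([pts, pts[:1]])
    if knots is None:
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s /= s[-1]
    else:
        s = np.asarray(knots, dtype=float)
        if s.size == pts.shape[0]:
            s = np.concatenate([s, [1.0]])
        if s[0] != 0.0 or s[-1] != 1.0 or np.any(np.diff(s) <= 0):
            raise ValueError("knots must increase from 0 to 1")
    spline = CubicSpline(s, closed, bc_type="periodic")
    contour = ClosedContour(points=pts, knots=s[:-1], _spline=spline)
    if n_samples is not None:
        return contour.sample(np.linspace(0.0, 1.0, n_samples, endpoint=False))
    return contour


# ---------------------------------------------------------------------------
# Two-plane lofting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValvePipeSpec:
    """Pipe-type valve openings attached at the basal (+x) end.

    Cross-sections: elliptic mitral (radii ``mitral_radii``) and circular
    aortic (radius ``aortic_radius``), centred at the given (y, z) or
    (z, y)-symmetric positions; pipes extend ``length`` metres beyond the
    basal cap.
    """

    mitral_center: tuple[float, float] = (0.011, 0.0)
    mitral_radii: tuple[float, float] = (0.0115, 0.009)
    aortic_center: tuple[float, float] = (-0.011, 0.0)
    aortic_radius: float = 0.009
    length: float = 0.012


def _crossings(samples: np.ndarray, x: float) -> np.ndarray:
    """Ordinates where a closed polyline crosses the vertical line at x."""
    sx = samples[:, 0]
    sy = samples[:, 1]
    sx2 = np.roll(sx, -1)
    sy2 = np.roll(sy, -1)
    hit = (sx - x) * (sx2 - x) <= 0
    hit &= sx != sx2
    if not hit.any():
        return np.empty(0)
    t = (x - sx[hit]) / (sx2[hit] - sx[hit])
    return sy[hit] + t * (sy2[hit] - sy[hit])


def _half_widths(
    contour: ClosedContour, xs: np.ndarray, n_dense: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Per-height centre and half-width of a contour (NaN outside)."""
    samples = contour.sample(np.linspace(0, 1, n_dense, endpoint=False))
    center = np.full(xs.size, np.nan)
    half = np.full(xs.size, np.nan)
    for i, x in enumerate(xs):
        ys = _crossings(samples, x)
        if ys.size >= 2:
            center[i] = 0.5 * (ys.min() + ys.max())
            half[i] = 0.5 * (ys.max() - ys.min())
    return center, half


def loft_surface(
    contours_a: list[ClosedContour],
    contours_b: list[ClosedContour],
    grid: StructuredGrid,
    valve_spec: ValvePipeSpec | None = None,
) -> list[MaskedDomain]:
    """Loft two orthogonal contour stacks into per-frame 3-D masks.

    Plane A is the x-y plane (contour points are (x, y) metres), plane B
    the x-z plane ((x, z) metres); both share the x long axis.  At each
    height x the cross-section is the ellipse through the two planes'
    half-widths (elliptic azimuthal blending).  With a ``valve_spec``,
    pipe-type openings are appended at the basal (maximum-x) end and their
    end caps labelled as valve boundary.  A single-frame input produces a
    single static mask.
    """
    if len(contours_a) != len(contours_b):
        raise ValueError("contour stacks must have the same number of frames")
    X, Y, Z = grid.meshgrid()
    xs = grid.axes()[0]
    out = []
    for ca, cb in zip(contours_a, contours_b):
        yc, ry = _half_widths(ca, xs)
        zc, rz = _half_widths(cb, xs)
        ok = ~(np.isnan(ry) | np.isnan(rz)) & (ry > 0) & (rz > 0)
        if not ok.any():
            raise ValueError("contour planes do not overlap along the long "
                             "axis")
        inside = np.zeros(grid.shape, dtype=bool)
        ell = (
            ((Y - yc[:, None, None]) / np.where(ok, ry, 1.0)[:, None, None]) ** 2
            + ((Z - zc[:, None, None]) / np.where(ok, rz, 1.0)[:, None, None]) ** 2
        )
        inside = (ell <= 1.0) & ok[:, None, None]
        valve_pred = None
        if valve_spec is not None:
            x_base = xs[ok].max()
            x_end = x_base + valve_spec.length
            my, mz = valve_spec.mitral_center
            ry_m, rz_m = valve_spec.mitral_radii
            ay, az = valve_spec.aortic_center
            mitral = ((Y - my) / ry_m) ** 2 + ((Z - mz) / rz_m) ** 2 <= 1.0
            aortic = (Y - ay) ** 2 + (Z - az) ** 2 <= valve_spec.aortic_radius**2
            in_pipe = (X >= x_base - grid.h) & (X <= x_end) & (mitral | aortic)
            inside |= in_pipe

            def valve_pred(points, _xe=x_end, _h=grid.h):
                x, y, z = points.T
                cap = x > _xe - 1.5 * _h
                m = ((y - my) / ry_m) ** 2 + ((z - mz) / rz_m) ** 2 <= 1.0
                a = (y - ay) ** 2 + (z - az) ** 2 <= valve_spec.aortic_radius**2
                return cap & (m | a)

        out.append(MaskedDomain.from_mask(grid, inside, valve_predicate=valve_pred))
    return out


def extract_plane_contour(
    domain: MaskedDomain, plane: str = "xy", n_samples: int = 400
) -> np.ndarray:
    """Mid-plane mask contour in physical coordinates (round-trip check).

    Extracts the 0.5-level contour of the mask slice through the domain
    centroid on the requested plane ("xy" or "xz") with subpixel marching
    squares, returning (m, 2) points in metres.
    """
    from skimage import measure

    grid = domain.grid
    m = domain.inside.astype(float)
    com = np.array(np.nonzero(domain.inside)).mean(axis=1)
    if plane == "xy":
        sl = m[:, :, int(round(com[2]))]
        o0, o1 = grid.origin[0], grid.origin[1]
    elif plane == "xz":
        sl = m[:, int(round(com[1])), :]
        o0, o1 = grid.origin[0], grid.origin[2]
    else:
        raise ValueError("plane must be 'xy' or 'xz'")
    contours = measure.find_contours(sl, 0.5)
    if not contours:
        raise ValueError("empty mask slice")
    c = max(contours, key=len)
    pts = np.column_stack([o0 + grid.h * c[:, 0], o1 + grid.h * c[:, 1]])
    if pts.shape[0] > n_samples:
        pts = pts[:: max(pts.shape[0] // n_samples, 1)]
    return pts
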