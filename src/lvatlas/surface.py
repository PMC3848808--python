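"""Parametric LV surface model.

Each surface (endocardium, epicardium) is a radial function ``lambda(u, v)``
of two angular coordinates, represented as a tensor-product cubic B-spline
over an ``Nc x Nl`` grid of nodal lambda values: periodic in the
circumferential direction u and clamped in the longitudinal direction v
(v = 0 apex, v = 1 base).  The nodal values are the shape parameters on
which the statistical machinery of the package operates; the surface is C1
in (u, v) and can be sampled at arbitrary resolution.

Angular coordinates map to prolate spheroidal coordinates as
``theta = 2*pi*u`` and ``mu = v * mu_max`` (default ``mu_max`` = 120 deg),
and from there to Cartesian millimetres via :mod:`lvatlas.prolate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline, NdBSpline

from . import aha
from .prolate import ProlateFrame, prolate_to_cartesian

__all__ = [
    "LVShape",
    "SurfaceSamples",
    "SplineSurface",
    "evaluate_surface",
    "sample_surface",
    "sample_segment",
    "aha_assign",
    "DEFAULT_MU_MAX",
    "DEFAULT_GRID",
]

DEFAULT_MU_MAX = 2.0 * np.pi / 3.0  # 120 degrees
DEFAULT_GRID = (8, 8)  # (Nc circumferential, Nl longitudinal)
SURFACES = ("endo", "epi")

_DEGREE = 3


class SplineSurface:
    """Scalar tensor spline ``lambda(u, v)`` on the unit square.

    Periodic uniform cubic B-spline in u (period 1), clamped cubic B-spline
    in v; coefficients are the ``Nc x Nl`` nodal values.
    """

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 2 or grid.shape[0] < 4 or grid.shape[1] < 4:
            raise ValueError("control grid must be at least 4x4")
        if not np.all(np.isfinite(grid)):
            raise ValueError("control values must be finite")
        self.grid = grid
        nc, nl = grid.shape
        tu = np.arange(-_DEGREE, nc + _DEGREE + 1) / nc
        tv = np.r_[np.zeros(_DEGREE), np.linspace(0.0, 1.0, nl - 2),
                   np.ones(_DEGREE)]
        coef = np.vstack([grid, grid[:_DEGREE]])  # periodic wrap in u
        self._spline = NdBSpline((tu, tv), coef, k=_DEGREE)

    def __call__(self, u, v) -> np.ndarray:
        u = np.mod(np.asarray(u, dtype=float), 1.0)
        v = np.asarray(v, dtype=float)
        if np.any((v < 0.0) | (v > 1.0)):
            raise ValueError("v must lie in [0, 1]")
        pts = np.stack(np.broadcast_arrays(u, v), axis=-1)
        return self._spline(pts)


def _knots(nc: int, nl: int):
    tu = np.arange(-_DEGREE, nc + _DEGREE + 1) / nc
    tv = np.r_[np.zeros(_DEGREE), np.linspace(0.0, 1.0, nl - 2), np.ones(_DEGREE)]
    return tu, tv


def basis_matrix(grid_shape: tuple, uv: np.ndarray) -> np.ndarray:
    """Dense matrix B with ``lambda(uv) = B @ grid.ravel()``.

    The surface value is linear in the nodal lambda values; B has shape
    ``(len(uv), Nc * Nl)`` with columns in row-major (circumferential,
    longitudinal) node order.  Exposes the linear structure used for
    vectorized wall checks and per-parameter regional support weights.
    """
    nc, nl = grid_shape
    uv = np.asarray(uv, dtype=float)
    tu, tv = _knots(nc, nl)
    du = BSpline.design_matrix(np.mod(uv[:, 0], 1.0), tu, _DEGREE).toarray()
    # fold the periodic wrap columns back onto the first three nodes
    du_f = du[:, :nc].copy()
    du_f[:, :_DEGREE] += du[:, nc:]
    dv = BSpline.design_matrix(np.clip(uv[:, 1], 0.0, 1.0), tv, _DEGREE).toarray()
    return (du_f[:, :, None] * dv[:, None, :]).reshape(len(uv), nc * nl)


@lru_cache(maxsize=8)
def wall_check_matrix(grid_shape: tuple, res: int = 17) -> np.ndarray:
    """Cached basis matrix on the wall-thickness check grid."""
    u = np.arange(res) / res
    v = np.linspace(0.0, 1.0, res)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return basis_matrix(grid_shape, np.column_stack([uu.ravel(), vv.ravel()]))


def greville_uv(grid_shape: tuple):
    """Parametric (u_i, v_j) node locations (Greville abscissae)."""
    nc, nl = grid_shape
    tu, tv = _knots(nc, nl)
    # periodic coefficient i peaks at (i - 1) / Nc (uniform knots start at -3/Nc)
    u = np.mod((np.arange(nc) - 1.0) / nc, 1.0)
    v = np.array([tv[j + 1:j + 1 + _DEGREE].mean() for j in range(nl)])
    return u, v


@dataclass
class LVShape:
    """Shape of one LV at one cardiac frame.

    The shape parameters are the two nodal lambda grids (endocardium and
    epicardium); ``parameters`` flattens them into the vector on which the
    protocol bias transform operates (endo first, row-major over
    (circumferential, longitudinal) indices).
    """

    frame_label: str = "ED"
    prolate: ProlateFrame = field(default_factory=ProlateFrame)
    endo_grid: np.ndarray = None
    epi_grid: np.ndarray = None
    case_id: str = ""
    protocol: str = ""
    mu_max: float = DEFAULT_MU_MAX
    #: raise on wall-thickness violation (False: warn and flag instead,
    #: used for transformed shapes where violations are logged, not errors)
    enforce_wall: bool = True

    #: grid used by the constructor's wall-thickness check
    _CHECK_RES = 17

    def __post_init__(self):
        if self.frame_label not in ("ED", "ES"):
            raise ValueError("frame_label must be 'ED' or 'ES'")
        if not 0.0 < self.mu_max < np.pi:
            raise ValueError("mu_max must lie in (0, pi)")
        for name in ("endo_grid", "epi_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.ndim != 2:
                raise ValueError(f"{name} must be a 2-D nodal grid")
            if not np.all(np.isfinite(g)) or np.any(g <= 0.0):
                raise ValueError(f"{name}: nodal lambda values must be finite and > 0")
            setattr(self, name, g)
        if self.endo_grid.shape != self.epi_grid.shape:
            raise ValueError("endo and epi grids must have identical dimensions")
        self._splines = {}
        self.wall_violation = not self.wall_ok()
        if self.wall_violation:
            if self.enforce_wall:
                raise ValueError(
                    f"wall-thickness violation for case {self.case_id!r}: "
                    "epicardial surface must enclose the endocardium"
                )
            import warnings

            warnings.warn(
                f"wall-thickness violation flagged for case {self.case_id!r}",
                RuntimeWarning,
                stacklevel=2,
            )

    # -- parameter vector interface -------------------------------------
    @property
    def grid_shape(self) -> tuple:
        return self.endo_grid.shape

    @property
    def n_parameters(self) -> int:
        return 2 * self.endo_grid.size

    @property
    def parameters(self) -> np.ndarray:
        return np.concatenate([self.endo_grid.ravel(), self.epi_grid.ravel()])

    def with_parameters(self, params: np.ndarray, **meta) -> "LVShape":
        """New shape with the same frame/geometry but replaced parameters."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_parameters,):
            raise ValueError("parameter vector length mismatch")
        half = self.endo_grid.size
        return replace(
            self,
            endo_grid=params[:half].reshape(self.grid_shape).copy(),
            epi_grid=params[half:].reshape(self.grid_shape).copy(),
            **meta,
        )

    # -- geometry -------------------------------------------------------
    def spline(self, surface: str) -> SplineSurface:
        if surface not in SURFACES:
            raise ValueError("surface must be 'endo' or 'epi'")
        if surface not in self._splines:
            grid = self.endo_grid if surface == "endo" else self.epi_grid
            self._splines[surface] = SplineSurface(grid)
        return self._splines[surface]

    def wall_ok(self, resolution: int | None = None) -> bool:
        """Check lambda_epi >= lambda_endo on a parametric check grid."""
        res = resolution or self._CHECK_RES
        u = np.arange(res) / res
        v = np.linspace(0.0, 1.0, res)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        endo = SplineSurface(self.endo_grid)(uu, vv)
        epi = SplineSurface(self.epi_grid)(uu, vv)
        return bool(np.all(epi - endo >= -1e-12))


@dataclass
class SurfaceSamples:
    """Registered Cartesian point cloud sampled from one LV surface."""

    points: np.ndarray          # (n, 3) world mm
    parametric_uv: np.ndarray   # (n, 2) in [0,1) x [0,1]
    surface_label: str          # 'endo' or 'epi'
    segment_id: np.ndarray      # (n,) ints 1..17
    case_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.parametric_uv = np.asarray(self.parametric_uv, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        n = len(self.points)
        if self.parametric_uv.shape != (n, 2) or self.segment_id.shape != (n,):
            raise ValueError("inconsistent SurfaceSamples array lengths")
        if np.any((self.segment_id < 1) | (self.segment_id > 17)):
            raise ValueError("segment_id must lie in 1..17")

    def __len__(self):
        return len(self.points)


def evaluate_surface(shape: LVShape, surface: str, u, v) -> np.ndarray:
    """Evaluate world-space surface points at parametric (u, v).

    u is circumferential and periodic (taken mod 1); v in [0, 1] runs from
    the apical pole to the base.  Returns (..., 3) mm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(~np.isfinite(v)):
        raise ValueError("u and v must be finite")
    if np.any((v < 0.0) | (v > 1.0)):
        raise ValueError("v out of range [0, 1]")
    lam = shape.spline(surface)(u, v)
    mu = v * shape.mu_max
    theta = 2.0 * np.pi * np.mod(u, 1.0)
    return prolate_to_cartesian(lam, mu, theta, shape.prolate)


def aha_assign(uv: np.ndarray, apex_band: float = aha.DEFAULT_APEX_BAND,
               septal_angle: float = aha.DEFAULT_SEPTAL_ANGLE) -> np.ndarray:
    """AHA segment ids (1..17) for parametric sample locations (n, 2)."""
    uv = np.asarray(uv, dtype=float)
    return aha.segment_of(uv[..., 0], uv[..., 1], apex_band, septal_angle)


def sample_surface(shape: LVShape, surface: str, n_u: int = 33,
                   n_v: int = 33) -> SurfaceSamples:
    """Sample a uniform parametric grid of ``n_u x n_v`` points.

    The default 33 x 33 grid yields 1,089 registered points per surface; u
    is sampled half-open (33 distinct circumferential stations) and v closed
    from apex (v = 0) to base (v = 1).
    """
    if n_u < 4 or n_v < 4:
        raise ValueError("n_u and n_v must be >= 4")
    u = np.arange(n_u) / n_u
    v = np.linspace(0.0, 1.0, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    pts = evaluate_surface(shape, surface, uv[:, 0], uv[:, 1])
    return SurfaceSamples(
        points=pts,
        parametric_uv=uv,
        surface_label=surface,
        segment_id=aha_assign(uv),
        case_id=shape.case_id,
    )


def _segment_lattice(segment_id: int, n: int) -> np.ndarray:
    """Deterministic uniform cell-centred lattice of n (u, v) points in a segment.

    The lattice dimensions are the divisor pair of n whose parametric cells
    are closest to square within the segment's rectangle; for n = 1 this is
    the rectangle's centroid.  Rectangles of distinct segments are disjoint,
    so per-segment lattices never collide.
    """
    (u0, u1), (v0, v1) = aha.segment_bounds(segment_id)
    du, dv = u1 - u0, v1 - v0
    best, best_score = (n, 1), np.inf
    for m_u in range(1, n + 1):
        if n % m_u:
            continue
        m_v = n // m_u
        cell_aspect = (du / m_u) / (dv / m_v)
        score = abs(np.log(cell_aspect))
        if score < best_score:
            best, best_score = (m_u, m_v), score
    m_u, m_v = best
    cu = u0 + (np.arange(m_u) + 0.5) / m_u * du
    cv = v0 + (np.arange(m_v) + 0.5) / m_v * dv
    uu, vv = np.meshgrid(cu, cv, indexing="ij")
    return np.column_stack([np.mod(uu.ravel(), 1.0), vv.ravel()])


def sample_segment(shape: LVShape, surface: str, segment_id: int,
                   n: int = 200) -> SurfaceSamples:
    """Sample ``n`` points on a deterministic uniform lattice in one segment."""
    if n < 1:
        raise ValueError("n must be >= 1")
    uv = _segment_lattice(segment_id, int(n))
    pts = evaluate_surface(shape, surface, uv[:, 0], uv[:, 1])
    return SurfaceSamples(
        points=pts,
        parametric_uv=uv,
        surface_label=surface,
        segment_id=np.full(len(uv), int(segment_id)),
        case_id=shape.case_id,
    )
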