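"""Prolate spheroidal coordinate frame for the left ventricle.

The LV long axis is aligned with the first axis of the frame; the two foci of
the coordinate system sit on that axis at ``+-focal_length`` from the origin.
A point with prolate coordinates ``(lam, mu, theta)`` maps to local Cartesian

    x1 = f * cosh(lam) * cos(mu)
    x2 = f * sinh(lam) * sin(mu) * cos(theta)
    x3 = f * sinh(lam) * sin(mu) * sin(theta)

with ``lam`` the radial coordinate, ``mu`` the angle from the apical pole
(``mu = 0`` at the apex) and ``theta`` circumferential.  The frame then
rotates and translates local coordinates into world space (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProlateFrame", "prolate_to_cartesian", "cartesian_to_prolate"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class ProlateFrame:
    """Rigid placement and scale of a prolate spheroidal coordinate system.

    Parameters
    ----------
    focal_length : float
        Half-distance between the two foci, mm.  Must be positive.
    origin : (3,) array_like
        World position of the coordinate origin, mm.
    axes : (3, 3) array_like
        Orthonormal rotation matrix; rows are the frame axes expressed in
        world coordinates.  The first row is the long axis (apex side at
        positive local x1).
    """

    focal_length: float = 42.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if not np.isfinite(self.focal_length) or self.focal_length <= 0:
            raise ValueError("focal_length must be finite and > 0")
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix")
        if not np.allclose(axes @ axes.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("axes must be orthonormal (A A^T = I to 1e-9)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        """Map local (..., 3) coordinates into world space."""
        local = np.asarray(local, dtype=float)
        return local @ self.axes + self.origin

    def to_local(self, world: np.ndarray) -> np.ndarray:
        """Map world (..., 3) coordinates into the local frame."""
        world = np.asarray(world, dtype=float)
        return (world - self.origin) @ self.axes.T

    def to_dict(self) -> dict:
        return {
            "focal_length": float(self.focal_length),
            "origin": self.origin.tolist(),
            "axes": self.axes.ravel().tolist(),  # row-major
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProlateFrame":
        return cls(
            focal_length=float(d["focal_length"]),
            origin=np.asarray(d["origin"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float).reshape(3, 3),
        )


def prolate_to_cartesian(lam, mu, theta, frame: ProlateFrame) -> np.ndarray:
    """Convert prolate coordinates to world Cartesian coordinates (mm).

    Broadcasts over array inputs; returns shape (..., 3).
    """
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    f = frame.focal_length
    x1 = f * np.cosh(lam) * np.cos(mu)
    r = f * np.sinh(lam) * np.sin(mu)
    local = np.stack([x1, r * np.cos(theta), r * np.sin(theta)], axis=-1)
    return frame.to_world(local)


def cartesian_to_prolate(points: np.ndarray, frame: ProlateFrame):
    """Invert :func:`prolate_to_cartesian`.

    Uses the focal distances: with ``d+`` and ``d-`` the distances from the
    point to the foci at ``(+f, 0, 0)`` and ``(-f, 0, 0)``,

        cosh(lam) = (d+ + d-) / (2 f),   cos(mu) = (d- - d+) / (2 f).

    Unstable exactly on the long axis (``mu`` in {0, pi}); callers should stay
    away from the axis (see the round-trip tolerance of 1e-8 in the tests).

    Returns
    -------
    lam, mu, theta : ndarray
        Prolate coordinates, broadcast to the leading shape of ``points``.
    """
    local = frame.to_local(points)
    f = frame.focal_length
    x1, x2, x3 = local[..., 0], local[..., 1], local[..., 2]
    rho2 = x2**2 + x3**2
    d_plus = np.sqrt((x1 - f) ** 2 + rho2)
    d_minus = np.sqrt((x1 + f) ** 2 + rho2)
    cosh_lam = (d_plus + d_minus) / (2.0 * f)
    cos_mu = (d_minus - d_plus) / (2.0 * f)
    lam = np.arccosh(np.clip(cosh_lam, 1.0, None))
    mu = np.arccos(np.clip(cos_mu, -1.0, 1.0))
    theta = np.mod(np.arctan2(x3, x2), 2.0 * np.pi)
    return lam, mu, theta
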