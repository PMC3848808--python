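"""AHA 17-segment assignment on the parametric (u, v) domain.

The standard 17-segment model divides the LV into a basal, a mid-cavity and
an apical ring (6, 6 and 4 circumferential sectors) plus the apical cap
(segment 17).  Here the partition is purely parametric and therefore
identical for the endocardial and epicardial surfaces: the apical cap is the
apex-most band ``v < apex_band`` and the three rings split the remaining v
range equally, apical ring first.

Circumferential sectors are anchored to a configurable septal reference
angle: ``theta = septal_angle`` points at the mid-septum (the middle of the
two septal sectors).  Walking counterclockwise (increasing theta = 2*pi*u)
from the anterior wall, the basal/mid sector order is anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral (segments 1-6 / 7-12);
the apical sectors are anterior, septal, inferior, lateral (13-16).
"""

from __future__ import annotations

import numpy as np

__all__ = ["segment_of", "segment_bounds", "DEFAULT_APEX_BAND", "DEFAULT_SEPTAL_ANGLE"]

#: Fraction of the v range forming the apical-cap band (segment 17).
DEFAULT_APEX_BAND = 0.125
#: Angle (radians, in theta = 2*pi*u) of the mid-septum.
DEFAULT_SEPTAL_ANGLE = 0.0

# Basal/mid sector ids in counterclockwise order starting at the
# anterior-anterolateral boundary (phi = 0 defined below).
_BASAL_ORDER = np.array([1, 2, 3, 4, 5, 6])
_MID_ORDER = _BASAL_ORDER + 6
_APICAL_ORDER = np.array([13, 14, 15, 16])


def _phi(u, septal_angle):
    """Sector angle: 0 at the start of the anterior sector, ccw.

    The mid-septum (theta = septal_angle) is placed at the boundary between
    the anteroseptal and inferoseptal sectors, phi = 120 deg, hence
    phi = theta - septal_angle + 2*pi/3.
    """
    theta = 2.0 * np.pi * np.asarray(u, dtype=float)
    return np.mod(theta - septal_angle + 2.0 * np.pi / 3.0, 2.0 * np.pi)


def segment_of(u, v, apex_band: float = DEFAULT_APEX_BAND,
               septal_angle: float = DEFAULT_SEPTAL_ANGLE) -> np.ndarray:
    """Assign AHA segment ids (1..17) to parametric locations.

    Parameters
    ----------
    u, v : array_like in [0, 1)
        Circumferential / apex-to-base parametric coordinates (v = 0 apex).
    apex_band : float
        v threshold below which points belong to the apical cap (segment 17).
    septal_angle : float
        theta of the mid-septum, radians.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("v must lie in [0, 1]")
    seg = np.full(np.broadcast(u, v).shape, 17, dtype=int)
    phi = np.broadcast_to(_phi(u, septal_angle), seg.shape)
    band = (v - apex_band) / (1.0 - apex_band)  # 0..1 over the three rings
    ring = np.clip((band * 3).astype(int), 0, 2)  # 0 apical, 1 mid, 2 basal

    above = np.broadcast_to(v >= apex_band, seg.shape)
    sec6 = np.clip((phi / (np.pi / 3.0)).astype(int), 0, 5)
    # Apical sectors are rotated 45 deg so the septal sector straddles the
    # mid-septum, mirroring the basal/mid anchoring.
    sec4 = np.clip((np.mod(phi + np.pi / 4.0, 2.0 * np.pi)
                    / (np.pi / 2.0)).astype(int), 0, 3)
    seg = np.where(above & (ring == 2), _BASAL_ORDER[sec6], seg)
    seg = np.where(above & (ring == 1), _MID_ORDER[sec6], seg)
    seg = np.where(above & (ring == 0), _APICAL_ORDER[sec4], seg)
    return seg


def segment_bounds(segment_id: int, apex_band: float = DEFAULT_APEX_BAND,
                   septal_angle: float = DEFAULT_SEPTAL_ANGLE):
    """Parametric rectangle [u0, u1) x [v0, v1) of one segment.

    u bounds may wrap past 1 (callers take u mod 1); rectangles of distinct
    segments are disjoint, which guarantees duplicate-free per-segment
    sampling lattices.
    """
    if not 1 <= int(segment_id) <= 17:
        raise ValueError("segment_id must be in 1..17")
    segment_id = int(segment_id)
    if segment_id == 17:
        return (0.0, 1.0), (0.0, apex_band)
    ring_h = (1.0 - apex_band) / 3.0
    if segment_id <= 6:
        ring, sector, n_sec, offset = 2, segment_id - 1, 6, 0.0
    elif segment_id <= 12:
        ring, sector, n_sec, offset = 1, segment_id - 7, 6, 0.0
    else:
        ring, sector, n_sec, offset = 0, segment_id - 13, 4, -np.pi / 4.0
    v0 = apex_band + ring * ring_h
    v1 = v0 + ring_h
    # invert phi -> u:  phi = 2 pi u - septal_angle + 2 pi / 3  (mod 2 pi)
    phi0 = sector * 2.0 * np.pi / n_sec + offset
    u0 = (phi0 + septal_angle - 2.0 * np.pi / 3.0) / (2.0 * np.pi)
    u0 = u0 % 1.0
    u1 = u0 + 1.0 / n_sec
    return (u0, u1), (v0, v1)
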