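"""Planar polygon primitives used by the morphometry stage.

Coordinates are continuous µm with the origin at the lower-left corner of
the microscope field. Outlines are ordered vertex lists describing simple
(non-self-intersecting) polygons.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError

Outline = "np.ndarray"  # (n, 2) float array of vertices


def as_outline(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GeometryError(
            f"an outline needs >=3 (x, y) vertices, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise GeometryError("outline contains non-finite coordinates")
    return arr


def validate_simple_polygon(vertices) -> Polygon:
    """Return the shapely polygon, raising if degenerate or self-intersecting."""
    arr = as_outline(vertices)
    poly = Polygon(arr)
    if not poly.is_valid or poly.area == 0.0:
        raise GeometryError("outline is not a simple polygon (self-intersecting or degenerate)")
    return poly


def polygon_area(vertices) -> float:
    """Absolute (orientation-independent) area of a simple polygon, µm².

    The outline need not be closed; the last vertex connects back to the
    first. Raises :class:`GeometryError` for <3 vertices or a
    self-intersecting outline.
    """
    return validate_simple_polygon(vertices).area


def interior_angles(vertices) -> np.ndarray:
    """Interior angle (radians) at every vertex of a simple polygon."""
    arr = as_outline(vertices)
    validate_simple_polygon(arr)
    # normalise to counter-clockwise so the turn-angle sign convention holds
    if _signed_area(arr) < 0:
        arr = arr[::-1]
    prev = np.roll(arr, 1, axis=0)
    nxt = np.roll(arr, -1, axis=0)
    e_in = arr - prev
    e_out = nxt - arr
    turn = np.arctan2(
        e_in[:, 0] * e_out[:, 1] - e_in[:, 1] * e_out[:, 0],
        (e_in * e_out).sum(axis=1),
    )
    return np.pi - turn


def angularity(vertices, angle_threshold_deg: float = 150.0) -> float:
    """Fraction of interior vertex angles below ``angle_threshold_deg``.

    High angularity corresponds to the thin, angular margins of mature
    squamous cells; near-circular outlines (many shallow vertices) score 0.
    """
    ang = np.degrees(interior_angles(vertices))
    return float(np.mean(ang < angle_threshold_deg))


def _signed_area(arr: np.ndarray) -> float:
    x, y = arr[:, 0], arr[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
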