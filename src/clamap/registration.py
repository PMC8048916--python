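"""Per-slice spatial registration and core/shell classification.

Every slice is aligned to the population of neurons retrogradely labeled
from the reference injection site (retrosplenial cortex): the centroid of
the reference-channel neurons becomes the origin, so every neuron's
coordinate is its displacement from that centroid.  The claustrum *core* is
the convex polygon spanned by the closest 90% of reference neurons to the
centroid; neurons outside the polygon are *dorsal shell* (y >= 0) or
*ventral shell* (y < 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .core_model import CellRecord

logger = logging.getLogger(__name__)

#: Fewest reference neurons needed to form a polygon; slices below this are
#: skipped (and logged) rather than registered.
MIN_REFERENCE_NEURONS = 3


class DegenerateGeometryError(ValueError):
    """The reference points do not span a 2D polygon (e.g. collinear)."""


class InsufficientReferenceError(ValueError):
    """A slice has too few reference-channel neurons to register."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Registration parameters recorded for one slice."""

    slice_id: str
    centroid_x_um: float
    centroid_y_um: float
    rotation_deg: float = 0.0


@dataclass(frozen=True)
class CorePolygon:
    """Convex region spanned by the closest ``keep_fraction`` of reference neurons."""

    vertices: tuple
    keep_fraction: float

    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, x_um: float, y_um: float) -> bool:
        """True if the point is inside or on the polygon boundary."""
        return self.shapely().covers(Point(x_um, y_um))

    @property
    def area_um2(self) -> float:
        return self.shapely().area


def _check_single_slice(cells) -> str:
    slice_ids = {c.slice_id for c in cells}
    if len(slice_ids) != 1:
        raise ValueError(f"cells span multiple slices: {sorted(slice_ids)}")
    return slice_ids.pop()


def rotate_cells(cells, angle_deg: float, center=(0.0, 0.0)) -> list:
    """Rotate one slice's coordinates about ``center`` by ``angle_deg`` (CCW).

    A pure isometry: pairwise distances are preserved.  Used to make the
    dorsoventral axis vertical before registration.
    """
    _check_single_slice(cells)
    theta = math.radians(angle_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    cx, cy = center
    out = []
    for c in cells:
        dx, dy = c.x_um - cx, c.y_um - cy
        out.append(c.moved_to(cx + dx * cos_t - dy * sin_t, cy + dx * sin_t + dy * cos_t))
    return out


def reference_cells(cells, ref_channel: str, hemisphere: str = "ipsi") -> list:
    return [c for c in cells if ref_channel in c.labels and c.hemisphere == hemisphere]


def estimate_rotation(cells, ref_channel: str) -> float:
    """Angle (deg) that makes the reference population's first principal axis vertical.

    Fallback for synthetic or unrotated data; slices imaged with the
    dorsoventral axis already vertical need no rotation and should pass 0.
    """
    ref = reference_cells(cells, ref_channel)
    pts = np.array([[c.x_um, c.y_um] for c in ref])
    if len(pts) < MIN_REFERENCE_NEURONS:
        raise InsufficientReferenceError(
            f"need >= {MIN_REFERENCE_NEURONS} reference neurons, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = eigvecs[:, int(np.argmax(eigvals))]
    # rotate the major axis onto +y
    return math.degrees(math.atan2(major[1], major[0])) * -1 + 90.0


def register_to_reference(cells, ref_channel: str, rotation_deg: float = 0.0):
    """Translate one slice so the reference-channel centroid is the origin.

    Returns the registered cells and the :class:`ReferenceFrame` recording
    the centroid (measured after rotation) and the rotation applied.
    """
    slice_id = _check_single_slice(cells)
    ref = reference_cells(cells, ref_channel)
    if len(ref) < MIN_REFERENCE_NEURONS:
        raise InsufficientReferenceError(
            f"slice {slice_id!r}: {len(ref)} reference neurons "
            f"(need >= {MIN_REFERENCE_NEURONS})"
        )
    if rotation_deg:
        pivot = (
            float(np.mean([c.x_um for c in ref])),
            float(np.mean([c.y_um for c in ref])),
        )
        cells = rotate_cells(cells, rotation_deg, center=pivot)
        ref = reference_cells(cells, ref_channel)
    cx = float(np.mean([c.x_um for c in ref]))
    cy = float(np.mean([c.y_um for c in ref]))
    registered = [c.moved_to(c.x_um - cx, c.y_um - cy) for c in cells]
    return registered, ReferenceFrame(slice_id, cx, cy, rotation_deg)


def core_polygon(ref_points, cell_ids=None, keep_fraction: float = 0.9) -> CorePolygon:
    """Convex hull of the ``keep_fraction`` of reference points closest to the origin.

    Points are ranked by Euclidean distance to the origin of the registered
    frame; ties at the cutoff are broken by ``cell_ids`` order so the
    selection is reproducible.  Because the retained points all lie within
    the radius of the furthest retained one, every dropped point falls
    strictly outside the hull (up to exact radius ties).
    """
    pts = np.asarray(ref_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("ref_points must be an (n, 2) array")
    n = len(pts)
    if n < MIN_REFERENCE_NEURONS:
        raise InsufficientReferenceError(f"need >= {MIN_REFERENCE_NEURONS} points, got {n}")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    radii = np.hypot(pts[:, 0], pts[:, 1])
    if cell_ids is None:
        tiebreak = np.arange(n)
    else:
        tiebreak = np.argsort(np.argsort(np.asarray(cell_ids, dtype=object)))
    order = np.lexsort((tiebreak, radii))
    n_keep = math.ceil(keep_fraction * n)
    kept = pts[order[:n_keep]]
    try:
        hull = ConvexHull(kept)
    except QhullError as exc:
        raise DegenerateGeometryError(f"reference points are degenerate: {exc}") from exc
    vertices = tuple((float(x), float(y)) for x, y in kept[hull.vertices])
    return CorePolygon(vertices=vertices, keep_fraction=keep_fraction)


def classify_zone(x_um: float, y_um: float, polygon: CorePolygon) -> str:
    """Total classification of a registered point into core or shell.

    Inside or on the polygon -> ``core``; outside at or above the reference
    centroid (y >= 0) -> ``dorsal_shell``; outside below -> ``ventral_shell``.
    """
    if polygon.contains(x_um, y_um):
        return "core"
    return "dorsal_shell" if y_um >= 0 else "ventral_shell"


def classify_cells(cells, polygon: CorePolygon) -> list:
    return [c.with_zone(classify_zone(c.x_um, c.y_um, polygon)) for c in cells]


def register_slices(
    cells,
    ref_channel: str,
    keep_fraction: float = 0.9,
    rotation_by_slice=None,
    auto_rotate: bool = False,
):
    """Register and zone-classify a whole cell table, slice by slice.

    Rotation angles come from ``rotation_by_slice`` metadata when provided;
    with ``auto_rotate`` the angle is estimated from the reference
    population's principal axis.  Slices with too few reference neurons are
    skipped with a logged warning.  Returns ``(registered_cells, frames,
    polygons, skipped_slice_ids)``; zone classification uses each slice's
    own core polygon (ipsilateral reference neurons only).
    """
    by_slice: dict = {}
    for c in cells:
        by_slice.setdefault(c.slice_id, []).append(c)
    registered_all: list = []
    frames: dict = {}
    polygons: dict = {}
    skipped: list = []
    for slice_id in sorted(by_slice):
        group = by_slice[slice_id]
        angle = 0.0
        if rotation_by_slice and slice_id in rotation_by_slice:
            angle = rotation_by_slice[slice_id]
        elif auto_rotate:
            try:
                angle = estimate_rotation(group, ref_channel)
            except InsufficientReferenceError:
                angle = 0.0
        try:
            registered, frame = register_to_reference(group, ref_channel, angle)
        except InsufficientReferenceError as exc:
            logger.warning("skipping slice %s: %s", slice_id, exc)
            skipped.append(slice_id)
            continue
        ref = reference_cells(registered, ref_channel)
        poly = core_polygon(
            [(c.x_um, c.y_um) for c in ref],
            cell_ids=[c.cell_id for c in ref],
            keep_fraction=keep_fraction,
        )
        registered_all.extend(classify_cells(registered, poly))
        frames[slice_id] = frame
        polygons[slice_id] = poly
    return registered_all, frames, polygons, skipped
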