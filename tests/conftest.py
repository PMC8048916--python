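"""Shared fixtures and independent oracle implementations.

The oracle helpers here deliberately re-derive results by brute force
(gift-wrapping hull, ray casting, exhaustive threshold search, direct
multiset tabulation) so tests compare the library against an independent
route, not against itself.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from clamap.core_model import CellRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(
    cell_id,
    x,
    y,
    labels,
    slice_id="s1",
    mouse_id="m1",
    rc_level="rostral",
    hemisphere="ipsi",
    **kw,
):
    return CellRecord(
        cell_id=cell_id,
        mouse_id=mouse_id,
        slice_id=slice_id,
        rc_level=rc_level,
        hemisphere=hemisphere,
        x_um=float(x),
        y_um=float(y),
        labels=frozenset(labels),
        **kw,
    )


# ---------------------------------------------------------------------------
# Geometry oracles


def gift_wrap_hull(points):
    """Jarvis-march convex hull; returns vertices in CCW order."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = None
        for p in pts:
            if p == current:
                continue
            if candidate is None:
                candidate = p
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and math.dist(current, p) > math.dist(current, candidate)
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return hull


def polygon_area(vertices):
    """Shoelace formula."""
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def ray_cast_inside(x, y, vertices, eps=1e-9):
    """Point-in-polygon by ray casting; boundary points count as inside."""
    n = len(vertices)
    # boundary check: distance to each segment
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        t = 0.0 if seg2 == 0 else max(0.0, min(1.0, ((x - x1) * dx + (y - y1) * dy) / seg2))
        if math.hypot(x - (x1 + t * dx), y - (y1 + t * dy)) <= eps:
            return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# Statistics oracles


def otsu_exhaustive(values, n_levels=256):
    """Exhaustive threshold search minimizing within-class variance.

    Works on the same n_levels histogram discretization: candidate cuts are
    the histogram bin boundaries; returns the boolean partition (value in
    upper class) that minimizes the weighted within-class variance.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_levels)
    best_cut, best_wcv = None, np.inf
    for i in range(1, n_levels):
        cut = edges[i]
        lower = values[values < cut]
        upper = values[values >= cut]
        if len(lower) == 0 or len(upper) == 0:
            continue
        wcv = len(lower) * lower.var() + len(upper) * upper.var()
        if wcv < best_wcv - 1e-12:
            best_wcv = wcv
            best_cut = cut
    return values >= best_cut


def tabulate_patterns(label_sets, channels):
    """Direct multiset tabulation of exact and uncorrected pattern counts."""
    from itertools import chain, combinations

    channels = sorted(channels)
    patterns = [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(channels, k) for k in range(1, len(channels) + 1)
        )
    ]
    exact = {p: sum(1 for s in label_sets if frozenset(s) == p) for p in patterns}
    uncorrected = {
        p: sum(1 for s in label_sets if p <= frozenset(s)) for p in patterns
    }
    return exact, uncorrected
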