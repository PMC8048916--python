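"""Binned spatial density maps, module boundaries, and topography summaries.

Densities are raw 2D histograms on a 30 μm × 30 μm grid anchored at the
registered origin (the reference-pathway centroid): bin edges fall on
integer multiples of the bin size and bins are half-open ``[edge, edge +
bin)``.  Module outlines are extracted by Otsu thresholding of the binned
density values; spatial overlap between two modules is the jointly occupied
area divided by the *sum* of the two module areas (so complete overlap
scores 0.5, not 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core_model import RC_LEVELS

logger = logging.getLogger(__name__)

DEFAULT_BIN_UM = 30.0


@dataclass
class DensityMap:
    """Grid of per-bin counts (or averaged densities) in the registered frame.

    ``grid[i, j]`` covers x in ``[ (x0+j)*b, (x0+j+1)*b )`` and y in
    ``[ (y0+i)*b, (y0+i+1)*b )`` where ``b`` is the bin size and
    ``(x0, y0)`` the integer bin offset of the grid corner.
    """

    bin_size_um: float
    x0_bin: int
    y0_bin: int
    grid: np.ndarray

    @property
    def x_edges(self) -> np.ndarray:
        nx = self.grid.shape[1]
        return (self.x0_bin + np.arange(nx + 1)) * self.bin_size_um

    @property
    def y_edges(self) -> np.ndarray:
        ny = self.grid.shape[0]
        return (self.y0_bin + np.arange(ny + 1)) * self.bin_size_um

    @property
    def extent(self) -> tuple:
        return (self.x_edges[0], self.x_edges[-1], self.y_edges[0], self.y_edges[-1])

    def same_grid(self, other: "DensityMap") -> bool:
        return (
            self.bin_size_um == other.bin_size_um
            and self.x0_bin == other.x0_bin
            and self.y0_bin == other.y0_bin
            and self.grid.shape == other.grid.shape
        )


@dataclass
class ModuleMask:
    """Boolean module outline aligned to a :class:`DensityMap` grid.

    ``mask`` is True exactly where the density is >= ``threshold``.
    """

    threshold: float
    mask: np.ndarray
    bin_size_um: float
    x0_bin: int
    y0_bin: int

    def same_grid(self, other: "ModuleMask") -> bool:
        return (
            self.bin_size_um == other.bin_size_um
            and self.x0_bin == other.x0_bin
            and self.y0_bin == other.y0_bin
            and self.mask.shape == other.mask.shape
        )

    @property
    def area_bins(self) -> int:
        return int(self.mask.sum())


def density_map(
    points,
    bin_size_um: float = DEFAULT_BIN_UM,
    grid_spec: tuple | None = None,
    pad_bins: int = 1,
) -> DensityMap:
    """Histogram registered points on an origin-anchored grid.

    The extent is the bounding box of the points expanded by ``pad_bins``
    bins on each side, unless a shared ``grid_spec`` (x0_bin, y0_bin, ny,
    nx) is supplied.  Conservation: the grid total equals the number of
    points inside the extent.
    """
    if bin_size_um <= 0:
        raise ValueError("bin_size_um must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    ix = np.floor(pts[:, 0] / bin_size_um).astype(int)
    iy = np.floor(pts[:, 1] / bin_size_um).astype(int)
    if grid_spec is None:
        x0 = int(ix.min()) - pad_bins
        y0 = int(iy.min()) - pad_bins
        nx = int(ix.max()) - x0 + 1 + pad_bins
        ny = int(iy.max()) - y0 + 1 + pad_bins
    else:
        x0, y0, ny, nx = grid_spec
    grid = np.zeros((ny, nx), dtype=float)
    inside = (ix >= x0) & (ix < x0 + nx) & (iy >= y0) & (iy < y0 + ny)
    np.add.at(grid, (iy[inside] - y0, ix[inside] - x0), 1.0)
    return DensityMap(bin_size_um=float(bin_size_um), x0_bin=x0, y0_bin=y0, grid=grid)


def _points_of(cells) -> np.ndarray:
    return np.array([[c.x_um, c.y_um] for c in cells], dtype=float)


def pathway_density_maps(
    cells,
    bin_size_um: float = DEFAULT_BIN_UM,
    hemisphere: str = "ipsi",
    normalize_peak: bool = True,
) -> dict:
    """Average per-pathway density maps on one shared grid.

    Per-slice count maps are averaged across the slices of each mouse, then
    across mice, then (optionally) rescaled to peak 1 — so a mouse with
    more slices or neurons does not dominate the group map.  A multi-label
    neuron contributes to every pathway it is labeled for.
    """
    cells = [c for c in cells if c.hemisphere == hemisphere]
    if not cells:
        raise ValueError("no cells in the requested hemisphere")
    all_pts = _points_of(cells)
    shared = density_map(all_pts, bin_size_um)
    spec = (shared.x0_bin, shared.y0_bin) + shared.grid.shape
    channels = sorted({ch for c in cells for ch in c.labels})
    out = {}
    for ch in channels:
        mouse_maps = []
        by_mouse: dict = {}
        for c in cells:
            if ch in c.labels:
                by_mouse.setdefault(c.mouse_id, {}).setdefault(c.slice_id, []).append(c)
        for mouse_id in sorted(by_mouse):
            slice_maps = [
                density_map(_points_of(group), bin_size_um, grid_spec=spec).grid
                for group in by_mouse[mouse_id].values()
            ]
            mouse_maps.append(np.mean(slice_maps, axis=0))
        grid = np.mean(mouse_maps, axis=0)
        if normalize_peak and grid.max() > 0:
            grid = grid / grid.max()
        out[ch] = DensityMap(
            bin_size_um=float(bin_size_um),
            x0_bin=shared.x0_bin,
            y0_bin=shared.y0_bin,
            grid=grid,
        )
    return out


def otsu_boundary(dmap: DensityMap, n_levels: int = 256) -> ModuleMask:
    """Outline a projection module by Otsu thresholding the bin densities.

    The threshold maximizes the between-class variance of the ``n_levels``-bin
    histogram of density values (empty bins inside the extent included);
    the mask is True where density >= threshold.  The returned threshold is
    the smallest density value in the upper class, so ``mask == (grid >=
    threshold)`` holds exactly.
    """
    values = dmap.grid.ravel()
    if np.unique(values).size < 2:
        raise ValueError("density map is constant; no threshold separates two classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cut = threshold_otsu(values, nbins=n_levels)
    upper = values[values > cut]
    threshold = float(upper.min())
    return ModuleMask(
        threshold=threshold,
        mask=dmap.grid >= threshold,
        bin_size_um=dmap.bin_size_um,
        x0_bin=dmap.x0_bin,
        y0_bin=dmap.y0_bin,
    )


def spatial_overlap(mask_a: ModuleMask, mask_b: ModuleMask) -> float:
    """Jointly occupied area over the sum of both module areas; range [0, 0.5]."""
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks are on different grids")
    total = mask_a.area_bins + mask_b.area_bins
    if total == 0:
        raise ValueError("both masks are empty; overlap is undefined")
    joint = int(np.logical_and(mask_a.mask, mask_b.mask).sum())
    return joint / total


def axis_histograms(
    cells,
    bin_size_um: float = DEFAULT_BIN_UM,
    hemisphere: str = "ipsi",
) -> dict:
    """Normalized per-pathway distributions along DV, ML, and RC axes.

    All pathways share common dorsoventral/mediolateral bin edges (anchored
    at the origin) so profiles are directly comparable; each histogram sums
    to 1.  Pathways with no cells are excluded with a warning.
    """
    cells = [c for c in cells if c.hemisphere == hemisphere]
    if not cells:
        raise ValueError("no cells in the requested hemisphere")
    pts = _points_of(cells)
    x_edges = (
        np.arange(
            np.floor(pts[:, 0].min() / bin_size_um),
            np.floor(pts[:, 0].max() / bin_size_um) + 2,
        )
        * bin_size_um
    )
    y_edges = (
        np.arange(
            np.floor(pts[:, 1].min() / bin_size_um),
            np.floor(pts[:, 1].max() / bin_size_um) + 2,
        )
        * bin_size_um
    )
    channels = sorted({ch for c in cells for ch in c.labels})
    out = {}
    for ch in channels:
        sub = [c for c in cells if ch in c.labels]
        if not sub:
            logger.warning("pathway %s has no cells; excluded", ch)
            continue
        xs = np.array([c.x_um for c in sub])
        ys = np.array([c.y_um for c in sub])
        # np.histogram treats the last bin as closed; the extra trailing bin
        # added above keeps every interior edge half-open.
        ml, _ = np.histogram(xs, bins=x_edges)
        dv, _ = np.histogram(ys, bins=y_edges)
        rc = np.array([sum(c.rc_level == lvl for c in sub) for lvl in RC_LEVELS])
        out[ch] = {
            "ml_edges": x_edges,
            "ml": ml / ml.sum(),
            "dv_edges": y_edges,
            "dv": dv / dv.sum(),
            "rc_levels": RC_LEVELS,
            "rc": rc / rc.sum(),
        }
    return out


def core_shell_proportions(cells, hemisphere: str = "ipsi") -> pd.DataFrame:
    """Zone percentages and per-slice counts per (pathway, rostrocaudal level).

    Requires zone-classified cells.  Percentages sum to 100 within each row;
    a multi-label neuron is counted under every pathway it is labeled for.
    """
    rows = []
    cells = [c for c in cells if c.hemisphere == hemisphere]
    channels = sorted({ch for c in cells for ch in c.labels})
    for ch in channels:
        for rc in RC_LEVELS:
            sub = [c for c in cells if ch in c.labels and c.rc_level == rc]
            if not sub:
                continue
            if any(c.zone is None for c in sub):
                raise ValueError("cells must be zone-classified first")
            n = len(sub)
            per_slice = pd.Series([c.slice_id for c in sub]).value_counts()
            rows.append(
                {
                    "pathway": ch,
                    "rc_level": rc,
                    "n_neurons": n,
                    "pct_dorsal_shell": 100.0 * sum(c.zone == "dorsal_shell" for c in sub) / n,
                    "pct_core": 100.0 * sum(c.zone == "core" for c in sub) / n,
                    "pct_ventral_shell": 100.0 * sum(c.zone == "ventral_shell" for c in sub) / n,
                    "slice_count_mean": float(per_slice.mean()),
                    "slice_count_sd": float(per_slice.std(ddof=1)) if len(per_slice) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def contra_ipsi_ratio(cells) -> pd.DataFrame:
    """Contralateral/ipsilateral labeling ratio per mouse and pathway.

    Counts are pooled over slices within a mouse; a pathway with zero
    ipsilateral neurons yields a missing (NaN) ratio.
    """
    rows = []
    mice = sorted({c.mouse_id for c in cells})
    for mouse in mice:
        sub = [c for c in cells if c.mouse_id == mouse]
        channels = sorted({ch for c in sub for ch in c.labels})
        for ch in channels:
            n_ipsi = sum(ch in c.labels and c.hemisphere == "ipsi" for c in sub)
            n_contra = sum(ch in c.labels and c.hemisphere == "contra" for c in sub)
            ratio = n_contra / n_ipsi if n_ipsi > 0 else float("nan")
            rows.append(
                {
                    "mouse_id": mouse,
                    "pathway": ch,
                    "n_ipsi": n_ipsi,
                    "n_contra": n_contra,
                    "contra_ipsi_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
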