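"""Interneuron topography relative to the claustrum core/shell frame.

PV, SST, and NPY cells are counted in regions of interest (claustrum core,
shell, and surrounding structures) together with the mean neuropil
fluorescence of each marker.  This module computes areal densities,
between-marker ratios, subtype overlap (the same Jaccard formula used for
co-projections), and correlations between binned spatial profiles.

Interneuron somata reuse :class:`~clamap.core_model.CellRecord` with
``cell_class`` set and the marker channel in ``labels``, so the
registration and zone machinery applies to them unchanged.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model import FormatError, _read_delimited
from .coprojection import jaccard_rate

ROI_NAMES = ("core", "shell", "insula", "piriform", "striatum", "somatosensory_cortex")

ROI_TABLE_COLUMNS = ("slice_id", "roi", "cell_class", "area_mm2", "count")


def area_density(count: float, area_mm2: float) -> float:
    """Cells per mm²."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_mm2


def normalized_neuropil(core_value: float, shell_value: float, norm: str = "max") -> tuple:
    """Normalize a marker's core/shell neuropil fluorescence to [0, 1].

    ``max`` divides both by the larger of the two (the slice's brightest
    ROI for that marker); ``sum`` divides by their total.  Both strategies
    preserve the core/shell ordering.
    """
    if core_value < 0 or shell_value < 0:
        raise ValueError("fluorescence values must be non-negative")
    if core_value == 0 and shell_value == 0:
        raise ValueError("both values zero; normalization undefined")
    if norm == "max":
        denom = max(core_value, shell_value)
    elif norm == "sum":
        denom = core_value + shell_value
    else:
        raise ValueError(f"unknown normalization strategy {norm!r}")
    return core_value / denom, shell_value / denom


def subtype_overlap(count_a: int, count_b: int, count_ab: int) -> float:
    """Overlap of two interneuron classes: AB / (A + B − AB).

    Identical, input for input, to the co-projection rate.
    """
    return jaccard_rate(count_a, count_b, count_ab)


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson r between two equal-length binned spatial profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1D arrays")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile; correlation undefined")
    r, _ = sps.pearsonr(a, b)
    return float(r)


def load_roi_table(path) -> pd.DataFrame:
    """Read a per-slice ROI measurement table (delimited text).

    Columns: slice_id, roi, cell_class, area_mm2, count, and optionally
    neuropil_fluorescence.
    """
    df = _read_delimited(path)
    missing = [c for c in ROI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ROI table {path} missing columns: {missing}")
    df["area_mm2"] = df["area_mm2"].astype(float)
    df["count"] = df["count"].astype(float)
    if "neuropil_fluorescence" in df.columns:
        df["neuropil_fluorescence"] = pd.to_numeric(
            df["neuropil_fluorescence"], errors="coerce"
        )
    bad_roi = set(df["roi"]) - set(ROI_NAMES)
    if bad_roi:
        raise ValueError(f"unknown ROI names: {sorted(bad_roi)}")
    return df


def density_table(roi_df: pd.DataFrame, roi: str | None = None) -> pd.DataFrame:
    """Per-class mean ± SD areal density across slices (optionally one ROI)."""
    df = roi_df if roi is None else roi_df[roi_df["roi"] == roi]
    df = df.assign(density=df["count"] / df["area_mm2"])
    out = (
        df.groupby("cell_class")["density"]
        .agg(density_mean="mean", density_sd="std", n_slices="count")
        .reset_index()
    )
    out["density_sd"] = out["density_sd"].fillna(0.0)
    return out


def density_ratio_table(roi_df: pd.DataFrame, reference_class: str = "PV") -> pd.DataFrame:
    """Per-ROI density of each class relative to ``reference_class``.

    Ratios of densities are invariant to the area unit, so they compare
    regions with differently sized ROIs directly.
    """
    df = roi_df.assign(density=roi_df["count"] / roi_df["area_mm2"])
    mean_density = df.groupby(["roi", "cell_class"])["density"].mean().unstack()
    if reference_class not in mean_density.columns:
        raise ValueError(f"reference class {reference_class!r} absent from table")
    rows = []
    for roi_name, row in mean_density.iterrows():
        ref = row[reference_class]
        for cls in mean_density.columns:
            if cls == reference_class:
                continue
            rows.append(
                {
                    "roi": roi_name,
                    "ratio": f"{cls}:{reference_class}",
                    "value": row[cls] / ref if ref > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def overlap_matrix(counts: dict, pair_counts: dict) -> pd.DataFrame:
    """Overlap fraction for every pair of interneuron classes.

    ``counts`` maps class -> soma count; ``pair_counts`` maps frozenset
    pairs -> double-labeled count (missing pairs default to 0).
    """
    rows = []
    for a, b in combinations(sorted(counts), 2):
        ab = pair_counts.get(frozenset((a, b)), 0)
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "overlap": subtype_overlap(counts[a], counts[b], ab),
            }
        )
    return pd.DataFrame(rows)
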