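"""Bundled reference tables.

Three small text tables ship with the package:

* ``injection_sites.csv`` — the 14 cortical injection regions with their
  stereotaxic coordinates (AP/ML in mm from bregma, DV in mm from brain
  surface) and the tracers used at each site.
* ``zone_fractions.csv`` — per-slice neuron counts (mean ± SD) and the
  dorsal-shell / core / ventral-shell percentages of each claustrocortical
  pathway at rostral, intermediate, and caudal levels.
* ``multicolor_counts.csv`` — uncorrected labeling-pattern counts for the 17
  multicolor tracing experiments; a neuron contributes to the count of every
  subset of its label set.  Blank region/count entries mark off-target
  injections whose channel was not analyzed.
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations

import pandas as pd

from .core_model import (
    ChannelSpec,
    RegionCatalog,
    TracingExperiment,
    canonical_region,
)

#: Channel tokens in the order the multicolor count table uses them.
CHANNEL_ORDER = ("A", "B", "C", "D")

#: Tracer loaded in each channel of the multicolor experiments.
CHANNEL_TRACER = {
    "A": "FB",
    "B": "CTB647",
    "C": "rAAV2-GFP",
    "D": "rAAV2-tdTomato",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("clamap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def load_region_catalog() -> RegionCatalog:
    return RegionCatalog.default()


def load_zone_fractions() -> pd.DataFrame:
    df = _read("zone_fractions.csv")
    num = [c for c in df.columns if c not in ("region", "rc_level")]
    df[num] = df[num].astype(float)
    df["region"] = df["region"].map(canonical_region)
    return df


def load_multicolor_counts() -> pd.DataFrame:
    """The per-mouse uncorrected pattern-count table (empty string = off target)."""
    return _read("multicolor_counts.csv")


def _pattern_columns():
    cols = []
    for k in range(1, 5):
        for combo in combinations(CHANNEL_ORDER, k):
            cols.append("".join(combo))
    return cols


def experiments_from_counts(df: pd.DataFrame | None = None) -> list:
    """Build :class:`TracingExperiment` metadata from the multicolor count table."""
    if df is None:
        df = load_multicolor_counts()
    experiments = []
    for row in df.itertuples(index=False):
        channels = {}
        off_target = set()
        for ch in CHANNEL_ORDER:
            region = getattr(row, f"region_{ch.lower()}")
            if region:
                channels[ch] = ChannelSpec(CHANNEL_TRACER[ch], region)
            # A missing region means the channel was not used or was off
            # target; either way it carries no analyzable pathway.
        experiments.append(
            TracingExperiment(
                mouse_id=row.mouse_id,
                sex=row.sex or None,
                channels=channels,
                off_target=frozenset(off_target),
            )
        )
    return experiments


def uncorrected_counts_for_mouse(mouse_id: str, df: pd.DataFrame | None = None) -> dict:
    """Uncorrected pattern counts for one mouse, keyed by frozenset of channels.

    Only patterns whose every channel was analyzed for that mouse are
    returned, so two-, three-, and four-channel experiments all yield a
    complete ``2^k - 1`` pattern table over their analyzed channels.
    """
    if df is None:
        df = load_multicolor_counts()
    match = df[df["mouse_id"] == mouse_id]
    if match.empty:
        raise KeyError(f"mouse {mouse_id!r} not in the bundled count table")
    row = match.iloc[0]
    analyzed = [ch for ch in CHANNEL_ORDER if row[f"region_{ch.lower()}"]]
    counts = {}
    for col in _pattern_columns():
        if not set(col) <= set(analyzed):
            continue
        value = row[col]
        if value == "":
            continue
        counts[frozenset(col)] = int(value.replace(",", ""))
    return counts


def channel_regions_for_mouse(mouse_id: str, df: pd.DataFrame | None = None) -> dict:
    if df is None:
        df = load_multicolor_counts()
    match = df[df["mouse_id"] == mouse_id]
    if match.empty:
        raise KeyError(f"mouse {mouse_id!r} not in the bundled count table")
    row = match.iloc[0]
    return {
        ch: canonical_region(row[f"region_{ch.lower()}"])
        for ch in CHANNEL_ORDER
        if row[f"region_{ch.lower()}"]
    }


def mouse_ids() -> list:
    return list(load_multicolor_counts()["mouse_id"])


def pooled_multi_target_percentage(
    mice=("M58", "M59"), min_labels: int = 3
) -> float:
    """Percentage of distinct neurons labeled by >= ``min_labels`` tracers.

    Converts each mouse's uncorrected pattern counts to exact counts by
    inclusion–exclusion, pools neurons across the given mice, and returns
    100 × (neurons with >= min_labels labels) / (distinct neurons).  The
    default mice are the two four-tracer midline-injection experiments.
    Manual double counts can Möbius-invert to small negative values, so the
    non-strict inversion is used; the union and higher-order counts are
    unaffected.
    """
    from .coprojection import inclusion_exclusion

    total = union_total = 0
    for mouse in mice:
        unc = uncorrected_counts_for_mouse(mouse)
        exact, union = inclusion_exclusion(unc, strict=False)
        total += sum(v for s, v in exact.items() if len(s) >= min_labels)
        union_total += union
    if union_total == 0:
        raise ValueError("no neurons in the selected experiments")
    return 100.0 * total / union_total
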