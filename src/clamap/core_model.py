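"""Domain types and tabular readers/writers shared by all analysis stages.

The package operates on per-slice tables of retrogradely labeled neurons.
Each neuron is a 2D point (μm) in a coronal slice, carrying the set of
imaging channels in which it was detected.  Channels map, per mouse, to a
retrograde tracer and the cortical region it was injected into.  All spatial
coordinates follow the convention: x increases laterally, y increases
dorsally; the rostrocaudal position is categorical (rostral / intermediate /
caudal slice groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RC_LEVELS = ("rostral", "intermediate", "caudal")
HEMISPHERES = ("ipsi", "contra")
CELL_CLASSES = ("projection", "PV", "SST", "NPY")
TRACERS = ("FB", "CTB647", "rAAV2-GFP", "rAAV2-tdTomato")
ZONES = ("core", "dorsal_shell", "ventral_shell")

#: Alternate spellings of the rostral/caudal retrosplenial injection sites.
REGION_SYNONYMS = {"aRSP": "rRSP", "pRSP": "cRSP"}

CELL_TABLE_COLUMNS = (
    "cell_id",
    "mouse_id",
    "slice_id",
    "rc_level",
    "hemisphere",
    "x_um",
    "y_um",
    "labels",
)


class FormatError(ValueError):
    """A tabular input does not have the expected layout."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


class ConfigurationError(ValueError):
    """An experiment or generator configuration is inconsistent."""


def canonical_region(name: str) -> str:
    """Resolve alternate region spellings to their canonical token."""
    name = name.strip()
    return REGION_SYNONYMS.get(name, name)


@dataclass(frozen=True)
class CellRecord:
    """One labeled neuron in one coronal slice.

    ``labels`` is the non-empty set of imaging channels in which the neuron
    was detected; a multi-label record represents a neuron co-projecting to
    the regions those channels trace.  ``zone`` is filled in after
    registration (core / dorsal_shell / ventral_shell).
    """

    cell_id: str
    mouse_id: str
    slice_id: str
    rc_level: str
    hemisphere: str
    x_um: float
    y_um: float
    labels: frozenset
    cell_class: str | None = None
    zone: str | None = None

    def __post_init__(self):
        if self.rc_level not in RC_LEVELS:
            raise ValidationError(
                f"unknown rc_level {self.rc_level!r} for cell {self.cell_id!r}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"unknown hemisphere {self.hemisphere!r} for cell {self.cell_id!r}"
            )
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValidationError(f"non-finite coordinates for cell {self.cell_id!r}")
        if not self.labels:
            raise ValidationError(f"empty label set for cell {self.cell_id!r}")
        if self.cell_class is not None and self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"unknown cell_class {self.cell_class!r} for cell {self.cell_id!r}"
            )
        if self.zone is not None and self.zone not in ZONES:
            raise ValidationError(f"unknown zone {self.zone!r} for cell {self.cell_id!r}")
        object.__setattr__(self, "labels", frozenset(self.labels))

    def moved_to(self, x_um: float, y_um: float) -> "CellRecord":
        return replace(self, x_um=x_um, y_um=y_um)

    def with_zone(self, zone: str) -> "CellRecord":
        return replace(self, zone=zone)


@dataclass(frozen=True)
class ChannelSpec:
    tracer: str
    region: str

    def __post_init__(self):
        if self.tracer not in TRACERS:
            raise ValidationError(f"unknown tracer {self.tracer!r}")
        object.__setattr__(self, "region", canonical_region(self.region))


@dataclass(frozen=True)
class TracingExperiment:
    """Per-mouse mapping of imaging channels to tracers and injected regions.

    ``off_target`` channels had injection sites outside the intended region
    and are excluded from analysis.
    """

    mouse_id: str
    channels: Mapping[str, ChannelSpec]
    sex: str | None = None
    off_target: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "channels", dict(self.channels))
        object.__setattr__(self, "off_target", frozenset(self.off_target))
        if not 2 <= len(self.channels) <= 4:
            raise ValidationError(
                f"experiment {self.mouse_id!r}: expected 2-4 channels, "
                f"got {len(self.channels)}"
            )
        regions = [spec.region for spec in self.channels.values()]
        if len(set(regions)) != len(regions):
            raise ValidationError(
                f"experiment {self.mouse_id!r}: injected regions must be distinct"
            )
        if not self.off_target < set(self.channels):
            raise ValidationError(
                f"experiment {self.mouse_id!r}: off_target must be a proper "
                "subset of the declared channels"
            )

    @property
    def analyzed_channels(self) -> tuple:
        return tuple(c for c in self.channels if c not in self.off_target)

    @property
    def analyzed_regions(self) -> tuple:
        return tuple(self.channels[c].region for c in self.analyzed_channels)


class RegionCatalog:
    """The 14-region cortical injection vocabulary with stereotaxic coordinates.

    Coordinates are AP/ML in mm from bregma and DV in mm from brain surface.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"region", "ap_mm", "ml_mm", "dv_mm"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"region catalog missing columns: {sorted(missing)}")
        table = table.copy()
        table["region"] = table["region"].map(canonical_region)
        if table["region"].duplicated().any():
            raise ValidationError("duplicate region names in catalog")
        self._table = table.set_index("region")

    @classmethod
    def default(cls) -> "RegionCatalog":
        with resources.files("clamap.data").joinpath("injection_sites.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @property
    def regions(self) -> tuple:
        return tuple(self._table.index)

    def __contains__(self, region: str) -> bool:
        return canonical_region(region) in self._table.index

    def __len__(self) -> int:
        return len(self._table)

    def coordinates(self, region: str) -> np.ndarray:
        region = canonical_region(region)
        if region not in self._table.index:
            raise KeyError(f"region {region!r} not in catalog")
        row = self._table.loc[region]
        return np.array([row["ap_mm"], row["ml_mm"], row["dv_mm"]], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self._table.reset_index()


class ConnectivityTable:
    """Directed corticocortical projection strengths and their symmetrization.

    The input is a directed (source, target, strength) table; the analysis
    uses the mean of the two directions of each unordered pair as a single
    connectivity value.  A pair observed in only one direction keeps that
    sole observation.
    """

    def __init__(self, directed: Mapping[tuple, float]):
        self.directed = {}
        for (src, tgt), val in directed.items():
            key = (canonical_region(src), canonical_region(tgt))
            if val < 0:
                raise ValidationError(f"negative strength for pair {key}")
            if key in self.directed:
                raise ValidationError(f"duplicate ordered pair {key}")
            self.directed[key] = float(val)

    def symmetrized(self) -> dict:
        grouped: dict = {}
        for (src, tgt), val in self.directed.items():
            grouped.setdefault(frozenset((src, tgt)), []).append(val)
        return {pair: float(np.mean(vals)) for pair, vals in grouped.items()}

    def value(self, region_a: str, region_b: str) -> float:
        pair = frozenset((canonical_region(region_a), canonical_region(region_b)))
        sym = self.symmetrized()
        if pair not in sym:
            raise KeyError(f"no connectivity entry for pair {sorted(pair)}")
        return sym[pair]


# ---------------------------------------------------------------------------
# Tabular IO


def _read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-separated table, sniffing the delimiter."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_cell_table(path, channels: Iterable[str] | None = None) -> list:
    """Parse a delimited cell table into :class:`CellRecord` objects.

    ``channels``, when given, is the experiment's declared channel set;
    label tokens outside it raise a :class:`ValidationError` naming the row.
    Row order is preserved.
    """
    df = _read_delimited(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path} missing mandatory columns: {missing}")
    channel_set = set(channels) if channels is not None else None
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        labels = frozenset(tok for tok in str(row.labels).split(";") if tok)
        if channel_set is not None and not labels <= channel_set:
            bad = sorted(labels - channel_set)
            raise ValidationError(f"row {i}: labels {bad} not among declared channels")
        cell_class = getattr(row, "cell_class", "") or None
        zone = getattr(row, "zone", "") or None
        try:
            records.append(
                CellRecord(
                    cell_id=row.cell_id,
                    mouse_id=row.mouse_id,
                    slice_id=row.slice_id,
                    rc_level=row.rc_level,
                    hemisphere=row.hemisphere,
                    x_um=float(row.x_um),
                    y_um=float(row.y_um),
                    labels=labels,
                    cell_class=cell_class,
                    zone=zone,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def cells_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "mouse_id": r.mouse_id,
                "slice_id": r.slice_id,
                "rc_level": r.rc_level,
                "hemisphere": r.hemisphere,
                "x_um": repr(float(r.x_um)),
                "y_um": repr(float(r.y_um)),
                "labels": ";".join(sorted(r.labels)),
                "cell_class": r.cell_class or "",
                "zone": r.zone or "",
            }
        )
    return pd.DataFrame(
        rows, columns=list(CELL_TABLE_COLUMNS) + ["cell_class", "zone"]
    )


def write_cell_table(records: Sequence[CellRecord], path, sep: str = ",") -> None:
    """Write records in canonical form (sorted labels, shortest-round-trip floats)."""
    cells_to_frame(records).to_csv(path, sep=sep, index=False)


def load_connectivity_table(path) -> ConnectivityTable:
    """Read a directed (source, target, strength) table."""
    df = _read_delimited(path)
    missing = [c for c in ("source", "target", "strength") if c not in df.columns]
    if missing:
        raise FormatError(f"connectivity table {path} missing columns: {missing}")
    directed: dict = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (canonical_region(row.source), canonical_region(row.target))
        if key in directed:
            raise ValidationError(f"row {i}: duplicate ordered pair {key}")
        strength = float(row.strength)
        if strength < 0:
            raise ValidationError(f"row {i}: negative strength {strength}")
        directed[key] = strength
    return ConnectivityTable(directed)
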