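"""Reproducible end-to-end pipeline: simulate → register → density → coproject → stats.

Each stage is a thin wrapper over the library modules that reads/writes
delimited text, so any stage can also be run standalone from the CLI.  A
single seed drives all randomness; rerunning a configuration reproduces
every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import load_cell_table, write_cell_table
from .coprojection import (
    multi_target_fraction,
    pairwise_jaccard,
    pattern_counts_from_label_sets,
)
from .density import (
    contra_ipsi_ratio,
    core_shell_proportions,
    otsu_boundary,
    pathway_density_maps,
    spatial_overlap,
)
from .registration import register_slices
from .stats import correlate_grand_means
from .synthetic import default_coprojection, default_pathways, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed or the stage DAG is inconsistent."""


@dataclass
class PipelineConfig:
    """Parameters, paths, seed, and stage toggles for one pipeline run."""

    out_dir: str = "clamap_out"
    seed: int = 0
    cell_table: str | None = None  # input; omit to simulate
    ref_channel: str = "iRSP"
    bin_size_um: float = 30.0
    match_radius_um: float = 50.0
    keep_fraction: float = 0.9
    otsu_levels: int = 256
    simulate_regions: list = field(
        default_factory=lambda: ["iRSP", "PL", "ALM", "ENTl"]
    )
    n_mice: int = 3
    n_slices: int = 2
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "register": True,
            "density": True,
            "coproject": True,
            "stats": True,
        }
    )

    def __post_init__(self):
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must be in (0, 1)")
        for name in ("bin_size_um", "match_radius_um", "otsu_levels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _check_dag(config: PipelineConfig):
    s = config.stages
    have_cells = s.get("simulate") or config.cell_table
    if s.get("register") and not have_cells:
        raise PipelineError("register requires simulated cells or an input cell_table")
    for stage in ("density", "coproject", "stats"):
        if s.get(stage) and not s.get("register"):
            raise PipelineError(f"{stage} requires the register stage")


def _round(x, nd=6):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write all outputs under ``config.out_dir``.

    Returns the machine-readable summary that is also written to
    ``summary.json``.
    """
    _check_dag(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    if config.stages.get("simulate"):
        pathways = default_pathways(config.simulate_regions, reference_region=config.ref_channel)
        coproj = default_coprojection(pathways)
        configs = [
            {
                "pathways": pathways,
                "coproj": coproj,
                "n_slices": config.n_slices,
                "mouse_id": f"SIM{k:02d}",
                "reference_region": config.ref_channel,
                "keep_fraction": config.keep_fraction,
            }
            for k in range(config.n_mice)
        ]
        cells, truths = generate_cohort(configs, seed=config.seed)
        write_cell_table(cells, out / "cells.csv")
        pd.concat(
            [t.neurons.assign(mouse_id=mid) for mid, t in truths.items()],
            ignore_index=True,
        ).to_csv(out / "ground_truth.csv", index=False)
        summary["stages"]["simulate"] = {
            "n_mice": config.n_mice,
            "n_cells": len(cells),
        }
    else:
        cells = load_cell_table(config.cell_table)

    # --- register -----------------------------------------------------------
    if config.stages.get("register"):
        registered, frames, polygons, skipped = register_slices(
            cells, config.ref_channel, keep_fraction=config.keep_fraction
        )
        write_cell_table(registered, out / "registered.csv")
        pd.DataFrame(
            [
                {
                    "slice_id": f.slice_id,
                    "centroid_x_um": f.centroid_x_um,
                    "centroid_y_um": f.centroid_y_um,
                    "rotation_deg": f.rotation_deg,
                }
                for f in frames.values()
            ]
        ).to_csv(out / "frames.csv", index=False)
        summary["stages"]["register"] = {
            "n_slices": len(frames),
            "skipped_slices": sorted(skipped),
        }
    else:
        registered = cells

    # --- density ------------------------------------------------------------
    if config.stages.get("density"):
        proportions = core_shell_proportions(registered)
        proportions.to_csv(out / "zone_proportions.csv", index=False)
        ratios = contra_ipsi_ratio(registered)
        ratios.to_csv(out / "contra_ipsi.csv", index=False)
        maps = pathway_density_maps(registered, bin_size_um=config.bin_size_um)
        masks = {}
        for ch, dmap in maps.items():
            np.savetxt(out / f"density_{ch}.txt", dmap.grid, fmt="%.6g")
            try:
                masks[ch] = otsu_boundary(dmap, n_levels=config.otsu_levels)
                np.savetxt(
                    out / f"mask_{ch}.txt", masks[ch].mask.astype(int), fmt="%d"
                )
            except ValueError:
                logger.warning("no module boundary for pathway %s", ch)
        overlaps = {}
        names = sorted(masks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlaps[f"{a}|{b}"] = spatial_overlap(masks[a], masks[b])
        summary["stages"]["density"] = {
            "pathways": names,
            "spatial_overlap": {k: _round(v) for k, v in overlaps.items()},
        }

    # --- coproject ----------------------------------------------------------
    if config.stages.get("coproject"):
        jaccard_rows = []
        pattern_rows = []
        mice = sorted({c.mouse_id for c in registered})
        channel_to_region = None
        for mouse in mice:
            sub = [c for c in registered if c.mouse_id == mouse and c.hemisphere == "ipsi"]
            counts = pattern_counts_from_label_sets([c.labels for c in sub])
            for pattern, n in sorted(counts.uncorrected.items(), key=lambda kv: sorted(kv[0])):
                pattern_rows.append(
                    {
                        "mouse_id": mouse,
                        "pattern": ";".join(sorted(pattern)),
                        "uncorrected": n,
                        "exact": counts.exact[pattern],
                    }
                )
            for pair, rate in pairwise_jaccard(counts).items():
                a, b = sorted(pair)
                jaccard_rows.append(
                    {"mouse_id": mouse, "region_a": a, "region_b": b, "rate": rate}
                )
            pattern_rows.append(
                {
                    "mouse_id": mouse,
                    "pattern": "(union)",
                    "uncorrected": counts.union_count,
                    "exact": counts.union_count,
                }
            )
        pd.DataFrame(pattern_rows).to_csv(out / "pattern_counts.csv", index=False)
        jaccard_df = pd.DataFrame(jaccard_rows)
        jaccard_df.to_csv(out / "coprojection_rates.csv", index=False)
        pooled = pattern_counts_from_label_sets(
            [c.labels for c in registered if c.hemisphere == "ipsi"]
        )
        summary["stages"]["coproject"] = {
            "n_neurons": pooled.union_count,
            "multi_target_fraction_ge2": _round(multi_target_fraction(pooled, 2)),
        }

    # --- stats --------------------------------------------------------------
    if config.stages.get("stats"):
        stats_summary = {}
        if config.stages.get("coproject") and config.stages.get("density"):
            pair_overlap = {
                frozenset(k.split("|")): v for k, v in overlaps.items()
            }
            merged = jaccard_df.assign(
                pair=[frozenset((a, b)) for a, b in zip(jaccard_df.region_a, jaccard_df.region_b)]
            )
            merged["overlap"] = merged["pair"].map(pair_overlap)
            merged = merged.dropna(subset=["overlap"])
            if merged["pair"].nunique() >= 3:
                try:
                    r, p = correlate_grand_means(merged["pair"], merged["overlap"], merged["rate"])
                    stats_summary["r_overlap_vs_rate"] = _round(r)
                    stats_summary["p_overlap_vs_rate"] = _round(p)
                except ValueError as exc:
                    stats_summary["r_overlap_vs_rate"] = None
                    logger.warning("correlation unavailable: %s", exc)
        summary["stages"]["stats"] = stats_summary

    run_log = {
        "clamap_version": __version__,
        "seed": config.seed,
        "parameters": {
            "bin_size_um": config.bin_size_um,
            "match_radius_um": config.match_radius_um,
            "keep_fraction": config.keep_fraction,
            "otsu_levels": config.otsu_levels,
            "ref_channel": config.ref_channel,
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
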