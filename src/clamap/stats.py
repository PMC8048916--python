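"""Pairwise pathway associations and the shared statistical tests.

Relates per-pair co-projection rates to module overlap, cortical
injection-site distance, and corticocortical connectivity strength.
Correlations are computed on grand means (replicates averaged per region
pair first); group comparisons use pairwise t or Wilcoxon rank-sum tests
with Bonferroni correction over the comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_model import RegionCatalog, canonical_region

#: Retrosplenial injection sites collapsed to one structure for the
#: connectivity comparison (the connectivity table does not resolve them).
RSP_VARIANTS = {"rRSP", "iRSP", "cRSP"}
#: Region absent from the connectivity table's parcellation.
CONNECTIVITY_EXCLUDED = {"ALM"}


@dataclass
class PairAssociation:
    region_pair: frozenset
    coprojection_rate: float
    spatial_overlap: float | None = None
    injection_distance_mm: float | None = None
    connectivity: float | None = None


def injection_distance(
    region_a: str,
    region_b: str,
    catalog: RegionCatalog | None = None,
    include_dv: bool = True,
) -> float:
    """Euclidean distance (mm) between two cortical injection sites.

    Uses the stereotaxic AP/ML/DV coordinates of the bundled catalog; with
    ``include_dv=False`` only the horizontal AP/ML plane is used.
    """
    catalog = catalog or RegionCatalog.default()
    a = catalog.coordinates(region_a)
    b = catalog.coordinates(region_b)
    if not include_dv:
        a, b = a[:2], b[:2]
    return float(np.linalg.norm(a - b))


def design_pairs(experiments) -> set:
    """Unique unordered region pairs analyzed across a set of experiments."""
    pairs = set()
    for exp in experiments:
        for ra, rb in combinations(exp.analyzed_regions, 2):
            pairs.add(frozenset((ra, rb)))
    return pairs


def reduce_pairs_for_connectivity(pairs) -> set:
    """Collapse RSP variants and drop pairs unusable for the connectivity test.

    The rostral/intermediate/caudal retrosplenial sites are relabeled
    ``RSP``; pairs containing an excluded region and pairs that collapse to
    a single region are removed.
    """
    reduced = set()
    for pair in pairs:
        relabeled = {
            "RSP" if canonical_region(r) in RSP_VARIANTS else canonical_region(r)
            for r in pair
        }
        if relabeled & CONNECTIVITY_EXCLUDED:
            continue
        if len(relabeled) < 2:
            continue
        reduced.add(frozenset(relabeled))
    return reduced


def correlate_grand_means(pairs, x, y) -> tuple:
    """Pearson r (and p) between per-pair grand means.

    ``pairs`` labels each replicate with its region pair; replicates are
    averaged within pair before correlating, so every pair contributes one
    point regardless of how many mice measured it.
    """
    df = pd.DataFrame({"pair": [frozenset(p) for p in pairs], "x": x, "y": y})
    means = df.groupby("pair", sort=False)[["x", "y"]].mean()
    if len(means) < 3:
        raise ValueError("need >= 3 region pairs to correlate")
    if means["x"].nunique() == 1 or means["y"].nunique() == 1:
        raise ValueError("zero variance in grand means; correlation undefined")
    r, p = sps.pearsonr(means["x"], means["y"])
    return float(r), float(p)


def pairwise_tests(
    groups,
    paired: bool = False,
    method: str = "t",
    family_size: int | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons with Bonferroni-adjusted p-values.

    ``method`` is ``"t"`` (Student/paired t) or ``"wilcoxon"`` (rank-sum,
    or signed-rank when paired).  The Bonferroni family defaults to the
    number of comparisons actually performed; comparisons with fewer than
    two observations per group are skipped with a NaN row.
    """
    if method not in ("t", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    names = list(groups)
    rows = []
    for a, b in combinations(names, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if len(xa) < 2 or len(xb) < 2 or (paired and len(xa) != len(xb)):
            rows.append({"group_a": a, "group_b": b, "statistic": np.nan, "p_raw": np.nan})
            continue
        if method == "t":
            if paired:
                if np.ptp(xa - xb) == 0 and (xa - xb)[0] == 0:
                    stat, p = 0.0, 1.0  # identical pairs: no effect, by convention
                else:
                    stat, p = sps.ttest_rel(xa, xb)
            else:
                stat, p = sps.ttest_ind(xa, xb)
        else:
            if paired:
                stat, p = sps.wilcoxon(xa, xb)
            else:
                stat, p = sps.ranksums(xa, xb)
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(stat), "p_raw": float(p)}
        )
    df = pd.DataFrame(rows)
    valid = df["p_raw"].notna()
    m = family_size if family_size is not None else int(valid.sum())
    adjusted = np.full(len(df), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = np.minimum(1.0, m * df.loc[valid, "p_raw"].to_numpy())
    df["p_bonferroni"] = adjusted
    df["significant"] = df["p_bonferroni"] < 0.05
    return df


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple:
    """Two-sample t from printed summary statistics (mean ± SD, n per group)."""
    stat, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2)
    return float(stat), float(p)


def association_table(
    jaccard_by_pair,
    overlap_by_pair=None,
    catalog: RegionCatalog | None = None,
    connectivity=None,
) -> pd.DataFrame:
    """Assemble the per-pair association table used for the correlations.

    ``jaccard_by_pair`` maps region pairs to one or more replicate
    co-projection rates; overlap, injection distance, and (optionally)
    symmetrized connectivity are attached per pair.
    """
    catalog = catalog or RegionCatalog.default()
    conn = connectivity.symmetrized() if connectivity is not None else {}
    rows = []
    for pair, rates in jaccard_by_pair.items():
        pair = frozenset(pair)
        ra, rb = sorted(pair)
        rates = np.atleast_1d(np.asarray(rates, dtype=float))
        for rate in rates:
            rows.append(
                {
                    "region_a": ra,
                    "region_b": rb,
                    "coprojection_rate": float(rate),
                    "spatial_overlap": (
                        overlap_by_pair.get(pair) if overlap_by_pair else np.nan
                    ),
                    "injection_distance_mm": injection_distance(ra, rb, catalog),
                    "connectivity": conn.get(
                        frozenset(
                            "RSP" if canonical_region(r) in RSP_VARIANTS else r
                            for r in pair
                        ),
                        np.nan,
                    ),
                }
            )
    return pd.DataFrame(rows)
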