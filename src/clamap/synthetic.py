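"""Synthetic multicolor retrograde tracing experiments with known ground truth.

The generator emulates the structure of real multichannel claustrum data:

* each claustrocortical pathway is a 2D Gaussian module in the registered
  slice plane, displaced from the reference-pathway centroid mainly along
  the dorsoventral axis;
* latent neurons project to 1–4 cortical targets, the target set drawn from
  an explicit distribution over region subsets;
* each target is *observed* independently with a per-tracer detection
  probability below 1, emulating incomplete tracer uptake — so observed
  co-labeling underestimates true co-projection;
* per-slice neuron counts are Poisson and decrease rostral → caudal.

Positions of multi-target neurons are drawn from the equal-weight mixture
of their targets' module Gaussians, which makes co-projecting neurons
spatially intermediate between modules.

Ground-truth zones use the reference module's analytic geometry: a neuron
is "core" if it falls inside the circle (centered on the reference module
mean) that carries ``keep_fraction`` of the reference Gaussian's mass —
the large-sample limit of the closest-90% polygon the pipeline estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_model import RC_LEVELS, CellRecord, ConfigurationError

DEFAULT_REF_SD_UM = 50.0
DEFAULT_KEEP_FRACTION = 0.9


@dataclass(frozen=True)
class PathwayModel:
    """Gaussian spatial module and per-slice counts for one pathway."""

    region: str
    dv_offset_um: float = 0.0
    ml_offset_um: float = 0.0
    dv_sd_um: float = DEFAULT_REF_SD_UM
    ml_sd_um: float = DEFAULT_REF_SD_UM
    count_by_rc: dict = field(
        default_factory=lambda: {"rostral": 60.0, "intermediate": 40.0, "caudal": 25.0}
    )
    contra_fraction: float = 0.0

    def __post_init__(self):
        if self.dv_sd_um <= 0 or self.ml_sd_um <= 0:
            raise ConfigurationError(f"pathway {self.region}: spreads must be positive")
        if any(v < 0 for v in self.count_by_rc.values()):
            raise ConfigurationError(f"pathway {self.region}: counts must be >= 0")
        if not 0.0 <= self.contra_fraction < 1.0:
            raise ConfigurationError(f"pathway {self.region}: contra_fraction in [0, 1)")


@dataclass(frozen=True)
class CoprojectionModel:
    """Latent target-set distribution and per-tracer detection probabilities.

    ``target_set_probs`` maps frozensets of regions to probabilities summing
    to 1; ``detection_prob`` maps each region's tracer channel to its
    detection probability in (0, 1].
    """

    target_set_probs: dict
    detection_prob: dict

    def __post_init__(self):
        probs = dict(self.target_set_probs)
        if not probs:
            raise ConfigurationError("target_set_probs must be non-empty")
        total = sum(probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigurationError(f"target-set probabilities sum to {total}, not 1")
        for p in self.detection_prob.values():
            if not 0.0 < p <= 1.0:
                raise ConfigurationError("detection probabilities must lie in (0, 1]")
        object.__setattr__(
            self, "target_set_probs", {frozenset(k): float(v) for k, v in probs.items()}
        )
        object.__setattr__(self, "detection_prob", dict(self.detection_prob))


@dataclass
class GroundTruth:
    """Latent truth for every generated neuron, observed or not.

    ``neurons`` has one row per latent neuron: true target set, true
    position, true zone, observed label set (empty if undetected).
    """

    neurons: pd.DataFrame
    detection_prob: dict
    reference_region: str
    keep_fraction: float
    core_radius_um: float


def core_radius(ref_sd_um: float, keep_fraction: float = DEFAULT_KEEP_FRACTION) -> float:
    """Radius of the circle holding ``keep_fraction`` of an isotropic 2D Gaussian."""
    return float(ref_sd_um * math.sqrt(stats.chi2.ppf(keep_fraction, df=2)))


def _true_zone(x, y, ref_center, radius):
    dx, dy = x - ref_center[0], y - ref_center[1]
    if math.hypot(dx, dy) <= radius:
        return "core"
    return "dorsal_shell" if dy >= 0 else "ventral_shell"


def generate_experiment(
    pathways,
    coproj: CoprojectionModel,
    n_slices: int = 2,
    seed=0,
    mouse_id: str = "SIM00",
    reference_region: str = "iRSP",
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
) -> tuple:
    """Simulate one mouse: ``n_slices`` per rostrocaudal level.

    The per-slice latent intensity at each level is set so that the
    expected number of *observed* label events matches the sum of the
    pathway ``count_by_rc`` values at that level.  Latent neurons with no
    detected channel are dropped from the cell table but kept in the
    ground truth.  Channel tokens equal region names.
    """
    pathways = list(pathways)
    path_by_region = {p.region: p for p in pathways}
    if reference_region not in path_by_region:
        raise ConfigurationError(f"reference pathway {reference_region!r} missing")
    for subset in coproj.target_set_probs:
        for region in subset:
            if region not in path_by_region:
                raise ConfigurationError(f"target-set region {region!r} has no pathway")
            if region not in coproj.detection_prob:
                raise ConfigurationError(f"region {region!r} has no detection probability")

    rng = np.random.default_rng(seed)
    subsets = sorted(coproj.target_set_probs, key=lambda s: sorted(s))
    probs = np.array([coproj.target_set_probs[s] for s in subsets])
    # expected detected label events per latent neuron
    e_det = sum(
        p * sum(coproj.detection_prob[r] for r in s) for s, p in zip(subsets, probs)
    )
    ref = path_by_region[reference_region]
    ref_center = (ref.ml_offset_um, ref.dv_offset_um)
    radius = core_radius(0.5 * (ref.dv_sd_um + ref.ml_sd_um), keep_fraction)

    records = []
    truth_rows = []
    neuron_counter = 0
    for rc in RC_LEVELS:
        target_events = sum(p.count_by_rc.get(rc, 0.0) for p in pathways)
        lam = target_events / e_det if e_det > 0 else 0.0
        for s_idx in range(n_slices):
            slice_id = f"{mouse_id}-{rc}-{s_idx}"
            n_latent = rng.poisson(lam)
            set_idx = rng.choice(len(subsets), size=n_latent, p=probs)
            for i in range(n_latent):
                targets = subsets[set_idx[i]]
                # position from the equal-weight mixture of target modules
                home = sorted(targets)[rng.integers(len(targets))]
                pw = path_by_region[home]
                x = rng.normal(pw.ml_offset_um, pw.ml_sd_um)
                y = rng.normal(pw.dv_offset_um, pw.dv_sd_um)
                hemisphere = "contra" if rng.random() < pw.contra_fraction else "ipsi"
                observed = frozenset(
                    r for r in targets if rng.random() < coproj.detection_prob[r]
                )
                neuron_id = f"{mouse_id}-n{neuron_counter:06d}"
                neuron_counter += 1
                zone = _true_zone(x, y, ref_center, radius)
                truth_rows.append(
                    {
                        "neuron_id": neuron_id,
                        "slice_id": slice_id,
                        "rc_level": rc,
                        "hemisphere": hemisphere,
                        "x_um": x,
                        "y_um": y,
                        "targets": ";".join(sorted(targets)),
                        "observed": ";".join(sorted(observed)),
                        "zone": zone,
                    }
                )
                if observed:
                    records.append(
                        CellRecord(
                            cell_id=neuron_id,
                            mouse_id=mouse_id,
                            slice_id=slice_id,
                            rc_level=rc,
                            hemisphere=hemisphere,
                            x_um=float(x),
                            y_um=float(y),
                            labels=observed,
                            cell_class="projection",
                        )
                    )
    truth = GroundTruth(
        neurons=pd.DataFrame(
            truth_rows,
            columns=[
                "neuron_id",
                "slice_id",
                "rc_level",
                "hemisphere",
                "x_um",
                "y_um",
                "targets",
                "observed",
                "zone",
            ],
        ),
        detection_prob=dict(coproj.detection_prob),
        reference_region=reference_region,
        keep_fraction=keep_fraction,
        core_radius_um=radius,
    )
    return records, truth


def generate_cohort(configs, seed=0):
    """Simulate several mice with independent substreams of one seed.

    Mouse ``k`` uses ``SeedSequence(seed, spawn_key=(k,))``, so appending a
    mouse to the cohort never perturbs earlier mice.  ``configs`` is a
    sequence of dicts of :func:`generate_experiment` keyword arguments.
    """
    all_records = []
    truths = {}
    for k, cfg in enumerate(configs):
        cfg = dict(cfg)
        cfg["seed"] = np.random.SeedSequence(seed, spawn_key=(k,))
        records, truth = generate_experiment(**cfg)
        all_records.extend(records)
        truths[cfg.get("mouse_id", f"SIM{k:02d}")] = truth
    return all_records, truths


def split_channels(records, jitter_um: float = 0.0, seed=0) -> list:
    """Explode resolved multi-label records into per-channel detection records.

    Emulates raw per-channel counting, where a co-projecting neuron appears
    once in each channel with independent positional jitter; the co-label
    matching stage should reassemble them.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        for ch in sorted(rec.labels):
            dx = rng.normal(0.0, jitter_um) if jitter_um > 0 else 0.0
            dy = rng.normal(0.0, jitter_um) if jitter_um > 0 else 0.0
            out.append(
                CellRecord(
                    cell_id=f"{rec.cell_id}@{ch}",
                    mouse_id=rec.mouse_id,
                    slice_id=rec.slice_id,
                    rc_level=rec.rc_level,
                    hemisphere=rec.hemisphere,
                    x_um=rec.x_um + dx,
                    y_um=rec.y_um + dy,
                    labels=frozenset({ch}),
                    cell_class=rec.cell_class,
                )
            )
    return out


def expected_observed_jaccard(p_a: float, p_b: float, true_rate: float) -> float:
    """Expected observed co-projection rate under independent tracer detection.

    For a population whose *true* co-projection (Jaccard) rate is
    ``true_rate`` — assumed symmetric between the two regions — with
    per-tracer detection probabilities ``p_a`` and ``p_b``, treating counts
    as expectations:

        observed = AB·p_a·p_b / (A·p_a + B·p_b − AB·p_a·p_b)

    with A = B = (1 + j)/2 and AB = j per unit of distinctly labeled
    neurons.  At p_a = p_b = 1 this is the identity; at j = 1 it gives the
    detectability ceiling p_a·p_b/(p_a + p_b − p_a·p_b).
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must lie in [0, 1]")
    j = true_rate
    a = b = (1.0 + j) / 2.0
    ab = j
    denom = a * p_a + b * p_b - ab * p_a * p_b
    return ab * p_a * p_b / denom


# ---------------------------------------------------------------------------
# Zone-fraction calibration


def zone_probabilities(
    dv_offset_um: float,
    sd_um: float,
    ref_sd_um: float = DEFAULT_REF_SD_UM,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
) -> tuple:
    """(core, dorsal, ventral) probabilities of an isotropic module.

    The module is Gaussian with the given dorsoventral offset from the
    reference centroid; the core is the circle holding ``keep_fraction`` of
    the reference Gaussian's mass.  The core probability is a noncentral
    chi-square tail; the dorsal/ventral split of the out-of-core mass is
    evaluated by Gauss–Legendre quadrature over the upper half-disk.
    """
    if sd_um <= 0 or ref_sd_um <= 0:
        raise ValueError("standard deviations must be positive")
    radius = core_radius(ref_sd_um, keep_fraction)
    nc = (dv_offset_um / sd_um) ** 2
    p_core = float(stats.ncx2.cdf((radius / sd_um) ** 2, df=2, nc=nc))
    # mass of the module in the upper half-disk (y >= 0)
    r_nodes, r_w = np.polynomial.legendre.leggauss(120)
    t_nodes, t_w = np.polynomial.legendre.leggauss(120)
    r = 0.5 * radius * (r_nodes + 1.0)
    theta = 0.5 * math.pi * (t_nodes + 1.0)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    pdf = (
        np.exp(
            -(rr**2 - 2.0 * rr * np.sin(tt) * dv_offset_um + dv_offset_um**2)
            / (2.0 * sd_um**2)
        )
        / (2.0 * math.pi * sd_um**2)
    )
    weights = np.outer(r_w * 0.5 * radius, t_w * 0.5 * math.pi)
    core_upper = float(np.sum(pdf * rr * weights))
    p_upper = float(stats.norm.cdf(dv_offset_um / sd_um))
    p_dorsal = max(p_upper - core_upper, 0.0)
    p_ventral = max(1.0 - p_core - p_dorsal, 0.0)
    return p_core, p_dorsal, p_ventral


@lru_cache(maxsize=256)
def calibrate_pathway_offset(
    dorsal_pct: float,
    core_pct: float,
    ref_sd_um: float = DEFAULT_REF_SD_UM,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
) -> tuple:
    """Solve for (dv_offset_um, sd_um) hitting target dorsal/core percentages.

    Inverts :func:`zone_probabilities` with a bounded least-squares search;
    the ventral percentage follows from the other two.  Used to build
    generator defaults that reproduce published zone fractions.
    """
    target = np.array([core_pct, dorsal_pct]) / 100.0
    ventral = 1.0 - target.sum()

    def residual(params):
        d, s = params
        core, dorsal, _ = zone_probabilities(d, s, ref_sd_um, keep_fraction)
        return [core - target[0], dorsal - target[1]]

    sign = 1.0 if dorsal_pct >= 100.0 * ventral else -1.0
    best = None
    for d0, s0 in ((sign * ref_sd_um, ref_sd_um), (sign * 2 * ref_sd_um, 1.5 * ref_sd_um)):
        sol = optimize.least_squares(
            residual,
            x0=[d0, s0],
            bounds=([-10 * ref_sd_um, 5.0], [10 * ref_sd_um, 10 * ref_sd_um]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return float(best.x[0]), float(best.x[1])


# ---------------------------------------------------------------------------
# Default study configuration


def default_pathways(regions=None, ref_sd_um=DEFAULT_REF_SD_UM, reference_region="iRSP"):
    """Pathway models with offsets calibrated to the bundled zone-fraction table.

    Counts per slice are the bundled per-level means; each module's
    dorsoventral offset and spread are solved so its expected
    dorsal/core/ventral split matches the bundled percentages averaged over
    rostrocaudal levels.  The reference pathway sits at the origin with the
    reference spread.
    """
    from .datasets import load_zone_fractions

    zf = load_zone_fractions()
    if regions is None:
        regions = list(dict.fromkeys(zf["region"]))
    pathways = []
    for region in regions:
        sub = zf[zf["region"] == region]
        if sub.empty:
            raise ConfigurationError(f"region {region!r} not in the bundled table")
        counts = {row.rc_level: float(row.count_mean) for row in sub.itertuples()}
        if region == reference_region:
            pathways.append(
                PathwayModel(
                    region=region,
                    dv_offset_um=0.0,
                    ml_offset_um=0.0,
                    dv_sd_um=ref_sd_um,
                    ml_sd_um=ref_sd_um,
                    count_by_rc=counts,
                )
            )
            continue
        dorsal = float(sub["dorsal_pct"].mean())
        core = float(sub["core_pct"].mean())
        dv, sd = calibrate_pathway_offset(dorsal, core, ref_sd_um)
        pathways.append(
            PathwayModel(
                region=region,
                dv_offset_um=dv,
                ml_offset_um=0.0,
                dv_sd_um=sd,
                ml_sd_um=sd,
                count_by_rc=counts,
            )
        )
    return pathways


def _module_overlap_weight(pa: PathwayModel, pb: PathwayModel) -> float:
    """Bhattacharyya-style proximity of two modules along the DV axis."""
    s2 = 0.5 * (pa.dv_sd_um**2 + pb.dv_sd_um**2)
    d = pa.dv_offset_um - pb.dv_offset_um
    return math.exp(-(d**2) / (8.0 * s2))


def default_coprojection(
    pathways,
    detection=None,
    pair_coupling: float = 0.25,
) -> CoprojectionModel:
    """Target-set distribution with overlap-dependent pairwise co-projection.

    Singleton weights follow each pathway's total counts; the probability
    of a two-target set scales with ``pair_coupling`` times the spatial
    proximity of the two modules, so spatially overlapping modules share
    more neurons.  Default detection probabilities span 0.6–0.75.
    """
    pathways = list(pathways)
    if detection is None:
        base = (0.7, 0.65, 0.75, 0.6)
        detection = {p.region: base[i % len(base)] for i, p in enumerate(pathways)}
    weights = {p.region: sum(p.count_by_rc.values()) for p in pathways}
    total_w = sum(weights.values())
    masses = {frozenset({r}): w / total_w for r, w in weights.items()}
    for i, pa in enumerate(pathways):
        for pb in pathways[i + 1 :]:
            m = (
                pair_coupling
                * _module_overlap_weight(pa, pb)
                * math.sqrt(weights[pa.region] * weights[pb.region])
                / total_w
            )
            if m > 0:
                masses[frozenset({pa.region, pb.region})] = m
    z = sum(masses.values())
    probs = {s: m / z for s, m in masses.items()}
    return CoprojectionModel(target_set_probs=probs, detection_prob=detection)
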