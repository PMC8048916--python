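# Methods

This note records the models, conventions, and numerical choices behind
`clamap`, and what the synthetic-data tests do and do not establish about
real tracing data.

## Coordinate and data model

Neurons are 2D points per coronal slice, in μm, with x increasing
laterally and y dorsally. The rostrocaudal position is categorical
(rostral / intermediate / caudal slice groups): slices within a group are
a few hundred μm apart and the analysis treats them as replicates, so no
continuous rostrocaudal coordinate is modeled. Contralateral neurons live
in the same table flagged by hemisphere; all spatial analyses default to
the ipsilateral side, with the contralateral side entering only the
contra/ipsi ratio. The two alternate spellings of the rostral and caudal
retrosplenial sites are canonicalized to single tokens (`rRSP`, `cRSP`).

## Registration and the core polygon

Registration is strictly per slice: the centroid of the ipsilateral
reference-channel neurons becomes the origin, after an optional rotation
(taken from slice metadata when supplied, otherwise estimable as the angle
that makes the reference population's first principal axis vertical —
real images are typically already rotated, so the automatic estimate is a
fallback for unaligned input). Registration is translation-equivariant by
construction; slices with fewer than 3 reference neurons cannot span a
polygon and are skipped with a logged warning.

The core is the **convex hull** of the ⌈0.9 n⌉ reference neurons closest
to the centroid. A traced (concave) outline would also be defensible, but
the convex hull is deterministic, parameter-free, and has a useful exact
property: every retained point lies within the radius of the furthest
retained point, so the hull is contained in that disk and every dropped
point is strictly outside it — the core fraction of the reference pathway
is exactly ⌈0.9 n⌉/n on every slice. Distance ties at the cutoff are
broken by cell-id order. Outside the polygon, the dorsal/ventral split is
the sign of the registered y coordinate; no outer limit is imposed on the
shell.

## Density maps and module boundaries

Density maps are raw counts on a 30 μm grid whose edges are integer
multiples of the bin size (bins half-open, `[edge, edge + bin)`, so a
point exactly on an interior edge belongs to the higher bin). The map
extent is the bounding box of the registered neurons padded by one bin;
empty bins inside the extent participate in the Otsu histogram. Per
pathway, per-slice count maps are averaged within mouse, then across
mice, then peak-normalized, so mice with more slices or neurons do not
dominate; the averaging order is a package choice.

Otsu thresholding runs on the 256-bin histogram of bin densities
(scikit-image). The reported threshold is snapped to the smallest density
value in the upper class so that `mask == (density >= threshold)` holds
exactly; tests verify the partition against an exhaustive
minimum-within-class-variance search. The overlap of two module masks is
|A∩B| / (|A| + |B|), deliberately kept on its native 0–0.5 scale rather
than converted to a Jaccard of areas.

## Co-label matching and pattern counts

Manual co-label scoring is emulated by a deterministic rule: within each
unordered channel pair, candidate cross-channel pairs within the 50 μm
radius are matched greedily by ascending distance (ties by lexicographic
cell-id order), one-to-one; matched pairs are then merged across channel
pairs by union-find, dropping any edge that would place two same-channel
detections in one component (the nearer, earlier merge wins). Matching
operates on per-slice maximum-projection coordinates. With dense labeling
and a 50 μm radius, chance matches between distinct neurons are possible —
as they are for any purely geometric rule — so exact label-set recovery is
only expected for sparse data or small radii, which is how the tests
exercise it.

Uncorrected pattern counts (a neuron tallied under every subset of its
label set) convert to exact counts by Möbius inversion over the subset
lattice. The inversion is exact for any table generated from a real
multiset; manually scored tables can be slightly inconsistent (a double
count smaller than the triples containing it), producing small negative
exact doubles. `inclusion_exclusion(strict=False)` returns the signed
inversion in that case — the union and the ≥3-label counts, which the
headline fractions use, are unaffected. Strict mode raises, naming the
offending pattern.

Pairwise co-projection rates use **uncorrected** counts in
AB/(A + B − AB), matching the original scoring convention, not the exact
pattern counts. Headline fractions are pooled (counts summed across mice
before dividing); per-mouse values are also available, since pooling vs
averaging is ambiguous in general.

Tracer efficacy from a dual-tracer co-injection uses Lincoln–Petersen:
p_a = both/(both + b_only), p_b = both/(both + a_only); the observable
co-projection ceiling is p_a·p_b/(p_a + p_b − p_a·p_b). The closed form
`expected_observed_jaccard` extends this to a population with true
(symmetric) co-projection rate j: observed = j·p_a·p_b / ((1+j)(p_a+p_b)/2
− j·p_a·p_b). Note the ceiling is ≈0.48 at p=0.65 and ≈0.67 at p=0.8, so
"50–60%" describes the central part of that detection range, not its
corners.

## Associations and tests

Injection distances are 3D Euclidean over the stereotaxic (AP, ML, DV)
coordinates; a 2D (AP, ML) variant is available since inclusion of depth
is a judgment call. For the connectivity comparison the three
retrosplenial sites collapse to one `RSP` token and pairs containing ALM
are dropped (the connectivity parcellation resolves neither), reducing
the 27 designed pathway pairs to 19. Correlations are Pearson r on
per-pair grand means (replicates averaged first). Pairwise group
comparisons offer t and Wilcoxon variants; Bonferroni multiplies by the
family size, which defaults to the number of comparisons performed in the
call — the caller owns the family definition.

## Synthetic data generator

Each pathway is an isotropic-by-default 2D Gaussian module with a
dorsoventral (and optionally mediolateral) offset from the reference
centroid. Latent neurons draw a target set from an explicit distribution
over region subsets; a multi-target neuron's position comes from the
equal-weight mixture of its targets' modules, making co-projecting
neurons spatially intermediate. Each target is detected independently
with its tracer's probability; neurons with no detected channel are
dropped from the cell table but retained in the ground truth. Per-slice
latent counts are Poisson, with the intensity at each rostrocaudal level
set so the expected number of *observed* label events matches the sum of
the configured per-pathway counts at that level; region marginals follow
the target-set distribution. Hemisphere is contralateral with a
per-pathway probability, so the expected contra/ipsi ratio is f/(1−f).

Defaults encode the study conditions: the reference module has a 50 μm
spread (a ~107 μm core radius, matching the scale of the mouse claustrum
core); per-slice counts come from the bundled per-pathway table and
decrease rostral → caudal; detection probabilities default to 0.6–0.75
per tracer, consistent with the measured 50–60% co-labeling ceiling; the
default target-set distribution is singleton-dominated with two-target
mass scaling with module proximity (a Bhattacharyya-style weight), so
overlapping modules share more neurons.

Ground-truth zones use the reference module's analytic geometry — the
circle holding 90% of the reference Gaussian's mass — which is the
large-sample limit of the estimated polygon. Module offsets for target
zone fractions are obtained by inverting the analytic zone probabilities
(noncentral-χ² core mass; Gauss–Legendre quadrature over the upper
half-disk for the dorsal share) with bounded least squares. The finite-n
hull is slightly smaller than the limiting circle, biasing recovered core
fractions down by well under one point at n ≥ 2000, within the 3-point
recovery tolerance the tests use.

One seed drives everything; cohorts give mouse k the substream
`SeedSequence(seed, spawn_key=(k,))`, so appending a mouse never perturbs
earlier ones.

**What the generator does not emulate:** tracer competition at co-injected
sites (detections are independent), slice-to-slice registration error,
anisotropic or curved module shapes, mediolateral topography (offsets are
dorsoventral by default), spatial variation of detection probability, and
cell-detection false positives. Passing tests therefore validate the
analysis machinery under the stated generative assumptions, not the
biology of any particular real dataset.

## Problem sizes and determinism

The test suite and acceptance script run on deliberately modest problem
sizes — populations of 500–10,000 synthetic neurons, 1,000-instance oracle
sweeps, 6-seed directional checks — chosen as the smallest sizes at which
the statistical assertions have comfortable margins (binomial error a few
times smaller than the tolerance). All randomness flows from explicit
seeds; reruns are byte-identical.

## Known limitations

* The convex-hull core is one of several defensible readings of a traced
  perimeter; a concave variant would shrink the core slightly.
* The dorsal/ventral split by the sign of y assumes the reference centroid
  lies on the core's dorsoventral midline.
* Greedy matching is not a minimum-cost assignment; it mirrors a
  nearest-first manual workflow and is deterministic, but can differ from
  the optimal matching in dense configurations.
* Negative exact counts from inconsistent manual tables are reported, not
  repaired; only union and high-order sums should be trusted there.
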