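"""Cross-channel co-label matching and labeling-pattern statistics.

A neuron projecting to several traced regions appears once per imaging
channel; detections from different channels lying within a 50 μm matching
radius are paired one-to-one (greedy, ascending distance) and merged into a
single resolved neuron whose label set is the union of its member channels.

Pattern counts come in two conventions.  *Uncorrected* counts follow the
tally used during manual scoring: a neuron contributes to the count of
every non-empty subset of its label set, so a triple-labeled neuron is
counted under three singles, three doubles, and one triple.  *Exact* counts
tally neurons whose label set equals the pattern.  The two are related by
Möbius inversion over the subset lattice (inclusion–exclusion), which also
yields the number of distinct neurons.

The pairwise co-projection rate for regions A and B uses the uncorrected
counts: AB / (A + B − AB), i.e. a Jaccard index of the two labeled
populations.  Because each tracer detects only a fraction of the neurons
projecting to its injection site, the observable rate saturates below 1;
the ceiling is estimated by capture–recapture from a dual-tracer
co-injection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np

DEFAULT_MATCH_RADIUS_UM = 50.0


@dataclass(frozen=True)
class MatchPair:
    cell_a: str
    cell_b: str
    channel_a: str
    channel_b: str
    distance_um: float


@dataclass
class MatchSet:
    radius_um: float
    pairs: list


@dataclass(frozen=True)
class ResolvedNeuron:
    neuron_id: str
    labels: frozenset
    x_um: float
    y_um: float
    members: tuple


@dataclass
class PatternCounts:
    """Uncorrected and exact counts over the 2^k − 1 patterns of k channels."""

    channels: tuple
    uncorrected: dict
    exact: dict
    union_count: int


class InconsistentCountsError(ValueError):
    """An uncorrected count table admits no non-negative exact counts."""


def _nonempty_subsets(channels):
    channels = sorted(channels)
    return [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(channels, k) for k in range(1, len(channels) + 1)
        )
    ]


def match_colabels(cells, radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> MatchSet:
    """Pair detections across channels that lie within ``radius_um`` of each other.

    For every unordered channel pair, candidate cross-channel pairs are
    matched greedily by ascending distance (ties broken by the lexicographic
    order of the two cell ids), one-to-one within that channel pair.
    Cells must all come from one slice.
    """
    slice_ids = {c.slice_id for c in cells}
    if len(slice_ids) > 1:
        raise ValueError(f"cells span multiple slices: {sorted(slice_ids)}")
    by_channel: dict = {}
    for c in cells:
        for ch in c.labels:
            by_channel.setdefault(ch, []).append(c)
    pairs = []
    for ch_a, ch_b in combinations(sorted(by_channel), 2):
        candidates = []
        for ca in by_channel[ch_a]:
            for cb in by_channel[ch_b]:
                if ca.cell_id == cb.cell_id:
                    continue
                d = float(np.hypot(ca.x_um - cb.x_um, ca.y_um - cb.y_um))
                if d <= radius_um:
                    candidates.append((d, ca.cell_id, cb.cell_id))
        candidates.sort()
        used_a: set = set()
        used_b: set = set()
        for d, ida, idb in candidates:
            if ida in used_a or idb in used_b:
                continue
            used_a.add(ida)
            used_b.add(idb)
            pairs.append(MatchPair(ida, idb, ch_a, ch_b, d))
    return MatchSet(radius_um=float(radius_um), pairs=pairs)


def assemble_label_sets(cells, matches: MatchSet) -> list:
    """Merge matched detections into resolved neurons with full label sets.

    Connected components of the match graph become single neurons; an edge
    that would place two detections from the same channel in one component
    is dropped (larger-distance edges are considered later, so the nearer
    interpretation wins).  Unmatched detections pass through as singletons.
    """
    cells_by_id = {c.cell_id: c for c in cells}
    parent = {cid: cid for cid in cells_by_id}
    channels_of = {cid: set(cells_by_id[cid].labels) for cid in cells_by_id}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(matches.pairs, key=lambda p: (p.distance_um, p.cell_a, p.cell_b))
    for edge in edges:
        ra, rb = find(edge.cell_a), find(edge.cell_b)
        if ra == rb:
            continue
        if channels_of[ra] & channels_of[rb]:
            continue  # same-channel conflict: keep the nearer, earlier merge
        parent[rb] = ra
        channels_of[ra] |= channels_of[rb]
    components: dict = {}
    for cid in cells_by_id:
        components.setdefault(find(cid), []).append(cid)
    resolved = []
    for members in components.values():
        members = sorted(members)
        group = [cells_by_id[m] for m in members]
        labels = frozenset().union(*(c.labels for c in group))
        resolved.append(
            ResolvedNeuron(
                neuron_id=members[0],
                labels=labels,
                x_um=float(np.mean([c.x_um for c in group])),
                y_um=float(np.mean([c.y_um for c in group])),
                members=tuple(members),
            )
        )
    resolved.sort(key=lambda r: r.neuron_id)
    return resolved


def enumerate_patterns(k: int) -> int:
    """Number of possible labeling patterns for k channels: 2^k − 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2**k - 1


def pattern_counts_from_label_sets(label_sets, channels=None) -> PatternCounts:
    """Tabulate exact pattern counts directly and derive the uncorrected table."""
    label_sets = [frozenset(s) for s in label_sets]
    if channels is None:
        channels = sorted(frozenset().union(*label_sets)) if label_sets else []
    patterns = _nonempty_subsets(channels)
    exact = {p: 0 for p in patterns}
    for s in label_sets:
        exact[s] += 1
    uncorrected = {p: sum(v for t, v in exact.items() if p <= t) for p in patterns}
    return PatternCounts(
        channels=tuple(sorted(channels)),
        uncorrected=uncorrected,
        exact=exact,
        union_count=len(label_sets),
    )


def inclusion_exclusion(uncorrected: dict, channels=None, strict: bool = True) -> tuple:
    """Möbius-invert uncorrected counts into exact counts and the neuron union.

    exact(S) = Σ_{T ⊇ S} (−1)^{|T|−|S|} uncorrected(T);
    union = Σ_S (−1)^{|S|+1} uncorrected(S).  Patterns absent from the input
    are treated as zero.  A negative exact count means the input table is
    not realizable by any multiset of label sets; with ``strict`` this
    raises :class:`InconsistentCountsError`.  Manually scored tables can
    carry small such inconsistencies in the double patterns while their
    union and higher-order counts remain meaningful, so ``strict=False``
    returns the signed inversion unchanged.
    """
    uncorrected = {frozenset(k): int(v) for k, v in uncorrected.items()}
    if channels is None:
        channels = sorted(frozenset().union(*uncorrected.keys()))
    patterns = _nonempty_subsets(channels)
    unc = {p: uncorrected.get(p, 0) for p in patterns}
    exact = {}
    for s in patterns:
        total = 0
        for t in patterns:
            if s <= t:
                total += (-1) ** (len(t) - len(s)) * unc[t]
        if total < 0 and strict:
            raise InconsistentCountsError(
                f"pattern {''.join(sorted(s))} implies a negative exact count ({total})"
            )
        exact[s] = total
    union_count = sum((-1) ** (len(s) + 1) * unc[s] for s in patterns)
    return exact, union_count


def pattern_counts_from_uncorrected(
    uncorrected: dict, channels=None, strict: bool = True
) -> PatternCounts:
    exact, union = inclusion_exclusion(uncorrected, channels, strict=strict)
    channels = tuple(sorted(frozenset().union(*exact.keys())))
    unc = {p: uncorrected.get(p, uncorrected.get(frozenset(p), 0)) for p in exact}
    return PatternCounts(channels=channels, uncorrected=unc, exact=exact, union_count=union)


def jaccard_rate(count_a: int, count_b: int, count_ab: int) -> float:
    """Pairwise co-projection rate AB / (A + B − AB) from uncorrected counts."""
    if min(count_a, count_b, count_ab) < 0:
        raise ValueError("counts must be non-negative")
    if count_ab > min(count_a, count_b):
        raise ValueError("double-labeled count exceeds a single-channel count")
    denom = count_a + count_b - count_ab
    if denom == 0:
        raise ValueError("co-projection rate undefined: no labeled neurons")
    return count_ab / denom


def pairwise_jaccard(counts: PatternCounts) -> dict:
    """Co-projection rate for every unordered channel pair, from uncorrected counts."""
    out = {}
    for ch_a, ch_b in combinations(counts.channels, 2):
        a = counts.uncorrected[frozenset({ch_a})]
        b = counts.uncorrected[frozenset({ch_b})]
        ab = counts.uncorrected[frozenset({ch_a, ch_b})]
        out[frozenset({ch_a, ch_b})] = jaccard_rate(a, b, ab)
    return out


def multi_target_fraction(counts: PatternCounts, min_labels: int) -> float:
    """Fraction of distinct neurons whose label set has >= ``min_labels`` channels."""
    if counts.union_count == 0:
        raise ValueError("no neurons; fraction undefined")
    total = sum(v for s, v in counts.exact.items() if len(s) >= min_labels)
    return total / counts.union_count


def detection_probability(a_only: int, b_only: int, both: int) -> tuple:
    """Capture–recapture tracer efficacies and the observable co-projection ceiling.

    For a dual-tracer co-injection into one site every labeled neuron truly
    projects there, so the Lincoln–Petersen estimates are p_a = both /
    (both + b_only) and p_b = both / (both + a_only).  The ceiling is the
    expected observed Jaccard for a fully co-projecting population:
    p_a·p_b / (p_a + p_b − p_a·p_b).
    """
    if min(a_only, b_only, both) < 0:
        raise ValueError("counts must be non-negative")
    if both == 0:
        raise ValueError("no double-labeled neurons; detection probabilities inestimable")
    p_a = both / (both + b_only)
    p_b = both / (both + a_only)
    ceiling = p_a * p_b / (p_a + p_b - p_a * p_b)
    return p_a, p_b, ceiling
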