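"""Co-label matching, pattern combinatorics, and co-projection statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clamap.coprojection import (
    InconsistentCountsError,
    assemble_label_sets,
    detection_probability,
    enumerate_patterns,
    inclusion_exclusion,
    jaccard_rate,
    match_colabels,
    multi_target_fraction,
    pattern_counts_from_label_sets,
    pattern_counts_from_uncorrected,
    pairwise_jaccard,
)
from clamap.datasets import (
    pooled_multi_target_percentage,
    uncorrected_counts_for_mouse,
)
from conftest import make_cell, tabulate_patterns


class TestMatching:
    def test_nearby_cross_channel_pair_matched(self):
        cells = [make_cell("a1", 0, 0, {"A"}), make_cell("b1", 10, 0, {"B"})]
        ms = match_colabels(cells)
        assert len(ms.pairs) == 1
        assert ms.pairs[0].distance_um == pytest.approx(10.0)

    def test_beyond_radius_not_matched(self):
        cells = [make_cell("a1", 0, 0, {"A"}), make_cell("b1", 60, 0, {"B"})]
        assert match_colabels(cells, radius_um=50).pairs == []

    def test_same_channel_cells_never_matched(self):
        cells = [make_cell("a1", 0, 0, {"A"}), make_cell("a2", 5, 0, {"A"})]
        assert match_colabels(cells).pairs == []

    def test_one_to_one_keeps_nearer_pair(self):
        cells = [
            make_cell("a1", 0, 0, {"A"}),
            make_cell("a2", 30, 0, {"A"}),
            make_cell("b1", 10, 0, {"B"}),
        ]
        ms = match_colabels(cells)
        matched_a = {p.cell_a for p in ms.pairs}
        assert matched_a == {"a1"}  # a1-b1 at 10 beats a2-b1 at 20

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_replayed_reference_greedy(self, seed):
        """Independent replay: sort all candidate pairs by (distance, ids) and
        greedily accept — the library must produce exactly this matching."""
        rng = np.random.default_rng(seed)
        cells = []
        for ch in ("A", "B", "C"):
            for i in range(rng.integers(2, 9)):
                cells.append(
                    make_cell(f"{ch.lower()}{i}", *rng.uniform(0, 120, 2), {ch})
                )
        ms = match_colabels(cells, radius_um=50)
        got = {(p.cell_a, p.cell_b) for p in ms.pairs}
        expected = set()
        from itertools import combinations

        by_ch = {}
        for c in cells:
            by_ch.setdefault(next(iter(c.labels)), []).append(c)
        for ca_ch, cb_ch in combinations(sorted(by_ch), 2):
            cands = sorted(
                (np.hypot(ca.x_um - cb.x_um, ca.y_um - cb.y_um), ca.cell_id, cb.cell_id)
                for ca in by_ch[ca_ch]
                for cb in by_ch[cb_ch]
                if np.hypot(ca.x_um - cb.x_um, ca.y_um - cb.y_um) <= 50
            )
            seen_a, seen_b = set(), set()
            for d, ia, ib in cands:
                if ia in seen_a or ib in seen_b:
                    continue
                seen_a.add(ia)
                seen_b.add(ib)
                expected.add((ia, ib))
        assert got == expected


class TestAssembly:
    def test_chain_becomes_triple_labeled_neuron(self):
        cells = [
            make_cell("a1", 0, 0, {"A"}),
            make_cell("b1", 10, 0, {"B"}),
            make_cell("c1", 20, 0, {"C"}),
        ]
        ms = match_colabels(cells)
        resolved = assemble_label_sets(cells, ms)
        assert len(resolved) == 1
        assert resolved[0].labels == frozenset({"A", "B", "C"})

    def test_conflicting_merge_drops_farther_edge(self):
        # a1-b1 (10 um) and a2-b1 (20 um) cannot coexist one-to-one
        cells = [
            make_cell("a1", 0, 0, {"A"}),
            make_cell("a2", 30, 0, {"A"}),
            make_cell("b1", 10, 0, {"B"}),
        ]
        resolved = assemble_label_sets(cells, match_colabels(cells))
        by_labels = sorted(r.labels for r in resolved)
        assert by_labels == [frozenset({"A"}), frozenset({"A", "B"})]
        merged = next(r for r in resolved if len(r.labels) == 2)
        assert "a1" in merged.members

    def test_perfect_detection_sparse_data_recovers_truth_exactly(self):
        from collections import Counter

        from clamap.synthetic import (
            CoprojectionModel,
            PathwayModel,
            generate_experiment,
            split_channels,
        )

        pws = [
            PathwayModel("iRSP", count_by_rc={"rostral": 12, "intermediate": 8, "caudal": 6}),
            PathwayModel("PL", dv_offset_um=40, count_by_rc={"rostral": 12, "intermediate": 8, "caudal": 6}),
        ]
        cop = CoprojectionModel(
            {
                frozenset({"iRSP"}): 0.4,
                frozenset({"PL"}): 0.35,
                frozenset({"iRSP", "PL"}): 0.25,
            },
            {"iRSP": 1.0, "PL": 1.0},
        )
        cells, truth = generate_experiment(pws, cop, n_slices=2, seed=5)
        detections = split_channels(cells, jitter_um=0.0)
        resolved = []
        for sl in {c.slice_id for c in detections}:
            sub = [c for c in detections if c.slice_id == sl]
            # zero jitter: co-detections of one neuron are at distance 0, so a
            # tight radius separates them from distinct nearby neurons
            resolved += assemble_label_sets(sub, match_colabels(sub, radius_um=1.0))
        true_sets = Counter(
            frozenset(t.split(";")) for t in truth.neurons["targets"]
        )
        assert Counter(r.labels for r in resolved) == true_sets


class TestPatternCombinatorics:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 3), (3, 7), (4, 15)])
    def test_pattern_count(self, k, expected):
        assert enumerate_patterns(k) == expected

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            enumerate_patterns(0)

    def test_exact_table_length_is_2k_minus_1(self):
        counts = pattern_counts_from_label_sets(
            [{"A"}, {"B", "C"}], channels=("A", "B", "C", "D")
        )
        assert len(counts.exact) == enumerate_patterns(4)


class TestInclusionExclusion:
    def test_four_tracer_midline_mouse(self):
        """The bundled PL/rRSP/cRSP/iRSP experiment: 1,241 distinct neurons,
        137 of them labeled by three or four tracers."""
        unc = uncorrected_counts_for_mouse("M58")
        exact, union = inclusion_exclusion(unc, strict=False)
        assert union == 1241
        assert sum(v for s, v in exact.items() if len(s) >= 3) == 137

    def test_no_multilabels_means_exact_equals_uncorrected(self):
        unc = {frozenset("A"): 10, frozenset("B"): 7}
        exact, union = inclusion_exclusion(unc, channels=("A", "B"))
        assert exact[frozenset("A")] == 10
        assert exact[frozenset({"A", "B"})] == 0
        assert union == 17

    @pytest.mark.parametrize("seed", range(5))
    def test_random_multisets_round_trip(self, seed):
        """Inversion reproduces latent exact counts on 1,000 random multisets."""
        rng = np.random.default_rng(seed)
        channels = ("A", "B", "C", "D")
        for _ in range(200):
            n = rng.integers(1, 40)
            label_sets = [
                frozenset(rng.choice(channels, size=rng.integers(1, 5), replace=False))
                for _ in range(n)
            ]
            exact_oracle, unc_oracle = tabulate_patterns(label_sets, channels)
            exact, union = inclusion_exclusion(unc_oracle, channels=channels)
            assert exact == exact_oracle
            assert union == n

    def test_inconsistent_table_raises_naming_pattern(self):
        unc = {frozenset("A"): 1, frozenset("B"): 1, frozenset({"A", "B"}): 5}
        with pytest.raises(InconsistentCountsError, match="A"):
            inclusion_exclusion(unc)


class TestJaccard:
    def test_printed_counts_example(self):
        # MOs-iRSP pair of the bundled MOs/iRSP/ALM/MOp experiment
        assert jaccard_rate(482, 434, 131) == pytest.approx(131 / 785)

    def test_complete_overlap_is_one(self):
        assert jaccard_rate(50, 50, 50) == 1.0

    def test_no_overlap_is_zero(self):
        assert jaccard_rate(10, 20, 0) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.integers(0, 1000), b=st.integers(0, 1000), ab=st.integers(0, 1000)
    )
    def test_symmetric_and_bounded(self, a, b, ab):
        if ab > min(a, b) or a + b - ab == 0:
            return
        r1 = jaccard_rate(a, b, ab)
        assert r1 == jaccard_rate(b, a, ab)
        assert 0.0 <= r1 <= 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            jaccard_rate(0, 0, 0)

    def test_excess_double_count_rejected(self):
        with pytest.raises(ValueError):
            jaccard_rate(5, 10, 6)


class TestMultiTarget:
    def test_pooled_midline_fraction_near_ten_percent(self):
        pct = pooled_multi_target_percentage(("M58", "M59"), min_labels=3)
        assert pct == pytest.approx(10.497, abs=0.01)

    def test_all_singletons_zero(self):
        counts = pattern_counts_from_label_sets([{"A"}, {"B"}, {"A"}])
        assert multi_target_fraction(counts, 2) == 0.0

    def test_min_one_is_unity(self):
        counts = pattern_counts_from_label_sets([{"A"}, {"A", "B"}])
        assert multi_target_fraction(counts, 1) == 1.0


class TestDetectionProbability:
    def test_perfect_tracers(self):
        assert detection_probability(0, 0, 50) == (1.0, 1.0, 1.0)

    def test_symmetric_seventy_percent(self):
        p_a, p_b, ceiling = detection_probability(30, 30, 70)
        assert p_a == pytest.approx(0.7)
        assert p_b == pytest.approx(0.7)
        assert ceiling == pytest.approx(0.49 / 0.91)

    def test_no_double_label_inestimable(self):
        with pytest.raises(ValueError):
            detection_probability(10, 10, 0)

    def test_simulation_recovery(self, rng):
        p_a, p_b, n = 0.6, 0.8, 10_000
        det_a = rng.random(n) < p_a
        det_b = rng.random(n) < p_b
        both = int((det_a & det_b).sum())
        a_only = int((det_a & ~det_b).sum())
        b_only = int((~det_a & det_b).sum())
        est_a, est_b, _ = detection_probability(a_only, b_only, both)
        assert est_a == pytest.approx(p_a, abs=0.02)
        assert est_b == pytest.approx(p_b, abs=0.02)


class TestPairwiseJaccardTable:
    def test_uses_uncorrected_counts(self):
        counts = pattern_counts_from_uncorrected(
            uncorrected_counts_for_mouse("M176"), strict=False
        )
        rates = pairwise_jaccard(counts)
        assert rates[frozenset({"A", "B"})] == pytest.approx(131 / (482 + 434 - 131))
        assert len(rates) == 6
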