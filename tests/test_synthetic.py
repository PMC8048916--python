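"""Generator ground-truth invariants, detection attenuation, and calibration."""

import math
from collections import Counter

import numpy as np
import pytest

from clamap.core_model import ConfigurationError
from clamap.coprojection import jaccard_rate, pattern_counts_from_label_sets
from clamap.synthetic import (
    CoprojectionModel,
    PathwayModel,
    calibrate_pathway_offset,
    core_radius,
    default_coprojection,
    default_pathways,
    expected_observed_jaccard,
    generate_cohort,
    generate_experiment,
    zone_probabilities,
)


def _two_region_model(p_pair, p_a=1.0, p_b=1.0, counts=200):
    pws = [
        PathwayModel("iRSP", count_by_rc={"rostral": counts, "intermediate": counts, "caudal": counts}),
        PathwayModel("PL", dv_offset_um=40, count_by_rc={"rostral": counts, "intermediate": counts, "caudal": counts}),
    ]
    cop = CoprojectionModel(
        {
            frozenset({"iRSP"}): (1 - p_pair) / 2,
            frozenset({"PL"}): (1 - p_pair) / 2,
            frozenset({"iRSP", "PL"}): p_pair,
        },
        {"iRSP": p_a, "PL": p_b},
    )
    return pws, cop


class TestGroundTruthInvariants:
    def test_perfect_detection_preserves_label_multiset(self):
        pws, cop = _two_region_model(0.3)
        cells, truth = generate_experiment(pws, cop, n_slices=2, seed=9)
        observed = Counter(c.labels for c in cells)
        latent = Counter(
            frozenset(t.split(";")) for t in truth.neurons["targets"]
        )
        assert observed == latent

    def test_observed_labels_subset_of_truth(self):
        pws, cop = _two_region_model(0.4, p_a=0.6, p_b=0.7)
        cells, truth = generate_experiment(pws, cop, n_slices=1, seed=2)
        targets = {
            row.neuron_id: frozenset(row.targets.split(";"))
            for row in truth.neurons.itertuples()
        }
        for c in cells:
            assert c.labels <= targets[c.cell_id]

    def test_singleton_targets_give_zero_colabels(self):
        pws, cop = _two_region_model(0.0)
        cells, _ = generate_experiment(pws, cop, n_slices=1, seed=4)
        counts = pattern_counts_from_label_sets([c.labels for c in cells])
        assert counts.uncorrected.get(frozenset({"PL", "iRSP"}), 0) == 0

    def test_observed_counts_match_binomial_expectation(self):
        """Per-region observed counts ~ n_latent x P(region in S) x p_detect."""
        pws, cop = _two_region_model(0.4, p_a=0.65, p_b=0.8, counts=1700)
        cells, truth = generate_experiment(pws, cop, n_slices=1, seed=7)
        n_latent = len(truth.neurons)
        assert n_latent > 8000
        for region, p_det in (("iRSP", 0.65), ("PL", 0.8)):
            marginal = sum(
                p for s, p in cop.target_set_probs.items() if region in s
            )
            expected = n_latent * marginal * p_det
            sd = math.sqrt(n_latent * marginal * p_det * (1 - marginal * p_det))
            observed = sum(region in c.labels for c in cells)
            assert abs(observed - expected) < 4 * sd

    def test_counts_decrease_rostral_to_caudal(self):
        pws = default_pathways(["iRSP", "PL", "ALM"])
        for pw in pws:
            c = pw.count_by_rc
            assert c["rostral"] >= c["intermediate"] >= c["caudal"]

    def test_missing_reference_pathway_rejected(self):
        pws, cop = _two_region_model(0.2)
        with pytest.raises(ConfigurationError):
            generate_experiment(pws, cop, reference_region="VISp")

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            CoprojectionModel({frozenset({"iRSP"}): 0.5}, {"iRSP": 1.0})


class TestSeedStreams:
    def test_adding_a_mouse_does_not_perturb_earlier_mice(self):
        pws, cop = _two_region_model(0.3)
        base = {"pathways": pws, "coproj": cop, "n_slices": 1}
        cells2, _ = generate_cohort(
            [dict(base, mouse_id="A"), dict(base, mouse_id="B")], seed=1
        )
        cells3, _ = generate_cohort(
            [dict(base, mouse_id="A"), dict(base, mouse_id="B"), dict(base, mouse_id="C")],
            seed=1,
        )
        first_two = [c for c in cells3 if c.mouse_id in ("A", "B")]
        assert first_two == cells2


class TestExpectedObservedJaccard:
    @pytest.mark.parametrize("true_rate", [0.0, 0.2, 0.5, 1.0])
    def test_perfect_detection_is_identity(self, true_rate):
        assert expected_observed_jaccard(1.0, 1.0, true_rate) == pytest.approx(true_rate)

    def test_nothing_to_codetect(self):
        assert expected_observed_jaccard(0.7, 0.7, 0.0) == 0.0

    def test_seventy_percent_detection_ceiling(self):
        assert expected_observed_jaccard(0.7, 0.7, 1.0) == pytest.approx(
            0.49 / (0.7 + 0.7 - 0.49)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_observed_jaccard(0.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            expected_observed_jaccard(0.5, 0.5, 1.5)

    def test_monte_carlo_agreement_at_ten_thousand_neurons(self):
        """Fully co-projecting population, p=0.7 per tracer: observed rate
        ~ 0.538 within Monte-Carlo error."""
        pws, cop = _two_region_model(1.0, p_a=0.7, p_b=0.7, counts=2400)
        cells, truth = generate_experiment(pws, cop, n_slices=1, seed=13)
        assert len(truth.neurons) > 9000
        counts = pattern_counts_from_label_sets([c.labels for c in cells])
        a = counts.uncorrected[frozenset({"iRSP"})]
        b = counts.uncorrected[frozenset({"PL"})]
        ab = counts.uncorrected[frozenset({"PL", "iRSP"})]
        assert jaccard_rate(a, b, ab) == pytest.approx(
            expected_observed_jaccard(0.7, 0.7, 1.0), abs=0.02
        )

    def test_observed_rate_decreases_with_detection(self):
        """Holding the true rate fixed, lower detection gives lower observed
        co-projection, tracking the closed form."""
        true_rate, rates = 0.5, []
        for p in (1.0, 0.8, 0.6):
            pws, cop = _two_region_model(true_rate, p_a=p, p_b=p, counts=1200)
            cells, _ = generate_experiment(pws, cop, n_slices=1, seed=21)
            counts = pattern_counts_from_label_sets([c.labels for c in cells])
            a = counts.uncorrected[frozenset({"iRSP"})]
            b = counts.uncorrected[frozenset({"PL"})]
            ab = counts.uncorrected[frozenset({"PL", "iRSP"})]
            observed = jaccard_rate(a, b, ab)
            assert observed == pytest.approx(
                expected_observed_jaccard(p, p, true_rate), abs=0.03
            )
            rates.append(observed)
        assert rates[0] > rates[1] > rates[2]


class TestZoneCalibration:
    def test_centered_module_core_mass_equals_keep_fraction(self):
        core, dorsal, ventral = zone_probabilities(0.0, 50.0, ref_sd_um=50.0)
        assert core == pytest.approx(0.9, abs=1e-6)
        assert dorsal == pytest.approx(ventral, abs=1e-6)

    def test_radius_marks_ninety_percent_mass(self):
        from scipy import stats

        r = core_radius(50.0, 0.9)
        assert stats.chi2.cdf((r / 50.0) ** 2, df=2) == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "dorsal,core", [(70.0, 23.0), (40.0, 42.0), (11.0, 31.0)]
    )
    def test_calibration_inverts_zone_probabilities(self, dorsal, core):
        dv, sd = calibrate_pathway_offset(dorsal, core)
        got_core, got_dorsal, _ = zone_probabilities(dv, sd)
        assert got_core * 100 == pytest.approx(core, abs=0.5)
        assert got_dorsal * 100 == pytest.approx(dorsal, abs=0.5)

    def test_ventral_biased_module_gets_negative_offset(self):
        dv, _ = calibrate_pathway_offset(11.0, 31.0)  # 58% ventral
        assert dv < 0


class TestParameterRecovery:
    def test_dorsal_shell_fraction_recovered_within_three_points(self):
        """A module configured to 70% dorsal shell / 23% core is recovered
        within 3 percentage points by the full register-and-classify
        pipeline at n >= 2,000 neurons."""
        from clamap.density import core_shell_proportions
        from clamap.registration import register_slices

        dv, sd = calibrate_pathway_offset(70.0, 23.0)
        ref = PathwayModel("iRSP", count_by_rc={"rostral": 2500, "intermediate": 0, "caudal": 0})
        alm = PathwayModel(
            "ALM", dv_offset_um=dv, dv_sd_um=sd, ml_sd_um=sd,
            count_by_rc={"rostral": 2500, "intermediate": 0, "caudal": 0},
        )
        cop = CoprojectionModel(
            {frozenset({"iRSP"}): 0.5, frozenset({"ALM"}): 0.5},
            {"iRSP": 1.0, "ALM": 1.0},
        )
        cells, _ = generate_experiment([ref, alm], cop, n_slices=1, seed=31)
        registered, _, _, _ = register_slices(cells, "iRSP")
        props = core_shell_proportions(registered)
        row = props[(props.pathway == "ALM") & (props.rc_level == "rostral")].iloc[0]
        assert row.n_neurons >= 2000
        assert row.pct_dorsal_shell == pytest.approx(70.0, abs=3.0)


class TestDefaultConfiguration:
    def test_default_coprojection_is_valid_and_biased_to_singletons(self):
        pws = default_pathways(["iRSP", "PL", "ALM", "ENTl"])
        cop = default_coprojection(pws)
        assert sum(cop.target_set_probs.values()) == pytest.approx(1.0)
        singles = sum(p for s, p in cop.target_set_probs.items() if len(s) == 1)
        assert singles > 0.5
        for p in cop.detection_prob.values():
            assert 0.6 <= p <= 0.75
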