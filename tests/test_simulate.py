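"""The synthetic-data generator: rotation, determinism, noise model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from itraqpipe.reporter import CHANNELS
from itraqpipe.significance import classify
from itraqpipe.simulate import (
    GroundTruth,
    SimulationConfig,
    make_class_annotation,
    make_ground_truth,
    make_tag_rotation,
    simulate_experiment,
)

ABCD = ("A", "B", "C", "D")


class TestTagRotation:
    def test_identity_at_first_experiment(self):
        assert make_tag_rotation(1, ABCD) == {114: "A", 115: "B", 116: "C", 117: "D"}

    def test_one_step_cyclic_shift(self):
        assert make_tag_rotation(2, ABCD) == {114: "D", 115: "A", 116: "B", 117: "C"}

    def test_five_rotations_pairwise_distinct_bijections(self):
        rotations = [make_tag_rotation(i, ABCD) for i in range(1, 6)]
        for rotation in rotations:
            assert sorted(rotation.values()) == sorted(ABCD)  # bijection
        for i, a in enumerate(rotations):
            for b in rotations[i + 1:]:
                assert a != b

    @pytest.mark.parametrize("conditions", [("A", "B", "C"), ("A",) * 4, ("A",) * 5])
    def test_bad_condition_lists_rejected(self, conditions):
        with pytest.raises(ValueError):
            make_tag_rotation(1, conditions)


def uniform_truth(n_proteins=3, n_peptides=2, fold=1.0, conditions=ABCD):
    folds = {c: fold for c in conditions}
    folds[conditions[0]] = 1.0
    return [
        GroundTruth(
            protein_id=f"P{i}",
            condition_fold=dict(folds),
            condition_tier={c: 0 for c in conditions},
            tier_label=0,
            n_peptides=n_peptides,
            peptide_sequences=tuple(f"P{i}PEP{j}K" for j in range(n_peptides)),
        )
        for i in range(n_proteins)
    ]


class TestSimulateExperiment:
    CFG = SimulationConfig(n_proteins=3, conditions=ABCD, reference_condition="A",
                           noise_sd_log=0.0, seed=11)

    def test_unit_folds_and_zero_noise_give_equal_channels(self):
        records = simulate_experiment(uniform_truth(), self.CFG, 1)
        assert len(records) == 6  # 3 proteins x 2 peptides
        for record in records:
            values = record.intensities.intensities
            assert values[0] > 0
            for v in values[1:]:
                assert v / values[0] == pytest.approx(1.0, abs=0.0)

    def test_reproducible_under_fixed_seed(self):
        cfg = dataclasses.replace(self.CFG, noise_sd_log=0.05, missing_rate=0.1,
                                  decoy_rate=0.1, subthreshold_score_fraction=0.2)
        truth = uniform_truth()
        a = simulate_experiment(truth, cfg, 2)
        b = simulate_experiment(truth, cfg, 2)
        assert a == b

    def test_experiments_differ_from_each_other(self):
        cfg = dataclasses.replace(self.CFG, noise_sd_log=0.05)
        truth = uniform_truth()
        assert simulate_experiment(truth, cfg, 1) != simulate_experiment(truth, cfg, 2)

    def test_folds_drive_channel_ratios_through_the_rotation(self):
        truth = uniform_truth(fold=2.0)
        for experiment in (1, 3):
            tag_map = make_tag_rotation(experiment, ABCD)
            records = simulate_experiment(truth, self.CFG, experiment)
            for record in records:
                ref_channel = next(c for c, cond in tag_map.items() if cond == "A")
                for channel in CHANNELS:
                    expected = 1.0 if tag_map[channel] == "A" else 2.0
                    ratio = record.intensities[channel] / record.intensities[ref_channel]
                    assert ratio == pytest.approx(expected, rel=1e-12)

    def test_missing_rate_zeroes_channels(self):
        cfg = dataclasses.replace(self.CFG, missing_rate=0.5)
        records = simulate_experiment(uniform_truth(n_proteins=100), cfg, 1)
        values = np.array([r.intensities.intensities for r in records]).ravel()
        zero_fraction = (values == 0).mean()
        assert 0.4 < zero_fraction < 0.6

    def test_decoy_rate_annotates_records(self):
        cfg = dataclasses.replace(self.CFG, decoy_rate=0.3)
        records = simulate_experiment(uniform_truth(n_proteins=200), cfg, 1)
        flagged = [r for r in records if r.flags]
        assert 0.2 < len(flagged) / len(records) < 0.4
        for r in flagged:
            assert r.flags <= {"REVERSED", "Fragment"}
            if "REVERSED" in r.flags:
                assert r.accession.endswith("_REVERSED")

    def test_subthreshold_score_fraction_is_calibrated(self):
        cfg = dataclasses.replace(self.CFG, subthreshold_score_fraction=0.3)
        records = simulate_experiment(uniform_truth(n_proteins=1000, n_peptides=3), cfg, 1)
        below = np.mean([r.score <= 30.0 for r in records])
        assert below == pytest.approx(0.3, abs=0.03)

    def test_zero_subthreshold_fraction_puts_all_scores_above_cutoff(self):
        records = simulate_experiment(uniform_truth(n_proteins=200), self.CFG, 1)
        assert all(r.score > 30.0 for r in records)

    def test_out_of_range_experiment_rejected(self):
        with pytest.raises(ValueError):
            simulate_experiment(uniform_truth(), self.CFG, 6)


class TestGroundTruth:
    def test_tiers_consistent_with_classification_boundaries(self):
        cfg = SimulationConfig(n_proteins=300, fraction_regulated=0.4, seed=5)
        truth = make_ground_truth(cfg)
        thresholds = cfg.null_thresholds
        for protein in truth:
            for cond, fold in protein.condition_fold.items():
                assert protein.condition_tier[cond] == classify(fold, thresholds)
            assert abs(protein.tier_label) == max(
                abs(t) for t in protein.condition_tier.values()
            )
            assert protein.n_peptides >= 1
            assert len(protein.peptide_sequences) == protein.n_peptides

    def test_peptide_sequences_unique_across_proteome(self):
        truth = make_ground_truth(SimulationConfig(n_proteins=400, seed=3))
        sequences = [s for t in truth for s in t.peptide_sequences]
        assert len(sequences) == len(set(sequences))

    def test_unregulated_ratio_sample_mean_near_generating_mean(self):
        """370 unregulated folds average to the generating mean 1.02 +/- 0.02."""
        cfg = SimulationConfig(n_proteins=370, fraction_regulated=0.0,
                               noise_sd_log=0.05, seed=42)
        truth = make_ground_truth(cfg)
        folds = [
            fold
            for t in truth
            for cond, fold in t.condition_fold.items()
            if cond != cfg.reference_condition
        ]
        assert np.mean(folds[:370]) == pytest.approx(1.02, abs=0.02)

    def test_unregulated_folds_follow_configured_gaussian(self):
        """KS test against Normal(1.02, 0.10) on 10^4 unregulated folds."""
        cfg = SimulationConfig(n_proteins=4000, fraction_regulated=0.0, seed=8)
        truth = make_ground_truth(cfg)
        folds = np.array([
            fold
            for t in truth
            for cond, fold in t.condition_fold.items()
            if cond != cfg.reference_condition
        ])[:10000]
        assert folds.size == 10000
        p = stats.kstest(folds, "norm", args=(1.02, 0.10)).pvalue
        assert p > 0.01

    def test_regulated_fraction_and_band_centre_effects(self):
        cfg = SimulationConfig(n_proteins=2000, fraction_regulated=0.25, seed=9)
        truth = make_ground_truth(cfg)
        regulated = [t for t in truth if t.tier_label != 0]
        # includes null draws that land outside +/-1 SD on any of the three
        # non-reference conditions, so the fraction exceeds the configured
        # 0.25 by the null tail mass (~1 - 0.68^3 on the unregulated 75%)
        assert 0.25 < len(regulated) / len(truth) < 0.9
        centres = {1.17, 1.27, 1.37, 0.87, 0.77, 0.67}
        planted = [
            fold
            for t in truth
            for fold in t.condition_fold.values()
            if any(abs(fold - c) < 1e-12 for c in centres)
        ]
        assert len(planted) == pytest.approx(0.25 * len(truth), rel=0.15)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conditions": ("a", "b", "c")},
            {"conditions": ("a", "a", "b", "c")},
            {"reference_condition": "missing"},
            {"fraction_regulated": 1.5},
            {"missing_rate": -0.1},
            {"n_proteins": 0},
            {"null_ratio_sd": 0.0},
        ],
    )
    def test_degenerate_configs_rejected_at_construction(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


def test_class_annotation_covers_every_protein():
    truth = make_ground_truth(SimulationConfig(n_proteins=100, seed=2))
    annotation, membership = make_class_annotation(truth, n_classes=6, seed=2)
    assert set(membership) == {t.protein_id for t in truth}
    assert set(membership.values()) <= set(annotation)
    assert all(count >= 1 for _, count in annotation.values())
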