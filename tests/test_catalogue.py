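"""Filtering cascade, frequency-index catalogue and median aggregation."""

import numpy as np
import pytest

from itraqpipe.catalogue import (
    PeptideCatalogueEntry,
    aggregate_protein_ratios,
    build_catalogue,
    filter_peptides,
    select_top_frequency,
)
from itraqpipe.reporter import PeptideQuantRecord

from conftest import random_quant_records

FULL = {"a": 1.0, "b": 0.9, "c": 1.1, "d": 1.3}


def record(score=50.0, ratios=None, flags=(), peptide="PEPK", accession="ACC",
           experiment="exp1"):
    return PeptideQuantRecord(
        peptide_sequence=peptide,
        accession=accession,
        flags=frozenset(flags),
        score=score,
        ratios=dict(FULL if ratios is None else ratios),
        experiment_id=experiment,
    )


class TestFilter:
    def test_score_cutoff_is_strict(self):
        kept, report = filter_peptides([record(score=30.0)])
        assert kept == [] and report.removed_score == 1

    def test_just_above_cutoff_retained(self):
        kept, _ = filter_peptides([record(score=31.0)])
        assert len(kept) == 1

    def test_decoy_flag_removes_despite_good_score_and_ratios(self):
        kept, report = filter_peptides([record(score=80.0, flags={"REVERSED"})])
        assert kept == [] and report.removed_decoy == 1

    def test_fragment_flag_removed(self):
        kept, _ = filter_peptides([record(flags={"Fragment"})])
        assert kept == []

    def test_null_ratio_removes_record(self):
        kept, report = filter_peptides([record(ratios={**FULL, "c": None})])
        assert kept == [] and report.removed_null_ratio == 1

    def test_rule_order_in_report(self):
        # violates every rule; charged to the score rule, which is applied first
        _, report = filter_peptides(
            [record(score=10.0, ratios={**FULL, "b": None}, flags={"REVERSED"})]
        )
        assert report.as_dict() == {
            "n_input": 1, "n_retained": 0,
            "removed_score": 1, "removed_null_ratio": 0, "removed_decoy": 0,
        }

    def test_order_preserved_and_idempotent(self, rng):
        records = random_quant_records(rng, 300)
        kept, report = filter_peptides(records)
        assert report.n_input == 300
        assert report.n_retained == len(kept)
        positions = [records.index(r) for r in kept]
        assert positions == sorted(positions)
        again, report2 = filter_peptides(kept)
        assert again == kept
        assert report2.removed_score == report2.removed_null_ratio == 0
        assert report2.removed_decoy == 0


class TestCatalogue:
    def test_frequency_index_counts_distinct_experiments(self):
        records = [record(experiment=e) for e in ("exp1", "exp3", "exp5")]
        (entry,) = build_catalogue(records)
        assert entry.frequency_index == 3

    def test_duplicates_within_one_experiment_count_once(self):
        records = [
            record(experiment="exp2", ratios={**FULL, "b": 0.8}),
            record(experiment="exp2", ratios={**FULL, "b": 1.2}),
        ]
        (entry,) = build_catalogue(records)
        assert entry.frequency_index == 1
        assert sorted(r for _, r in entry.ratios_for("b")) == [0.8, 1.2]

    def test_pairs_keyed_on_sequence_and_accession(self):
        records = [
            record(peptide="AAK", accession="P1"),
            record(peptide="AAK", accession="P2"),
            record(peptide="CCK", accession="P1", experiment="exp2"),
        ]
        entries = build_catalogue(records)
        assert {(e.peptide_sequence, e.accession) for e in entries} == {
            ("AAK", "P1"), ("AAK", "P2"), ("CCK", "P1"),
        }

    def test_index_matches_brute_force_set_count(self, rng):
        records, _ = filter_peptides(random_quant_records(rng, 100))
        entries = build_catalogue(records)
        for entry in entries:
            expected = len({
                r.experiment_id
                for r in records
                if (r.peptide_sequence, r.accession)
                == (entry.peptide_sequence, entry.accession)
            })
            assert entry.frequency_index == expected

    def test_mapping_input_with_mislabelled_experiment_rejected(self):
        with pytest.raises(ValueError):
            build_catalogue({"exp2": [record(experiment="exp1")]})


def entry(index, peptide="P", accession="A"):
    observations = {f"exp{i}": [dict(FULL)] for i in range(1, index + 1)}
    return PeptideCatalogueEntry(peptide, accession, observations)


class TestSelectTopFrequency:
    def test_keeps_only_entries_at_required_index(self):
        catalogue = [entry(5), entry(4), entry(5), entry(2)]
        assert len(select_top_frequency(catalogue, 5)) == 2

    def test_requirement_of_one_keeps_everything(self):
        catalogue = [entry(5), entry(4), entry(5), entry(2)]
        assert select_top_frequency(catalogue, 1) == catalogue

    def test_empty_selection_warns_but_does_not_raise(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_top_frequency([entry(2)], 5) == []
        assert "frequency index" in caplog.text


class TestAggregation:
    def _single_protein(self, ratios_b):
        return [PeptideCatalogueEntry(f"PEP{i}", "ACC", {"exp1": [{"a": 1.0, "b": r}]})
                for i, r in enumerate(ratios_b)]

    def test_odd_count_median(self):
        (protein,) = aggregate_protein_ratios(self._single_protein([0.8, 1.0, 1.2]))
        assert protein.overall_ratio["b"] == 1.0

    def test_even_count_median_is_mean_of_central_pair(self):
        (protein,) = aggregate_protein_ratios(self._single_protein([1.0, 2.0]))
        assert protein.overall_ratio["b"] == 1.5

    def test_matches_sort_and_pick_oracle(self, rng):
        records, _ = filter_peptides(random_quant_records(rng, 400))
        proteins = aggregate_protein_ratios(build_catalogue(records))
        for protein in proteins:
            mine = [r for r in records if r.accession == protein.accession]
            for cond in protein.overall_ratio:
                values = sorted(r.ratios[cond] for r in mine)
                k = len(values)
                oracle = (
                    values[k // 2]
                    if k % 2
                    else (values[k // 2 - 1] + values[k // 2]) / 2.0
                )
                assert protein.overall_ratio[cond] == pytest.approx(oracle, rel=1e-12)
                # series medians, per experiment
            for (experiment, cond), value in protein.series_ratio.items():
                values = sorted(
                    r.ratios[cond] for r in mine if r.experiment_id == experiment
                )
                assert value == pytest.approx(float(np.median(values)), rel=1e-12)

    def test_permutation_invariance(self, rng):
        records, _ = filter_peptides(random_quant_records(rng, 200))
        forward = aggregate_protein_ratios(build_catalogue(records))
        shuffled = list(records)
        rng.shuffle(shuffled)
        backward = aggregate_protein_ratios(build_catalogue(shuffled))
        a = {p.accession: p.overall_ratio for p in forward}
        b = {p.accession: p.overall_ratio for p in backward}
        assert a == b

    def test_median_robust_to_minority_corruption(self, rng):
        k = 9
        clean = [float(v) for v in rng.uniform(0.8, 1.2, size=k)]
        corrupt = list(clean)
        for i in range((k - 1) // 2):  # corrupt floor((k-1)/2) of k values
            corrupt[i] *= 100.0
        (protein,) = aggregate_protein_ratios(self._single_protein(corrupt))
        assert min(clean) <= protein.overall_ratio["b"] <= max(clean)

    def test_n_peptides_counts_distinct_sequences(self):
        entries = [
            PeptideCatalogueEntry("PEP1", "ACC", {"exp1": [{"b": 1.0}]}),
            PeptideCatalogueEntry("PEP2", "ACC", {"exp1": [{"b": 2.0}], "exp2": [{"b": 3.0}]}),
        ]
        (protein,) = aggregate_protein_ratios(entries, n_required=1)
        assert protein.n_peptides == 2
        assert protein.frequency_index_used == 1
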