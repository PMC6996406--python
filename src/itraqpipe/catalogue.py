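"""Replicate-consensus protein quantitation from peptide ratio tables.

Implements the customizable iTRAQ ratio calculation stage: a three-rule
exclusion cascade on peptide records, a cross-replicate catalogue of
(peptide sequence, accession) pairs carrying a frequency index — the number
of independent experiments in which the pair survived filtering — and
median aggregation of peptide ratios into per-protein ratios, both pooled
over all experiments ("overall") and within each experiment
("series-specific").

Filtering rules, applied in order:
  (a) identification confidence: score strictly greater than the cutoff
      (default 30, i.e. random-match probability below 5%);
  (b) quantification confidence: every condition ratio present (records
      with 0.0 / uncalculated "null" ratios are discarded);
  (c) decoy exclusion: records flagged "Fragment" or "REVERSED" (or whose
      accession carries the REVERSED suffix) are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reporter import PeptideQuantRecord

__all__ = [
    "FilterReport",
    "PeptideCatalogueEntry",
    "ProteinQuant",
    "DECOY_FLAGS",
    "filter_peptides",
    "build_catalogue",
    "select_top_frequency",
    "aggregate_protein_ratios",
]

logger = logging.getLogger(__name__)

#: Annotation flags marking decoy / artefact database entries.
DECOY_FLAGS: frozenset[str] = frozenset({"Fragment", "REVERSED"})


@dataclass
class FilterReport:
    """Removal counts per exclusion rule (first failing rule wins)."""

    n_input: int = 0
    n_retained: int = 0
    removed_score: int = 0
    removed_null_ratio: int = 0
    removed_decoy: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_score": self.removed_score,
            "removed_null_ratio": self.removed_null_ratio,
            "removed_decoy": self.removed_decoy,
        }


@dataclass
class PeptideCatalogueEntry:
    """One (peptide sequence, accession) pair across the replicate series.

    ``observations`` maps experiment id to the list of per-condition ratio
    mappings contributed by that experiment; duplicate identifications
    within one experiment each contribute their ratios but the experiment
    counts once toward ``frequency_index``.
    """

    peptide_sequence: str
    accession: str
    observations: dict[str, list[dict[str, float]]] = field(default_factory=dict)

    @property
    def frequency_index(self) -> int:
        return len(self.observations)

    def ratios_for(self, condition: str) -> list[tuple[str, float]]:
        """(experiment, ratio) pairs for one condition, in catalogue order."""
        out = []
        for experiment, ratio_maps in self.observations.items():
            for ratios in ratio_maps:
                if condition in ratios:
                    out.append((experiment, ratios[condition]))
        return out


@dataclass
class ProteinQuant:
    """Median-aggregated ratios for one protein accession."""

    accession: str
    overall_ratio: dict[str, float]
    series_ratio: dict[tuple[str, str], float]  # (experiment, condition) -> median
    n_peptides: int
    frequency_index_used: int


def filter_peptides(
    records: Iterable[PeptideQuantRecord],
    score_cutoff: float = 30.0,
) -> tuple[list[PeptideQuantRecord], FilterReport]:
    """Apply the exclusion cascade; order of surviving records is preserved.

    Returns the retained records and a report counting removals per rule.
    A record violating several rules is charged to the first rule in the
    (a) score, (b) null-ratio, (c) decoy order.
    """
    report = FilterReport()
    retained: list[PeptideQuantRecord] = []
    for record in records:
        report.n_input += 1
        if not record.score > score_cutoff:
            report.removed_score += 1
            continue
        if not record.ratios or any(r is None for r in record.ratios.values()):
            report.removed_null_ratio += 1
            continue
        if record.flags & DECOY_FLAGS or record.accession.endswith("_REVERSED"):
            report.removed_decoy += 1
            continue
        retained.append(record)
    report.n_retained = len(retained)
    return retained, report


def build_catalogue(
    records: Iterable[PeptideQuantRecord] | Mapping[str, Sequence[PeptideQuantRecord]],
) -> list[PeptideCatalogueEntry]:
    """Exhaustive catalogue of (sequence, accession) pairs with frequency index.

    Accepts either a flat iterable of filtered records (each carries its
    experiment id) or a mapping experiment -> records.  Entries appear in
    first-encounter order, which makes the catalogue deterministic for a
    deterministic input order.
    """
    if isinstance(records, Mapping):
        flat: list[PeptideQuantRecord] = []
        for experiment, recs in records.items():
            for record in recs:
                if record.experiment_id and record.experiment_id != experiment:
                    raise ValueError(
                        f"record labelled {record.experiment_id!r} found under "
                        f"experiment {experiment!r}"
                    )
                flat.append(record)
        records = flat
    entries: dict[tuple[str, str], PeptideCatalogueEntry] = {}
    for record in records:
        key = (record.peptide_sequence, record.accession)
        entry = entries.get(key)
        if entry is None:
            entry = entries[key] = PeptideCatalogueEntry(
                peptide_sequence=record.peptide_sequence,
                accession=record.accession,
            )
        complete = {c: r for c, r in record.ratios.items() if r is not None}
        entry.observations.setdefault(record.experiment_id, []).append(complete)
    return list(entries.values())


def select_top_frequency(
    catalogue: Sequence[PeptideCatalogueEntry],
    n_required: int,
) -> list[PeptideCatalogueEntry]:
    """Second catalogue: only pairs identified in at least ``n_required`` experiments.

    With ``n_required`` equal to the number of replicates this keeps the
    peptides reproducibly identified in every experiment.  An empty result
    is legal (logged as a warning): it simply means no peptide reached the
    requested frequency index.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    selected = [e for e in catalogue if e.frequency_index >= n_required]
    if not selected:
        logger.warning(
            "no peptide reached frequency index %d (catalogue of %d entries)",
            n_required,
            len(catalogue),
        )
    return selected


def aggregate_protein_ratios(
    selected: Sequence[PeptideCatalogueEntry],
    n_required: int | None = None,
) -> list[ProteinQuant]:
    """Median peptide ratios per accession, overall and per experiment.

    The overall median pools every (experiment, peptide) ratio observation
    for the accession; series-specific medians are taken within each
    experiment.  Even-sized samples use the mean-of-central-pair median.
    """
    by_accession: dict[str, list[PeptideCatalogueEntry]] = defaultdict(list)
    for entry in selected:
        by_accession[entry.accession].append(entry)
    results: list[ProteinQuant] = []
    for accession, entries in by_accession.items():
        overall: dict[str, list[float]] = defaultdict(list)
        series: dict[tuple[str, str], list[float]] = defaultdict(list)
        conditions: set[str] = set()
        for entry in entries:
            for experiment, ratio_maps in entry.observations.items():
                for ratios in ratio_maps:
                    for condition, value in ratios.items():
                        conditions.add(condition)
                        overall[condition].append(value)
                        series[(experiment, condition)].append(value)
        results.append(
            ProteinQuant(
                accession=accession,
                overall_ratio={
                    c: float(np.median(overall[c])) for c in sorted(conditions)
                },
                series_ratio={
                    key: float(np.median(vals)) for key, vals in series.items()
                },
                n_peptides=len({e.peptide_sequence for e in entries}),
                frequency_index_used=(
                    n_required
                    if n_required is not None
                    else min(e.frequency_index for e in entries)
                ),
            )
        )
    return results
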