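"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-delimited text with a single header row:

* PSM tables — one identified spectrum per row with the four raw reporter
  intensities (``intensity_114`` .. ``intensity_117``);
* peptide quantitation tables (the ``.jpf`` dialect) — one row per peptide
  with per-condition ratios relative to the reference condition, nulls
  serialized as ``NA``;
* ground-truth tables for simulated studies;
* MGF fragment-spectrum files, through pyteomics.

Floats are written as their shortest round-tripping decimal representation,
so a fixed seed yields byte-identical files and exact read-backs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import yaml
from pyteomics import mgf as pyteomics_mgf

from .reporter import CHANNELS, REPORTER_MZ, ChannelIntensities, PeptideQuantRecord, ReporterSpectrum
from .simulate import GroundTruth, PsmRecord
from .significance import tier_label, tier_from_label

__all__ = [
    "write_psm_table",
    "read_psm_table",
    "write_jpf",
    "read_jpf",
    "write_ground_truth",
    "read_ground_truth",
    "write_mgf",
    "read_mgf",
    "read_flat_config",
]

_NA = "NA"


def _fmt(value: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(value))


def _format_flags(flags: frozenset[str]) -> str:
    return ",".join(sorted(flags)) if flags else "-"


def _parse_flags(cell: str) -> frozenset[str]:
    return frozenset() if cell in ("-", "") else frozenset(cell.split(","))


# ---------------------------------------------------------------------------
# PSM tables

def write_psm_table(records: Sequence[PsmRecord], path: str | Path) -> None:
    header = ["spectrum_id", "experiment", "peptide", "accession", "flags", "score"]
    header += [f"intensity_{c}" for c in CHANNELS]
    lines = ["\t".join(header)]
    for r in records:
        cells = [
            r.spectrum_id,
            r.experiment_id,
            r.peptide_sequence,
            r.accession,
            _format_flags(r.flags),
            _fmt(r.score),
        ]
        cells += [_fmt(v) for v in r.intensities.intensities]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        intensities = ChannelIntensities(
            tuple(float(row[f"intensity_{c}"]) for c in CHANNELS)
        )
        records.append(
            PsmRecord(
                spectrum_id=row["spectrum_id"],
                experiment_id=row["experiment"],
                peptide_sequence=row["peptide"],
                accession=row["accession"],
                flags=_parse_flags(row["flags"]),
                score=float(row["score"]),
                intensities=intensities,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Peptide quantitation (.jpf dialect)

def write_jpf(
    records: Sequence[PeptideQuantRecord],
    path: str | Path,
    conditions: Sequence[str],
) -> None:
    """Write a peptide ratio table with one ``ratio_<condition>`` column per
    condition (reference included, ratio 1 when computable); nulls as NA."""
    header = ["peptide", "accession", "flags", "score", "experiment"]
    header += [f"ratio_{c}" for c in conditions]
    lines = ["\t".join(header)]
    for r in records:
        cells = [
            r.peptide_sequence,
            r.accession,
            _format_flags(r.flags),
            _fmt(r.score),
            r.experiment_id,
        ]
        for cond in conditions:
            value = r.ratios.get(cond)
            cells.append(_NA if value is None else _fmt(value))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_jpf(path: str | Path) -> list[PeptideQuantRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    conditions = [h[len("ratio_"):] for h in header if h.startswith("ratio_")]
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        ratios: dict[str, float | None] = {}
        for cond in conditions:
            cell = row[f"ratio_{cond}"]
            ratios[cond] = None if cell == _NA else float(cell)
        records.append(
            PeptideQuantRecord(
                peptide_sequence=row["peptide"],
                accession=row["accession"],
                flags=_parse_flags(row["flags"]),
                score=float(row["score"]),
                ratios=ratios,
                experiment_id=row["experiment"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Ground truth

def write_ground_truth(
    truth: Sequence[GroundTruth], path: str | Path, conditions: Sequence[str]
) -> None:
    header = ["protein_id", "tier_label", "n_peptides"]
    header += [f"fold_{c}" for c in conditions] + [f"tier_{c}" for c in conditions]
    lines = ["\t".join(header)]
    for t in truth:
        cells = [t.protein_id, tier_label(t.tier_label), str(t.n_peptides)]
        cells += [_fmt(t.condition_fold[c]) for c in conditions]
        cells += [tier_label(t.condition_tier[c]) for c in conditions]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    conditions = [h[len("fold_"):] for h in header if h.startswith("fold_")]
    truths = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        truths.append(
            GroundTruth(
                protein_id=row["protein_id"],
                condition_fold={c: float(row[f"fold_{c}"]) for c in conditions},
                condition_tier={c: tier_from_label(row[f"tier_{c}"]) for c in conditions},
                tier_label=tier_from_label(row["tier_label"]),
                n_peptides=int(row["n_peptides"]),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# MGF spectra

def write_mgf(records: Sequence[PsmRecord], path: str | Path) -> None:
    """Write the reporter region of each PSM as an MGF spectrum.

    Peaks are emitted at the nominal reporter masses (zero-intensity
    channels omitted), which is all the reporter-extraction path consumes.
    """
    spectra = []
    for r in records:
        mz, intensity = [], []
        for channel in CHANNELS:
            value = r.intensities[channel]
            if value > 0:
                mz.append(REPORTER_MZ[channel])
                intensity.append(value)
        spectra.append(
            {
                "m/z array": mz,
                "intensity array": intensity,
                "params": {
                    "title": r.spectrum_id,
                    "pepmass": (500.0, None),
                    "charge": "2+",
                },
            }
        )
    with open(path, "w") as handle:
        pyteomics_mgf.write(spectra, handle)


def read_mgf(path: str | Path, experiment_id: str = "") -> list[ReporterSpectrum]:
    spectra = []
    with pyteomics_mgf.read(str(path)) as reader:
        for entry in reader:
            peaks = tuple(
                (float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                ReporterSpectrum(
                    spectrum_id=str(entry["params"].get("title", "")),
                    experiment_id=experiment_id,
                    peaks=peaks,
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# Config

def read_flat_config(path: str | Path) -> dict:
    """Flat key-value run configuration (YAML mapping, no nesting required)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return data
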