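"""End-to-end orchestration: simulate -> quantify -> aggregate -> classify
-> enrich -> cluster, with a run manifest.

Every stage writes its table under the run's output directory and records
its input/output row counts in the manifest; the whole run is a
deterministic function of the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import catalogue as cat
from . import cluster as clu
from . import enrichment as enr
from . import io as pio
from . import reporter as rep
from . import significance as sig
from .simulate import (
    PsmRecord,
    SimulationConfig,
    make_class_annotation,
    make_tag_rotation,
    simulate_study,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "quantify_psms"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the reference workflow: score cutoff 30, reporter
    tolerance 0.05 Da, frequency index requirement equal to the number of
    replicate experiments, bin width 0.05, alpha 0.05, average linkage.
    ``null_mean``/``null_sd``, when both set, fix the tier thresholds
    instead of the Gaussian fitted from the data (the fit is still computed
    and reported when possible).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | Path = "itraqpipe_run"
    score_cutoff: float = 30.0
    reporter_tolerance: float = 0.05
    bin_width: float = 0.05
    n_required: int | None = None
    alpha: float = 0.05
    linkage: str = "average"
    cluster_columns: bool = False
    null_mean: float | None = None
    null_sd: float | None = None
    enrichment_classes: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))
        if self.n_required is None:
            self.n_required = self.simulation.n_experiments


def quantify_psms(
    records: Sequence[PsmRecord],
    tag_map: Mapping[int, str],
    reference_condition: str,
    matrix: rep.IsotopeCorrectionMatrix | None = None,
    qc: dict | None = None,
) -> list[rep.PeptideQuantRecord]:
    """Turn PSM reporter intensities into per-condition peptide ratios."""
    out = []
    for record in records:
        intensities = record.intensities
        if matrix is not None:
            intensities = rep.correct_isotope_impurities(intensities, matrix, qc=qc)
        ratios = rep.compute_peptide_ratios(intensities, tag_map, reference_condition)
        out.append(
            rep.PeptideQuantRecord(
                peptide_sequence=record.peptide_sequence,
                accession=record.accession,
                flags=record.flags,
                score=record.score,
                ratios=ratios,
                experiment_id=record.experiment_id,
            )
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_protein_quant(
    proteins: Sequence[cat.ProteinQuant],
    path: Path,
    conditions: Sequence[str],
    experiments: Sequence[str],
) -> None:
    header = ["accession", "n_peptides", "frequency_index"]
    header += [f"ratio_{c}" for c in conditions]
    header += [f"series_{e}_{c}" for e in experiments for c in conditions]
    lines = ["\t".join(header)]
    for p in sorted(proteins, key=lambda p: p.accession):
        cells = [p.accession, str(p.n_peptides), str(p.frequency_index_used)]
        for c in conditions:
            v = p.overall_ratio.get(c)
            cells.append("NA" if v is None else f"{v:.10g}")
        for e in experiments:
            for c in conditions:
                v = p.series_ratio.get((e, c))
                cells.append("NA" if v is None else f"{v:.10g}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def _write_classification(
    rows: Sequence[tuple[str, str, float, int]], path: Path
) -> None:
    lines = ["accession\tcondition\tratio\ttier"]
    for accession, condition, ratio, tier in rows:
        lines.append(f"{accession}\t{condition}\t{ratio:.10g}\t{sig.tier_label(tier)}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    The manifest lists, per stage, the row counts in and out plus stage
    summaries, and a checksum inventory of every file written.  Identical
    configuration and seed give byte-identical outputs.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.simulation
    conditions = list(scfg.conditions)
    non_reference = [c for c in conditions if c != scfg.reference_condition]
    manifest: dict = {
        "seed": scfg.seed,
        "config": {
            "score_cutoff": cfg.score_cutoff,
            "reporter_tolerance": cfg.reporter_tolerance,
            "bin_width": cfg.bin_width,
            "n_required": cfg.n_required,
            "alpha": cfg.alpha,
            "linkage": cfg.linkage,
            "conditions": conditions,
            "reference_condition": scfg.reference_condition,
            "n_experiments": scfg.n_experiments,
            "tag_rotation": "cyclic shift by (experiment - 1)",
            "simulation": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(scfg).items()
            },
        },
        "stages": {},
        "files": {},
    }

    def _stage(name: str):
        logger.info("stage %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- simulate -----------------------------------------------------
    try:
        info = _stage("simulate")
        truth, tables = simulate_study(scfg)
        pio.write_ground_truth(truth, out_dir / "ground_truth.tsv", conditions)
        for experiment, records in tables.items():
            pio.write_psm_table(records, out_dir / f"psm_{experiment}.tsv")
        info["n_proteins"] = len(truth)
        info["n_psms"] = {e: len(r) for e, r in tables.items()}
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    # --- quantify -----------------------------------------------------
    try:
        info = _stage("quantify")
        matrix = (
            rep.load_default_correction_matrix()
            if scfg.apply_isotope_impurities
            else None
        )
        qc: dict = {}
        quant: dict[str, list[rep.PeptideQuantRecord]] = {}
        for e in range(1, scfg.n_experiments + 1):
            experiment = f"exp{e}"
            tag_map = make_tag_rotation(e, conditions)
            quant[experiment] = quantify_psms(
                tables[experiment], tag_map, scfg.reference_condition,
                matrix=matrix, qc=qc,
            )
            pio.write_jpf(quant[experiment], out_dir / f"peptides_{experiment}.jpf", conditions)
        info["n_records"] = {e: len(r) for e, r in quant.items()}
        info["isotope_correction"] = matrix is not None
        info["qc"] = qc
    except Exception as exc:
        raise PipelineError(f"stage quantify failed: {exc}") from exc

    # --- aggregate ----------------------------------------------------
    try:
        info = _stage("aggregate")
        filtered: dict[str, list[rep.PeptideQuantRecord]] = {}
        reports = {}
        for experiment, records in quant.items():
            kept, report = cat.filter_peptides(records, cfg.score_cutoff)
            filtered[experiment] = kept
            reports[experiment] = report.as_dict()
        peptide_catalogue = cat.build_catalogue(filtered)
        selected = cat.select_top_frequency(peptide_catalogue, cfg.n_required)
        proteins = cat.aggregate_protein_ratios(selected, n_required=cfg.n_required)
        experiments = sorted(quant)
        _write_protein_quant(
            proteins, out_dir / "protein_quant.tsv", conditions, experiments
        )
        info["filter_reports"] = reports
        info["catalogue_entries"] = len(peptide_catalogue)
        info["selected_entries"] = len(selected)
        info["n_proteins_quantified"] = len(proteins)
        if not proteins:
            logger.warning("no protein reached frequency index %d", cfg.n_required)
    except Exception as exc:
        raise PipelineError(f"stage aggregate failed: {exc}") from exc

    # --- classify -----------------------------------------------------
    try:
        info = _stage("classify")
        ratio_rows = [
            (p.accession, c, p.overall_ratio[c])
            for p in sorted(proteins, key=lambda p: p.accession)
            for c in non_reference
            if c in p.overall_ratio
        ]
        ratios = [r for _, _, r in ratio_rows]
        fit = None
        if ratios:
            try:
                fit = sig.fit_gaussian(sig.build_ratio_histogram(ratios, cfg.bin_width))
            except sig.GaussianFitError as exc:
                logger.warning("Gaussian fit unavailable: %s", exc)
        if cfg.null_mean is not None and cfg.null_sd is not None:
            thresholds = sig.TierThresholds.from_fit(cfg.null_mean, cfg.null_sd)
            info["thresholds_source"] = "configured null"
        elif fit is not None:
            thresholds = sig.tier_thresholds(fit)
            info["thresholds_source"] = "gaussian fit"
        else:
            thresholds = None
            info["thresholds_source"] = "unavailable"
        classified = []
        if thresholds is not None:
            classified = [
                (accession, condition, ratio, sig.classify(ratio, thresholds))
                for accession, condition, ratio in ratio_rows
            ]
            _write_classification(classified, out_dir / "classification.tsv")
        if fit is not None:
            (out_dir / "gaussian_fit.json").write_text(
                json.dumps(dataclasses.asdict(fit), indent=2, sort_keys=True) + "\n"
            )
            info["fit"] = dataclasses.asdict(fit)
        info["n_classified"] = len(classified)
        if thresholds is not None:
            info["boundaries"] = [round(b, 10) for b in thresholds.boundaries]
    except Exception as exc:
        raise PipelineError(f"stage classify failed: {exc}") from exc

    # --- enrich -------------------------------------------------------
    try:
        info = _stage("enrich")
        quantified = sorted(p.accession for p in proteins)
        if len(quantified) >= 2:
            annotation_map, membership = make_class_annotation(
                truth, n_classes=cfg.enrichment_classes, seed=scfg.seed
            )
            reference_total = 20000
            annotation = enr.AnnotationTable(
                classes=annotation_map, reference_total=reference_total
            )
            observed: dict[str, int] = {}
            for accession in quantified:
                cid = membership.get(accession)
                if cid is not None:
                    observed[cid] = observed.get(cid, 0) + 1
            rows = enr.overrepresentation_test(
                annotation, observed, input_size=len(quantified)
            )
            retained = enr.bonferroni_filter(rows, alpha=cfg.alpha)
            enr.write_enrichment_table(rows, out_dir / "enrichment.tsv")
            info["n_classes_tested"] = len(rows)
            info["n_significant"] = len(retained)
        else:
            logger.warning("enrich skipped: fewer than 2 quantified proteins")
            info["skipped"] = "fewer than 2 quantified proteins"
    except Exception as exc:
        raise PipelineError(f"stage enrich failed: {exc}") from exc

    # --- cluster ------------------------------------------------------
    try:
        info = _stage("cluster")
        complete = [
            p for p in proteins
            if all(c in p.overall_ratio for c in non_reference)
        ]
        if len(complete) >= 2:
            matrix_df = pd.DataFrame(
                [[p.overall_ratio[c] for c in non_reference] for p in complete],
                index=[p.accession for p in complete],
                columns=non_reference,
            ).sort_index()
            rows_dend, cols_dend = clu.cluster_matrix(
                matrix_df, linkage=cfg.linkage, cluster_columns=cfg.cluster_columns
            )
            ordered = clu.order_matrix(matrix_df, rows_dend, cols_dend)
            clu.write_ordered_matrix(ordered, out_dir / "heatmap_matrix.tsv")
            (out_dir / "dendrogram.nwk").write_text(clu.to_newick(rows_dend) + "\n")
            info["n_rows"] = int(matrix_df.shape[0])
            info["leaf_order_first"] = rows_dend.ordered_labels[0]
        else:
            logger.warning("cluster skipped: fewer than 2 complete profiles")
            info["skipped"] = "fewer than 2 complete ratio profiles"
    except Exception as exc:
        raise PipelineError(f"stage cluster failed: {exc}") from exc

    # --- manifest -----------------------------------------------------
    for path in sorted(out_dir.iterdir()):
        if path.name == "run_manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256(path)
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
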