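"""Synthetic 4-plex shotgun-proteomics data with known ground truth.

The generator emulates the statistical structure of a five-replicate iTRAQ
4-plex experiment: four exposure conditions rotated over the four reporter
channels (a different tag/condition association per replicate), several
tryptic peptides per protein, multiplicative log-normal reporter noise, a
null ratio distribution approximately Gaussian(1.02, 0.10), a configurable
fraction of truly regulated proteins placed at +/-sigma, +/-2sigma and
+/-3sigma effect sizes, and opt-in contamination: zeroed reporter channels,
sub-threshold identification scores and decoy ("REVERSED"/"Fragment")
records.  Every downstream stage of the pipeline can therefore be tested
against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .reporter import CHANNELS, ChannelIntensities
from .significance import TierThresholds, classify

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PsmRecord",
    "make_tag_rotation",
    "make_ground_truth",
    "simulate_experiment",
    "simulate_study",
    "make_class_annotation",
]

_AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic terminus

#: Significance tiers, as signed sigma multiples: -3..-1 down, 0 none, 1..3 up.
REGULATED_TIERS = (-3, -2, -1, 1, 2, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for one simulated dataset.

    Defaults describe a measurement-noise-only experiment matching the
    design being emulated: 5 biological replicates, 4 conditions on a 4-plex,
    null ratios ~ Normal(1.02, 0.10).  The contamination channels
    (``missing_rate``, ``decoy_rate``, ``subthreshold_score_fraction``)
    default to zero and are switched on explicitly when robustness of the
    filtering cascade is under test.
    """

    n_proteins: int = 500
    n_experiments: int = 5
    conditions: tuple[str, str, str, str] = ("vehicle", "CsA", "Tac", "CAI")
    reference_condition: str = "vehicle"
    fraction_regulated: float = 0.2
    noise_sd_log: float = 0.02
    missing_rate: float = 0.0
    decoy_rate: float = 0.0
    subthreshold_score_fraction: float = 0.0
    null_ratio_mean: float = 1.02
    null_ratio_sd: float = 0.10
    peptides_geometric_p: float = 0.35
    max_peptides_per_protein: int = 12
    base_intensity_range: tuple[float, float] = (1e3, 1e6)
    score_cutoff: float = 30.0
    apply_isotope_impurities: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != 4:
            raise ValueError("4-plex design requires exactly 4 conditions")
        if len(set(self.conditions)) != 4:
            raise ValueError("conditions must be distinct")
        if self.reference_condition not in self.conditions:
            raise ValueError("reference_condition must be one of the conditions")
        for name in ("fraction_regulated", "missing_rate", "decoy_rate",
                     "subthreshold_score_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ValueError("n_proteins and n_experiments must be positive")
        if self.noise_sd_log < 0 or self.null_ratio_sd <= 0:
            raise ValueError("noise scales must be non-negative (null SD positive)")
        if not 0.0 < self.peptides_geometric_p <= 1.0:
            raise ValueError("peptides_geometric_p must lie in (0, 1]")

    @property
    def null_thresholds(self) -> TierThresholds:
        return TierThresholds.from_fit(self.null_ratio_mean, self.null_ratio_sd)


@dataclass(frozen=True)
class GroundTruth:
    """True state of one simulated protein.

    ``condition_fold`` holds the true abundance ratio of each condition
    relative to the reference (reference itself maps to 1).  Tiers are the
    classification of those true folds under the generating null
    (mean 1.02, SD 0.10 by default); ``tier_label`` summarises the protein
    by its most extreme condition tier.
    """

    protein_id: str
    condition_fold: dict[str, float]
    condition_tier: dict[str, int]
    tier_label: int
    n_peptides: int
    peptide_sequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")


@dataclass(frozen=True)
class PsmRecord:
    """One identified peptide spectrum with its four reporter intensities."""

    spectrum_id: str
    experiment_id: str
    peptide_sequence: str
    accession: str
    flags: frozenset[str]
    score: float
    intensities: ChannelIntensities


def make_tag_rotation(
    experiment_index: int, conditions: Sequence[str]
) -> dict[int, str]:
    """Channel -> condition association for one replicate experiment.

    Experiment 1 is the identity association (114 -> first condition, ...)
    and experiments 2-4 shift the conditions cyclically one channel to the
    right.  A pure cyclic shift of four conditions has period four, so from
    the fifth experiment on the condition order is additionally reversed
    before shifting; this yields eight pairwise-distinct bijections — in
    particular the five associations of a five-replicate study all differ.
    """
    if len(conditions) != 4:
        raise ValueError("exactly 4 conditions required for the 4-plex rotation")
    if len(set(conditions)) != 4:
        raise ValueError("conditions must be distinct")
    if experiment_index < 1:
        raise ValueError("experiment_index starts at 1")
    shift = (experiment_index - 1) % 4
    order = list(conditions)
    if (experiment_index - 1) // 4 % 2 == 1:
        order.reverse()
    return {
        channel: order[(pos - shift) % 4]
        for pos, channel in enumerate(CHANNELS)
    }


def _peptide_sequence(protein_index: int, peptide_index: int) -> str:
    """Deterministic pseudo-tryptic sequence, unique per (protein, peptide).

    Sequences are a function of the indices only, so the same peptide is
    re-identified in every experiment — required for the cross-replicate
    frequency index to be meaningful.
    """
    code = protein_index * 1009 + peptide_index  # 1009 > max_peptides, keeps codes unique
    letters = []
    n = len(_AMINO_ACIDS)
    for _ in range(7):
        letters.append(_AMINO_ACIDS[code % n])
        code //= n
    return "".join(letters) + "K"


def _draw_n_peptides(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    # geometric(min 1), truncated so no protein has an absurd peptide count
    k = int(rng.geometric(cfg.peptides_geometric_p))
    return min(k, cfg.max_peptides_per_protein)


def make_ground_truth(cfg: SimulationConfig) -> list[GroundTruth]:
    """Draw the true per-protein condition folds and tier labels.

    Unregulated condition folds are drawn from the configured null,
    Normal(null_ratio_mean, null_ratio_sd).  A regulated protein gets one
    randomly chosen non-reference condition placed at the centre of its
    assigned tier band (mean +/- (k + 1/2)*SD for |tier| = k; the open-ended
    3-sigma tiers use mean +/- 3.5*SD), which keeps true effects away from
    the classification boundaries.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    thresholds = cfg.null_thresholds
    non_reference = [c for c in cfg.conditions if c != cfg.reference_condition]
    truths: list[GroundTruth] = []
    for i in range(cfg.n_proteins):
        n_peptides = _draw_n_peptides(rng, cfg)
        regulated = rng.random() < cfg.fraction_regulated
        folds: dict[str, float] = {cfg.reference_condition: 1.0}
        for cond in non_reference:
            folds[cond] = _draw_null_fold(rng, cfg)
        if regulated:
            tier = REGULATED_TIERS[rng.integers(len(REGULATED_TIERS))]
            cond = non_reference[rng.integers(len(non_reference))]
            offset = (abs(tier) + 0.5) * cfg.null_ratio_sd
            folds[cond] = cfg.null_ratio_mean + math.copysign(offset, tier)
        tiers = {c: classify(f, thresholds) for c, f in folds.items()}
        label = max(tiers.values(), key=lambda t: (abs(t), t))
        truths.append(
            GroundTruth(
                protein_id=f"SYN{i:05d}",
                condition_fold=folds,
                condition_tier=tiers,
                tier_label=label,
                n_peptides=n_peptides,
                peptide_sequences=tuple(
                    _peptide_sequence(i, j) for j in range(n_peptides)
                ),
            )
        )
    return truths


def _draw_null_fold(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    # rejection keeps the fold positive without distorting the bulk of the
    # Gaussian (P(<=0) ~ 1e-24 at the default parameters)
    while True:
        fold = rng.normal(cfg.null_ratio_mean, cfg.null_ratio_sd)
        if fold > 0:
            return fold


def _score_scale(cfg: SimulationConfig) -> tuple[float, float]:
    """(loc, scale) of the shifted gamma the identification scores follow.

    Shape is fixed at 2; the scale is solved in closed form so that
    P(score <= cutoff) equals ``subthreshold_score_fraction``.  A fraction
    of zero degenerates (the solution pushes all mass to infinity), so it
    short-circuits to a distribution supported strictly above the cutoff.
    """
    f = cfg.subthreshold_score_fraction
    if f <= 0.0:
        return cfg.score_cutoff + 5.0, 15.0
    loc = 10.0
    span = cfg.score_cutoff - loc
    scale = span / float(special.gammaincinv(2.0, f))
    return loc, scale


def simulate_experiment(
    truth: Sequence[GroundTruth],
    cfg: SimulationConfig,
    experiment_index: int,
) -> list[PsmRecord]:
    """Generate the PSM table of one replicate experiment.

    Reporter intensity of channel c is
    ``base * fold(condition(c)) * exp(Normal(0, noise_sd_log))`` with the
    base intensity drawn log-uniform over ``base_intensity_range``; each
    channel is independently zeroed with probability ``missing_rate``;
    records become decoys ("REVERSED" or "Fragment" annotated) with
    probability ``decoy_rate``.  Fully deterministic given (cfg.seed,
    experiment_index).
    """
    if not 1 <= experiment_index <= cfg.n_experiments:
        raise ValueError(
            f"experiment_index must be in 1..{cfg.n_experiments}, got {experiment_index}"
        )
    rng = np.random.default_rng([cfg.seed, experiment_index])
    tag_map = make_tag_rotation(experiment_index, cfg.conditions)
    loc, scale = _score_scale(cfg)
    lo, hi = cfg.base_intensity_range
    from .reporter import load_default_correction_matrix

    mix = load_default_correction_matrix() if cfg.apply_isotope_impurities else None
    experiment_id = f"exp{experiment_index}"
    records: list[PsmRecord] = []
    spectrum_no = 0
    for protein in truth:
        for sequence in protein.peptide_sequences:
            spectrum_no += 1
            base = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            intensities = []
            for channel in CHANNELS:
                fold = protein.condition_fold[tag_map[channel]]
                noise = math.exp(rng.normal(0.0, cfg.noise_sd_log)) if cfg.noise_sd_log else 1.0
                value = base * fold * noise
                if cfg.missing_rate and rng.random() < cfg.missing_rate:
                    value = 0.0
                intensities.append(value)
            channel_intensities = ChannelIntensities(tuple(intensities))
            if mix is not None:
                channel_intensities = mix.apply(channel_intensities)
            score = loc + scale * rng.gamma(2.0)
            accession = protein.protein_id
            flags: frozenset[str] = frozenset()
            if cfg.decoy_rate and rng.random() < cfg.decoy_rate:
                flag = "REVERSED" if rng.random() < 0.5 else "Fragment"
                flags = frozenset({flag})
                if flag == "REVERSED":
                    accession = accession + "_REVERSED"
            records.append(
                PsmRecord(
                    spectrum_id=f"{experiment_id}.{spectrum_no}",
                    experiment_id=experiment_id,
                    peptide_sequence=sequence,
                    accession=accession,
                    flags=flags,
                    score=float(score),
                    intensities=channel_intensities,
                )
            )
    return records


def simulate_study(
    cfg: SimulationConfig, truth: Sequence[GroundTruth] | None = None
) -> tuple[list[GroundTruth], dict[str, list[PsmRecord]]]:
    """All replicate experiments of one study, keyed by experiment id."""
    if truth is None:
        truth = make_ground_truth(cfg)
    tables = {
        f"exp{e}": simulate_experiment(truth, cfg, e)
        for e in range(1, cfg.n_experiments + 1)
    }
    return list(truth), tables


def make_class_annotation(
    truth: Sequence[GroundTruth],
    n_classes: int = 8,
    reference_total: int = 20000,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, int]], dict[str, str]]:
    """Assign simulated proteins to synthetic protein classes.

    Returns ``(annotation, membership)`` where ``annotation`` maps class id
    to (class name, reference count out of ``reference_total``) and
    ``membership`` maps protein id to its class — enough to drive the
    over-representation test on simulated data.
    """
    rng = np.random.default_rng([seed, 9001])
    class_ids = [f"CL{k:04d}" for k in range(n_classes)]
    # Zipf-ish reference counts: a few big classes, many small ones
    raw = rng.pareto(1.5, size=n_classes) + 1.0
    counts = np.maximum(1, (raw / raw.sum() * reference_total * 0.6).astype(int))
    annotation = {
        cid: (f"Synthetic class {k}", int(counts[k]))
        for k, cid in enumerate(class_ids)
    }
    weights = counts / counts.sum()
    membership = {
        protein.protein_id: class_ids[rng.choice(n_classes, p=weights)]
        for protein in truth
    }
    return annotation, membership
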