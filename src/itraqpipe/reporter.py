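"""Reporter-ion quantitation for iTRAQ 4-plex spectra.

The four isobaric tags release reporter fragments at nominal m/z 114-117 on
CID; the intensity of each reporter is proportional to the amount of peptide
contributed by the correspondingly labelled sample.  This module extracts
those intensities from fragment spectra, removes inter-channel isotope
leakage using the vendor purity factors, and turns corrected intensities
into per-condition ratios relative to a reference (control) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CHANNELS",
    "REPORTER_MZ",
    "ReporterSpectrum",
    "ChannelIntensities",
    "IsotopeCorrectionMatrix",
    "PeptideQuantRecord",
    "extract_reporter_intensities",
    "correct_isotope_impurities",
    "compute_peptide_ratios",
    "load_default_correction_matrix",
]

#: iTRAQ 4-plex reporter channels, by nominal mass.
CHANNELS: tuple[int, ...] = (114, 115, 116, 117)

#: Monoisotopic reporter-ion m/z for the 4-plex tags.
REPORTER_MZ: dict[int, float] = {
    114: 114.1112,
    115: 115.1083,
    116: 116.1116,
    117: 117.1150,
}

# Half the smallest spacing between adjacent reporter masses; a tolerance at
# or above this makes the extraction windows overlap.
_MAX_TOLERANCE = min(
    b - a for a, b in zip(sorted(REPORTER_MZ.values()), sorted(REPORTER_MZ.values())[1:])
) / 2.0


@dataclass(frozen=True)
class ReporterSpectrum:
    """A fragment spectrum restricted to what reporter extraction needs."""

    spectrum_id: str
    experiment_id: str
    peaks: tuple[tuple[float, float], ...]  # (m/z [Da], intensity [counts])

    def __post_init__(self) -> None:
        for mz, intensity in self.peaks:
            if mz <= 0:
                raise ValueError(f"non-positive m/z {mz!r} in {self.spectrum_id}")
            if intensity < 0:
                raise ValueError(f"negative intensity {intensity!r} in {self.spectrum_id}")


@dataclass(frozen=True)
class ChannelIntensities:
    """Reporter intensities for the four channels, in acquisition counts."""

    intensities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.intensities) != 4:
            raise ValueError("exactly 4 channels required")
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_mapping(cls, values: Mapping[int, float]) -> "ChannelIntensities":
        return cls(tuple(float(values.get(c, 0.0)) for c in CHANNELS))

    def __getitem__(self, channel: int) -> float:
        return self.intensities[CHANNELS.index(channel)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intensities, dtype=float)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(CHANNELS, self.intensities))


class IsotopeCorrectionMatrix:
    """4x4 isotope-purity mixing matrix.

    Entry ``(i, j)`` is the fraction of tag *j*'s reporter signal that is
    observed in channel *i*; observed = M @ true.  Columns sum to at most 1
    (signal lost outside the four windows is allowed) and the matrix must be
    invertible so the true intensities can be solved for.
    """

    def __init__(self, matrix: np.ndarray | Sequence[Sequence[float]]):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"correction matrix must be 4x4, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("purity fractions must be non-negative")
        colsums = m.sum(axis=0)
        if np.any(colsums > 1.0 + 1e-9):
            raise ValueError("each column of purity fractions must sum to <= 1")
        if abs(np.linalg.det(m)) < 1e-12:
            raise np.linalg.LinAlgError("correction matrix is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "IsotopeCorrectionMatrix":
        return cls(np.eye(4))

    @classmethod
    def from_impurity_percentages(
        cls, impurities: Mapping[int, Mapping[int, float]]
    ) -> "IsotopeCorrectionMatrix":
        """Build the mixing matrix from a vendor-style impurity table.

        ``impurities[channel][offset]`` is the percentage of tag ``channel``'s
        signal appearing ``offset`` channels away (offsets -2..+2, percent
        units as printed on the certificate of analysis).  The diagonal is
        one minus the sum of the listed impurities.
        """
        m = np.zeros((4, 4))
        for j, channel in enumerate(CHANNELS):
            offsets = impurities.get(channel, {})
            leaked = 0.0
            for offset, percent in offsets.items():
                frac = float(percent) / 100.0
                leaked += frac
                i = j + int(offset)
                if 0 <= i < 4:
                    m[i, j] += frac
            m[j, j] += 1.0 - leaked
        return cls(m)

    def apply(self, true_intensities: ChannelIntensities) -> ChannelIntensities:
        """Forward-mix pure intensities into what the instrument observes."""
        mixed = self.matrix @ true_intensities.as_array()
        return ChannelIntensities(tuple(mixed))


@dataclass
class PeptideQuantRecord:
    """One row of a peptide quantitation (.jpf-style) table.

    ``ratios`` maps condition name to the reporter-intensity ratio *r*
    against the reference condition; ``None`` marks a null ratio (a zero or
    uncalculable channel).  The reference condition's ratio is 1 when it is
    computable at all.
    """

    peptide_sequence: str
    accession: str
    flags: frozenset[str] = field(default_factory=frozenset)
    score: float = 0.0
    ratios: dict[str, float | None] = field(default_factory=dict)
    experiment_id: str = ""

    def __post_init__(self) -> None:
        for cond, r in self.ratios.items():
            if r is not None and r <= 0:
                raise ValueError(f"ratio for {cond!r} must be positive or null, got {r}")


def extract_reporter_intensities(
    spectrum: ReporterSpectrum, tolerance: float = 0.05
) -> ChannelIntensities:
    """Sum peak intensities within ``tolerance`` Da of each reporter mass.

    Channels with no peak in their window get intensity 0.  The default
    window of +/-0.05 Da is narrow enough that the four windows never
    overlap; a tolerance of half the inter-channel spacing or more is
    rejected as a configuration error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if tolerance >= _MAX_TOLERANCE:
        raise ValueError(
            f"tolerance {tolerance} Da makes reporter windows overlap "
            f"(must be < {_MAX_TOLERANCE:.3f} Da)"
        )
    if not spectrum.peaks:
        return ChannelIntensities((0.0, 0.0, 0.0, 0.0))
    mz = np.array([p[0] for p in spectrum.peaks])
    inten = np.array([p[1] for p in spectrum.peaks])
    sums = []
    for channel in CHANNELS:
        in_window = np.abs(mz - REPORTER_MZ[channel]) <= tolerance
        sums.append(float(inten[in_window].sum()))
    return ChannelIntensities(tuple(sums))


def correct_isotope_impurities(
    observed: ChannelIntensities,
    matrix: IsotopeCorrectionMatrix,
    qc: dict | None = None,
) -> ChannelIntensities:
    """Solve the isotope mixing system M @ x = observed for the pure signal.

    Small negative solutions (noise pushed through the inversion) are
    clipped to zero; when ``qc`` is given, ``qc["clipped_negative"]`` counts
    how many channels were clipped across calls.
    """
    x = np.linalg.solve(matrix.matrix, observed.as_array())
    negative = x < 0
    if negative.any():
        if qc is not None:
            qc["clipped_negative"] = qc.get("clipped_negative", 0) + int(negative.sum())
        x = np.where(negative, 0.0, x)
    return ChannelIntensities(tuple(x))


def compute_peptide_ratios(
    corrected: ChannelIntensities,
    tag_map: Mapping[int, str],
    reference_condition: str,
) -> dict[str, float | None]:
    """Reporter ratios per condition, relative to the reference channel.

    A ratio is null (``None``) whenever the reference intensity is zero or
    the condition's own channel intensity is zero — the "0.0 / uncalculated"
    ratios that the downstream filter discards.
    """
    cond_to_channel = {cond: ch for ch, cond in tag_map.items()}
    if reference_condition not in cond_to_channel:
        raise ValueError(f"reference condition {reference_condition!r} not in tag map")
    ref_intensity = corrected[cond_to_channel[reference_condition]]
    ratios: dict[str, float | None] = {}
    for cond, channel in cond_to_channel.items():
        intensity = corrected[channel]
        if ref_intensity == 0 or intensity == 0:
            ratios[cond] = None
        else:
            ratios[cond] = intensity / ref_intensity
    return ratios


def load_default_correction_matrix() -> IsotopeCorrectionMatrix:
    """Load the packaged 4-plex isotope-impurity table.

    The shipped values are typical certificate-of-analysis figures for the
    4-plex reagent; real lots vary, so production use should point at the
    certificate for the lot actually used (see ``data/isotope_correction_4plex.yaml``).
    """
    ref = resources.files("itraqpipe.data").joinpath("isotope_correction_4plex.yaml")
    table = yaml.safe_load(ref.read_text())
    impurities = {
        int(channel): {int(off): float(pct) for off, pct in offsets.items()}
        for channel, offsets in table["impurity_percent"].items()
    }
    return IsotopeCorrectionMatrix.from_impurity_percentages(impurities)


def quantify_spectra(
    spectra: Iterable[ReporterSpectrum],
    tag_map: Mapping[int, str],
    reference_condition: str,
    matrix: IsotopeCorrectionMatrix | None = None,
    tolerance: float = 0.05,
    qc: dict | None = None,
) -> list[dict[str, float | None]]:
    """Convenience path: extract, correct and ratio a stream of spectra."""
    matrix = matrix or load_default_correction_matrix()
    out = []
    for spectrum in spectra:
        obs = extract_reporter_intensities(spectrum, tolerance)
        corrected = correct_isotope_impurities(obs, matrix, qc=qc)
        out.append(compute_peptide_ratios(corrected, tag_map, reference_condition))
    return out
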