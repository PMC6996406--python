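"""Significance tiers for relative protein abundance ratios.

The bulk of protein ratios in a well-behaved isobaric-tag experiment is a
narrow, approximately Gaussian null centred close to 1.  A Gaussian
``A * exp(-(x - mean)^2 / (2 sd^2))`` is fitted to the frequency
distribution of the ratios by nonlinear least squares, and each protein is
then ranked by its distance from that fitted null in units of the fitted
SD: ratios within one SD of the mean are non-impacted, ratios beyond are
assigned to +/-sigma, +/-2sigma or +/-3sigma tiers.  With a fitted null of
mean 1.02 and SD 0.10 the tier boundaries are
{0.72, 0.82, 0.92, 1.12, 1.22, 1.32}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Histogram",
    "GaussianFitResult",
    "TierThresholds",
    "GaussianFitError",
    "TIER_LABELS",
    "tier_label",
    "build_ratio_histogram",
    "fit_gaussian",
    "tier_thresholds",
    "classify",
    "classify_ratios",
]

#: Human-readable labels for the signed tiers -3..+3.
TIER_LABELS: dict[int, str] = {
    -3: "-3sigma",
    -2: "-2sigma",
    -1: "-sigma",
    0: "none",
    1: "+sigma",
    2: "+2sigma",
    3: "+3sigma",
}

_LABEL_TO_TIER = {label: tier for tier, label in TIER_LABELS.items()}


def tier_label(tier: int) -> str:
    return TIER_LABELS[tier]


def tier_from_label(label: str) -> int:
    return _LABEL_TO_TIER[label]


class GaussianFitError(RuntimeError):
    """Nonlinear fit failed or the histogram cannot support a fit."""


@dataclass(frozen=True)
class Histogram:
    """Frequency distribution of ratios on a fixed-width grid."""

    centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    n: int


@dataclass(frozen=True)
class GaussianFitResult:
    mean: float
    sd: float
    amplitude: float
    r_squared: float
    n: int
    bin_width: float


@dataclass(frozen=True)
class TierThresholds:
    """The six tier boundaries mean +/- k*sd, k in {1, 2, 3}."""

    mean: float
    sd: float

    @classmethod
    def from_fit(cls, mean: float, sd: float) -> "TierThresholds":
        if sd <= 0:
            raise ValueError("sd must be positive")
        return cls(float(mean), float(sd))

    @property
    def boundaries(self) -> tuple[float, float, float, float, float, float]:
        m, s = self.mean, self.sd
        return (m - 3 * s, m - 2 * s, m - s, m + s, m + 2 * s, m + 3 * s)


def build_ratio_histogram(
    ratios: Iterable[float], bin_width: float = 0.05
) -> Histogram:
    """Bin ratios on a grid of width ``bin_width`` anchored at multiples of it.

    Bins are half-open ``[left, right)`` except the last, which is closed so
    the maximum is counted; counts always sum to the number of ratios.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(list(ratios), dtype=float)
    if values.size == 0:
        raise ValueError("at least one ratio required")
    lo = np.floor(values.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((values.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Histogram(centers=centers, counts=counts, bin_width=bin_width, n=values.size)


def _gaussian(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


def fit_gaussian(histogram: Histogram) -> GaussianFitResult:
    """Least-squares Gaussian fit to (bin center, count) pairs.

    Initialised from the count-weighted sample mean/SD and the maximum
    count; R^2 is one minus the residual/total sum of squares over the
    histogram bins.  Refuses histograms with fewer than three occupied bins
    (a spike distribution carries no width information).
    """
    x = np.asarray(histogram.centers, dtype=float)
    y = np.asarray(histogram.counts, dtype=float)
    if int((y > 0).sum()) < 3:
        raise GaussianFitError(
            f"need >= 3 occupied bins to fit a Gaussian, got {int((y > 0).sum())}"
        )
    total = y.sum()
    mean0 = float((x * y).sum() / total)
    var0 = float((y * (x - mean0) ** 2).sum() / total)
    sd0 = max(np.sqrt(var0), histogram.bin_width / 2.0)
    p0 = (float(y.max()), mean0, sd0)
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=p0,
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological histograms
        raise GaussianFitError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, mean, sd = (float(v) for v in popt)
    residuals = y - _gaussian(x, *popt)
    ss_res = float((residuals**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFitResult(
        mean=mean,
        sd=abs(sd),
        amplitude=amplitude,
        r_squared=max(0.0, min(1.0, r_squared)),
        n=histogram.n,
        bin_width=histogram.bin_width,
    )


def tier_thresholds(fit: GaussianFitResult) -> TierThresholds:
    """Tier boundaries mean +/- k*sd, k in {1,2,3}, from a fitted null."""
    return TierThresholds.from_fit(fit.mean, fit.sd)


def classify(ratio: float, thresholds: TierThresholds) -> int:
    """Signed sigma tier of one ratio: -3..-1 down, 0 none, +1..+3 up.

    Interval conventions (for mean m, SD s):
      +3: r >= m+3s;  +2: [m+2s, m+3s);  +1: [m+s, m+2s);
      none: [m-s, m+s);
      -1: (m-2s, m-s);  -2: (m-3s, m-2s];  -3: r <= m-3s.
    Every positive ratio falls in exactly one tier.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    m, s = thresholds.mean, thresholds.sd
    if ratio <= m - 3 * s:
        return -3
    if ratio <= m - 2 * s:
        return -2
    if ratio < m - s:
        return -1
    if ratio < m + s:
        return 0
    if ratio < m + 2 * s:
        return 1
    if ratio < m + 3 * s:
        return 2
    return 3


def classify_ratios(
    ratios: Sequence[float],
    thresholds: TierThresholds | None = None,
    bin_width: float = 0.05,
) -> tuple[list[int], GaussianFitResult | None]:
    """Classify a vector of ratios, fitting the null first if none is given.

    Returns the tier of each ratio and the fit actually used (``None`` when
    explicit thresholds were supplied).
    """
    fit: GaussianFitResult | None = None
    if thresholds is None:
        fit = fit_gaussian(build_ratio_histogram(ratios, bin_width))
        thresholds = tier_thresholds(fit)
    return [classify(r, thresholds) for r in ratios], fit
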