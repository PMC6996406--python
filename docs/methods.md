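# Methods

This note documents the models, conventions and design choices behind
`itraqpipe`, in the order data flows through the pipeline.

## Reporter quantitation

**Extraction.** Reporter intensity per channel is the *sum* of all peak
intensities within ±`tolerance` Da (default 0.05) of the nominal 4-plex
reporter masses 114.1112, 115.1083, 116.1116 and 117.1150 Da. Summation
(rather than apex picking) was chosen because it is robust to slight peak
splitting and makes extraction additive in the peak list; with the default
tolerance the four windows cannot overlap, and a tolerance of half the
minimum inter-channel spacing (≈0.498 Da) or more is rejected outright.

**Isotope-impurity correction.** The tags leak a few percent of their
signal into neighbouring channels. With *M* the 4×4 purity matrix
(entry *(i,j)* = fraction of tag *j* observed in channel *i*; columns sum
to ≤ 1, diagonally dominant), the observed intensities are *M·x* and the
true signal is recovered by solving the linear system. Small negative
solutions — inversion noise — are clipped to zero and counted in a QC
tally. The packaged impurity table holds typical certificate-of-analysis
percentages and is explicitly a placeholder: real factors vary per reagent
lot and should be taken from the lot certificate.

**Ratios.** Each condition's ratio is its (corrected) channel intensity
divided by the reference condition's intensity. The reference defaults to
the vehicle/control condition. A zero reference or zero channel produces a
*null* ratio (serialized as `NA`), which is ground for exclusion
downstream rather than a silent zero.

## Filtering, frequency index and protein ratios

Records pass three rules, applied in this order and so charged to the
first failing rule in the filter report:

(a) identification confidence — score strictly greater than the cutoff
    (default 30, the usual −10·log₁₀ p < 0.05 point for a Mascot-style
    score; a record at exactly 30 is removed);
(b) quantification confidence — every condition ratio present and
    positive;
(c) decoy exclusion — any "Fragment" or "REVERSED" annotation (or a
    `_REVERSED` accession suffix).

Filtering is idempotent and order-preserving. Surviving records are
catalogued by **(peptide sequence, accession)** pair; keying on the pair
rather than the bare sequence keeps peptides shared between proteins from
being merged, a deliberately conservative protein-inference stance.
Duplicate identifications inside one experiment contribute all their
ratios but count once toward the frequency index. The second catalogue
keeps pairs with frequency index ≥ `n_required` (default: the number of
experiments, i.e. peptides reproducibly identified in *every* replicate);
`n_required` is exposed because reporting proteins at lower indices is a
legitimate, less stringent variant.

Protein ratios are medians of peptide ratios per accession. The *overall*
median pools every (experiment, peptide) observation; *series-specific*
medians are taken within each experiment. Pooling was preferred over a
median-of-series-medians because it weights each retained observation
equally and is the more natural reading of "median of peptide ratios
associated with a given accession"; the series medians are reported
alongside, so the other convention can be recovered. Even-sized samples
use the mean-of-central-pair median. Medians make the protein ratio
robust to a minority of aberrant peptides (up to ⌊(k−1)/2⌋ of k).

## Significance tiers

Ratios are binned on a fixed grid (width 0.05 by default, anchored at
multiples of the width; half-open bins, last bin closed) and the histogram
is fitted with *A·exp(−(r−μ)²/2σ²)* by `scipy.optimize.curve_fit`,
initialised from the count-weighted sample moments and the maximum count,
with σ bounded positive. R² = 1 − SS_res/SS_tot over the bins. Histograms
with fewer than three occupied bins are refused — a spike carries no width
information. The bin width is a visible parameter because the fitted σ
inherits a small binning inflation (Sheppard-type, ≈ w²/12 on the
variance, well under the tolerances used here).

Classification is purely threshold-based (no per-protein p-value): with
boundaries μ ± kσ, k ∈ {1,2,3},

* +3σ: r ≥ μ+3σ; +2σ: μ+2σ ≤ r < μ+3σ; +σ: μ+σ ≤ r < μ+2σ
* none: μ−σ ≤ r < μ+σ
* −σ: μ−2σ < r < μ−σ; −2σ: μ−3σ < r ≤ μ−2σ; −3σ: r ≤ μ−3σ

The mixed open/closed ends mirror the interval scheme the thresholds come
from; the classifier is total and monotone on r > 0, so every positive
ratio lands in exactly one tier and tier rank never decreases with r.

**Fitted vs configured null.** By default the pipeline classifies against
the null it fits from the data at hand. `RunConfig.null_mean`/`null_sd`
instead fix the thresholds at known values while still reporting the fit.
The fixed mode exists for validation: when scoring recovery of simulated
ground truth, tier labels must be defined against fixed thresholds,
because with re-fitted thresholds any null-drawn ratio adjacent to a
boundary flips tiers under arbitrarily small fit error, making "exact
recovery" ill-posed. Fit quality itself is assessed separately (parameter
recovery under repeated sampling).

## Over-representation test

For a class with `reference_count` members in a `reference_total`-protein
annotated proteome and `observed` members among `input_size` input
proteins: expected = input_size × reference_count / reference_total; fold
enrichment = observed / expected; direction "+" iff observed > expected.
The default test is the one-sided exact binomial tail
(P(X ≥ observed) for "+", P(X ≤ observed) for "−",
X ~ Binomial(input_size, reference_count/reference_total)), the classic
PANTHER-style choice; Fisher's exact test is available as an alternative.
Bonferroni correction multiplies raw p-values by the number of classes
actually tested (those with ≥ 1 input protein) unless an explicit
multiplier is given, capping at 1; retention is strict (< α). Report
columns are rounded to 2 d.p., full precision kept internally. Because the
correct multiplier for any given published table is generally unknowable,
corrected p-values should be compared across runs of this package, not
against third-party reports; expected counts and fold enrichments, by
contrast, are fully determined by the printed integers.

## Clustering

Row profiles (protein × condition median ratios, no missing cells,
reference column excluded as identically 1) are compared by plain
Euclidean distance, without row or column standardisation — ratios are
already on a common unit scale. Agglomeration uses
`scipy.cluster.hierarchy` with average linkage by default (complete and
single available); for the reducible linkages used here the merge
sequence ordered by height equals the greedy nearest-pair sequence, and
ties break deterministically for a fixed row order. Outputs are the
leaf-ordered matrix (TSV), the merge tree (newick with branch lengths)
and an optional raster heat map, which is a convenience rendering, not a
tested surface. Rows-only clustering is the default; column clustering is
a flag.

## Synthetic data generator

The generator emulates a five-replicate, four-condition 4-plex study:

* **Tag rotation.** Experiment 1 maps channels 114–117 to the conditions
  in order; experiments 2–4 shift the assignment cyclically one channel
  per experiment. Because a cyclic shift of four conditions has period
  four, the condition order is additionally reversed from the fifth
  experiment on, giving eight pairwise-distinct bijections — so the five
  associations of a five-replicate study all differ, as the emulated
  design requires. The rotation is a convention and is recorded in the
  run manifest.
* **Null ratios.** Unregulated condition folds are drawn from
  Normal(1.02, 0.10) — the narrow, slightly off-unity null typical of
  isobaric reporter ratios (rejection-resampled to stay positive, an
  event of negligible probability at these parameters).
* **Regulated proteins.** A configurable fraction (default 0.2) gets one
  randomly chosen non-reference condition placed at the centre of a
  uniformly chosen tier band: μ ± (k+½)σ for |tier| = k ≤ 2 and μ ± 3.5σ
  for the open ±3σ tiers. Band centres keep true effects away from
  classification boundaries, so recovery failures measure pipeline error,
  not boundary coin flips. Ground truth records the fold and tier per
  condition; the protein-level label is the most extreme condition tier.
* **Peptides.** Peptides per protein follow a truncated geometric
  distribution (p = 0.35, minimum 1, capped at 12 — a right-skewed count
  typical of shotgun coverage). Peptide sequences are deterministic
  functions of (protein, peptide) indices so the same peptide recurs in
  every experiment, which is what gives the frequency index meaning.
* **Intensities.** Base intensity per PSM is log-uniform on [10³, 10⁶]
  (spanning a realistic reporter dynamic range); channel intensity is
  base × fold(condition) × exp(Normal(0, noise_sd_log)), independent
  noise per channel, so observed ratios carry √2·noise_sd_log log-noise.
* **Contamination dials, off by default.** Channel dropout
  (`missing_rate`, per channel), decoy records (`decoy_rate`, annotated
  "REVERSED" — with accession suffix — or "Fragment"), and sub-threshold
  identification scores. Scores follow a shifted gamma (loc 10, shape 2)
  whose scale is solved in closed form so that P(score ≤ 30) equals the
  configured fraction; a fraction of zero uses a distribution supported
  above the cutoff. The defaults describe a measurement-noise-only
  experiment: requiring frequency index 5 means any per-record dropout
  removes single-peptide proteins wholesale, and the baseline
  configuration is meant to measure quantitation fidelity, not filter
  attrition — tests that exercise the filters switch the dials on
  explicitly.
* **Isotope mixing** (`apply_isotope_impurities`) optionally pushes true
  intensities through the packaged purity matrix so the correction path
  is exercised end to end; off by default so raw simulated intensities
  equal the generating model.

Everything derives from one integer seed via `numpy` `SeedSequence`
spawning (truth from (seed, 0), experiment *e* from (seed, e)), so a fixed
configuration is byte-identical across runs.

**What the simulation does not emulate:** chromatographic elution,
isotope envelopes beyond the four reporters, fractionation, peptide
misidentification (scores are independent of correctness),
protein-inference ambiguity (each peptide belongs to one protein), or
intensity-dependent noise. Passing tests therefore demonstrate that the
pipeline's arithmetic and bookkeeping are correct under the stated
statistical model — not that the model captures every pathology of real
LC-MS/MS data.

## Problem sizes and numerical conventions

The validation suite runs the full pipeline at 500 proteins × 5
experiments (≈1,500 classified ratios), fits the null at 370 draws per
replicate across 100 replicates, and checks the combinatorial cores
against brute-force oracles at 1,000 records — sizes at which every
quantity is stable yet the whole suite completes in seconds. Floats are
serialized as shortest round-tripping decimals; medians use numpy's
mean-of-central-pair convention; histogram edges are multiples of the bin
width; dendrogram tie-breaks follow scipy's deterministic ordering.

## Known limitations

* The shipped impurity matrix is a placeholder; lot-specific certificates
  must be supplied for real data.
* Decoys are excluded, not used for FDR estimation.
* No protein grouping/parsimony: accessions are taken at face value.
* Corrected enrichment p-values depend on the Bonferroni multiplier
  convention (classes tested); only expected counts and fold enrichments
  are multiplier-free.
* The Gaussian null is fitted to binned counts, not by maximum
  likelihood; with very few occupied bins the fit is refused rather than
  extrapolated.
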