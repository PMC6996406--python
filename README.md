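# itraqpipe

A tested, reusable pipeline for **iTRAQ 4-plex quantitative shotgun
proteomics**: reporter-ion quantitation with isotope-impurity correction, a
replicate-consensus peptide catalogue with median protein ratios, a
Gaussian-null significance-tier classifier, protein-class
over-representation testing, and Euclidean hierarchical clustering — plus a
ground-truthed synthetic-data generator so the entire chain can be
validated end to end without any raw instrument files.

It is aimed at proteomics analysts who have peptide-spectrum-match (PSM)
tables (or MGF fragment spectra) from an isobaric-tag experiment with
biological replicates, and at methods developers who want a controllable
test bed for filtering/aggregation heuristics.

## The method

An iTRAQ 4-plex experiment labels four conditions with isobaric tags whose
reporter ions appear at m/z 114–117 on fragmentation. For each identified
peptide spectrum the pipeline:

1. **Extracts** reporter intensities by summing peaks within ±0.05 Da of
   each nominal reporter mass.
2. **Corrects** inter-channel isotope leakage by solving the vendor purity
   system *M·x = observed* for the true intensities *x*.
3. **Computes ratios** *r* = intensity(condition) / intensity(reference);
   a zero or missing channel yields a *null* ratio.

Peptides then pass a three-rule exclusion cascade — identification score
strictly > 30 (random-match probability < 5%), no null ratio in any
condition, no "Fragment"/"REVERSED" decoy annotation — and surviving
(peptide, accession) pairs are catalogued across the replicate series with
a **frequency index** (the number of the five independent experiments in
which the pair was retained). Protein ratios are the **median** of peptide
ratios for each accession at the top frequency index, pooled over the
series (overall) and within each experiment (series-specific).

Significance is threshold-based: the frequency distribution of ratios is
fitted with a Gaussian *A·exp(−(r−μ)²/2σ²)* by nonlinear least squares, and
each protein ratio is ranked by its distance from the fitted null —
non-impacted within μ±σ, and ±σ/±2σ/±3σ tiers beyond. With the reference
null μ = 1.02, σ = 0.10 the boundaries are
{0.72, 0.82, 0.92, 1.12, 1.22, 1.32}.

Protein classes are scored by a PANTHER-style over-representation test:
expected = input_size × class_size / reference_total, fold enrichment =
observed / expected with an over (+) / under (−) direction, one-sided
binomial tail p-values and Bonferroni correction. Protein × condition
ratio matrices are clustered agglomeratively on Euclidean distances for
heat-map display.

## Worked example

Run the full pipeline on a simulated five-replicate study (500 proteins,
20% regulated, log-normal reporter noise 0.02):

```bash
itraqpipe run-all --seed 42 --out demo
```

The run writes `ground_truth.tsv`, per-experiment `psm_exp*.tsv` and
`peptides_exp*.jpf` tables, `protein_quant.tsv`, `classification.tsv`,
`enrichment.tsv`, `heatmap_matrix.tsv` + `dendrogram.nwk`, and
`run_manifest.json`. The classify stage prints the fitted null:

```
"fit": {
  "mean": 1.0171816812838193,
  "sd": 0.10428556593638318,
  "r_squared": 0.9908023738363974,
  "n": 1500,
  "bin_width": 0.05
}
```

i.e. the 1500 protein-by-condition ratios form a near-Gaussian null
(R² ≈ 0.99) whose fitted mean 1.017 and SD 0.104 recover the generating
distribution Normal(1.02, 0.10); the tier boundaries are the fitted
mean ± {1,2,3}·SD. `classification.tsv` then assigns one tier per
(protein, condition):

```
accession   condition  ratio        tier
SYN00000    CsA        1.094554369  none
SYN00000    Tac        1.134746872  +sigma
```

The library surface mirrors the CLI (`itraqpipe.simulate`,
`itraqpipe.reporter`, `itraqpipe.catalogue`, `itraqpipe.significance`,
`itraqpipe.enrichment`, `itraqpipe.cluster`, `itraqpipe.pipeline`); see
`docs/methods.md` for the model details and design choices.

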