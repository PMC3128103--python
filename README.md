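# chipdyn

Dynamic promoter-occupancy analysis for ChIP-chip tiling arrays, built
around the stress-responsive chromatin relocalization of the histone
deacetylase Sirt6 and the NF-κB subunit RelA in TNF-α-stimulated mouse
fibroblasts.

On promoter tiling arrays (probes covering −3250 bp to +750 bp around each
TSS), the package takes probe-level log2(ChIP/input) signal for a
factor × genotype × timepoint sample design and produces, stage by stage:

1. **Normalization** — per-sample subtraction of the Tukey biweight mean of
   the log2 ratios (robust to the minority of signal-bearing probes).
2. **Peak calling** — a sliding fixed-width window (default 500 bp, the
   chromatin fragment size) across each promoter's probes; windows with
   ≥ 4 probes and mean log2 ratio above a threshold merge into peaks.
3. **Permutation FDR** — probe values are shuffled within each promoter
   window and all windows re-scored; a peak's FDR at score *s* is
   E[null peaks ≥ *s*] / #observed peaks ≥ *s*, made monotone in *s*.
   Factor-specific thresholds (Sirt6 ≤ 0.1, RelA ≤ 0.2) can be calibrated
   against a known-target list.
4. **Target mapping** — peaks passing the FDR cut are intersected with
   ±4000 bp promoter windows; targets also called in the antibody-specificity
   knockout control (Sirt6 IP in *Sirt6*⁻/⁻, RelA IP in *RelA*⁻/⁻) are
   subtracted; unions over the time course give each factor's target
   universe.
5. **Occupancy analytics** — temporal dynamics classes per gene
   (constitutive / baseline-vacated / induced / periodic on-off-on), the
   hypergeometric co-occupancy test

   P(X ≥ k), X ~ Hypergeom(N, K, n)

   computed in log space for the promoter universe N with target-set sizes
   K, n and overlap k; peak-centre site distances for co-bound genes; and
   RelA-dependence classes (abrogated / reduced / independent) from Sirt6
   occupancy in wild-type vs RelA-null cells.
6. **Epistasis classification** — genotype × time expression profiles
   (WT, *Sirt6*⁻/⁻, *Sirt6*⁻/⁻ *RelA*⁻/⁻) filtered at a detection floor,
   normalized to untreated wild type, and rule-classified into AllUp /
   TNFUp / ZeroUp (antagonistic: Sirt6 loss derepresses, RelA loss
   reverts), Inverse, and RelA-blocked-Sirt6 classes, plus average-linkage
   hierarchical clustering under the 1 − Pearson distance.
7. **Gene-set enrichment** — hypergeometric enrichment of target sets
   against user-supplied collections (GMT), Benjamini–Hochberg corrected.

Because the original array data cannot be bundled, the package ships a
first-class synthetic-data generator (`chipdyn.simulate`) that plants every
quantity the analysis estimates — co-occupancy fraction, RelA-dependent
fraction, site-distance mixture, oscillatory occupancy patterns, epistasis
class mixture, detection-floor censoring — so the entire pipeline is
testable against known ground truth.

## Worked example

`examples/03_cooccupancy_dependence.py` simulates a 2000-promoter study,
runs the full ChIP stage and prints:

```
Sirt6 targets: 474, RelA targets: 238, shared: 116
overlap = 49.0% of RelA targets (log10 p = -18.9; planted fraction 0.54)
co-bound genes with sites < 500 bp apart: 0.66 (planted 0.65)
RelA dependence of Sirt6 occupancy at co-bound genes:
abrogated      0.534
reduced        0.155
independent    0.310
```

Reading: of the 238 recovered RelA target promoters, 116 are also Sirt6
targets — an overlap that independent target sets of these sizes would
essentially never reach (log10 p ≈ −19). Two thirds of the co-bound genes
have their Sirt6 and RelA peaks within 500 bp (the assay's resolution
limit), and half of them lose Sirt6 binding entirely in RelA-null cells,
recovering the planted RelA-dependent fraction. The other examples cover
peak calling (`01`), occupancy dynamics (`02`), epistasis classes (`04`)
and gene-set enrichment (`05`); each prints the planted value next to the
recovered one.

A thin CLI wraps the same calls: `chipdyn --seed 1 --out-dir out run-all`
generates a study, runs everything, and writes targets, dynamics tallies,
epistasis calls and a `metrics.json` of recovered-vs-planted measures; see
`chipdyn --help` for the per-stage subcommands (`simulate`, `normalize`,
`callpeaks`, `calibrate-fdr`, `targets`, `dynamics`, `cooccupy`,
`epistasis`, `enrich`).

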