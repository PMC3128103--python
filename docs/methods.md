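# Methods

## Scope and data model

The pipeline analyzes promoter tiling-array ChIP data for two chromatin
factors (Sirt6, RelA) across a TNF-α time course in wild-type and knockout
mouse fibroblasts, together with genotype × time expression arrays.  Each
gene has exactly one promoter window, tiled from 3250 bp upstream to 750 bp
downstream of its TSS (multi-TSS genes are out of scope).  Probe positions
are signed, strand-oriented offsets from the TSS; peaks are half-open
intervals in window coordinates (0 = upstream edge); genomic BED output
converts strand-awarely, mirroring the point set across the TSS on the
minus strand so that the conversion is an involution.

The ChIP design comprises Sirt6 IP in WT, *Sirt6*⁻/⁻ (antibody-specificity
control) and *RelA*⁻/⁻ cells at 0/15/30/60 min, and RelA IP in WT and
*RelA*⁻/⁻ cells at 0/15/30 min — the 60-min RelA sample is excluded from
the design because RelA oscillation desynchronizes by then.  Expression
covers WT, *Sirt6*⁻/⁻ and the double knockout at 0/90 min.

## Normalization

Each sample's log2(ChIP/input) ratios are centred by subtracting their
Tukey biweight location (tuning constant c = 9, scale = raw median absolute
deviation, iterated to convergence from the median).  The biweight is
insensitive to the minority of signal-carrying probes, so centring removes
array-to-array offset without deflating enrichment.  If the MAD is zero
(degenerate input) the median is subtracted instead and a warning logged.

## Peak calling

Within each promoter, a window of `window_bp` (default 500 bp — the
sonicated fragment size, hence the resolution limit) slides across the
probes.  Every distinct window placement is considered; placements sharing
a first probe are nested, so the scan keeps, per first probe, the largest
realizable probe set whose mean reaches `score_threshold` with at least
`min_probes` (default 4) probes.  Truncated probe sets arise at the
upstream edge of the tiled region and after inter-probe gaps; the caller
enumerates them exactly, and a brute-force scan over every integer window
start is the test oracle.  Overlapping or touching candidate windows merge
into maximal runs (bookended windows do not merge); each run emits one peak
spanning its member probes, scored by their mean.

`score_threshold` defaults to 0.4 log2 units: with the design noise level
(σ = 0.3 per probe) a full five-probe window mean has σ ≈ 0.134, so 0.4 is
a ~3σ detection rule.  Raising the threshold was found to *hurt* the
null-to-signal separation downstream, because merged-run score dilution
shrinks faster for permutation-null runs than for true bumps.

## Permutation FDR

The null is built by shuffling probe values within each promoter window
(preserving per-promoter probe count and local variance) and re-running the
identical scan, `n_permutations` times (default 25; nulls pool across all
windows, so even 25 permutations of a 5000-promoter array give ~10⁵ null
window scores).  For an observed peak of score *s*,

FDR(s) = min(1, E_null[#peaks ≥ s] / #observed peaks ≥ s),

then a cumulative minimum in ascending score order makes the estimate
monotone (a q-value): a peak inherits the best FDR among thresholds that
include it.  A score exceeding every pooled null is reported as 0, i.e.
below the 1/n_permutations resolution of the null.  Tied scores share one
FDR.

Two properties of this estimator are worth stating plainly.  First,
because promoter windows that *do* contain signal are also permuted, the
null is inflated by scattered signal probes, making the estimate
conservative: the empirical false-discovery proportion at FDR ≤ 0.1 is
~10⁻³ on synthetic data, far below nominal.  Second, at the other end, the
top-ranked observed peak is compared against a pooled null in which, by
exchangeability under a global null, fewer than 0.1·n_permutations null
peaks exceed it about 10% of the time — so on entirely signal-free data
roughly one dataset in ten yields a (single) FDR ≤ 0.1 peak.  That is
inherent to FDR-at-0.1 semantics; consumers wanting family-wise control on
empty designs should use a stricter threshold.

Factor-specific FDR cuts default to 0.1 (Sirt6) and 0.2 (RelA).  The
`calibrate_fdr_threshold` operation reproduces the threshold-selection
procedure: candidate thresholds are scored by their recovery of a
known-target list and the smallest threshold reaching the recovery goal
(default 100%) is chosen; if none qualifies, the best-recovering one is
returned with a warning.

## Target mapping and occupancy

A gene is a target of a sample iff some peak with FDR ≤ the factor's
threshold intersects the ±4000 bp promoter window around its TSS by at
least one base (half-open genomic intervals).  Targets called in the
knockout control at the same timepoint are subtracted.  Unions over
timepoints define each factor's target universe ("bound at ≥ 1
timepoint").

Dynamics labels partition the 16 possible 4-bit occupancy patterns with
precedence unbound > constitutive > periodic > baseline_vacated > induced >
other; "periodic" is on-at-15 / off-at-30 / on-at-60 regardless of the
baseline bit, the planted oscillation.

Co-occupancy uses the upper-tail hypergeometric probability with the whole
promoter universe as N (not the union of targets — this matches the
magnitude of headline p-values), computed via `scipy.stats.hypergeom.logsf`
so values below 10⁻³⁰⁰ remain representable.  Overlap percentages are
reported to the nearest integer at ≥ 20% and one decimal below.

Site distance for a co-bound gene is the minimum centre-to-centre distance
over its two factors' passing peaks (centres = floor((start+end)/2); the
caller does not estimate summits).  RelA dependence compares binary Sirt6
occupancy patterns between WT and RelA-null cells: abrogated (no occupancy
left), reduced (≥ 1 but strictly fewer timepoints), independent (at least
as many).  Only binary occupancy is compared because IP efficiency differs
between genotypes; score magnitudes are not comparable.

## Expression and epistasis classes

Genes are kept if any sample's detection value reaches the floor (default
100, inclusive), then divided by the untreated wild-type detection so the
reference cell is exactly 1 (non-positive references drop the gene with a
logged count).  Classification compares, per timepoint, Sirt6KO/WT and
DKO/WT fold ratios against explicit thresholds (`up_fold` = 1.5,
`down_fold` = 1/1.5 — the sources state directions but no cutoffs, so the
conventional 1.5× array fold threshold is used and exposed in config):

* **AllUp** — elevated at t = 0 and every TNF timepoint, reverted in the
  double knockout everywhere;
* **TNFUp** — elevated only under TNF, reverted there;
* **ZeroUp** — elevated only at baseline, reverted;
* **Inverse** — repressed by Sirt6 loss somewhere and overshooting in the
  double knockout somewhere;
* **RelABlockedSirt6** — elevated without reversion (RelA was blocking
  Sirt6, not recruiting it);
* **Unclassified** otherwise.

Precedence AllUp > TNFUp > ZeroUp > Inverse > RelABlockedSirt6 >
Unclassified makes the classes exclusive; the classifier is total over all
positive profiles and scale-invariant.  Hierarchical clustering (average
linkage, 1 − Pearson distance, constant rows at distance 1) is descriptive
ordering only — class assignment is rule-based, not cluster-derived.  Leaf
order is fixed by the convention that at each merge the subtree containing
the smaller original row index comes first.

## Gene-set enrichment

Upper-tail hypergeometric per set against the promoter universe, BH
correction across the collection (via `statsmodels`), significance at
q < 0.05.  Set members outside the universe are dropped with a logged
count.  Motif-module or functional collections are user-supplied GMT
inputs, never shipped content.

## Synthetic-data generator

The generator is the package's study stand-in; its defaults are the study
conditions, not tuning knobs:

* universe fractions — RelA targets 0.13, Sirt6 targets 0.238, Sirt6-bound
  at baseline 0.09 (the published 2738 / 5050 / 1899 out of 21,249);
* conditional fractions — co-bound share of RelA targets 0.54, abrogated
  share of co-bound genes 0.49 (plus a 0.20 "reduced" share), within-500-bp
  share 0.65, vacated share of baseline targets 0.36 (684/1899);
* RelA per-timepoint occupancy 13% / 91% / 50% at 0/15/30 min; Sirt6
  patterns: vacated (1,0,0,0); retained baseline mostly oscillatory
  (1,1,0,1) with a constitutive minority; induced mostly periodic (0,1,0,1)
  with late-only and transient minorities;
* signal — triangular bump of height 1.5 log2 units and half-width 500 bp
  (the fragment size; the bump *shape* is a design choice — compact support
  makes exact expectations testable) on N(0, 0.3) probe noise, probes every
  100 bp (spacing is not published; 100 bp is the design default);
  knockout-control samples carry noise only;
* expression — multiplicative class templates (effect size 2×, WT TNF
  induction 3×) with lognormal noise of σ = 0.10 on the natural-log scale
  (~10% CV, typical bead-array technical noise); 67.6% of genes are scaled
  to sit entirely below the detection floor (the published 480-of-1481
  detection rate); the class mixture over co-bound genes puts 0.63 into the
  antagonistic classes (301/480), split AllUp 0.25 / TNFUp 0.30 / ZeroUp
  0.08, with Inverse 0.10, RelABlockedSirt6 0.07, Neutral 0.20 — the
  per-class split is not published and is a design choice.

Memberships are independent Bernoulli draws, so realized fractions match
parameters to binomial sampling error.  Co-bound site distances are drawn
U(0, 400) bp for the "within" component and U(700, 2000) bp for the "far"
component: a deliberate buffer around the 500 bp reporting cut equal to a
few probe spacings, so the planted within-500-bp fraction remains well
defined under the caller's peak-centre jitter.  All randomness flows from
one integer seed; identical parameters give bitwise-identical output.

What the generator does *not* emulate: correlated probe noise and GC/probe
affinity structure, replicate arrays, partial/weak binding (occupancy is
binary), unsynchronized cell populations, cross-hybridization, and any
genomic sequence context.  Passing tests therefore demonstrate the
statistical machinery recovers planted structure under idealized noise —
not performance on raw array data.

## Problem sizes and numerical choices

The self-check study runs at 5000 promoters (the published universe is
21,249; fractions, not counts, are compared), 25 permutations, 20 seeds in
the test suite and 5 in the acceptance script.  Degenerate inputs are
handled explicitly: empty peak lists pass through FDR estimation; constant
samples normalize by the median; zero-variance expression rows get
correlation distance 1; tied peak scores share an FDR; hypergeometric
tails at k = 0 return probability exactly 1.

## Known limitations

* The permutation null treats signal-bearing windows as noise, so FDR
  estimates are conservative and sensitivity is paid for at stringent
  thresholds; a control-sample-based null would be sharper but requires
  matched input arrays.
* "Reduced" RelA dependence needs ≥ 2 bound WT timepoints to be
  observable; singly-bound genes can only be abrogated or independent.
* One promoter per gene; no summit estimation; no replicate handling.
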