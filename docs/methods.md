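# Methods

## Screen design assumed by the pipeline

A pooled shRNA library (5–6 hairpins per gene, each hairpin carrying a
unique 18-nt DNA barcode) is transduced into the cell population of
interest. Hairpin abundance is measured by sequencing the barcodes at
t = 0 (shortly after transduction) and t = 14 days of clonal culture, in
R ≥ 2 independent replicate screens. Genes required for clonal
growth/survival lose their hairpins over the culture period (depletion);
genes restraining growth gain them (enrichment).

## Barcode counting

A read is assigned to a hairpin when its 18-mer at a configurable offset
matches a library barcode with at most `max_mismatch` substitutions
(default 0) and that best match is unique at the minimal distance. Ties
and too-short reads are tallied as unassigned, never silently dropped, so
assigned + unassigned always equals the number of reads. Matching is on
the forward orientation only; the amplicon design is assumed to put the
barcode at a fixed position. Hairpins present in the library but absent
from a supplied count table are zero-filled rather than dropped so that
complete dropout remains visible downstream.

## Normalization and fold changes

Counts are scaled to reads per million per sample (columns sum to 10⁶
before the pseudocount); a pseudocount (default 1 CPM) is then added to
every cell so that log-ratios of fully dropped-out hairpins are finite
(a hairpin at 1000 CPM at t0 that disappears entirely bottoms out at
log2(1/1001) ≈ −10). Fold changes are computed per replicate between
paired t14/t0 samples; pairing is by replicate index unless an explicit
map is given.

**Median-centering.** Sequencing counts are compositional: if a few
hairpins expand massively, every other hairpin's raw log-ratio is pushed
down by a common offset even though nothing about those cells changed.
The robust-z score below is invariant to such shifts, but the gene-level
fold-change cutoff is not, so the model centers each replicate's log2FC
distribution at zero (its median — the growth-neutral bulk) by default
(`DropoutScreen(center=...)`). With centering, the fold-change cutoff
refers to change relative to the typical hairpin, which is what a "0.7
log2 units" threshold means in practice.

## Per-hairpin significance

No external negative-control hairpin set is assumed. Instead the
library-wide distribution serves as an empirical null, which is valid
precisely because the vast majority of genes do not affect clonal growth.
Per replicate, each hairpin receives a robust z-score
(log2FC − median) / (1.4826 · MAD); replicates are combined by Stouffer's
method (Σz/√R) and converted to a two-sided normal p-value. Significance
is raw p ≤ α (default α = 0.05); Benjamini–Hochberg adjustment is
available behind a flag (`adjust_pvalues=True`) for users who prefer
FDR-controlled hairpin lists. A replicate with zero MAD (a degenerate,
e.g. constant, fold-change distribution) is rejected with a message
suggesting its exclusion rather than silently producing infinities.

**Calibration caveat.** The empirical null assumes hairpin-level noise is
roughly homogeneous across the library. When counting noise dominates
(deep multinomial sampling with no biological overdispersion), the
per-hairpin variance scales as 1/count, so a very uneven library makes
the null a scale mixture and the tail slightly anticonservative. At the
simulator's default representation spread this effect is negligible; for
strongly skewed real libraries, users should prefer the BH-adjusted mode
or filter very-low-count hairpins.

## Gene-level calling

With S the set of a gene's significant hairpins and A the mean log2FC
over S:

1. |S| < `min_significant` (default 2) → unchanged, reason
   `no_significant`;
2. S contains both positive and negative fold changes → unchanged,
   reason `ambiguous`;
3. |A| < `lfc_cutoff` (default 0.7) → unchanged, reason `below_cutoff`;
4. otherwise depleted (A < 0) or enriched (A > 0).

Every library gene receives exactly one call (the classes partition the
gene set), and raising the cutoff can only move genes from hit classes to
`below_cutoff` — both properties are enforced by tests. The default
`min_significant=2` reflects that single-hairpin calls are dominated by
off-target effects when 5–6 hairpins per gene are available; setting it
to 1 recovers the permissive reading. "Ambiguous" is operationalized as
sign disagreement among significant hairpins; stricter concordance rules
could be layered on top but are not needed to reproduce the three
unchanged reasons. Hits are ranked by |A| (descending), ties broken by
the number of significant hairpins and then alphabetically, so rankings
are fully deterministic.

## Overlap analysis

Cross-screen Venn intersections operate on gene symbols after
upper-casing; no alias resolution is attempted (mismatches surface as
"not present" rather than being guessed). The hypergeometric test
computes the exact upper tail P(X ≥ k) by integer-arithmetic summation of
binomial coefficients — exact to the final float division, verified
against exhaustive enumeration for all universes up to N = 12. The
default universe is the screened library, which is the correct background
for screen hits; annotations are intersected with the universe before
testing, and a disjoint annotation yields p = 1 with a warning.

## Synthetic screens

The generator plants ground truth and reproduces the statistical
structure the analysis relies on:

- **Classes and effects.** A configured fraction of genes is depleted
  (default 10%) or enriched (default 5%); planted fitness magnitudes are
  |s| = 0.5 + Exponential(0.25) (so every planted gene has |s| ≥ 0.5,
  with a realistic tail), signed by class.
- **Hairpin efficacy.** Each hairpin is inert with probability 0.2,
  otherwise e ~ Beta(5, 2) (mean ≈ 0.71) — reproducing the real-library
  behaviour that only a subset of a hit gene's 5–6 hairpins scores.
- **Growth.** Over d population doublings (default 7 for a 14-day clonal
  culture) a hairpin's lineage grows by 2^{d(1 + e·s)}, so its expected
  log2FC relative to the neutral bulk is d·e·s.
- **Representation.** Initial proportions are log-normal with σ = 0.2
  (natural-log units, ≈1.7-fold 10th–90th percentile range — a tightly
  cloned library). This default keeps counting-noise variance nearly
  homogeneous across hairpins, so the empirical-null score is exactly
  calibrated under the default noise model; wider spreads are available
  via `library_sigma` and exhibit the anticonservatism discussed above.
- **Sequencing.** Per sample, counts are a single multinomial draw of
  `reads_per_sample` (default 5×10⁶) reads; optional
  Dirichlet-multinomial overdispersion (concentration κ·q) models
  biological replicate noise but is off by default to keep the null
  exactly calibrated for the test suite.
- **Determinism.** One seed drives library construction, truth
  assignment and per-sample draws through sub-streams spawned from a
  single `SeedSequence`; identical configurations are bit-identical.

What the simulator does *not* emulate: hairpin-specific sequence biases
(PCR/GC effects), off-target phenotypes, cell-to-cell infection
multiplicity, clonal drift within a replicate, and batch effects between
replicates. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not performance on any
particular real screen.

Recovery is scored as sensitivity per planted class, false-positive rate
among neutral genes, and the empirical FDR of the hit list (a hit whose
planted class differs from the called direction counts as false).

## Assay quantification

- **H-score**: Σ_c (% cells at intensity category c)·c for c ∈ {1,2,3};
  range 0–300, monotone under shifting cells to stronger categories.
  Category percentages must sum to 100 (tolerance 10⁻⁶).
- **Localization**: per-cell ratio of nuclear to cytoplasmic median
  fluorescence intensity; a cell is N=C when |log2 ratio| ≤ tol, N>C/N<C
  by the sign otherwise. The tolerance band is a required-to-report
  parameter (default tol = 0.2 log2 units, i.e. ratios within ±15% of 1);
  the category is invariant to global intensity scaling. Cells with zero
  cytoplasmic signal are excluded and logged, never imputed.
- **Colony statistics**: particles below `min_area` (default 0.01 mm²)
  are removed before counting; CFE is the mean over wells of
  100 × colonies/seeded; the retained area distribution is summarized by
  median and quartiles.
- **Relative expression**: fold = 2^(−ΔΔCt) with
  ΔΔCt = (Ct_target − Ct_housekeeping)_sample − (…)_control, amplification
  efficiency fixed at 2 (no efficiency calibration is modelled).
- **Positive fractions**: 100·n_positive/n_total, with clone "expansion"
  conventions such as ">3 cells" interpreted as ≥4.

## Problem sizes used in validation

The shipped test suite validates the pipeline at 150–2,000 genes.
The calibration and recovery checks run at 2,000 genes × ~11,000 hairpins
× 5×10⁶ reads/sample × 2 replicates — large enough that Monte-Carlo error
on the null fraction (±0.004 at 3σ) is well inside the ±0.01 acceptance
band, while a full fit completes in seconds. Genome scale
(~15,000 genes × ~82,000 hairpins) differs only linearly in memory and
time and is exercised indirectly through the library-invariant tests.

## Known limitations

- The per-hairpin test has no hairpin-specific variance model; very
  low-count hairpins are noisier than the empirical null assumes (see
  calibration caveat above).
- Barcode matching does not consider indels or reverse-complement
  orientation; both would be simple extensions but are not part of the
  assumed amplicon design.
- Gene symbols are matched textually; curated lists using aliases must be
  harmonized upstream.
- `A` is undefined (NaN) for genes with no significant hairpins; ranking
  only ever applies to hit classes, where it is always defined.
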