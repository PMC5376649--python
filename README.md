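# clonescreen

Analysis toolkit for pooled shRNA dropout screens of clonal cell growth,
built for screens that compare hairpin abundance between an initial
timepoint (t = 0, shortly after library transduction) and the end of a
clonal culture period (t = 14 days). Hairpins targeting genes required for
clonal expansion drop out of the population; hairpins targeting growth
suppressors become over-represented. `clonescreen` takes you from raw
barcode reads (or a count table) to gene-level **depleted / enriched /
unchanged** calls, ranked hit lists, cross-screen overlaps and
hypergeometric gene-set tests. It also ships a truth-labelled screen
simulator for validating the pipeline, and the small quantification
statistics used by follow-up assays (H-score, nuclear/cytoplasmic
localization categories, colony-forming efficiency, ΔΔCt relative
expression).

Intended users: groups running genome-scale RNAi/CRISPR dropout screens in
primary cells or cell lines — typically libraries of ~10⁴ genes with 5–6
hairpins per gene, identified by unique 18-nt barcodes.

## The statistics

**Per-hairpin score.** Counts are normalized to reads per million with a
pseudocount, per-replicate fold changes are computed between paired t14/t0
samples, and (by default) median-centered per replicate to remove
compositional shifts. Because the overwhelming majority of hairpins are
growth-neutral, the library-wide distribution is used as an empirical
null: each hairpin *i* in replicate *r* gets a robust z-score

    z_ir = (log2FC_ir − median_r) / (1.4826 · MAD_r)

which is Stouffer-combined across replicates, z_i = Σ_r z_ir / √R, with a
two-sided normal p-value p_i = 2(1 − Φ(|z_i|)).

**Gene call.** With S the significant hairpins (p ≤ α) of a gene and
A = mean log2FC over S, the gene is *unchanged* when |S| < min_significant
(reason `no_significant`), when the significant hairpins disagree in sign
(`ambiguous`), or when |A| < cutoff (default 0.7, `below_cutoff`); otherwise
it is **depleted** (A ≤ −0.7; candidate positive growth regulator) or
**enriched** (A ≥ +0.7; candidate negative growth regulator). Hits are
ranked by |A| with ties broken by the number of supporting hairpins.

**Overlap tests.** Exact upper-tail hypergeometric p-values
P(X ≥ k), X ~ Hypergeom(N, K, n), computed by integer summation, with the
screened library as the default universe.

## Worked example

Simulate a 500-gene screen with planted effects (10% depleted genes at
|s| ≥ 0.5, 20% inert hairpins, 7 population doublings, two replicates),
fit it, and score recovery against the planted truth:

```python
from clonescreen import DropoutScreen, simulate_screen
from clonescreen.simulate import SimConfig

cfg = SimConfig(n_genes=500, reads_per_sample=1_000_000, seed=42)
library, counts, truth = simulate_screen(cfg)

results = DropoutScreen(counts, library).fit(alpha=0.05, lfc_cutoff=0.7,
                                             min_significant=2)
print(results.summary())
```

```
Pooled shRNA dropout screen
============================================================
screen:            SIM
shRNAs:            2762
genes:             500
replicates:        2
alpha:             0.05
lfc cutoff:        0.7
min significant:   2
------------------------------------------------------------
significant shRNAs: 418 (15.13%)
depleted genes:     50  (candidate positive growth regulators)
enriched genes:     25  (candidate negative growth regulators)
unchanged genes:    425  [no significant: 419, below cutoff: 3, ambiguous: 3]
total hits:         75
============================================================
```

The 50 depleted genes are exactly the 10% planted as depleted; the top of
the ranked list shows the strongest average dropout among significant
hairpins:

```python
print(results.rank_hits("depleted").head(5))
#              n_shrnas  n_significant         A  rank_score
# gene_symbol
# G00011              6              6 -6.128060    6.128060
# G00134              6              5 -5.507949    5.507949
# G00445              5              4 -5.272388    5.272388
# ...

print(results.evaluate(truth))
# {'sensitivity_depleted': 1.0, 'sensitivity_enriched': 1.0,
#  'fpr_neutral': 0.0, 'n_hits': 75, 'fdr_hits': 0.0, ...}
```

A (mean log2 fold change over a gene's significant hairpins) is the effect
size of each call: G00011 at A ≈ −6.1 means its hairpins dropped ~70-fold
over the culture period. `sensitivity_depleted = 1.0` and
`fpr_neutral = 0.0` say every planted depleted gene was recovered and no
neutral gene was called a hit.

Two fitted screens can be intersected
(`clonescreen.intersect_hits(calls_a, calls_b, "depleted")`) and tested
against curated gene sets
(`clonescreen.hypergeom_test(hits, gene_set, universe)`), e.g. a curated
pathway interactome loaded from GMT via `clonescreen.read_gmt`.

### Command line

```bash
# barcode counting from FASTQ (plain or gzipped)
clonescreen count --fastq sample.fastq.gz --library library.tsv \
    --offset 0 --max-mismatch 0 --out counts.tsv

# assay statistics
clonescreen quantify hscore --p0 0 --p1 0 --p2 0 --p3 100   # -> 300
clonescreen quantify cfe --colonies colonies.tsv --seeded 100
clonescreen quantify localization --cells cells.tsv --tol 0.2
clonescreen quantify ddct --ct-target-sample 17 --ct-housekeeping-sample 10 \
    --ct-target-control 20 --ct-housekeeping-control 10
```

## Layout

| module | contents |
| --- | --- |
| `clonescreen.io` | library/sample-sheet/count-matrix TSV I/O, FASTQ barcode counting, GMT reader |
| `clonescreen.stats` | CPM normalization, paired log2FC, median-centering, robust-z scoring |
| `clonescreen.calling` | gene-level calls, ranking, class summaries |
| `clonescreen.sets` | Venn intersections, exact hypergeometric tests, network-list annotation |
| `clonescreen.simulate` | truth-labelled screen generator and recovery metrics |
| `clonescreen.quant` | H-score, N/C localization, CFE, ΔΔCt, positive fractions |
| `clonescreen.model` | `DropoutScreen` / `ScreenResults` front end (fit, summary, plots) |

See `docs/methods.md` for the underlying models, default parameters and
known limitations.
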