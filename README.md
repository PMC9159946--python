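# clonescar

CRISPR–Cas9 scar-barcoding lineage analysis of thymic epithelial cells
(TECs), packaged as a tested, simulation-backed pipeline.

The thymic epithelium contains two mature compartments — cortical (cTEC)
and medullary (mTEC) — plus early (EP) and postnatal (PP) progenitor
populations. When Cas9 cuts a fixed target in exon 3 of *Hprt* early in
embryogenesis, each epithelial founder cell repairs the break into one of
many possible sequence outcomes ("scars"), which heritably barcode the
founder's entire clone. Reading these barcodes back from bulk-sorted
compartments and from single cells, alongside their transcriptomes, lets
one ask whether cTECs and mTECs descend from common bipotent progenitors
and which populations each clone feeds.

`clonescar` is aimed at computational biologists who want to analyse such
scar-barcoding experiments or to study the statistical behaviour of the
method itself under known ground truth.

## The statistics at the core

**Rare-barcode co-occurrence.** For sample *i*, let *B<sub>i</sub>* be the
set of barcodes observed no more than twice across all samples (rare
barcodes have low collision probability, so sharing implies shared clonal
origin). The co-occurrence probability is

&nbsp;&nbsp;&nbsp;&nbsp;*P<sub>ij</sub>* = |*B<sub>i</sub>* ∩ *B<sub>j</sub>*| / |*B<sub>i</sub>*|

and the per-mouse enrichment *E<sub>m</sub>* is the maximum of the two
directional ratios of the same-mouse *P* over the mean of the cross-mouse
*P* values (normalisation 1/(N−2), N = number of samples). *E<sub>m</sub>* ≈ 1
means rare barcodes co-occur in the two compartments of a mouse no more
often than across mice; *E<sub>m</sub>* ≫ 1 indicates a shared ancestor.
Age groups are compared with an exact one-sided Wilcoxon rank-sum test.

**Binomial over-representation.** The background frequency of barcode *b*
is the mean of its per-sample relative frequencies over bulk samples,
*f<sub>b</sub>* = (1/N) Σ<sub>i</sub> n<sub>b,i</sub> / Σ<sub>k</sub> n<sub>k,i</sub>.
In a single-cell dataset with *C<sub>i</sub>* barcode-carrying cells in
population *i*, of which *c<sub>b,i</sub>* carry barcode *b*, the P value
is the binomial right tail P(X ≥ c<sub>b,i</sub>), X ~ Binom(C<sub>i</sub>,
f<sub>b</sub>), Benjamini–Hochberg corrected jointly over all
(barcode, population) tests; calls at adjusted P < 0.001 are flagged and
the flag pattern names the clone (early/postnatal bipotent, cTEC/mTEC
biased, dormant, compartment-private).

**Signatures.** UMI counts are corrected for 6-nt tag collisions
(t = −K ln(1 − k/K), K = 4096), cells and genes pass the study's QC rules,
four population gene sets are derived by one-vs-rest negative-binomial
differential expression (adjusted P < 0.01, log2 fold change > 1), cells
are scored by summed transcript counts per set, and clusters are placed in
the EP/PP × C/M log-ratio plane relative to a reference dataset.

All of this is verifiable because the `simulate` module generates full
cohorts — founder pools, heavy-tailed barcode generation shared across
mice, fate-biased clonal expansion, bulk amplicon sampling, single-cell
sampling and NB count matrices with planted signatures — with complete
ground truth, plus a clone-free null for calibration.

## Worked example

```python
from clonescar import (SimConfig, simulate_cohort, CooccurrenceModel,
                       LineageModel, background_frequency)

cfg = SimConfig(n_mice=6, founders_per_mouse=2000, clone_size_log_mean=2.5,
                clone_size_log_sd=2.2, cells_per_sc_dataset=4000,
                make_count_matrices=False, seed=7)
cohort = simulate_cohort(cfg)

print(CooccurrenceModel(cohort.bulk).fit().summary())
bg = background_frequency(cohort.bulk)
print(LineageModel(cohort.sc["m01"].clone_map, bg).fit().summary())
```

prints

```
Rare-barcode co-occurrence summary
==================================
samples: 12   mice: 6   rarity threshold: 2 (reads)
mean same-mouse P_ij : 0.1241
mean cross-mouse P_ij: 0.0047
enrichment E_m (defined n=5): median 40.00, mean 37.00

Lineage over-representation summary
===================================
tests: 1024  barcodes: 256  alpha (BH-adjusted): 0.001
significant calls: 69  bulk-unseen barcodes: 20
clone patterns:
  unclassified           199
  mTEC-private           29
  cTEC-private           13
  postnatal mTEC-biased  6
  early cTEC-biased      6
  early dormant          2
  postnatal dormant      1
```

Reading: the cTEC and mTEC samples of the same mouse share 12.4% of their
rare barcodes versus 0.47% for samples from different mice, giving
enrichment values far above 1 — the signature of shared clonal origin. In
mouse m01's single-cell data, 69 (barcode, population) pairs are
significantly over-represented; the flag patterns identify, e.g., six
early-progenitor clones biased toward the cortical lineage. Barcodes never
seen in bulk (20 here) are reported separately rather than tested against
a zero background.

A command-line interface wraps the same stages:

```bash
clonescar simulate --out run/ --seed 1
clonescar cooccur --table run/bulk_counts.tsv --samples run/samples.tsv --out run/co
clonescar lineage --clones run/clones_m01.tsv --bulk run/bulk_counts.tsv \
    --samples run/samples.tsv --out run/lineage_m01.tsv
clonescar run --out full_run/ --seed 1      # entire pipeline + manifest
```

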