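# Methods

This note records the models, parameter choices and numerical conventions
behind `clonescar`, and what the simulation-based tests do and do not
establish about real data.

## The generative model

A cohort of `n_mice` (default 18) mice is simulated. Each mouse starts
from `founders_per_mouse` = 4,000 marked epithelial founder cells, the
estimated size of the thymic rudiment at the onset of marking. Every
founder draws one repair outcome (two independent outcomes in females, one
per X chromosome) from a single outcome distribution shared by all mice:
a truncated power law with `n_outcomes` = 30,000 possible outcomes and
exponent `outcome_skew` = 1.15 (rank k gets mass ∝ k^−1.15). The power-law
family is a modelling choice — the empirical functional form of the repair
outcome distribution is not known — selected because one parameter
reproduces the monotone rank–frequency profile of observed barcodes.
The default (30,000, 1.15) pair was fixed so that, at the default sampling
depth, a simulated thymus shows the observed-diversity regime of real
thymi: ~1,100 distinct barcodes truly present per mouse (three- to
fourfold below the founder count, because frequent outcomes are generated
independently more than once), ~600–900 observed per thymus in bulk reads,
the most frequent sequences shared by all mice, and a long tail of
mouse-private rare outcomes (these make rare-barcode statistics
informative; a much smaller outcome space leaves no outcomes rare enough
to be mouse-specific at realistic depth).

Outcome ranks map deterministically to scar sequences: the most frequent
outcomes are simple deletions inside the 21-nt target site (observed scars
are dominated by deletions), the tail adds insertion and
deletion+insertion alleles at the cut site; all sequences are distinct.

Clone sizes are log-normal (`clone_size_log_mean` = 2.0,
`clone_size_log_sd` = 1.0 by default: median ~7 cells) — strictly
positive and heavy-tailed with two parameters. Each descendant cell stays
progenitor-like with probability `frac_remain_progenitor` = 0.15 or
matures; early-progenitor (EP) clones mature into cTECs with probability
`bias_early_to_cTEC` (default 0.85), postnatal-progenitor (PP) clones into
mTECs with `bias_postnatal_to_mTEC` (default 0.85). A founder is EP with
probability `frac_early_progenitor` = 0.4.

Bulk samples draw `bulk_reads_per_sample` = 5,000 multinomial reads over
barcode abundance within each sorted fraction; EP-like cells sort with the
cTEC (Ly51⁺) fraction and PP-like cells with the mTEC (UEA-1⁺) fraction.
If a fraction contains no scarred cells the sample reads the germline
(unedited) window, mimicking unmarked carry-over. Single-cell datasets
sample `cells_per_sc_dataset` = 1,000 cells without replacement and attach
the population label and the exposed barcode. In females, dosage
compensation exposes one allele per cell, chosen per cell, with a small
`both_allele_readout_prob` = 0.02 chance of exposing both ("relaxed
X-inactivation"); homozygous founders expose one sequence.

Count matrices plant four disjoint 50-gene signature sets plus 800
background genes (panel means log-normal, clipped to [0.2, 50]); a cell's
own population set is elevated `sig_fold_change` = 4-fold, counts are
negative binomial with dispersion 0.1 (variance m + 0.1 m²). This is the
smallest panel that exercises gene-set derivation and NB differential
expression with known truth.

All randomness flows from one cohort seed through `numpy.random`
`SeedSequence` spawns (gene panel, scar panel, one stream per mouse), so
identical configs give byte-identical outputs and mice could be generated
in parallel.

### The calibration null

`simulate_null_cohort` removes clonal structure entirely: bulk reads and
single-cell barcodes are drawn iid from the outcome distribution, and
compartment/population labels are drawn independently of barcode identity.
This is deliberate and stronger than merely randomising compartments per
cell. The binomial over-representation test detects clones that are large
in one mouse relative to the cross-mouse background — any mouse-private
clone is a true positive for it regardless of compartment assignment — so
a null that keeps clones would not (and should not) calibrate to the
nominal rate. Under the clone-free null both calibration properties hold
by construction: rare-barcode co-occurrence is driven purely by sequence
collisions (E_m ≈ 1, measured 1.00 ± 0.04 over 180 simulated mice) and no
barcode is over-represented in any population (measured significant-call
rate ≪ 0.5%).

## Sequence extraction

Amplicons are delimited by the forward primer anchor (19 nt) and the
reverse-primer site (18 nt); anchors match with at most one substitution
(no indels) — the anchors are long enough that one mismatch absorbs
sequencer error without ambiguity. The flanking context between anchors
and target is synthetic but fixed, which exercises anchored extraction
identically to genomic context. Scar identity is the literal extracted
window; edit descriptions (e.g. `5D`, `2I:AT`) are annotation derived from
the longest common prefix/suffix against the germline window. Windows
containing `N` are dropped (scar identity must be exact).

Single-cell reads are `6 nt UMI + 6 nt cell barcode + amplicon` on the
left mate with the reverse complement on the right; a read counts only if
both mates yield the identical window (two-mate agreement). Per-cell
allele support is the number of distinct (UMI, scar) pairs, which stops
PCR jackpots from dominating the ≥10% secondary-allele rule; a flag
restores raw read counting for bulk-style input. The ≥200-read cell
threshold applies to usable (two-mate-agreeing) reads and a secondary
allele at exactly 10.0% of the major triggers exclusion (the rule is
"≥ 10%"). Bulk counting is read-level: the bulk primers carry no UMI.
Note that with per-base error ε the fraction of read pairs surviving
two-mate agreement is ≈ (1−ε)^(2·window); at ε = 0.01 roughly half the
reads of a cell are usable, so a 300-read cell sits near the 200-read
threshold — the error-tolerance tests therefore assert recovery of the
true allele as the top-supported sequence, which majority consensus
guarantees, rather than pass/fail status.

## Co-occurrence statistics

Rare barcodes default to total read occurrences ≤ 2 across all samples
("observed no more than twice"); a `count_mode="samples"` flag counts
samples of occurrence instead, since the phrase is ambiguous. Undefined
P_ij (empty B_i) propagate as NaN, are excluded from denominator averages
(with the divisor reduced accordingly) and never enter summaries. E_m
follows the prose definition: each denominator is the mean of P between
the reference sample and the N−2 samples of other mice. A zero denominator
with positive numerator yields +inf, flagged but rank-usable.

The one-sided rank-sum comparison is exact (full enumeration of group
assignments over average ranks, memory-bounded chunks) for combined n ≤ 25
— the study's group sizes are 5–12 — with P = P(W ≥ W_obs). A degenerate
permutation distribution (e.g. identical groups) returns P = 0.5 by
convention; larger samples use the normal approximation with tie and
continuity corrections.

## Lineage inference

C_i is the total number of barcode-carrying cells in population i. The
right tail is computed through the binomial survival function (never
1 − CDF), keeping relative precision in small tails; it matches exhaustive
enumeration to ≤ 1e−12 for C ≤ 25. Cells with two barcodes contribute an
order-normalised pair key whose background is the product of the singleton
frequencies; cells with more than two barcodes are excluded upstream as
doublets. BH correction forms one family per dataset across all
(barcode, population) tests (a flag switches to per-population families
for sensitivity analysis), and the 0.001 significance threshold applies to
adjusted values. Barcodes seen in single cells but never in bulk are
reported as "bulk-unseen" instead of tested — a zero-background binomial
is degenerate, and such barcodes are plausibly below bulk sampling depth.

Pattern labels are a deterministic function of the per-population flags
(progenitor prefix early/postnatal/dual; bipotent, cTEC/mTEC-biased,
dormant, compartment-private, unclassified).

Power considerations: a clone's single-cell count scales with its sampled
share while its background scales with its bulk share, so significance
requires clones large enough that the minority-compartment count exceeds
the binomial critical value. Recovery tests therefore use a heavy-tailed
fixture (2,000 founders, log-normal(2.5, 2.2) clone sizes, 4,000 sampled
cells) and evaluate recall on the clones whose true composition gives
≥ 0.99 power in both mature compartments at a conservative per-test level
of 1e−5; measured recall is 100%. The rank-correlation check between
estimated and true clone biases pools cohorts simulated at four different
bias settings, because with a single bias value the true biases form two
point masses and rank correlation is bounded by within-mass sampling
noise rather than estimator quality.

## Transcriptome side

UMI conversion uses t = −K ln(1 − k/K) with K = 4096 (6-nt tags);
saturated counts are evaluated at K − 0.5. The closed form agrees with a
Monte-Carlo collision simulation within Monte-Carlo error across the
sampling range.

Cell QC: per-dataset minimum totals (configuration), removal of cells with
> 2% Kcnq1ot1 content (low-quality marker), then normalisation by
downscaling — per-cell multivariate-hypergeometric downsampling to the
minimum retained total, the established meaning in plate-based UMI
pipelines (a `scale` flag substitutes simple rescaling for speed). Gene
QC removes the anchor gene, genes with Pearson r > 0.65 to it, mitochondrial
genes, the edited locus itself and configured patterns (Jun, Fos, Gm*).

Differential expression uses a quadratic mean–variance background trend
v(m) = m + a·m², a fitted by least squares across genes (the minimal
faithful background model for this data type); under the shared-mean null
the group total is compared with NB(mean n·m, size n/a) and the smaller
tail is doubled. Genes with zero counts in both groups get P = 1 and fold
change 0. Gene sets require adjusted P < 0.01 and log2 fold change
strictly > 1, exclude Gm*/·Rik identifiers and heat-shock families
(Hspa/Hspb/Hsph/Dnaj — configurable; these genes rise in both progenitor
types and do not separate them), and the EP ∩ cTEC overlap is removed
from the EP set.

Cluster ratio coordinates are log2((ΣEP + ε)/(ΣPP + ε)) and the C/M
analogue per cluster with ε = 1 transcript (prevents division by zero
without distorting aggregates; doubling ε changes no quadrant assignment
on the default fixture). Coordinates are centred by the unweighted mean of
the reference dataset's cluster coordinates — the weakest transform
consistent with a "reference time point" reading, chosen so the reference
evaluated against itself centres exactly at the origin; this centring is
interpretive, not a measured property of the assay. Cohort-level dominance
statements use the fraction-weighted centroid, since per-cluster
coordinates reflect population transcriptomes while composition enters
through cluster fractions.

## Problem sizes and limitations

Test and acceptance runs use 18-mouse cohorts at 5,000 bulk reads and
1,000–4,000 cells per dataset, and ten null cohorts for calibration —
sizes chosen so the statistics operate in the same regime as the real
experiment (rare-barcode sharing of a few per mille across mice, ~10⁵
tests per calibration batch) while each suite completes in well under a
minute per component.

The simulator does not model: spatial structure (medullary islets),
age-dependent transcriptome drift beyond configurable population
proportions, doublets, ambient RNA, PCR chimeras, or clone-level
X-inactivation correlation (allele exposure is per cell). Passing tests
demonstrate that the statistics are implemented correctly and behave as
designed under the stated generative model — not that the model captures
every property of real thymic data. Population definitions (cluster →
population maps), QC cutoffs and exclusion lists are configuration, as
they are dataset-specific in practice.
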