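# Methods

## Scope and model

`ucsig` operates strictly downstream of differential-expression testing: its
inputs are per-dataset DE result tables (gene id, biotype, mean expression,
log2 fold change, p, adjusted p), an orthology map, gene loci, risk loci,
miRNA→target maps, gene-set collections, a confidence-scored interaction
edge list, and qPCR Ct tables.  Read mapping, quantification and the DE fit
itself (DESeq2 or a microarray pipeline) are out of scope; the package
assumes their outputs are well-formed and validates them strictly at the
boundary.

## SDE calling (per dataset)

A gene is called SDE when padj ≤ `padj_max` (default 0.05, inclusive to
match the usual "padj ≤ 0.05" convention) and its fold change clears the
biotype-appropriate floor with a strict inequality: |log2FC| > 1 for
total-RNA assays, |FC| > 1.5 (i.e. |log2FC| > log2 1.5) for small-RNA
assays, applied in both directions because down-regulated miRNAs are
biologically meaningful calls.  Missing padj means the DE tool filtered the
gene (independent filtering / outlier flags) and is treated as *not
significant* — imputing it would inflate the SDE sets.  A significant gene
with log2FC exactly 0 has no direction and is excluded with a logged
warning.  Note FC > 2 is the same call as |log2FC| > 1, so the gene set
used for enrichment needs no separate thresholds.  The fold-change floor
may be set to 0 to obtain significance-only direction sets; the
cross-species overlap uses these, since the comparison is defined on
padj ≤ 0.05 alone.

## Multi-dataset combination (within one species and tissue)

Datasets are combined by vote, not by p-value pooling: a gene enters the
combined set when significant in at least `min_support` (default 2)
datasets with agreeing fold-change signs.  Direction consistency is judged
only over the datasets where the gene is significant — a non-significant
opposite-sign estimate elsewhere is noise and does not veto.  Significant
genes with conflicting signs form the *inconsistent* partition, which is
carried explicitly and excluded from all downstream comparison.  Genes
absent from a dataset's universe (platform differences) count as "not
significant" there rather than blocking combination.  No fold-change floor
applies at this stage (an optional one is exposed).  miRNAs use a laxer
rule — significant in ≥ 1 of exactly 2 datasets — reflecting the scarcity
of small-RNA studies; the count significant in both is reported alongside.
Meta-analytic pooling (Fisher, Stouffer, effect-size models) is an explicit
non-goal: the method combines calls, not statistics.

## Cross-species concordance and the core set

Every orthology pair whose mouse member is in the mouse SDE set and whose
human member is in the human combined set yields a row classified purely by
the direction pair: up/up → concordant-up, down/down → concordant-down,
otherwise contra.  Gene-level tallies count distinct mouse genes
(membership-oriented): a one-to-many mouse gene matched by several human
orthologs counts once — concordant if *any* matched pair is concordant,
contra only if all are.  The tally identities `total = ⇈ + ⇊ + ⇅` and
`same_direction = ⇈ + ⇊` hold on every input and are asserted in tests.
The core set contains genes concordant within colon AND within blood;
cross-tissue direction agreement is recorded as an annotation, not used as
a filter, so a gene up in blood and down in colon (each tissue internally
concordant) remains a member flagged `agreement=False`.  The relaxed miRNA
analysis repeats the overlap at padj < 0.1 (strict, matching the convention
"padj < 0.1"); relaxing the cutoff can only add genes except where the
wider significance window exposes a direction conflict, which moves the
gene to the inconsistent partition instead.

## Genomic context

All coordinates are 1-based inclusive (GTF convention); BED inputs are
converted at the reading boundary so a single convention governs the window
arithmetic.  lncRNA neighbors are expressed protein-coding genes whose body
intersects `[start − w, end + w]` (default w = 100 000 bp) on the same
chromosome — any-bp overlap, boundary inclusive, strand-agnostic, anchored
on the gene body (a TSS anchor is available; the choice of anchor is a
documented default, not a claim).  Risk-locus proximity flags genes whose
gap to any risk interval is ≤ w, with overlap counting as distance 0 and
point loci as single-base intervals.  miRNA target sets are input maps
intersected with the expressed universe; no sequence-based target
prediction is performed.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) from the hypergeometric
distribution (scipy) with BH step-up correction (statsmodels) across all
tested terms, gene ratio k/K, terms restricted to the universe and skipped
below `min_term_size` (default 3) members in it.  The universe defaults to
the expressed genes of the relevant experiment and is overridable; query
genes outside it are trimmed with a warning.  Zero-hit terms are reported
with p = 1 but excluded from plots.

## Network ranking

Degree, harmonic closeness and shortest-path betweenness are computed per
node (networkx); harmonic rather than classic closeness because interaction
subnetworks are frequently disconnected and the mean of inverse distances
stays defined across components.  Each measure is min-max scaled over the
node set (a constant measure carries no information and maps to 0.5), then
combined as a weighted mean — equal weights by default, the most defensible
reading of "a combination of degree, closeness and betweenness" absent a
published rule; weights are configurable and the default is documented as a
choice.  Ranking is dense (ties share the smaller rank) with lexicographic
output order for bit-stable results.  Optionally edge confidences enter as
lengths (1 − confidence + 1e-3) and degree as the confidence sum; default
is hop-count, since no published weighting scheme exists to match.  STRING
scores are divided by 1000 and thresholded at 0.4 ("medium confidence") by
default, configurable because the original cutoff is not stated.

## qPCR quantification

Pure Livak 2^−ΔΔCt, no amplification-efficiency correction: technical
replicates are averaged per (sample, gene); each sample's reference level
is the arithmetic mean of its reference-gene Cts (equivalent to a geometric
mean on the expression scale — the standard multi-reference pooling when no
rule is stated); ΔCt = target − reference per sample; ΔΔCt is the
difference of unpaired group means (case vs control subjects, so no
per-sample pairing is assumed); FC = 2^−ΔΔCt.  Reference normalization
cancels sample-wide offsets exactly, and swapping the groups inverts the
fold change — both are tested invariants.  A sample lacking all reference
genes is dropped; a target missing from one group fails only that target.

## Synthetic data: what it emulates and what it does not

The generator emulates the *outputs* of DE pipelines, not their inputs:
adjusted p-values are drawn directly (signal genes padj ~ U[0, 0.05] in the
datasets where they fire, null genes padj ~ U(0.05, 1]) and log2FC around a
class-signed effect mu with spread sigma.  This keeps every recovery check
analytic — at sigma = 0 and firing probability 1, pipeline recovery of all
planted classes is exact with zero false positives by construction.  It
deliberately does **not** model count-level noise (negative binomial
reads), batch effects, p-value/effect-size correlation, platform-specific
artifacts, or realistic orthology complexity; passing tests therefore
demonstrate the correctness of the integration logic, not robustness to
real-data pathologies.

Default study conditions, fixed once: one mouse dataset per tissue; four
human colon and three human blood total-RNA datasets; two human colon
small-RNA datasets; colon classes 50 concordant-up / 30 concordant-down /
20 contra / 15 inconsistent / 25 species-specific / 500 null with mu = 3
and sigma = 0.1; miRNA classes 9⇈ / 12⇊ / 4⇅ plus 3 borderline miRNAs
planted in the (0.05, 0.1) padj window that surface only under the relaxed
cutoff; qPCR with references GUSB/B2M/ACTB/TBP, 5+5 samples, 3 replicates.
Both tissues share one genome-wide universe (blood measures a prefix subset)
and the bundle plants ~10 core genes by forcing colon-concordant genes into
blood's concordant classes; one-to-many and unmapped orthology variation is
confined to genes null in both tissues so planted recovery stays exact.
Networks are star-plus-noise: hubs wired to 90% of core genes at confidence
0.9 over Erdős–Rényi noise at confidence U(0.41, 0.6).  Every generator is
deterministic given its seed; the bundle derives independent child seeds
from one SeedSequence.

## Numerical and design notes

* Fold-change comparisons are strict (>), padj comparisons inclusive (≤),
  relaxed-threshold comparisons strict (<) — each matching its stated
  convention literally.
* BH adjustment is not idempotent in general (for p = (0.01, 0.5) the
  step-up gives (0.02, 0.5); reapplying gives (0.04, 0.5)); the tested
  properties are fdr ≥ p, capping at 1 and monotonicity in rank.
* In hub-free noise networks the maximum combined centrality z-score stays
  below 4 (simulation over 100 seeds; betweenness is heavy-tailed, so a
  3-sd screen is too tight), while a planted hub's z-score exceeds 4.8 in
  every seed — the hub-detection margin the tests assert.
* Problem sizes in tests and the acceptance script (≤ ~640 ortholog pairs,
  1000 loci, ≤ 50-node oracle graphs, 500 qPCR seeds) are chosen so the
  whole suite completes in well under a minute while every check remains
  exact or tightly bounded.
* Degenerate inputs: empty graphs, empty gene sets, all-null universes and
  support thresholds exceeding the dataset count all yield well-defined
  empty results rather than errors at the pipeline level.

## Known limitations

Vote-based combination discards effect-size magnitude; the concordance
classification ignores fold-change magnitude agreement; network ranking
reflects the input interaction database's coverage bias; the synthetic
generator's independence assumptions understate real cross-dataset
correlation.  The published headline gene counts from the original cohorts
are not recomputable here — the package reproduces the arithmetic and logic
of those analyses, and verifies recovery on ground-truthed synthetic data.
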