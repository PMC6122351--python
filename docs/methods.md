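# Methods

## The problem and the model

A tumor-only differential-expression call replaces the missing
patient-matched normal with a *reference panel*: per-gene summary
statistics of healthy normal breast expression within one asservation
(FFPE or fresh-frozen) and one library-preparation (total-RNA or
exome-capture/targeted) group.  Expression values from different kits or
fixation methods are never mixed into one comparison; each (asservation,
kit) cell gets its own panel.

All expression arithmetic runs on counts per million (CPM):
`cpm[g,s] = counts[g,s] / total_s × 1e6`, defined over the full gene
universe of the annotation.  After gene subsetting, columns are
deliberately not renormalized — CPM is a property of the library, not of
the subset.

### CV threshold and its fold-change interpretation

Per gene, the coefficient of variation across a group's samples is
`CV = sd / mean` with the sample (n − 1) standard deviation — the unbiased
convention matters at the group sizes involved (9–19 samples).  CV is
computed on untransformed CPM.  Genes with zero group mean have undefined
CV and are never accepted as references: the stability of an unexpressed
gene cannot be certified.

The working threshold CV < 0.30 has an analytic reading: for normally
distributed expression with mean μ and sd = CV·μ, the central interval at
normal quantile z is [μ(1 − z·CV), μ(1 + z·CV)], so the largest fold
change expected between two healthy samples (both within the 95% band) is

    max log2FC(CV) = log2((1 + z·CV) / (1 − z·CV)),   z = 1.96.

This map is strictly increasing on [0, 1/z) with inverse
`CV(L) = (2^L − 1) / (z (2^L + 1))`.  At L = 2 (a 4-fold envelope) the
exact solution is CV\* = 3/9.8 ≈ 0.3061; the round threshold 0.30 sits just
below it (max log2FC(0.30) ≈ 1.95), i.e. it is the conservative round
number inside the 4-fold budget.  The domain ends at CV = 1/z, where the
lower confidence bound hits zero and the ratio is undefined.

### Exclusion flags

Two flags exclude genes regardless of CV:

- **TLV (left/right pair variability).**  For each patient with both
  breasts sampled, per-gene `log2((CPM_L + ε)/(CPM_R + ε))`; a gene
  exceeding |log2FC| > 2 in *at least one* pair is flagged.  The
  comparison is strict (exactly 2.0 does not flag), and the pseudocount
  ε defaults to 0.5 CPM (ε = 0 is allowed; 0/0 genes then get an undefined
  fold change and never flag).
- **ASG (adipocyte signature).**  Surgeon-prepared fresh-frozen breast
  tissue retains fat cells; pathologist-prepared FFPE sections do not.
  Genes are compared between the breast panel's mean CPM and the mean CPM
  of pure fat samples; genes with |log2FC| > 2 are flagged — but only
  among genes whose breast CV is already below the threshold, since a
  gene too variable in breast tissue carries no usable signal about fat
  confounding (it is excluded by CV anyway).

A gene is a trustworthy reference (`low_variability`) iff
`CV < 0.30 AND NOT TLV AND NOT ASG`.  The inverse conjunction labels
reported tumor genes: `variability = high` iff `CV > 0.30 OR ASG OR TLV`
(undefined CV ⇒ high, conservatively).  Both boundaries are strict, so a
gene at exactly CV 0.30 is neither a confident reference nor flagged high
by CV alone.

### Fold-change arithmetic

All pairwise/group ratios use `log2((a + ε)/(b + ε))` with ε = 0.5 CPM by
default.  Ratios are evaluated in a sign-canonical form,
`sign(a − b) · log2(max/min)`, which makes swapping the two sides an exact
floating-point negation (the antisymmetry invariant holds bitwise) while
preserving exact values for power-of-two ratios.

### The group test stand-in

Group comparisons with replicates use a per-gene Welch two-sample t-test
on log2(CPM + 1) with Benjamini–Hochberg adjustment; a gene is called at
q ≤ 0.05 together with the fold-change criterion (log2FC > 1.5 for tumor
overexpression, |log2FC| > 2 for confound sets).  This engine is a
declared stand-in for moderated count-model frameworks (limma/voom,
DESeq2) that a production workflow would use on real data; results carry
`attrs["engine"] = "welch_bh"` so they are never mislabeled.  Genes with
zero variance in both groups and equal means get p = 1 by convention.
Single-sample comparisons (one tumor against the panel; the two halves of
one split specimen) admit no replicate test and use the pure fold-change
rule, which is also how the confound exclusion sets are defined.

Percentages in summaries (category counts, set overlaps) are computed on
the exact rational and rounded half-up to integers — the convention that
reproduces every published summary percentage.

### Drug matching

Matching runs against a local TSV snapshot of a drug–gene interaction
database; no live API is queried, for reproducibility.  The filter keeps
records whose lowercase interaction type is in the 12-token
"inhibitor-like" family (antagonist, antibody, blocker, inhibitor,
suppressor, allosteric modulator, adduct, binder, immunotherapy,
inhibitory allosteric modulator, inverse agonist, vaccine) and which are
antineoplastic, clinically actionable and expert-curated — each
requirement individually relaxable in `DrugSelectionConfig`.  Report rows
exist only for genes above the overexpression threshold (default 1.5,
configurable — not hard-coded, since published reports sometimes list
genes below it) with at least one surviving interaction; inhibitors are
deduplicated and sorted, rows ordered by descending log2FC with
alphabetical tie-break.

### Immune repertoire

Depth harmonization mirrors read-level downsampling to the smallest
library, but acts on count summaries: `harmonize_depth` returns the
minimum total, and callers rescale either by exact hypergeometric
subsampling (integer counts; sums match the depth exactly) or by
expectation scaling — the mode is the caller's declared choice.  The unit
of analysis is the per-(sample, chain) aligned-read fraction; group
summaries are arithmetic means of member-sample fractions, and between-
group contrasts are ratios of those means (zero denominators are flagged
infinite rather than raised, so tabulations over many chains proceed).
Clonotype structure is represented only as a count per (sample, chain);
CDR3 clustering itself is out of scope.

## The synthetic cohort generator

`generate_cohort` emulates the study design so that every stage has a
testable ground truth.  Defaults (chosen once, as the package's standing
study conditions):

| parameter | default | rationale |
|---|---|---|
| groups | 19 FFPE/total + 9 FF/total + 11 FFPE/targeted normals, 10 FFPE/total tumors, 6 FF/targeted fat | the study's sample layout |
| left/right pairs | 7 (FFPE/total) + 1 (FF/total) | the study's pairing |
| n_genes, library size | 2000 genes, 2–5M reads | desk scale; per-gene depth comparable to 23686 genes at 20–80M reads, so shot noise is realistic |
| baseline log2 CPM | Normal(6, 2) across genes | typical bulk dynamic range at this gene count |
| biological CV | 70% of genes U(0.05, 0.20), 30% U(0.50, 1.00) | a stable majority plus a variable minority, straddling the 0.30 threshold |
| contamination π | U(0.2, 0.6) per FF breast sample; 0 for FFPE | strong adipocyte admixture in surgeon-prepared frozen tissue; fat-free microdissected FFPE |
| fat signature | 100 genes, \|log2FC\| U(3, 6), 70% up in fat, planted on low-CV genes | fat markers are strong and stably expressed |
| pair-discordant genes | 60 genes, \|log2FC\| U(2.5, 4.5), one side of one random pair, planted at baseline CPM ≥ 20 | clearly beyond the 2.0 threshold and the ε-distortion regime |
| tumor spikes | 50 genes, log2FC U(2, 4), planted at baseline CPM ≥ 10 | druggable overexpression happens on expressed genes |
| fixation effect | 150 genes, ±U(1, 3) log2 in FFPE | fixation-sensitive transcripts |
| targeted mask | 20% of genes zeroed | non-coding/untargeted genes absent from capture libraries |

Counts are negative binomial via a gamma–Poisson mixture with dispersion
CV², applied to a per-sample expected profile
`p = (1 − π)·breast + π·fat` (an exact convex mixture of CPM profiles,
which the mixture-check test verifies).  The per-gene biological gamma
factor is drawn **per patient**, shared between a patient's left and
right breast, with a small per-sample residual (CV 0.05): left/right
pairs are correlated, which is what makes the TLV filter informative —
an unpaired-noise model would flag every high-CV gene.  Planted gene sets
(fat signature, spikes, discordant) are mutually disjoint so recovery
tests are unambiguous.

What the generator does **not** model: fragment-level or positional bias,
FFPE degradation beyond a multiplicative gene-set effect, correlated
gene–gene modules, library-composition effects of extreme outliers, or
read-level data of any kind.  Passing recovery tests therefore shows the
*rules* behave as specified under the assumed noise model — not that the
thresholds are optimal for real tissue.

`generate_repertoire` draws per-(sample, chain) aligned counts
binomially at a common 1M-read depth around plausible bulk-tissue
fractions (1e-5–1e-3), with multipliers for the design contrasts: ×0.1 on
TRA in targeted libraries, ×0.03 on all chains in fat tissue, ×0.5 on IG
chains in fresh-frozen samples, and a log-normal per-(sample, chain)
noise of 0.4 log2 units.  `generate_interaction_table` mixes the
qualifying published gene–inhibitor pairs with planted records that each
fail exactly one filter (wrong type, not antineoplastic, not actionable,
weak source trust).

## Numerical and design choices

- **Low-count filter**: the published analysis reports only the outcome of
  its filter, not the rule; the default here is CPM > 1 in ≥ 25% of
  samples (`ceil` on the sample count), fully configurable.  The kept-set
  is monotone in both knobs.
- **QC PCA** runs on log2(CPM + 1) over the unfiltered gene universe by
  default (raw CPM is available); samples are mean-centered, components
  come from a full SVD.  If all samples coincide, scores and
  explained-variance fractions are defined as zero rather than NaN.
- **Ties and boundaries**: "low variability" needs CV strictly < threshold;
  TLV/ASG/overexpression need fold change strictly > threshold; BH uses
  the standard step-up with q ≤ α.
- **Degenerate inputs**: zero-total libraries are rejected by name;
  single-sample groups cannot yield a CV; empty groups cannot be compared;
  enrichment with degenerate 2×2 margins returns p = 1; an empty set's
  overlap percentage is reported as missing, not 0.
- **Determinism**: every generator is a pure function of its config
  (seed mandatory); identical configs give identical outputs, byte for
  byte, which the test suite asserts.

## Problem sizes

The bundled cohorts run at 2000 genes (5000 for the null-calibration
check) and the study's sample counts; the full test suite and the
acceptance script each complete in a few seconds on one core.

## Known limitations

- The published per-dataset gene counts (e.g. how many genes pass a CV
  threshold in a given cohort) are properties of unreleased sequencing
  data and are not reproduced; only the rules, their arithmetic and their
  statistical behavior on synthetic data are.
- The Welch/BH engine is a stand-in; effect-size shrinkage and
  count-model dispersion sharing of limma/DESeq2 are out of scope.
- Gene identifiers are opaque strings; no namespace mapping is attempted.
- The ASG/TLV interpretation of reliability flags follows the conjunction
  rule that reproduces all published report rows; the flags are
  membership in the fat-confound and pair-variability exclusion sets.
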