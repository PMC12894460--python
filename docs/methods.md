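# Methods

This note documents the statistical model, the defaults and their
rationale, the synthetic-data generator, and the numerical and design
choices made where the problem was genuinely open.

## Study design the package assumes

Two cross-sectional patient cohorts (self-identified African American
men, AAM, and Caucasian men, CM) each contribute one plasma cfDNA sample.
Each sample is variant-called twice (FreeBayes- and LoFreq-style VCFs);
the package consumes those VCFs — alignment and calling are out of scope.
There is no matched germline control, so somatic versus germline status
must be inferred from external references, and population allele
frequencies stand in for a healthy control arm: the gnomAD-style AFR
panel is the baseline for AAM, NFE for CM.

## Variant identity and ingestion

All joins across datasets use a normalized variant key (contig, 1-based
position, ref, alt) on hg38 with "chr"-prefixed contig names; bare names
are rewritten on read. Normalization is the standard parsimony algorithm:
shared trailing bases are trimmed first, then shared leading bases with
the position advanced, always leaving at least one base per allele. The
result is minimal and left-anchored, and normalization is idempotent.
Multi-allelic records are split per alternate allele before filtering;
the record-level depth and quality are shared across the split alleles
because a VCF record carries a single DP and QUAL.

Filtering retains calls with depth ≥ 199 and quality ≥ 30 (strictly lower
values are excluded; boundary values pass). Depth is the read-level DP
(INFO, falling back to the first sample's FORMAT field), not a
UMI-consensus depth — cfDNA libraries with unique molecular identifiers
have substantially lower effective molecular coverage than nominal read
depth, which is a stated limitation of read-level filtering. A variant
enters a patient's consensus set only when both callers report it after
filtering. The unit of analysis is the *carrier* (patient presence/
absence), not allele or read counts: with one cross-sectional plasma
sample per patient there is no meaningful per-patient allele dosage for
tumor-derived fragments.

## Cohort statistics

Category frequencies between cohorts are compared with the pooled
two-proportion z-test, z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), two-sided
normal p, with full cohort sizes as denominators (not-reported categories
stay in the denominator). z² equals the uncorrected Pearson chi-square on
the corresponding 2×2 table, which the suite verifies numerically. When
the pooled proportion is degenerate (0 or 1) both sample proportions are
necessarily equal and the test returns (z, p) = (0, 1).

Ages are compared with Welch's unequal-variance t-test and Satterthwaite
degrees of freedom, computable from summary statistics (mean, SD, n)
when raw values are unavailable; the pooled-variance test is an option
(`equal_var=True`). Printed percentages use decimal half-up rounding to
one decimal, matching how clinical tables are typeset (banker's rounding
would print 0.05 → 0.0).

## Differential testing

Each variant yields a 2×2 table of carriers/non-carriers per cohort,
tested with Fisher's exact test. The two-sided p-value sums the
probabilities of all tables at the observed margins whose point
probability does not exceed the observed one, with a relative tie
tolerance of 1e-7 so floating-point-equal probabilities count as ties;
this is the most common two-sided convention and the package implements
it directly (scipy's independent implementation is a cross-check in the
test suite, and exhaustive hypergeometric enumeration is the oracle for
all tables with margins ≤ 12). The odds ratio is the sample ad/bc with
0/∞ conventions.

Benjamini–Hochberg adjustment is applied once over *all* variants in the
run — one genome-wide family, not per gene or per chromosome. Variants
with q < α (default 0.05) are significant; the dominant cohort is the one
with the higher carrier proportion. Exact proportion ties give dominance
"none" and are excluded from ancestry classification, since alignment is
undefined without a direction.

## Somatic catalogue curation

Catalogue records pass three independent predicates: sample gender must
be male; primary sites indicative of female reproductive cancers are
excluded (defaults: ovary, breast, endometrium, cervix); histologies and
subtypes unrelated to a prostate context are excluded (defaults: sex
cord-stromal tumor, ductal carcinoma, serous carcinoma). The histology
list is inherently open-ended, so both lists are configuration inputs
with those defaults. Because the filters are independent predicates they
commute and are idempotent, which the suite checks on randomized tables.
All tissues surviving the filters are retained (broad-tissue inclusion):
with metastatic disease the organ of origin of a cfDNA fragment is
uncertain, so restricting to prostate-primary records would discard
relevant cross-cancer evidence.

Matching against cfDNA variants is coordinate-level by normalized key,
not gene-level — gene-level matching would inflate the overlap. A shared
variant is somatic-confirmed iff at least one matching curated record has
a confirmed-somatic status; raw status strings map to a three-way
vocabulary (confirmed_somatic / not_confirmed / other) via a configurable
rule (default: "not confirmed" or "unknown origin" → not_confirmed,
otherwise strings containing "confirmed somatic" → confirmed_somatic).
The somatic / not-somatic split partitions the shared set exactly.

## Ancestry classification

For each significant, dominance-called variant the AIM is
|AF_AFR − AF_NFE|. Alignment uses the *signed* difference in the
direction of the dominant cohort's reference population: an AAM-dominant
variant is aligned iff AF_AFR − AF_NFE ≥ 0.01 (CM symmetric). The
comparator is ≥ by default and configurable to strict >; the 0.01
threshold is likewise configurable. Opposite-direction and sub-threshold
differences are both "not aligned". If either population AF is missing
the variant is "no data": direction cannot be assessed from one
frequency, so one-sided records are not guessed at.

Alignment × somatic × PC-membership maps bijectively onto groups 1–8
(aligned first, somatic before non-somatic, PC-related before not). The
eight groups plus the no-data bin partition the classified variants;
tallies are reported separately for AAM-dominant and CM-dominant
variants. PC-pathway membership is a case-insensitive exact symbol match
against a user-supplied gene list.

## Enrichment

Over-representation only: p = P(X ≥ overlap) under the hypergeometric
distribution, with BH correction across all sets of one collection
(separate collections are corrected separately, mirroring how GO and
Hallmark analyses are run independently). The background defaults to an
integer universe of 20,000 genes — a conventional human protein-coding
count — because a reference tool's exact annotation universe is not
distributable; an explicit background gene list overrides it, in which
case the query is first intersected with the background.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at the study-scale defaults: 22 AAM and 66 CM patients, 500 variants,
metastasis site/timing categories drawn with the study-scale counts
(bone-dominant sites; 13/22 vs 24/66 at diagnosis), ages
N(59.45, 8.4²) vs N(62.3, 7.9²), and read depth overdispersed around
500× (negative binomial, dispersion 8).

Effect classes per variant: `null` (one carrier probability for both
cohorts, uniform on [0.05, 0.5]), `differential` (0.8 vs 0.05 carrier
probability, direction random), `somatic_spike` (differential and
catalogued confirmed-somatic), `missing_af` (differential with no AF
row, exercising the no-data routing); default mix 70/18/8/4%. Reference
AFs realize a configurable aligned fraction (default 0.7) with the
remainder discordant — half opposite-direction, half sub-threshold.
Carrier status is Bernoulli per patient; a variant drawn with zero
carriers overall receives one forced carrier so the matrix invariant
holds. A 5% fraction of carrier calls is written to fail ingestion
(sub-threshold depth, sub-threshold quality, or single-caller only) and
10% of VCF rows are suffix-padded to exercise normalization. The
catalogue includes decoy confirmed-somatic records violating each
curation filter, planted on truth-non-somatic variants, so skipping
curation corrupts the somatic flags and fails the round-trip tests.

All randomness derives from one master seed through named child streams
(variants, carriers, AFs, metadata, VCF, catalogue, gene sets), so
adding an output type does not perturb earlier draws and identical
configurations give byte-identical files; the VCF manifest stores
relative paths for the same reason.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: linkage between variants (sites are
independent), variant allele fractions and tumor fraction, sequencing
error and UMI structure, clonal-hematopoiesis contamination, and real
COSMIC/gnomAD ascertainment biases (including the thinner AFR coverage
that the no-data path only caricatures).

## Validation scale and numerical choices

The simulation checks run at sizes chosen to give tight Monte-Carlo
error while staying desk-scale: planted-variant detection and dominance
over 200–300 seeded replicates of 100-variant cohorts (detection is
effectively 100% at the planted 0.8 vs 0.05 effect), empirical FDR over
200 replicates with a 90/10 null/differential mix, and full
VCF-round-trip group recovery on cohorts of 150–300 variants. Exact-test
oracles run exhaustively (all 2×2 tables with margins ≤ 12; subset
enumeration for enrichment backgrounds ≤ 20). P- and q-values are
written with 6 significant digits; output tables are sorted by variant
key so reruns are byte-identical.

Known limitations: tumor-only carrier testing cannot distinguish
germline from somatic signal by itself (that is exactly why the
catalogue and AF axes exist); the two-proportion z-test is a normal
approximation, adequate at these cohort sizes but not for very rare
categories; enrichment results depend on the supplied gene-set
collections and background choice; and the eight-group classification
inherits any bias present in the reference panels' population coverage.
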