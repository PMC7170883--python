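# Methods

This note records the models, decision rules and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinates and formats

All in-memory intervals are 0-based half-open; VCF and SNP-array positions
are 1-based. The single conversion point maps a VCF position *p* with REF
length *L* to `[p−1, p−1+L)`. The VCF dialect is a minimal v4.2 subset
(CHROM…FILTER plus FORMAT/GT); multi-allelic records are split into
biallelic records on read, with a sample's code for ALT allele *k* being its
count of that allele, and any missing allele call making the genotype
missing. Phased separators are treated as unphased — no stage downstream
uses phase. All variants and array dosages are taken on the forward
reference strand; no strand reconciliation is attempted.

## Dominant sharing scan

The pedigree analysis asks a deliberately narrow question: which stretches
of the genome are *consistent* with a single dominantly inherited haplotype
carried by every affected member? Full multipoint identity-by-descent
inference is unnecessary for that role — the scan is used only as an
inclusion mask for variant filtering — so it is replaced by a per-SNP
obligate-sharing test plus run-length smoothing:

- A SNP is **compatible** when some allele *a* ∈ {ref, alt} is carried
  (≥ 1 copy) by every affected, genotyped individual, and no genotyped
  unaffected individual is homozygous for every allele that could play that
  role. (When both alleles are viable candidates no unaffected genotype can
  contradict sharing; when only one is, an unaffected homozygote for it
  means the "shared" allele could equally have come from the married-in
  side.)
- Missing genotypes are permissive (compatible). A filter mask should not
  lose the causal region to missingness; the cost is slightly wider regions,
  not lost ones. Compatibility is therefore monotone in missingness, which
  the property tests exercise.
- Maximal runs of ≥ `min_run` (default 3) consecutive compatible SNPs
  become regions spanning their outermost SNPs, `[pos_first−1, pos_last)`
  plus the last base.

Region boundaries from this scan will differ from a Lander–Green multipoint
reconstruction by construction; recovery is scored by Jaccard overlap with
the planted truth (mean ≥ 0.99 at 1 SNP / 50 kb in the shipped
simulations).

Array QC precedes the scan: SNPs with genotype-clustering (gentrain)
quality < 0.5 or call rate < 95% are dropped, then samples with call rate
≤ 95%. Bounds follow the published "<"/">" symbols: a gentrain of exactly
0.5 survives, a sample call rate of exactly 95% does not.

## Variant filter cascade

From the set of variants shared by the two sequenced relatives (both carry
≥ 1 alternate allele, QUAL ≥ 20 — the quality bound is inclusive), stages
apply in a fixed order: inside a sharing region → consequence in
{frameshift, missense, canonical splice, stop/start gain/loss} → absent or
MAF exactly 0 in database 1 → likewise database 2. "Non-synonymous" maps to
the missense consequence class; canonical splice sites are whatever the
annotation table says (the annotation engine is out of scope, annotations
are consumed as data). Database novelty is keyed on the full
(chrom, pos, ref, alt) tuple: positional matching alone would discard novel
alleles at known sites. An unannotated variant is an error, not a default —
silently treating it as non-coding would make the cascade's counts
unreproducible. Stage counts are non-increasing by construction and the
final set is order-independent, both fuzz-tested against a one-shot
predicate-conjunction oracle.

## CNV consensus

Per-sample metric gates (first caller: LRR SD < 0.35, BAF drift < 0.002,
|waviness| < 0.04; second caller: LRR SD < 0.3, BAF SD < 0.15) are strict
inequalities; failures report every violated criterion. The consensus rule
requires, for each member of a cross-caller pair: same state, ≥ 3
supporting SNPs, and its own caller's score > 10 (the conservative reading
of "confidence value or log Bayes factor > 10" — each call passes on its own
metric). Reciprocal overlap must reach 50% each way. When overlaps are
many-to-many, pairing is greedy by descending overlap product with a
leftmost tie-break, each input call used at most once — deterministic and
order-independent after sorting. The consensus interval takes the innermost
boundaries `[max(starts), min(ends))`; any consensus touching the
centromere/telomere mask (any-overlap, the stricter reading of "spanned")
is removed. Telomere extents are not modelled; they live in the mask file.
The implementation is verified against a brute-force all-pairs filter on
random call sets.

## Cohort phenotypes

Inclusion requires gestation > 32 weeks, birthweight > 1500 g, British
ethnicity and at least one phenotype; the common-variant analysis further
excludes nonverbal IQ < 65 and any air-conduction threshold > 40 dB HL. All
bounds strict; the filter is idempotent.

MinLow is the minimum across ears of the 0.5 kHz threshold (single-ear
fallback when one ear is missing). MinMid averages 1/2/4 kHz within each
ear first, then takes the minimum across ears with complete triples — the
per-ear-average-then-min reading, matching the measure's tabulated
definition where the two appear once each way in prose.

DLD cases score ≤ mean − 1 SD on WOLD comprehension OR < mean − 1 SD on
both CCC fluency and syntax, with no autism flag and no hearing impairment
(any 1/2/4 kHz threshold > 20 dB HL — the only operational impairment
definition available). Controls score strictly above the cohort mean on all
three language measures ("above expected levels" is not quantified in the
source analyses; the mean is the least arbitrary anchor and the threshold
is configurable), with nonverbal IQ > 80 and neither the autism nor the
special-educational-needs flag. Individuals missing any of the three
language measures are excluded outright; missing audiometry is treated as
unimpaired (the flag fires only on observed evidence). Cohort means/SDs are
computed on the filtered table, non-missing values only.

Carrier contrasts report the carrier-minus-non-carrier mean difference and
Cohen's *d* with pooled SD and a normal-approximation 95% CI
(SE² = (n₁+n₂)/(n₁n₂) + d²/2(n₁+n₂)). The source tables are not fully
reproducible on *d* (the published vocabulary *d* of 0.7237 does not follow
from the published means and SD, whose combination gives 0.711), so *d* is
verified structurally — sign, affine invariance — rather than against a
printed value. Relative risks use the log-scale CI
exp(log RR ± 1.96·√(1/a − 1/n₁ + 1/b − 1/n₂)); a zero comparison-group risk
leaves RR undefined and reported as such.

## Association statistics

Sample filters run first (call rate < 95%, autosomal heterozygosity beyond
mean ± 3 SD), then SNP filters: MAF < 5%, missingness > 5% (the sensible
reading of a "call rate < 5%" exclusion, which taken literally would retain
almost-entirely-missing SNPs), Hardy–Weinberg 1-df χ² p < 5 × 10⁻⁷, and —
when case/control labels are supplied — differential missingness at Fisher
exact p < 10⁻⁵ (no threshold is published; this is the common genotype-QC
convention, configurable). The χ² HWE test is analytically checkable and
sufficient at a 5 × 10⁻⁷ bar.

LD is the squared Pearson correlation of dosages on pairwise-complete
observations (composite LD, no phasing). Tag selection is greedy: pick the
SNP covering the most uncovered neighbours at r² ≥ 0.8 (position order on
ties), remove it and its neighbours, repeat. The output is re-verified post
hoc: every non-tag reaches a tag at r² ≥ 0.8 and no two tags do.

Additive association is OLS (identity link) or logistic regression with a
two-sided Wald p; perfect separation is flagged rather than reported as a
spurious p. The interaction model is OLS on the design [1, g, c, g·c] with
the Wald test on the product coefficient; rank-deficient designs raise an
error naming the collinear column. No genomic control or structure
correction is applied — out of scope for this design.

The gene-based test is a variance-component score test: with null-model
residuals r (intercept + covariates, Gaussian working model) and diagonal
weights W on the variant dosage matrix G,
Q = r′GWG′r / σ̂². Its null law, Σλⱼχ²₁ with λ the eigenvalues of
W^{1/2}G′(I−H)GW^{1/2}, is approximated by the Liu–Tang–Zhang
moment-matched noncentral χ² (matching skewness and kurtosis); with n < 50
or a degenerate approximation, a seeded residual-permutation p is returned
instead. Weights default to the Beta(1,25) density on MAF (the standard
rare-variant up-weighting; flat weights are available and are what the
single-variant oracle test uses, where Q reduces exactly to the analytic
score test). Mean imputation handles missing dosages. Rare/common
subsetting uses MAF ≤ 0.01 / ≥ 0.05. The Gaussian working model means
binary traits are handled as linear probability residuals; a
logistic-variance SKAT is a known limitation.

Bonferroni thresholds are α/n. Analytic power for a variant explaining a
fraction r² of trait variance uses the 1-df noncentral χ² with
ncp = n·r²/(1−r²), cross-checked against a seeded simulation of the
additive test; published power figures from the original design are not
asserted because their method is unstated. Enrichment is a one-sided Fisher
exact test per term with Benjamini–Hochberg q-values across terms; terms
with no background overlap are skipped with a warning.

## Mouse behaviour

The attenuation score for each (subject, task, day, cue level) cell is
100 × mean(cued ASR)/mean(uncued ASR); 100 means the cue was not detected,
lower is better detection, and the score is scale-invariant within a cell.
A cell with no uncued trials is an error naming the cell; a zero uncued
mean yields an explicitly flagged undefined score. Group comparison first
collapses each subject to one mean score (the full repeated-measures
ANCOVA of the original design, with day and cue as within-subject factors
and sphericity machinery, is deliberately simplified to a between-group
test on cell-averaged scores — the claims exercised here concern group
effects on synthetic data): one-way ANOVA without a covariate, or the
linear model score ~ covariate + group with Type-II sums of squares and
covariate-adjusted means when the frequency-matched simple-tone score is
supplied. Zero-variance or group-collinear covariates are rejected as
singular designs.

USV syllables are kept when mean frequency ∈ [35, 110] kHz and duration
∈ [8, 200] ms (inclusive — "between … to" read literally); any two
syllables within the same recording closer than 5 ms then have *both*
members removed (the upstream tool's behaviour is unstated; pair removal is
the conservative choice, and `drop="later"` is available). The rule runs
within each subject's recording, since recordings are independent audio
files. One pass is idempotent: removing a close pair can only widen the
gaps among survivors. Summaries are per-group means ± SEM collapsed across
the eight syllable categories; single-syllable groups have their SEM
flagged undefined.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (seed, parameters) and serializes a
truth record sufficient to score recovery.

- **Family** (`sim_family`): a 12-member, four-generation pedigree in which
  every descendant of the affected founder is affected; seven members
  genotyped (five affected plus the two married-in spouses), two sequenced.
  A risk haplotype spans a 5 Mb block of a 50 kb-spaced marker map (the
  density regime of a ~750k genome-wide array); inside it every genotyped
  affected carries the risk allele and no married-in is homozygous for it.
  The shared-variant set contains one causal stop-gain inside the region
  and one decoy per cascade stage (low QUAL, not shared, out of region —
  anchored in a deliberately incompatible marker stretch — synonymous,
  non-coding, known in each database). There is no recombination model, no
  linkage disequilibrium and uniform marker spacing: the simplest structure
  that exercises the scan. Passing tests show the filters implement their
  definitions, not that the scan matches multipoint inference on real
  pedigrees.
- **CNV** (`sim_cnv`): planted cross-caller pairs at 80% reciprocal
  overlap satisfying every consensus criterion, plus decoys violating
  exactly one criterion each, placed in disjoint 10 Mb slots so pairings
  are unambiguous. Real call sets have nested and chained overlaps; those
  paths are covered by the randomized brute-force comparison instead.
- **Cohort** (`sim_cohort`): genotypes in Hardy–Weinberg proportions at
  fixed MAFs (no LD). Per-ear 0.5 kHz thresholds share a per-child base
  level at the published non-carrier moments (mean 9.96, SD 5.81 dB HL)
  plus a 1.2 dB carrier shift (carrier frequency 0.85%) and 0.5 dB per
  index-SNP allele (≈ 0.3% of threshold variance at MAF 0.3, the published
  magnitude for the top SNP). Vocabulary follows the explicit interaction
  model with defaults b = (210, −1.0, −0.8, −0.3) and noise SD 18 on the
  instrument's 0–246 scale, plus a −17.65 carrier shift (the published
  carrier/non-carrier difference). The intercept and noise place the
  simulated scores almost entirely inside the instrument's range
  (< 1% truncation): the estimand here is the interaction coefficient, and
  a heavily ceilinged outcome — which the real instrument is — would
  confound coefficient-recovery calibration with censoring. A warning
  fires if chosen coefficients truncate > 10% of scores. DLD-defining
  traits are generated at ρ ≈ 0.5 with vocabulary; real trait correlation
  structure is richer.
- **Behaviour** (`sim_ppi_usv`): log-normal trial amplitudes around
  per-subject baselines; cued trials suppressed by a genotype × task
  detection fraction (defaults: 0.6 everywhere, 0.3 for heterozygotes on
  the low-frequency task and knockouts on the high-frequency task), so the
  expected attenuation is 100 × (1 − detection). Syllable tables include
  out-of-band durations and planted < 5 ms gaps so the filter has work to
  do, and per-genotype frequency/duration/volume shifts (heterozygotes
  +5 kHz, −10 ms, +3 dB; knockouts +3 kHz).

One recovery figure quoted elsewhere deserves a caveat: with the published
threshold SD of 5.81 dB and a 0.85% carrier rate, the sampling error of the
carrier mean difference at n = 10⁵ is ≈ 0.2 dB, so recovery of the planted
1.2 dB shift is asserted within 4 Monte-Carlo SEs, not at an arbitrary
tighter figure.

## Problem sizes

The shipped analyses and checks run at desk scale, chosen to make every
statistical assertion well-powered while keeping a full run in seconds to
minutes: 2 000-SNP marker maps over 4 chromosomes and 100 replicates for
region recovery; 200 replicates at n = 5 000 for interaction-CI coverage;
2 000 replicates at n = 500 with 20 variants for SKAT type-I error; 2 000
SNPs for null-uniformity of the additive test; 200 random call sets for the
consensus oracle. Cohort drivers default to n = 8 000–20 000, the order of
the original cohorts.

## Known limitations

- The sharing scan is a filter, not a linkage method: no LOD scores, no
  recombination model, no X-chromosome handling.
- SKAT here is the Gaussian-residual form; no SKAT-O, no logistic variance
  weights, no relatedness adjustment.
- No population-structure correction, imputation or meta-analysis.
- The repeated-measures structure of the behavioural designs (day × cue
  within subject) is collapsed before testing; within-subject F
  decompositions are out of scope.
- Published stage counts and p-values that depend on access-controlled
  cohort data are not reproducible here by construction; the pipeline's
  correctness on those stages rests on the oracle-equivalence and
  planted-truth recovery tests instead.
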