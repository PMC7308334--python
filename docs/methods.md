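# Methods

## Model and procedure

The unit of analysis is the *SNV-deletion event*: a sequence variant on
the remaining allele of an inherited heterozygous deletion, in the child
(proband) or in the parent who transmitted the deletion. Because every
family contributes exactly the same gene set for its proband and its
transmitting parent, the pooled proband sequence and the pooled
transmitting-parent sequence are identical in gene identity and length by
construction. Under the null hypothesis that events arise at the same rate
on both sides, the total event count N = a + b splits Binomial(N, ½)
between the groups. The pooled count test is therefore the one-degree-of-
freedom chi-square goodness-of-fit against the equal split,

    X² = (a − E)²/E + (b − E)²/E,  E = (a + b)/2  ⇔  X² = (a − b)²/(a + b),

with the p-value from the upper tail of χ²₁. No continuity correction is
applied: the published statistics for the pooled counts (68, 41), the
union-filtered counts (21, 8), and both sensitivity re-analyses (20, 8)
and (61, 34) are all reproduced by the uncorrected statistic to printed
precision, while the Yates-corrected version of (68, 41) gives 6.20 and
matches none of them. This four-way agreement is the evidence that the
equal-split goodness-of-fit is the right reading of the "chi-square test"
in this design, and a two-sample contingency variant is deliberately not
offered.

The burden test sums the scaled (PHRED-like) CADD scores of each
individual's countable events and fits a logistic regression of group
membership (proband = 1, parent = 0) on the summed score by maximum
likelihood (statsmodels `Logit`), reporting the Wald standard error and
p-value for the score coefficient β. Complete separation is detected and
flagged (`converged=False`, no estimates) rather than reported as a huge
unstable β. Two modes are first-class: carriers-only (individuals with at
least one event) and full-sample (all probands and transmitting parents,
zeros included). No covariates are included: whether the original analysis
adjusted for site or sex is unstated, and the unadjusted model is the
conservative default.

Three primary analyses (count test, burden test, filtered count test) give
a Bonferroni threshold of 0.05/3 ≈ 0.0167.

## Detection rules and their edge cases

* **Coordinates** are 0-based half-open internally. VCF positions and
  "start–end" CNV tables are treated as 1-based inclusive at the boundary
  and converted on ingestion; gene tables are BED-like (already 0-based).
* **Gene content of a deletion** uses a 500 kb fuzzy border on both ends
  (clipped at zero), reflecting uncertainty in array-derived CNV
  breakpoints. Scenario classification does *not* use the border: a
  countable scenario-1 event must lie strictly within the reported
  deletion boundaries; a variant in a covered gene but outside them is
  scenario 2 and never counted.
* **QC thresholds** follow the stated wording exactly: depth ≥ 10
  (inclusive, "at least"), quality > 20, non-reference allele fraction
  > 0.15, supporting reads > 3 on *each* strand, identical reads ≤ 5. An
  absent QC field fails its criterion. All thresholds are configurable
  (`QcThresholds`).
* **Hemizygous genotypes**: inside a deletion the locus is haploid and
  callers emit haploid ("1") or homozygous ("1/1") calls; both normalise
  to a single hemizygous-or-hom-alt state. The identical-call exclusion
  removes sites where proband and transmitting parent show the same alt
  allele in that state (the event then cannot distinguish the affected
  child from the unaffected parent); differing alt alleles at one position
  are distinct variants (multi-allelic sites must be decomposed to one ALT
  per record). Hom-ref and uncalled genotypes are both coded missing and
  contribute no event for that carrier.
* **Transmitting parent** resolution uses the CNV table's inheritance
  field; a deletion whose inheritance is de novo or unknown, or whose
  implicated parent has no genotype data, is skipped with a logged
  warning, never guessed. The non-transmitting parent of a trio is never a
  carrier source.
* **Overlapping covered genes**: a variant site yields at most one event
  per carrier per deletion and is attributed to the first covering gene by
  start coordinate, so pooled counts never double-count a variant.
* **Priority score**: each of the six features (inherited deletion count,
  brain-relevant inherited deletion count, inherited proportion among
  deletions, and the duplication analogues) is ranked across families
  (larger value → larger rank, mid-rank for ties) and combined with weight
  2 on deletion terms and 1 on duplication terms. The preference for fewer
  de novo CNVs is a separate ascending sort key applied before the score,
  since the score formula itself has no de novo term. The inherited
  proportion is defined as 0 when a family has no CNV of that type. The
  feature set and weights are arguments, so alternative readings of the
  score can be swapped in.
* **Deleteriousness filters**: CADD-10 passes scaled score ≥ 10,
  inclusive — the scaled score is a genome-wide rank, so ≥10 selects the
  top 10% of possible variants; protein-altering passes the missense,
  missense-plus-splice-region, and splice-region-in-intron consequence
  categories. The consequence vocabulary is closed (nine categories plus
  `other`); SnpEff-style tokens map through a configurable dialect table
  because upstream annotation pipelines differ in their exact strings.

## Synthetic cohort generator

The generator emulates the study conditions as its defaults: 149 families
with 47 trios and 102 pairs; one inherited heterozygous deletion per
family (configurable), log-uniform 10–500 kb; zero-truncated Poisson gene
counts with the underlying rate solved so the truncated mean equals 3.08
brain-relevant genes per deletion; per-gene parent variant rate
41/(149·3.08) ≈ 0.089 and a proband rate-ratio multiplier defaulting to
68/41, so the expected pooled counts at the defaults are ~68 vs ~41;
consequence categories drawn from the empirical distribution of the 109
published variants; scaled CADD scores Exponential(ln 10/10), which makes
P(score ≥ 10) = 0.10 exactly and the CADD-10 filter's selectivity
analytically known. Variants are placed uniformly within the relevant gene
region; a configurable fraction is directed to the in-gene-outside-
deletion region to produce scenario-2 events, falling back to inside
placement when a gene lies wholly within the deletion (so the realised
scenario-2 share is at most the configured fraction). In-deletion variants
are emitted hemizygous/homozygous-alt; all QC metrics are drawn strictly
above the default thresholds. The truth record (never read by the
pipeline) makes detection scoring exact.

What the generator does **not** model — and what passing tests therefore
do not show about real data: genotyping error and threshold-straddling QC
metrics; linkage and allele-frequency structure; within-family clustering
of events (events are spread Poisson-wise across families, so at matched
pooled counts the synthetic cohort has more carriers than the study's 20
probands / 16 parents); duplications and de novo CNVs (present in the
prioritization logic, absent from the default cohort); multi-deletion
families (supported but off by default, as the per-family deleted gene
set analysis does not specify multi-deletion handling); and shared
variants between overlapping genes.

Deletion sizes, gene lengths, and the genomic layout (one locus per
family, 20 Mb apart across 22 chromosome labels) are conventions chosen
for realism at desk scale, not estimates.

## Numerical choices

* Rank ties use average (mid) ranks — standard and deterministic.
* The chi-square is computed by `scipy.stats.chisquare`; p-values are kept
  at full precision and rounded only for display.
* The logistic fit is Newton-based ML; the test suite cross-checks it
  against an independent BFGS minimisation of the negative log-likelihood.
* Floating-point fields round-tripped through VCF pass through htslib's
  single precision; readers report 6 significant digits so write-then-read
  is exact for values written with up to 6 significant digits.
* CADD score lookups signal absence (`None`/`KeyError`), never 0, and
  duplicate table keys keep the last entry with a warning.
* Two-zero-count input to the count test, empty family lists, NaN
  features, and single-label burden inputs raise immediately rather than
  propagating degenerate values.

## Problem sizes used in validation

Replicate-based checks run at sizes chosen to keep the full suite fast on
one core while leaving Monte-Carlo error well inside the asserted bands:
200 cohort replicates for the enrichment calibration, 100 replicates of
n = 400 for burden-test coverage, 2000 null splits for the count-test
type-I error, and 100,000 draws for the CADD-10 selectivity check.

## Known limitations

* The carriers-only vs full-sample burden results depend on the carrier
  distribution across individuals, which the generator reproduces only in
  rate, not in clustering (see above); published per-individual CADD sums
  are not public, so the burden test is validated by recovery properties
  (planted-β coverage) rather than by numeric reproduction.
* The exact subscripts of the published priority-score formula are
  ambiguous; the implemented reading (counts of inherited CNVs, counts
  involving brain-relevant genes, inherited proportions) follows the
  surrounding prose and is configurable, not asserted as the only reading.
* The parent carrier percentage has an ambiguous denominator in the source
  (transmitting parents vs all genotyped parents); the summary reports raw
  counts and takes the denominator as a parameter.
* Consequence annotation and CADD scoring are consumed as inputs; the
  package neither re-annotates variants nor computes CADD scores, and
  brain-relevance and segmental-duplication flags are trusted as given.
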