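# Methods

This note documents the statistical procedures, the conventions that make
them reproducible, and the design choices taken where the problem was
genuinely open.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinates and interval semantics

All internal coordinates are 1-based with both endpoints inclusive
(`length = end − start + 1`), matching array-probe CNV tables; BED is the
only 0-based, half-open surface and is converted at the I/O boundary
(`internal_start = bed_start + 1`, `internal_end = bed_end`).  Chromosome
labels are normalized by stripping a leading `chr` (re-added only on BED
output).  Overlap between two segments is directional by default — shared
bases divided by the *query* segment's length — with reciprocal overlap
(minimum of the two directions) available everywhere as a config option.
Having exactly one convention in memory eliminates off-by-one drift; the
round-trip tests (`internal → BED → internal` is the identity) pin it down.

## Two-caller consensus merge

A consensus CNV requires one call from each caller, same sample, same
copy-state direction, with the overlap fraction of the caller-A segment at
least 0.5.  The merged segment keeps the outer envelope of the two source
calls, the maximum probe count, and the caller-B integer copy number
(caller B plays the Birdsuite role of reporting total copies; caller A the
GTC role of anchoring 5-probe segments).  Merged segments shorter than
20 kb or with fewer than 5 probes are discarded; caller-B calls below
confidence 10.0 are pre-filtered.  Matching is one-to-one and greedy by
descending overlap with leftmost-start tie-breaking; multi-way merges are
not attempted, and the greedy matching is verified against an exhaustive
maximum-total-overlap search on small random instances.

Whether the published 50–100% criterion was directional or reciprocal is not
derivable from its description; the directional reading (anchored on the
caller-A segment) is the default and the reciprocal mode is one flag away.

Common CNP loci get a population normal state: the mean copy number over all
individuals rounded half away from zero.  A population whose typical copy
number at a locus is 3 therefore flags only departures from 3.  Rare and
de novo calls are compared to the fixed reference instead (autosomes 2;
X: male 1 / female 2; Y: male 1 / female 0).

## Sample QC

Samples whose call count strictly exceeds `mean + 3·sd` are excluded; the
standard deviation uses the n−1 denominator (the convention is recorded in
the report), and boundary samples are retained because "above" is read
strictly.  The ancestry filter takes precomputed 2-D principal-component
coordinates (PC computation is out of scope) and removes samples outside
the ellipse `Σ((xᵢ − cᵢ)/(10·sdᵢ))² ≤ 1`; the rule is invariant under a
joint rescaling of points, center, and axis SDs.

## Burden and pooled association

Burden metrics (segments/sample, mean segment size, genes intersected —
each gene counted once per sample — and deletion/duplication counts) are
compared between affected and unaffected individuals with a two-sided
permutation test that shuffles phenotype labels only **within** families,
preserving each family's affected count exactly.  No distributional
assumptions are made; p-values use the add-one estimator.

Pools are the connected components of the ≥1 bp overlap graph (computed by a
per-chromosome sweep; verified against a union–find oracle).  Pool
association fits

    y_ij ~ Bernoulli(logit⁻¹(β₀ + β₁·carrier_ij + u_i)),  u_i ~ N(0, σ²)

by maximizing the marginal likelihood, integrating each family's random
intercept with 25-node Gauss–Hermite quadrature (the quadrature is checked
against direct `scipy.integrate.quad` integration, and the σ → 0 limit
against a plain logistic fit).  σ is optimized on [0, 10] by L-BFGS-B; Wald
standard errors come from the finite-difference Hessian over the fixed
effects with σ held at its estimate (the full Hessian is singular when σ̂
sits on the zero boundary).  A fit counts as converged when the optimizer
succeeds, estimates are finite, |β₁| < 15 (a separation guard), and the
Hessian is positive definite; otherwise the pool falls back to the one-sided
Fisher exact test on the carrier × phenotype table (upper hypergeometric
tail, carriers enriched in affecteds).  A likelihood-ratio test is available
behind a flag; Wald is the default since the original analysis does not name
its test.  Carrier status is coded 0/1 per model (duplication, deletion,
either); raw copy-number coding is a config option because "number of
copies as a fixed effect" admits both readings.

In the external-control contrast there is no family structure on the control
side, so the family random effect is replaced by the first two PC
coordinates as fixed covariates in an ordinary logistic regression
(statsmodels), with the same Fisher fallback.

Bonferroni columns report both the per-pool denominator and the
pools × models denominator, since the published test count of 535 does not
say which convention was used.  The Wald p-value of the mixed model is
slightly conservative in small cohorts (a few hundred samples); its null
tail fraction reaches the nominal 0.05 ± 0.02 band at cohort sizes around
600, which is where the tail-calibration test operates, while uniformity
(KS) holds already at 200.

## Rarity filter chain

Fixed stage order: unaffected-cohort uniqueness → control-cohort
uniqueness → segmental duplications → known common variants → family
consistency.  Uniqueness keeps a CNV whose overlap with every same-state
comparison CNV is ≤50% (the published wording "50% or less … regarded as
unique"); segdup removal triggers at ≥50% coverage of the CNV by the
*union* of segdup records; common-variant removal triggers at ≥50% coverage
by any *single* known record — the frequency criterion ("more than 0.01%")
is implemented through its stated operationalization, one database record at
≥50% overlap, because a desk artifact cannot know true population
frequencies.  The exact-50% point therefore behaves differently across
stages (kept by uniqueness, removed by segdup/common/family); this asymmetry
follows the stated definitions and is deliberately preserved and tested.
All comparisons are state-stratified (loss vs loss, gain vs gain): the
distinct duplication/deletion association models imply state matters, and a
deletion is not evidence against a duplication's rarity.

Sex-chromosomal calls use stricter any-overlap uniqueness, reflecting their
much higher false-call rate.  The family stage removes CNVs mirrored
(≥50%, same state) in unaffected relatives and groups surviving CNVs shared
among affected relatives into familial events by overlap closure.  Each
removed CNV is attributed to exactly one stage; segdup and common stages
commute (asserted on random instances), and adding comparison records can
only shrink the kept set (monotonicity).

## Transmission classification

A parent carries an offspring's CNV when any same-state parental call
overlaps ≥50% **of the offspring's CNV** — the offspring denominator is
deliberate because boundary jitter inflates parental envelopes.  Both
parents genotyped and neither carrying ⇒ de novo; exactly one carrier ⇒
inherited from that parent; both ⇒ either; an ungenotyped parent with no
genotyped carrier ⇒ unknown.  Parental evidence may include raw
single-caller calls alongside merged consensus calls: stringent-in-proband /
lenient-in-parents is the standard convention for asserting de novo events
and keeps the reported rate a conservative minimum (a parent call missed by
one caller cannot masquerade as a de novo transmission).  The de novo rate
is reported per trio per generation, stratified by offspring phenotype; the
denominator definition is printed because per-trio, per-call, and
per-transmission-opportunity rates are not interchangeable.

## Gene prioritization

Rank fusion: each evidence source ranks the candidate genes (mid-ranks on
ties); rank ratios `r = rank/N` are combined into
`Q = k!·V_k`, `V_0 = 1`,
`V_i = Σ_{j=1..i} (−1)^{j−1} (V_{i−j}/j!) r_{k−i+1}^j` — the joint
cumulative probability that k iid uniforms have their order statistics below
the observed ratios (verified against large Monte-Carlo simulation; Q is
monotone in every ratio).  Q is converted to an empirical p against a seeded
null of k iid uniform ratio vectors, with a calibration floor of 1,000
draws.  The trained data sources of the original web service are not
reproducible; user-supplied score tables stand in for them while the fusion
mathematics is implemented faithfully.

SAGE fold enrichment uses pseudocount-stabilized tags-per-million,
`tpm = 10⁶(tags+1)/(library+1)`, and the outflow-tract tpm over the **mean**
of atrium and ventricle tpms ("versus the atria and ventricles" read as a
joint comparator; max-of-the-two available).  The pseudocount keeps
zero-tag genes finite at fold 1 and has negligible effect at library sizes
≥10⁴ (scale invariance is asserted there).  The threshold is ≥3-fold,
inclusive.

A gene is a candidate when at least two of {fusion p < 0.05, fold ≥ 3,
curated expression flag +} hold; absent evidence is not positive.  When an
expected verdict accompanies the inputs, contradictions are flagged rather
than silently matched.  Expression flags are curated inputs, mirroring
visual database inspection, and are never computed.

The gene-set enrichment test regresses affection on the per-sample count of
set genes intersected by that sample's CNVs, with the sample's total call
count and total genic span (Mb) as covariates, and converts the
coefficient's z-statistic into an empirical one-sided p over within-family
phenotype permutations.  It runs over all CNVs and again restricted to
genic CNVs.  The internal IRLS logistic solver (with a tiny ridge guard) is
used because tens of thousands of refits inside the permutation loop make
library model objects impractical; it is cross-checked against statsmodels
in the test suite via the shared null-calibration behaviour.

## Synthetic cohorts

The generator emulates the study conditions of a multiplex-family CNV
screen: 60 three-generation families (~7.6 members each, ~460 individuals),
an affected fraction targeted at 0.375, 50 common CNP loci whose allele
frequencies are rescaled so the expected consensus call count is 15 per
sample (matching the ~15 autosomal CNVs per individual such arrays yield),
5 planted causal CNVs (one per selected family), a de novo probability of
0.02 per offspring (the reported trio rates are ~0.02), 10
segmental-duplication regions spawning 10 caller-correlated artifact calls
in affected samples, uncorrelated false positives at 1 per sample per
caller, a 2% per-caller false-negative rate, boundary jitter of ±10% of
segment length per end, and 200 unrelated controls drawn from the same CNP
frequencies (the real control cohort was ~8× larger; the scale here keeps a
full run in seconds while leaving every filter stage exercised).

Causal penetrance defaults to 1.0: the filter chain *by construction*
removes variants carried by unaffected relatives, so fully penetrant
planted variants are the regime in which recovery is a meaningful
correctness check; reduced penetrance is available as a config knob and
moves carriers into unaffecteds, where the family stage removes them — that
is the documented behaviour of the design, not a failure.  Phenotypes
follow a two-parameter model (penetrance for causal carriers, background
prevalence for everyone else, the latter solved to hit the cohort target
fraction) — the simplest model expressing reduced penetrance and
phenocopies.

The genome is abstract: 22 chromosomes of 100 Mb with uniformly placed,
non-overlapping loci.  Tests need controlled geometry (who overlaps whom,
and by how much), not human coordinates; no liftover or real-genome
annotation is attempted.  CNP alleles drift through pedigrees by Mendelian
allele dropping; causal variants seed a founder and are forced through the
reproducing lineage so every planted event is multiplex.  Every simulated
call is attributable to exactly one truth source (causal, CNP, de novo,
artifact, or caller false positive), which is what makes end-to-end
planted-truth evaluation exact.

What the generator does *not* emulate: linkage disequilibrium, array
intensity noise (jitter and miss rates stand in for it), locus-specific
mutation rates, population stratification within the cohort, and genuinely
incomplete phenotyping.  Passing the end-to-end tests therefore shows the
pipeline's logic is correct under realistic call-level noise — it does not
certify performance on real array data, where boundary error is not uniform
and artifact calls are not so cleanly confined to segmental duplications.
Note one deliberate stress choice: artifact calls are assigned to affected
samples (the worst case for the filter chain), which inflates the raw
de novo rate of affected trios in the default cohort until the segdup stage
removes those calls; the artifact-free parameter-recovery configuration is
the one that estimates the planted de novo probability.

## Numerical choices and degenerate inputs

Percentages in reports are rounded half away from zero (one decimal), the
convention of the published tables.  The CNP normal state rounds half away
from zero.  Quadrature uses 25 Hermite nodes (error well below the
optimizer's tolerance for family sizes in the tens).  Permutation p-values
use `(1 + exceedances)/(n + 1)`.  Degenerate cases are defined, not
accidental: an all-carrier pool falls back to Fisher with p = 1; empty
known-variant tracks keep everything; a sample with no calls contributes
zeros to burden counts and is excluded only from the mean-segment-size
metric; zero-tag SAGE genes give fold 1 via the pseudocount.

## Known limitations

Half-sib and avuncular relations require explicit founder placeholder
records in the PED file; individual ids must be unique across families.
The mixed model supports family-level random intercepts only — kinship
matrices within families are out of scope.  Exact conditional logistic
regression is not implemented.  The Fisher fallback is one-sided toward
enrichment in affecteds, so protective pools reaching the fallback path are
not flagged.  The per-trio de novo rate is not comparable across studies
that use per-call or per-opportunity denominators.
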