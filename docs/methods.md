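# Methods

## Scoring model

For individual *s* and p-value threshold *T*, the raw score is

    raw(s, T) = Σ over SNPs i with pᵢ ≤ T of βᵢ · Gᵢₛ

with βᵢ the discovery weight on the additive scale (the natural log of the
odds ratio for binary traits; betas pass through unchanged) and

    Gᵢₛ = 2·p(hom effect) + p(het)

the expected effect-allele dosage from the genotype probability triple.
Probability triples are taken as read: a sum in (0, 1) represents genuine
imputation uncertainty and is **not** renormalized (a sum above 1 + 1e−6 is
a malformed input). A triple summing to (numerically) zero marks a missing
genotype; it contributes nothing and is not counted. Hard calls are the
degenerate special case with one component equal to 1, in which the dosage
reduces exactly to the allele count G ∈ {0, 1, 2}.

The reported score is `raw(s, T) / count(s, T)` where the count is that
individual's own number of scored, non-missing SNPs at *T* — individuals
can differ in call rate, so a per-sample divisor keeps scores comparable.
A zero count yields a missing value (NA), never 0: no score is not a score
of zero.

Threshold inclusion is closed (pᵢ ≤ T). All thresholds are computed in a
single pass: a SNP is added to the bucket of its smallest qualifying
threshold, and buckets are cumulatively summed afterwards. Contributions
accumulate in stream order, so runs are bit-for-bit reproducible, and
partial tables computed on any chunking of the stream merge to the same
result up to float-addition reordering (≪ 1e−12 at these magnitudes). This
streaming contract is what makes the engine safe to parallelize or to run
on data that does not fit in memory.

## Effect-allele reconciliation

Non-ambiguous SNPs: the effect allele (and, when available, the other
allele) must equal target allele 1 or allele 2 directly; failing that, the
comparison is retried against the reverse complement of the target pair,
which handles opposite-strand reporting. Any remaining inconsistency
discards the SNP (`ALLELE_MISMATCH`).

Strand-ambiguous SNPs (A/T, C/G) equal their own reverse complement, so the
allele letters carry no positional information and the decision rests
entirely on two frequencies: the discovery effect-allele frequency *d*
(from the summary-statistics table) and the target allele-1 frequency *t*,
estimated as the mean halved expected allele-1 dosage over non-missing
samples. Same side of the exclusion zone → score allele 1; opposite sides →
score allele 2; either frequency inside the zone → discard.

Numerical choices here:

* The exclusion zone is the **closed** interval [0.4, 0.6] and is applied
  to **both** *d* and *t*: a near-0.5 frequency on either side makes the
  assignment unreliable, and misassignment (applying the weight to the
  wrong allele) is exactly the error the rule exists to prevent.
* A missing discovery frequency, or a target frequency undefined because
  every sample is missing, discards the SNP (`MISSING_AF`) rather than
  falling back to letter matching — conservative by design.
* Frequency matching can be disabled (`--no-af-matching`), in which case
  every ambiguous SNP is discarded (`AMBIGUOUS_DISABLED`), the behaviour of
  conventional tools.

Summary-statistics hygiene: rows with non-SNP alleles (indels,
multi-character), non-positive odds ratios, or p-values outside (0, 1] are
dropped and counted, never fatal. An allele-frequency value outside (0, 1)
drops the frequency, not the row. Duplicated rsIDs remove **all** copies:
with two candidate weights there is no right one, and a wrong weight is
worse than a missing SNP.

## Evaluation

Per threshold, the phenotype is regressed on the averaged PRS by ordinary
least squares with an intercept (one predictor; covariates are out of
scope). Samples lacking either a score or a phenotype are dropped pairwise;
fewer than three complete pairs is an error, and a zero-variance PRS yields
a flagged degenerate result. Reported: unadjusted R² (adjusted R² appears
as extra metadata in the report file), the model F statistic on (1, n−2)
degrees of freedom and its two-sided p-value, and the slope sign. The
best-fit threshold maximizes R², ties going to the smaller threshold (fewer
SNPs, the more parsimonious score).

## Synthetic panels

The generator emulates the three input conditions the pipeline targets —
imputed posterior probabilities, hard calls, observed genotypes — with
known ground truth:

* genotypes per SNP: binomial(2, MAF), MAF uniform on `maf_range`
  (default 0.05–0.5); no linkage disequilibrium, no stratification, no
  realistic coordinates;
* weights normal(0, 0.1) on the log-odds scale; p-values uniform(0, 1);
* a configurable fraction of SNPs is strand-ambiguous
  (`prop_ambiguous`, default 0.2) and a configurable fraction of the
  non-ambiguous SNPs is written with both target alleles
  reverse-complemented (`strand_flip_rate`, default 0.1);
* default cohort size 264, the scale of the community cohort this class of
  method is typically demonstrated on; tests and the acceptance script set
  sizes per check (oracle panels ≤ 50 SNPs × 20 samples; recovery panels
  2000 samples × 200 SNPs).

Imputation noise: with probability `imputation_noise` per genotype, the
unit probability mass is replaced by a triple whose mode stays on the true
genotype (mode ≥ 0.55, off-mode mass ≤ 0.45 split randomly between the
other two genotypes). All triples live on a 1/4096 grid, so they are exact
in decimal text, float32 (VCF GP fields) and float64 — the GEN and VCF
readers provably yield bit-identical genotypes for the same panel, and
hard-call conversion (argmax, ties toward the heterozygote) is unambiguous.
This noise model is deliberately simple: it separates probability scoring
from hard-call scoring and preserves a decidable truth, but it does not
emulate LD-informed imputation error structure, so passing tests say
nothing about imputation quality on real data — only about what the scorer
does with whatever probabilities it is given.

The discovery effect-allele frequency written to the synthetic summary
statistics is the frequency realized in the simulated cohort (a monomorphic
realization is written as absent, as a real GWAS would), which makes the
ambiguous-SNP decision exactly decidable from the generated data. The truth
record therefore carries every SNP's correct scored allele, and
`reference_prs` — a deliberately naive per-sample, per-threshold, per-SNP
loop that replays the frequency rule independently — serves as the
comparison oracle for the pipeline everywhere.

Random streams for each aspect (allele pairs, weights, p-values, genotypes,
noise, missingness, flips) are spawned independently from the seed, so
changing one condition (e.g. the flip rate) perturbs nothing else; this is
what makes the flipped/unflipped score-equality check exact.

Phenotypes are simulated as `y = PRS + ε` with the noise variance set to
`var(PRS)·(1−R²)/R²` for a chosen target R². At n = 2000 the fitted-R² bias
(≈ (1−R²)/n) is an order of magnitude below the Monte-Carlo resolution of
100 replicates, so mean recovery within 3 MC standard errors is the
appropriate check. Recovery panels use 200 SNPs with uniform p-values so
that successive thresholds hold materially different SNP sets and best-fit
threshold selection is meaningful.

## Known limitations

* rsID-keyed joining only; no positional matching, liftover, or reference
  panel strand correction.
* No LD clumping — summary statistics are assumed pre-clumped.
* No BGEN or PLINK bed/bim/fam input; no dosage (DS) VCF fields.
* Univariate evaluation only; no covariates, no permutation p-values.
* The frequency rescue assumes comparable allele frequencies between
  discovery and target populations; it should be disabled across cohorts
  with different ancestry.
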