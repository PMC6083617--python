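# polyscore

Polygenic risk scores (PRS) from genotype posterior probabilities, with
allele-frequency rescue of strand-ambiguous SNPs.

A PRS summarizes the additive contribution of many common variants to a
complex trait: given per-SNP weights β₁…βₙ from a discovery genome-wide
association study (GWAS), each individual in a target cohort is scored

    PRS = Σᵢ βᵢ · Gᵢ

where βᵢ is the beta coefficient (or the natural logarithm of the odds
ratio, for binary traits) and Gᵢ is the individual's count of the effect
allele at SNP *i*. Only SNPs whose discovery association p-value falls below
a threshold P_T enter the score, and the interesting P_T is rarely known in
advance, so scores are computed at several thresholds at once.

`polyscore` addresses two places where conventional PRS tools throw
information away:

1. **Imputed genotypes.** Imputation produces a posterior probability for
   each of the three diploid genotypes, not a single call. Instead of
   collapsing these to best-guess "hard calls", `polyscore` uses the
   expected effect-allele dosage directly:

       Gᵢ = 2·p(AAᵢ) + p(ABᵢ)   ∈ [0, 2]

2. **Strand-ambiguous SNPs.** An A/T or C/G polymorphism is its own reverse
   complement, so when discovery and target data may sit on different
   strands, the allele letters cannot identify the effect allele and such
   SNPs are usually discarded. `polyscore` rescues them by comparing the
   discovery effect-allele frequency *d* with the target allele-1 frequency
   *t*: if both are below 0.4 or both above 0.6, target allele 1 is the
   effect allele; if they lie on opposite sides, allele 2 is; if either
   frequency falls inside [0.4, 0.6], the match is too uncertain and the
   SNP is discarded. This presumes comparable population structure in the
   two datasets — do not enable it across cohorts of markedly different
   ancestry.

Scores at each threshold are divided by that individual's scored-SNP count
(missing genotypes are not counted), giving a weighted average that is
comparable across individuals with different call rates.

The single pass over the genotype stream works in bounded memory: each SNP
is routed to the bucket of its smallest qualifying threshold and the buckets
are cumulatively summed at the end, so any chunking of the input produces
identical results.

## Input formats

* **Summary statistics** — delimited text with a header (optionally
  gzipped): rsID, effect allele, other allele, effect size (OR or beta),
  p-value, and optionally the effect-allele frequency. Column names are
  configurable; defaults match PGC-style headers (`SNP A1 A2 OR P FRQ_A`).
* **Target genotypes** — Oxford GEN/SAMPLE (5- or 6-leading-field dialect,
  auto-detected) or VCF, using either GP genotype posteriors or GT hard
  calls. Joining is by rsID.
* **Phenotype** (optional) — two columns: sample id, value.

## Worked example

Simulate a small panel (6 samples × 12 SNPs, imputation noise, ambiguous and
strand-flipped SNPs included) and score it:

```python
from polyscore.simulate import SimConfig, simulate_panel
panel = simulate_panel(SimConfig(n_samples=6, n_snps=12, seed=42,
                                 imputation_noise=0.4, prop_ambiguous=0.3,
                                 strand_flip_rate=0.2))
panel.write_all("example/")
```

```
polyscore --sumstats example/sumstats.txt --geno example/panel.gen \
    --sample example/panel.sample --format gen \
    --effect-beta --effect-col BETA --snp-log --out example/demo
```

```
polyscore: wrote example/demo.scores.txt (10 SNPs scored, 2 discarded)
```

`demo.scores.txt` holds one row per sample with the averaged PRS and the
per-sample SNP count at every threshold (first three thresholds shown):

```
sample_id  PRS_0.1         COUNT_0.1  PRS_0.2         COUNT_0.2  PRS_0.3         COUNT_0.3
S00001     0.06597121255   2          0.06597121255   2          0.06597121255   2
S00002     0.0584405568    2          0.0584405568    2          0.0584405568    2
S00003     0.05050410475   2          0.05050410475   2          0.05050410475   2
```

Here only two SNPs have p ≤ 0.3, so the averages coincide across the first
three thresholds; a positive value means the sample carries, on average,
risk-increasing alleles at the scored SNPs. The run summary
(`demo.summary.txt`) reconciles every SNP: 12 matched, 10 scored, 2
ambiguous SNPs discarded because a frequency fell inside [0.4, 0.6]:

```
matched    12
scored     10
discarded_AMBIGUOUS_AF_ZONE  2
snps_at_0.1  2
...
snps_at_0.5  4
```

The SNP log (`demo.snplog.txt`) records which SNPs entered each threshold's
score and via which target allele column, plus the discards with reasons:

```
PRS_0.1    PRS_0.1_flag  ...  PRS_0.5    PRS_0.5_flag  Discard    Discard_reason
rs1000001  A1            ...  rs1000001  A1            rs1000006  AMBIGUOUS_AF_ZONE
rs1000003  A2            ...  rs1000003  A2            rs1000012  AMBIGUOUS_AF_ZONE
```

With `--pheno`, the phenotype is regressed on each threshold's PRS
(ordinary least squares) and `demo.fit.txt` reports R², F(1, n−2) and its
p-value per threshold, flagging the best-fitting threshold.

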