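# enhscreen

Three-stage prioritization of enhancer variants in case-control GWAS,
built for hepatocellular-carcinoma-style study designs: genotype QC,
additive-model logistic association, a regulatory filter cascade
(cis-eQTL + enhancer histone marks + transcription-factor motif),
same-direction replication, and fixed-effects meta-analysis — together
with a seeded synthetic-cohort generator so the whole pipeline can be
exercised, calibrated, and tested without access-restricted cohort data.

It is aimed at statistical geneticists who want a transparent, tested
re-implementation of this screening design, and at methodologists who
need a generative model matching its assumptions.

## The statistics

For each biallelic variant with effect-allele dosage `g ∈ {0,1,2}`:

- **QC**: MAF = min(q, 1−q) with q the coded-allele frequency; exact HWE
  test (conditional on allele counts, two-sided "as or less probable"
  summation, computed in controls); variants with MAF < 0.05 or
  HWE P < 1e-4 are removed.
- **Association**: `logit P(case) = β₀ + β·g + β_sex·male + β_age·age`,
  Wald test, OR = e^β, 95% CI = exp(β ± 1.96·se). Discovery retains
  P < 0.001; a replication passes iff P < 0.05 with the same direction of
  effect after allele harmonization.
- **Regulatory screen**: candidate iff significantly associated AND
  cis-eQTL (OLS of expression on dosage, TSS within ±1 Mb, BH-FDR ≤ 0.05)
  AND inside both H3K4me1 and H3K27ac intervals AND inside a TF-motif
  interval.
- **Meta-analysis**: Mantel-Haenszel pooled OR over per-cohort 2×2
  allele-count tables, `OR_MH = Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ)`, with
  Robins-Breslow-Greenland CI and MH chi-square P; inverse-variance
  pooling of adjusted log ORs reported alongside; Cochran's Q / I²;
  joint significance against a Bonferroni threshold α/m.
- **Motif scan**: exact fixed-string matching (e.g. the palindromic E-box
  CAGCTG) on both strands with palindrome deduplication.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole story on a synthetic
five-cohort study (4898 cases / 7060 controls, one planted risk variant
with per-allele OR 1.41 among 50 null variants):

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_run_pipeline.py
```

prints

```
QC: removed 2 variants
discovery: 1 variants at P < 0.001
screen: candidates = ['rs_planted']
final jointly significant candidates: ['rs_planted']
  rs_planted: MH OR = 1.500 (95% CI 1.415-1.591), P = 4.13e-42, I2 = 18.7%
  rs_planted: IV OR = 1.501 (95% CI 1.413-1.593), P = 2.33e-40
joint threshold: 0.00102
```

i.e. the two variants planted to fail QC are removed (one rare, one
violating HWE), only the planted risk variant survives the association
threshold and the four-criterion regulatory screen, it replicates with
the same direction in all four later cohorts, and its pooled odds ratio
(here 1.50 for this particular simulated study; the truth is 1.41)
is jointly significant far below the Bonferroni threshold.

```bash
python analysis/03_pooled_or_recovery.py --seed 1 --replicates 200
```

prints

```
inverse-variance: mean pooled OR = 1.4021 (truth 1.41), mean log OR = 0.3380 (truth 0.3436, MC SE 0.0021), coverage = 93.5%
Mantel-Haenszel: mean pooled OR = 1.3921 (truth 1.41), mean log OR = 0.3308 (truth 0.3436, MC SE 0.0020), coverage = 92.5%
```

— the five-cohort design recovers the planted per-allele odds ratio with
near-nominal 95% CI coverage. `analysis/04_promoter_motifs.py` scans the
simulated promoters for CAGCTG (counts 3, 0, 1 by construction) and shows
genotype-stratified Spearman co-expression.

The same functionality is available as a CLI
(`enhscreen simulate|qc|assoc|scan-motif|replicate|meta|run`), e.g.

```bash
enhscreen simulate --out study --seed 7
enhscreen run --config study/pipeline.yaml
```

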