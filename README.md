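# adburden

Multi-stage rare-variant gene burden association testing for cohorts with an
ordered case severity structure, modeled on large Alzheimer's disease (AD)
exome-sequencing case-control studies in which early-onset cases (EOAD,
onset ≤ 65 y) carry a heavier burden of damaging rare variants than
late-onset cases (LOAD), who in turn carry more than controls.

The package is aimed at statistical geneticists who want a tested, scriptable
implementation of this design — either to run on their own called and
annotated exome data (VCF + annotation/phenotype TSVs) or to study its
operating characteristics on synthetic cohorts generated by the built-in
simulator.

## The model

For each gene, variants are prioritized into four nested deleteriousness
tiers: high-confidence loss-of-function (LOF) only, and LOF plus missense
variants with REVEL score ≥ 75, ≥ 50 and ≥ 25 (REVEL on a 0–100 scale).
Qualifying variants must be rare (MAF < 1% in the sample *and* a reference
panel; a very-rare sub-analysis uses < 0.1%), have ≥ 1 carrier, and pass
missingness (> 20% of calls at read depth < 6, or differential missingness
across outcome groups, drops the variant) and Hardy–Weinberg QC. A
gene × tier selection is testable when its cumulative minor allele count
(cMAC) — the rounded sum of expected dosages — is at least 10.

The burden test is a proportional-odds ordinal logistic regression on the
outcome control < LOAD < EOAD:

    P(Y ≥ k | x) = logistic(βs + γᵀc − θ_k),   k = 1, 2

where `s` is the per-sample sum of qualifying allele dosages, `c` are six
population covariates and β > 0 is risk-increasing. Significance comes from
a 1-df likelihood-ratio test. Because genotypes are uncertain, each test is
run `n_reps` times (default 25) on genotypes sampled independently from the
per-call posterior triples (missing calls drawn from the Hardy–Weinberg
prior at the variant's sample MAF), and the arithmetic mean of the
per-repetition P values is reported.

Inference is two-stage: Benjamini–Hochberg FDR < 0.1 over all discovery
tests, one-sided confirmation (α = 0.05) in the discovery direction,
fixed-effect inverse-variance meta-analysis of the stage effects (with
Cochran's Q heterogeneity), and a Holm–Bonferroni familywise gate at 0.05
over the full discovery test count. Companion estimators include
multinomial per-onset-bin odds ratios (≤65, 65–70, 70–80, >80 vs controls),
Firth logistic regression (finite under separation), carrier frequencies,
attributable fractions AF = CF·(OR − 1)/OR, a genomic-inflation diagnostic
λ, a multinomial-allocation power simulator, and sensitivity analyses
(age-matched propensity weighting, APOE-ε4 interaction LRT, allelic-balance
screening, per-variant Fisher validation/refinement of selections).

## Worked example

Simulate a cohort with one risk gene (allele odds ratios 6.0 in EOAD and 2.5
in LOAD) and one null gene, then test both:

```python
import numpy as np
from adburden import (GeneSimSpec, SimConfig, simulate_cohort,
                      averaged_burden_test, build_selection,
                      DeleteriousnessThreshold)

cfg = SimConfig(
    n_eoad=300, n_load=300, n_control=300,
    genes=[GeneSimSpec("RISK1", n_variants=8, maf_range=(0.002, 0.01),
                       or_eoad=6.0, or_load=2.5),
           GeneSimSpec("NULL1", n_variants=8, maf_range=(0.002, 0.01))],
    seed=13)
geno, pheno, ann = simulate_cohort(cfg)

for gene in ("RISK1", "NULL1"):
    sel = build_selection(gene, DeleteriousnessThreshold.LOF_REVEL25,
                          ann, geno)
    res = averaged_burden_test(geno, sel, pheno, n_reps=25, rng=1)
    print(f"{gene}: cMAC={sel.cmac} p_avg={res.p_avg:.3g} "
          f"beta={res.beta_avg:.2f} carriers={res.carriers}")
```

Output:

```
RISK1: cMAC=66 p_avg=3.8e-07 beta=1.24 carriers={'EOAD': 39, 'LOAD': 19, 'control': 6}
NULL1: cMAC=48 p_avg=0.54 beta=0.17 carriers={'EOAD': 18, 'LOAD': 15, 'control': 14}
```

The enriched gene shows the expected EOAD > LOAD > control carrier gradient
and a strongly positive burden coefficient (log-odds 1.25 per allele); the
null gene is flat. The same pipeline is available from the shell
(`adburden simulate | prioritize | burden | two-stage | targeted |
descriptives | power | sensitivity | report`), with every run writing TSV
outputs plus a JSON manifest (config hash, seed, version).

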