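"""Synthetic cohort generation.

The generator emulates the statistical structure the burden pipeline
assumes, retrospectively (case-control): three ordered phenotype classes
(control < late-onset case < early-onset case) at fixed group sizes, rare
variants whose allele totals are binomial at a population MAF and whose
alleles are allocated to the outcome groups with multinomial probabilities
proportional to (n_eoad * OR_eoad, n_load * OR_load, n_control), genotype
uncertainty from finite Poisson read depth with sequencing error, per-site
missingness at depth < 6, population covariates and APOE-e4 dosages.

Cohorts serialize to VCF v4.2 (GT/DP/AD/PL) plus phenotype and annotation
TSVs and round-trip through :func:`write_cohort` / :func:`read_cohort`
within PL quantization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom, truncnorm

from .containers import ANNOTATION_COLUMNS, GenotypeData

__all__ = [
    "GeneSimSpec",
    "SimConfig",
    "simulate_cohort",
    "simulate_read_support",
    "write_cohort",
    "read_cohort",
    "stage1_config",
]

DEPTH_MISSING = 6  # calls below this depth are treated as missing
PL_CAP = 255

# discovery-stage cohort composition used as a preset
STAGE1_SIZES = {"n_eoad": 4060, "n_load": 8592, "n_control": 8693}


@dataclass
class GeneSimSpec:
    """Simulation recipe for one gene.

    ``maf_range`` bounds the per-variant population MAF sampler
    (log-uniform); ``revel_scores``/``lof_flags`` may be given explicitly or
    are drawn (REVEL uniform on [0, 100], LOF flags Bernoulli(lof_fraction)).
    ``or_eoad``/``or_load`` control the enrichment of this gene's alleles in
    the two case groups relative to controls.
    """

    gene_id: str
    n_variants: int = 10
    maf_range: tuple = (1e-4, 0.01)
    revel_scores: np.ndarray | None = None
    lof_flags: np.ndarray | None = None
    lof_fraction: float = 0.2
    or_eoad: float = 1.0
    or_load: float = 1.0

    def __post_init__(self):
        if self.or_eoad <= 0 or self.or_load <= 0:
            raise ValueError("odds ratios must be positive")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("MAF range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimConfig:
    n_eoad: int = 1000
    n_load: int = 1000
    n_control: int = 1000
    genes: list = field(default_factory=list)
    n_covariates: int = 6
    seed: int = 0
    depth_mean: float = 40.0
    base_error: float = 0.01
    missing_depth_rate: float = 0.02
    covariate_shift: tuple = (0.0, 0.0, 0.0)  # EOAD/LOAD/control cov1 means
    # onset/age distributions: (mean, sd); EOAD truncated above at 65,
    # LOAD truncated below at 65
    eoad_onset: tuple = (58.0, 5.0)
    load_onset: tuple = (75.0, 6.0)
    control_age: tuple = (70.0, 8.0)
    # APOE-e4 allele frequency per group (EOAD, LOAD, control)
    apoe4_freq: tuple = (0.35, 0.30, 0.14)
    prior: str = "hwe"  # genotype prior for posteriors: hwe | uniform

    def __post_init__(self):
        if min(self.n_eoad, self.n_load, self.n_control) < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must lie in (0, 0.5)")
        if not 0 <= self.missing_depth_rate <= 1:
            raise ValueError("missing_depth_rate must lie in [0, 1]")
        for g in self.genes:
            if g.or_eoad != 1.0 and self.n_eoad == 0:
                raise ValueError("nonzero EOAD odds ratio with empty group")
            if g.or_load != 1.0 and self.n_load == 0:
                raise ValueError("nonzero LOAD odds ratio with empty group")


def stage1_config(genes=None, seed: int = 0, **kwargs) -> SimConfig:
    """Preset with the discovery-stage group sizes (4,060 EOAD / 8,592 LOAD
    / 8,693 control)."""
    return SimConfig(genes=list(genes or []), seed=seed, **STAGE1_SIZES, **kwargs)


def _truncnorm_rvs(mean, sd, lower, upper, size, rng):
    a = (lower - mean) / sd if lower is not None else -np.inf
    b = (upper - mean) / sd if upper is not None else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _genotype_prior(maf: float, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.full(3, 1.0 / 3.0)
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def simulate_read_support(
    true_genotype: int,
    depth: int,
    error: float,
    rng,
    prior: np.ndarray | None = None,
):
    """Read support and genotype posterior for one call.

    Alt reads are binomial with success fraction error, 0.5 or 1 - error by
    genotype; the posterior is the binomial likelihood times the genotype
    prior, normalized.  Depth below the calling threshold flags the call
    missing and returns the prior as posterior.
    """
    if not 0 < error < 0.5:
        raise ValueError("error must lie in (0, 0.5)")
    if prior is None:
        prior = np.full(3, 1.0 / 3.0)
    fractions = np.array([error, 0.5, 1.0 - error])
    alt = int(rng.binomial(depth, fractions[true_genotype])) if depth else 0
    missing = depth < DEPTH_MISSING
    if missing:
        post = prior / prior.sum()
    else:
        lik = binom.pmf(alt, depth, fractions)
        post = lik * prior
        post /= post.sum()
    return depth, (depth - alt, alt), post, missing


def _read_support_matrix(true_geno, cfg: SimConfig, priors, rng):
    """Vectorized read simulation for an (n_samples, n_variants) genotype
    matrix; ``priors`` is (n_variants, 3)."""
    n, m = true_geno.shape
    depth = rng.poisson(cfg.depth_mean, size=(n, m))
    forced = rng.random((n, m)) < cfg.missing_depth_rate
    depth[forced] = rng.integers(0, DEPTH_MISSING, size=int(forced.sum()))
    fractions = np.array([cfg.base_error, 0.5, 1.0 - cfg.base_error])
    alt = rng.binomial(depth, fractions[true_geno])
    missing = depth < DEPTH_MISSING

    # binomial log-likelihood of the read pair under each genotype
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = alt[..., None] * np.log(fractions) + (
            depth - alt
        )[..., None] * np.log1p(-fractions)
    loglik += np.log(priors)[None, :, :]
    loglik -= loglik.max(axis=-1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=-1, keepdims=True)
    post[missing] = np.broadcast_to(priors[None, :, :], post.shape)[missing]
    ad = np.stack([depth - alt, alt], axis=-1)
    return depth, ad, post, missing


def _allocate_gene_alleles(total, sizes, ors, rng):
    """Multinomial allocation of one variant's alleles to the groups, capped
    at each group's chromosome count."""
    weights = np.array(
        [sizes[0] * ors[0], sizes[1] * ors[1], sizes[2] * 1.0], float
    )
    weights = np.where(np.array(sizes) > 0, weights, 0.0)
    if weights.sum() == 0 or total == 0:
        return np.zeros(3, dtype=int)
    probs = weights / weights.sum()
    caps = 2 * np.asarray(sizes)
    for attempt in range(100):
        counts = rng.multinomial(total, probs)
        if np.all(counts <= caps):
            if attempt:
                warnings.warn("allele allocation exceeded group capacity; "
                              "reallocated")
            return counts
    return np.minimum(rng.multinomial(total, probs), caps)


def _drop_alleles(n_alleles, n_samples, rng):
    """Dosage vector from placing alleles on distinct chromosomes."""
    dose = np.zeros(n_samples, dtype=np.int64)
    if n_alleles == 0 or n_samples == 0:
        return dose
    chroms = rng.choice(2 * n_samples, size=n_alleles, replace=False)
    np.add.at(dose, chroms // 2, 1)
    return dose


def simulate_cohort(config: SimConfig):
    """Generate (GenotypeData, phenotype table, annotation table).

    Deterministic given ``config.seed``.  True hard genotypes are recorded
    in the returned genotype object's ``true_genotypes`` attribute before
    read noise is applied.
    """
    rng = np.random.default_rng(config.seed)
    n_e, n_l, n_c = config.n_eoad, config.n_load, config.n_control
    n = n_e + n_l + n_c
    status = np.array(["EOAD"] * n_e + ["LOAD"] * n_l + ["control"] * n_c)
    outcome = np.array([2] * n_e + [1] * n_l + [0] * n_c)

    ages = np.empty(n)
    ages[:n_e] = _truncnorm_rvs(*config.eoad_onset, 30.0, 65.0, n_e, rng)
    ages[n_e:n_e + n_l] = _truncnorm_rvs(
        *config.load_onset, 65.0, None, n_l, rng
    )
    ages[n_e + n_l:] = _truncnorm_rvs(*config.control_age, 40.0, None, n_c, rng)

    covs = rng.standard_normal((n, config.n_covariates))
    if any(config.covariate_shift) and config.n_covariates:
        shift = np.concatenate(
            [
                np.full(n_e, config.covariate_shift[0]),
                np.full(n_l, config.covariate_shift[1]),
                np.full(n_c, config.covariate_shift[2]),
            ]
        )
        covs[:, 0] += shift

    apoe_freq = np.concatenate(
        [
            np.full(n_e, config.apoe4_freq[0]),
            np.full(n_l, config.apoe4_freq[1]),
            np.full(n_c, config.apoe4_freq[2]),
        ]
    )
    apoe = rng.binomial(2, apoe_freq)

    pheno = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "status": status,
            "outcome": outcome,
            "age_or_onset": np.round(ages, 1),
            "apoe4_dosage": apoe,
            "apoe_ascertained": False,
        }
    )
    for j in range(config.n_covariates):
        pheno[f"cov{j + 1}"] = covs[:, j]

    ann_rows = []
    true_cols = []
    priors = []
    pos = 1000
    sizes = (n_e, n_l, n_c)
    for spec in config.genes:
        m = spec.n_variants
        lo, hi = spec.maf_range
        mafs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        revel = (
            np.asarray(spec.revel_scores, float)
            if spec.revel_scores is not None
            else np.round(rng.uniform(0, 100, size=m), 1)
        )
        lof = (
            np.asarray(spec.lof_flags, bool)
            if spec.lof_flags is not None
            else rng.random(m) < spec.lof_fraction
        )
        for v in range(m):
            total = int(rng.binomial(2 * n, mafs[v]))
            alloc = _allocate_gene_alleles(
                total, sizes, (spec.or_eoad, spec.or_load), rng
            )
            dose = np.concatenate(
                [
                    _drop_alleles(alloc[0], n_e, rng),
                    _drop_alleles(alloc[1], n_l, rng),
                    _drop_alleles(alloc[2], n_c, rng),
                ]
            )
            true_cols.append(dose)
            maf_internal = dose.sum() / (2 * n)
            pos += int(rng.integers(50, 500))
            vid = f"1:{pos}:A:C"
            ann_rows.append(
                {
                    "chrom": "1",
                    "pos": pos,
                    "ref": "A",
                    "alt": "C",
                    "variant_id": vid,
                    "gene": spec.gene_id,
                    "functional_class": "LOF" if lof[v] else "missense",
                    "lof_confidence": "HC" if lof[v] else "NA",
                    "revel": np.nan if lof[v] else revel[v],
                    "maf_internal": maf_internal,
                    "maf_reference": mafs[v],
                }
            )
            priors.append(_genotype_prior(mafs[v], config.prior))

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    if true_cols:
        true_geno = np.stack(true_cols, axis=1)
        priors = np.stack(priors, axis=0)
        depth, ad, post, missing = _read_support_matrix(
            true_geno, config, priors, rng
        )
    else:
        true_geno = np.zeros((n, 0), dtype=np.int64)
        depth = np.zeros((n, 0), dtype=np.int64)
        ad = np.zeros((n, 0, 2), dtype=np.int64)
        post = np.zeros((n, 0, 3))
        missing = np.zeros((n, 0), dtype=bool)

    geno = GenotypeData(
        samples=pheno["sample_id"].to_numpy(),
        variants=annotations["variant_id"].to_numpy(),
        posterior=post,
        depth=depth,
        allele_depths=ad,
        missing=missing,
    )
    geno.true_genotypes = true_geno
    return geno, pheno, annotations


# ---------------------------------------------------------------------------
# serialization


def posterior_to_pl(post: np.ndarray) -> np.ndarray:
    """Phred-scaled, min-normalized genotype likelihoods capped at 255."""
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(np.maximum(post, 0.0))
    pl = pl - pl.min(axis=-1, keepdims=True)
    pl = np.where(np.isfinite(pl), pl, PL_CAP)
    return np.minimum(np.rint(pl), PL_CAP).astype(np.int32)


def pl_to_posterior(pl: np.ndarray) -> np.ndarray:
    post = np.power(10.0, -np.asarray(pl, float) / 10.0)
    return post / post.sum(axis=-1, keepdims=True)


def write_cohort(genotypes: GenotypeData, phenotypes, annotations, prefix):
    """Serialize a cohort to ``<prefix>.vcf`` / ``.phenotypes.tsv`` /
    ``.annotations.tsv``; returns the three paths."""
    import pysam

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = prefix.with_suffix(".vcf")
    header = pysam.VariantHeader()
    header.add_line("##source=adburden-synthetic-cohort")
    max_pos = int(annotations["pos"].max()) if len(annotations) else 1
    for chrom in pd.unique(annotations["chrom"]) if len(annotations) else ["1"]:
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1000}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref,alt)">'
    )
    header.add_line(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,'
        'Description="Phred-scaled genotype likelihoods">'
    )
    for s in genotypes.samples:
        header.add_sample(str(s))

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    calls = genotypes.posterior.argmax(axis=-1)
    pls = posterior_to_pl(genotypes.posterior)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for j, (_, ann) in enumerate(annotations.iterrows()):
            rec = vcf.new_record(
                contig=str(ann["chrom"]),
                start=int(ann["pos"]) - 1,  # pysam start is 0-based
                stop=int(ann["pos"]),
                alleles=(str(ann["ref"]), str(ann["alt"])),
                id=str(ann["variant_id"]),
            )
            for i, s in enumerate(genotypes.samples):
                smp = rec.samples[str(s)]
                if genotypes.missing[i, j]:
                    smp["GT"] = (None, None)
                else:
                    smp["GT"] = gt_codes[int(calls[i, j])]
                smp["DP"] = int(genotypes.depth[i, j])
                smp["AD"] = tuple(int(x) for x in genotypes.allele_depths[i, j])
                smp["PL"] = tuple(int(x) for x in pls[i, j])
            vcf.write(rec)

    pheno_path = prefix.parent / (prefix.name + ".phenotypes.tsv")
    ann_path = prefix.parent / (prefix.name + ".annotations.tsv")
    phenotypes.to_csv(pheno_path, sep="\t", index=False)
    annotations.to_csv(ann_path, sep="\t", index=False)
    return vcf_path, pheno_path, ann_path


def read_cohort(vcf_path, pheno_path, ann_path):
    """Load a cohort written by :func:`write_cohort` (or any VCF v4.2 with
    GT/DP/AD/PL); posteriors are reconstructed from PL within quantization.
    """
    import pysam

    phenotypes = pd.read_csv(pheno_path, sep="\t")
    annotations = pd.read_csv(
        ann_path, sep="\t", dtype={"chrom": str}
    )
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = np.array(list(vcf.header.samples))
        variants, posts, depths, ads, missings = [], [], [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"expected biallelic records; offending position "
                    f"{rec.chrom}:{rec.pos}"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            variants.append(vid)
            pl = np.array(
                [rec.samples[s]["PL"] for s in samples], dtype=float
            )
            dp = np.array(
                [rec.samples[s]["DP"] or 0 for s in samples], dtype=np.int64
            )
            ad = np.array(
                [rec.samples[s]["AD"] for s in samples], dtype=np.int64
            )
            posts.append(pl_to_posterior(pl))
            depths.append(dp)
            ads.append(ad)
            missings.append(dp < DEPTH_MISSING)
    if variants:
        geno = GenotypeData(
            samples=samples,
            variants=np.array(variants),
            posterior=np.stack(posts, axis=1),
            depth=np.stack(depths, axis=1),
            allele_depths=np.stack(ads, axis=1),
            missing=np.stack(missings, axis=1),
        )
    else:
        n = len(samples)
        geno = GenotypeData(
            samples=samples,
            variants=np.array([]),
            posterior=np.zeros((n, 0, 3)),
            depth=np.zeros((n, 0), dtype=np.int64),
            allele_depths=np.zeros((n, 0, 2), dtype=np.int64),
            missing=np.zeros((n, 0), dtype=bool),
        )
    return geno, phenotypes, annotations
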