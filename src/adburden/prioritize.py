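"""Variant prioritization: nested deleteriousness tiers, frequency and
missingness/HWE filters, and per-gene burden selections with the cMAC gate.

Four nested tiers are tested per gene, from most to least stringent:
high-confidence loss-of-function only, then LOF plus missense variants at
REVEL score cuts 75, 50 and 25 (REVEL on a 0-100 scale).  A selection is
testable only when its cumulative minor allele count (cMAC) is at least 10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .containers import GenotypeData

__all__ = [
    "DeleteriousnessThreshold",
    "BurdenSelection",
    "classify_variant",
    "classify_variants",
    "maf_filter",
    "missingness_filter",
    "hwe_exact_test",
    "build_selection",
    "orient_to_minor_allele",
]


class DeleteriousnessThreshold(Enum):
    """Nested tiers; every tier includes high-confidence LOF variants and the
    missense tiers add variants at or above the REVEL cut."""

    LOF = None
    LOF_REVEL75 = 75.0
    LOF_REVEL50 = 50.0
    LOF_REVEL25 = 25.0

    @property
    def revel_cut(self):
        return self.value

    def __str__(self):
        return self.name

    @classmethod
    def ordered(cls):
        """Most to least stringent."""
        return (cls.LOF, cls.LOF_REVEL75, cls.LOF_REVEL50, cls.LOF_REVEL25)


@dataclass
class BurdenSelection:
    """The variants entering a gene x threshold burden test."""

    gene_id: str
    threshold: DeleteriousnessThreshold
    variant_ids: list
    cmac: int
    testable: bool
    maf_internal: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self):
        return len(self.variant_ids)


def classify_variant(variant, threshold: DeleteriousnessThreshold) -> bool:
    """True iff the variant qualifies for the tier.

    Qualifying variants are either LOF annotated high-confidence, or (for the
    missense tiers) missense with REVEL at or above the tier's cut.  Variants
    of any other functional class never qualify; missense variants with a
    missing REVEL score are excluded with a warning.
    """
    cls = variant["functional_class"]
    if cls == "LOF":
        return variant["lof_confidence"] == "HC"
    if cls == "missense":
        if threshold.revel_cut is None:
            return False
        revel = variant["revel"]
        if revel is None or (isinstance(revel, float) and math.isnan(revel)):
            warnings.warn(
                f"missense variant {variant.get('variant_id', '?')} has no "
                "REVEL score; excluded from missense tiers"
            )
            return False
        return revel >= threshold.revel_cut
    return False


def classify_variants(
    annotations: pd.DataFrame, threshold: DeleteriousnessThreshold
) -> np.ndarray:
    """Vectorized tier membership over an annotation table."""
    is_lof = (annotations["functional_class"] == "LOF") & (
        annotations["lof_confidence"] == "HC"
    )
    if threshold.revel_cut is None:
        return is_lof.to_numpy()
    revel = pd.to_numeric(annotations["revel"], errors="coerce")
    n_missing = int(
        ((annotations["functional_class"] == "missense") & revel.isna()).sum()
    )
    if n_missing:
        warnings.warn(
            f"{n_missing} missense variants without REVEL score excluded"
        )
    is_mis = (annotations["functional_class"] == "missense") & (
        revel >= threshold.revel_cut
    )
    return (is_lof | is_mis).to_numpy()


def orient_to_minor_allele(
    annotations: pd.DataFrame, genotypes: GenotypeData
) -> tuple[pd.DataFrame, GenotypeData]:
    """Flip ref/alt dosage orientation wherever the internal AF exceeds 0.5.

    All downstream frequencies and dosages then count the minor allele.
    """
    ann = annotations.copy()
    flip = ann["maf_internal"].to_numpy() > 0.5
    if not flip.any():
        return ann, genotypes
    post = genotypes.posterior.copy()
    ad = genotypes.allele_depths.copy()
    idx = genotypes.variant_index(ann.loc[flip, "variant_id"].to_numpy())
    post[:, idx, :] = post[:, idx, ::-1]
    ad[:, idx, :] = ad[:, idx, ::-1]
    ann.loc[flip, "maf_internal"] = 1.0 - ann.loc[flip, "maf_internal"]
    ann.loc[flip, "maf_reference"] = 1.0 - ann.loc[flip, "maf_reference"]
    flipped = GenotypeData(
        samples=genotypes.samples,
        variants=genotypes.variants,
        posterior=post,
        depth=genotypes.depth,
        allele_depths=ad,
        missing=genotypes.missing,
    )
    return ann, flipped


def maf_filter(
    variant,
    upper: float = 0.01,
    n_carriers: int | None = None,
) -> bool:
    """Frequency filter: the minor allele must be rarer than ``upper`` both
    in the study sample and in the reference panel, and must have at least
    one carrier (a sample with posterior dosage > 0.5) when carrier counts
    are supplied."""
    ok = variant["maf_internal"] < upper and variant["maf_reference"] < upper
    if n_carriers is not None:
        ok = ok and n_carriers >= 1
    return bool(ok)


def maf_filter_table(
    annotations: pd.DataFrame,
    genotypes: GenotypeData | None = None,
    upper: float = 0.01,
) -> np.ndarray:
    keep = (annotations["maf_internal"] < upper) & (
        annotations["maf_reference"] < upper
    )
    if genotypes is not None:
        dose = genotypes.expected_dosage(annotations["variant_id"].to_numpy())
        keep &= (dose > 0.5).any(axis=0)
    return keep.to_numpy()


def missingness_filter(
    genotypes: GenotypeData,
    groups: np.ndarray,
    variant_ids=None,
    overall_max: float = 0.20,
    differential_alpha: float = 1e-4,
) -> pd.DataFrame:
    """Per-variant missingness QC.

    Drops a variant when overall missingness exceeds ``overall_max`` or when a
    Pearson chi-squared test on the 2x3 (missing x outcome-group) table is
    significant at ``differential_alpha``.  Returns a report frame with the
    per-group missing fractions, the test P and the drop reason.
    """
    if variant_ids is None:
        variant_ids = genotypes.variants
    idx = genotypes.variant_index(variant_ids)
    groups = np.asarray(groups)
    levels = ("EOAD", "LOAD", "control")
    rows = []
    for vid, j in zip(variant_ids, idx):
        miss = genotypes.missing[:, j]
        frac = {g: float(miss[groups == g].mean()) for g in levels}
        overall = float(miss.mean())
        reason = ""
        p_diff = np.nan
        if overall > overall_max:
            reason = "overall"
        else:
            table = np.array(
                [
                    [int(miss[groups == g].sum()) for g in levels],
                    [int((~miss)[groups == g].sum()) for g in levels],
                ]
            )
            # drop empty group columns; test needs >= 2 informative groups
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] >= 2 and table.sum(axis=1).min() > 0:
                p_diff = float(chi2_contingency(table, correction=False)[1])
                if p_diff < differential_alpha:
                    reason = "differential"
        rows.append(
            {
                "variant_id": vid,
                "missing_overall": overall,
                "missing_EOAD": frac["EOAD"],
                "missing_LOAD": frac["LOAD"],
                "missing_control": frac["control"],
                "p_differential": p_diff,
                "kept": reason == "",
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def hwe_exact_test(n_rr: int, n_ra: int, n_aa: int) -> float:
    """Levene-Haldane exact test for Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one (two-sided
    exact P, the standard SNP-HWE convention).  Monomorphic or empty data
    give P = 1.
    """
    n_rr, n_ra, n_aa = int(n_rr), int(n_ra), int(n_aa)
    if min(n_rr, n_ra, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_rr + n_ra + n_aa
    if n == 0:
        return 1.0
    n_minor = 2 * n_aa + n_ra
    n_major = 2 * n_rr + n_ra
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    # log-probability of each possible heterozygote count (same parity as
    # the minor allele count), via the Levene-Haldane distribution
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(hom_min + 1)
            - gammaln(h + 1)
            - gammaln(hom_maj + 1)
            - (
                gammaln(2 * n + 1)
                - gammaln(n_minor + 1)
                - gammaln(n_major + 1)
            )
        )

    logp = logprob(hets)
    logp -= np.logaddexp.reduce(logp)  # guard against rounding drift
    p_obs = logp[np.searchsorted(hets, n_ra)]
    return float(min(1.0, np.exp(logp[logp <= p_obs + 1e-12]).sum()))


def hwe_filter(
    genotypes: GenotypeData,
    groups: np.ndarray,
    variant_ids=None,
    alpha: float = 1e-6,
) -> pd.DataFrame:
    """HWE exclusion computed on controls' hard-called genotypes."""
    if variant_ids is None:
        variant_ids = genotypes.variants
    ctrl = np.asarray(groups) == "control"
    calls = genotypes.hard_calls(variant_ids)[ctrl]
    rows = []
    for k, vid in enumerate(variant_ids):
        c = calls[:, k]
        obs = c[c >= 0]
        p = hwe_exact_test(
            int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
        )
        rows.append({"variant_id": vid, "p_hwe": p, "kept": p >= alpha})
    return pd.DataFrame(rows)


def build_selection(
    gene_id: str,
    threshold: DeleteriousnessThreshold,
    annotations: pd.DataFrame,
    genotypes: GenotypeData,
    cmac_min: int = 10,
) -> BurdenSelection:
    """Assemble the burden selection for one gene x threshold.

    cMAC is the sum over selected variants of expected posterior dosages,
    rounded half-up to an integer; the testable flag requires cMAC >=
    ``cmac_min``.
    """
    gene_ann = annotations[annotations["gene"] == gene_id]
    if gene_ann.empty:
        raise KeyError(f"gene {gene_id!r} not present in annotations")
    mask = classify_variants(gene_ann, threshold)
    selected = gene_ann[mask]
    vids = selected["variant_id"].tolist()
    if vids:
        dose = genotypes.expected_dosage(vids)
        cmac = int(math.floor(dose.sum() + 0.5))  # round half-up
    else:
        cmac = 0
    return BurdenSelection(
        gene_id=gene_id,
        threshold=threshold,
        variant_ids=vids,
        cmac=cmac,
        testable=cmac >= cmac_min,
        maf_internal=selected["maf_internal"].to_numpy(),
    )
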