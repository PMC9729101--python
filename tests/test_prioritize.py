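"""Deleteriousness classification, frequency/missingness/HWE filters and
burden-selection construction with the cMAC gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adburden.containers import GenotypeData
from adburden.prioritize import (
    DeleteriousnessThreshold as T,
    build_selection,
    classify_variant,
    classify_variants,
    hwe_exact_test,
    maf_filter,
    missingness_filter,
    orient_to_minor_allele,
)


def _variant(**kw):
    base = {
        "variant_id": "1:100:A:C",
        "functional_class": "missense",
        "lof_confidence": "NA",
        "revel": 50.0,
        "maf_internal": 0.001,
        "maf_reference": 0.001,
    }
    base.update(kw)
    return base


@pytest.mark.parametrize(
    "variant, expected",
    [
        # high-confidence LOF qualifies in every tier, REVEL irrelevant
        (_variant(functional_class="LOF", lof_confidence="HC", revel=np.nan),
         {T.LOF: True, T.LOF_REVEL75: True, T.LOF_REVEL50: True,
          T.LOF_REVEL25: True}),
        # missense REVEL 60 sits between the 50 and 75 cuts
        (_variant(revel=60.0),
         {T.LOF: False, T.LOF_REVEL75: False, T.LOF_REVEL50: True,
          T.LOF_REVEL25: True}),
        # low-confidence LOF never qualifies
        (_variant(functional_class="LOF", lof_confidence="LC", revel=np.nan),
         {T.LOF: False, T.LOF_REVEL75: False, T.LOF_REVEL50: False,
          T.LOF_REVEL25: False}),
        # non-coding / other classes never qualify
        (_variant(functional_class="other"),
         {T.LOF: False, T.LOF_REVEL75: False, T.LOF_REVEL50: False,
          T.LOF_REVEL25: False}),
    ],
)
def test_classification_tiers(variant, expected):
    for thr, want in expected.items():
        assert classify_variant(variant, thr) is want


def test_missense_without_revel_excluded_with_warning():
    v = _variant(revel=np.nan)
    with pytest.warns(UserWarning, match="REVEL"):
        assert classify_variant(v, T.LOF_REVEL25) is False


def test_maf_filter_both_sources_and_carriers():
    assert not maf_filter(_variant(maf_internal=0.005, maf_reference=0.02))
    assert maf_filter(_variant(maf_internal=0.0005, maf_reference=0.0005),
                      upper=0.001)
    assert not maf_filter(_variant(), n_carriers=0)
    assert maf_filter(_variant(), n_carriers=3)


def _geno(missing, n_variants=1):
    n = missing.shape[0]
    post = np.zeros((n, n_variants, 3))
    post[..., 0] = 1.0
    return GenotypeData(
        samples=np.array([f"S{i}" for i in range(n)]),
        variants=np.array([f"1:{100 + j}:A:C" for j in range(n_variants)]),
        posterior=post,
        depth=np.where(missing, 3, 40),
        allele_depths=np.zeros((n, n_variants, 2), int),
        missing=missing,
    )


def test_missingness_overall_rule():
    n = 900
    groups = np.array(["EOAD"] * 300 + ["LOAD"] * 300 + ["control"] * 300)
    miss = np.zeros((n, 2), bool)
    miss[: int(0.25 * n), 0] = True  # 25% uniformly -> dropped
    rep = missingness_filter(_geno(miss, 2), groups)
    assert not rep.loc[0, "kept"] and rep.loc[0, "reason"] == "overall"
    assert rep.loc[1, "kept"]  # 0% missing everywhere -> kept


def test_missingness_differential_rule():
    """0% missing in controls vs 30% in EOAD is dropped as differential;
    the chi-squared P matches a direct 2x3 contingency computation."""
    from scipy.stats import chi2_contingency

    groups = np.array(["EOAD"] * 1000 + ["LOAD"] * 1000 + ["control"] * 1000)
    miss = np.zeros((3000, 1), bool)
    miss[:300, 0] = True  # 30% of EOAD
    rep = missingness_filter(_geno(miss), groups)
    assert not rep.loc[0, "kept"] and rep.loc[0, "reason"] == "differential"
    table = np.array([[300, 0, 0], [700, 1000, 1000]])
    p_direct = chi2_contingency(table, correction=False)[1]
    assert rep.loc[0, "p_differential"] == pytest.approx(p_direct, rel=1e-12)


def test_hwe_monomorphic_and_enumeration():
    assert hwe_exact_test(1000, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 0) == 1.0
    # brute-force oracle: enumerate all heterozygote counts for 100 minor
    # alleles in 100 samples and sum probabilities <= that of het = 100
    from math import lgamma

    n, n_minor = 100, 100

    def logp(h):
        # unnormalized Levene-Haldane weight 2^h * n! / (n_RR! h! n_AA!);
        # the constant normalizer cancels below
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            h * np.log(2)
            - lgamma(hom_min + 1)
            - lgamma(h + 1)
            - lgamma(hom_maj + 1)
        )

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    lp = np.array([logp(int(h)) for h in hets])
    lp -= np.logaddexp.reduce(lp)
    p_obs = lp[hets == 100][0]
    oracle = np.exp(lp[lp <= p_obs + 1e-12]).sum()
    assert hwe_exact_test(0, 100, 0) == pytest.approx(oracle, rel=1e-10)


def test_hwe_null_rejection_matches_exact_computation(rng):
    """Counts drawn from HWE proportions at MAF 1%, n=5,000: the empirical
    rejection rate at 0.05 matches the exactly-enumerated unconditional
    rejection probability (0.0169, conservative as exact tests are)."""
    from scipy.special import gammaln
    from scipy.stats import binom

    n, q, alpha = 5000, 0.01, 0.05

    def reject_prob(n_minor):
        hets = np.arange(n_minor % 2, n_minor + 1, 2)
        hom_min = (n_minor - hets) // 2
        hom_maj = n - hets - hom_min
        lp = (
            hets * np.log(2)
            - gammaln(hom_min + 1)
            - gammaln(hets + 1)
            - gammaln(hom_maj + 1)
        )
        lp -= np.logaddexp.reduce(lp)
        probs = np.exp(lp)
        pv = np.array(
            [probs[probs <= probs[i] + 1e-12].sum() for i in range(len(probs))]
        )
        return probs[pv <= alpha].sum()

    counts = np.arange(55, 150)  # covers the binomial allele-count mass
    weights = binom.pmf(counts, 2 * n, q)
    exact_rate = float(
        sum(w * reject_prob(int(c)) for c, w in zip(counts, weights))
        / weights.sum()
    )
    assert exact_rate == pytest.approx(0.0169, abs=0.001)

    probs3 = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    reps = 800
    rejects = sum(
        hwe_exact_test(*rng.multinomial(n, probs3)) <= alpha
        for _ in range(reps)
    )
    se = np.sqrt(exact_rate * (1 - exact_rate) / reps)
    assert abs(rejects / reps - exact_rate) < 4 * se
    assert rejects / reps < alpha  # the exact test stays conservative


def _cohort_for_selection(rng, n=400, m=12):
    classes = rng.choice(["LOF", "missense", "other"], size=m, p=[0.3, 0.6, 0.1])
    ann = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(100, 100 + m),
            "ref": "A",
            "alt": "C",
            "variant_id": [f"1:{100 + j}:A:C" for j in range(m)],
            "gene": "G1",
            "functional_class": classes,
            "lof_confidence": np.where(
                classes == "LOF", rng.choice(["HC", "LC"], size=m), "NA"
            ),
            "revel": np.where(
                classes == "missense", rng.uniform(0, 100, m).round(1), np.nan
            ),
            "maf_internal": rng.uniform(1e-4, 0.01, m),
            "maf_reference": rng.uniform(1e-4, 0.01, m),
        }
    )
    post = np.zeros((n, m, 3))
    het = rng.random((n, m)) < 0.02
    post[..., 0] = np.where(het, 0.0, 1.0)
    post[..., 1] = np.where(het, 1.0, 0.0)
    geno = GenotypeData(
        samples=np.array([f"S{i}" for i in range(n)]),
        variants=ann["variant_id"].to_numpy(),
        posterior=post,
        depth=np.full((n, m), 40),
        allele_depths=np.zeros((n, m, 2), int),
        missing=np.zeros((n, m), bool),
    )
    return ann, geno


def test_selection_cmac_gate_boundary():
    """Three variants with 4+3+2 carriers give cMAC 9 (not testable); one
    more singleton reaches the gate at 10."""
    m = 4
    ann = pd.DataFrame(
        {
            "variant_id": [f"1:{100 + j}:A:C" for j in range(m)],
            "gene": "G",
            "functional_class": "LOF",
            "lof_confidence": "HC",
            "revel": np.nan,
            "maf_internal": 0.005,
            "maf_reference": 0.005,
        }
    )
    n = 50
    post = np.zeros((n, m, 3))
    post[..., 0] = 1.0
    for j, count in enumerate([4, 3, 2, 1]):
        post[:count, j, 0] = 0.0
        post[:count, j, 1] = 1.0
    geno = GenotypeData(
        samples=np.array([f"S{i}" for i in range(n)]),
        variants=ann["variant_id"].to_numpy(),
        posterior=post,
        depth=np.full((n, m), 40),
        allele_depths=np.zeros((n, m, 2), int),
        missing=np.zeros((n, m), bool),
    )
    sel9 = build_selection("G", T.LOF, ann.iloc[:3], geno)
    assert sel9.cmac == 9 and not sel9.testable
    sel10 = build_selection("G", T.LOF, ann, geno)
    assert sel10.cmac == 10 and sel10.testable


def test_unknown_gene_raises(small_cohort):
    geno, _, ann = small_cohort
    with pytest.raises(KeyError):
        build_selection("NOPE", T.LOF, ann, geno)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_threshold_nesting_property(seed):
    """Tier membership and cMAC are monotone across the nested thresholds on
    randomized annotation sets, and match a brute-force per-variant
    recount."""
    rng = np.random.default_rng(seed)
    ann, geno = _cohort_for_selection(rng)
    sels = {
        thr: build_selection("G1", thr, ann, geno) for thr in T.ordered()
    }
    ordered = [sels[thr] for thr in T.ordered()]
    for a, b in zip(ordered, ordered[1:]):
        assert set(a.variant_ids) <= set(b.variant_ids)
        assert a.cmac <= b.cmac
    # brute-force recount of the widest tier
    wide = ordered[-1]
    expect = set()
    for _, v in ann.iterrows():
        if v["functional_class"] == "LOF" and v["lof_confidence"] == "HC":
            expect.add(v["variant_id"])
        elif v["functional_class"] == "missense" and v["revel"] >= 25:
            expect.add(v["variant_id"])
    assert set(wide.variant_ids) == expect


def test_classify_variants_idempotent_and_matches_scalar(rng):
    ann, _ = _cohort_for_selection(rng)
    for thr in T.ordered():
        mask1 = classify_variants(ann, thr)
        mask2 = classify_variants(ann[mask1], thr)
        assert mask2.all()  # applying the filter twice changes nothing
        scalar = np.array(
            [classify_variant(v, thr) for _, v in ann.iterrows()]
        )
        np.testing.assert_array_equal(mask1, scalar)


def test_minor_allele_orientation_invariance(rng):
    """Flipping a variant's allele coding leaves the post-orientation MAF and
    dosages unchanged."""
    ann, geno = _cohort_for_selection(rng)
    ann2 = ann.copy()
    j = 0
    vid = ann2.loc[j, "variant_id"]
    ann2.loc[j, "maf_internal"] = 1 - ann2.loc[j, "maf_internal"]
    ann2.loc[j, "maf_reference"] = 1 - ann2.loc[j, "maf_reference"]
    post = geno.posterior.copy()
    post[:, 0, :] = post[:, 0, ::-1]
    geno2 = GenotypeData(
        samples=geno.samples, variants=geno.variants, posterior=post,
        depth=geno.depth, allele_depths=geno.allele_depths,
        missing=geno.missing,
    )
    ann_o, geno_o = orient_to_minor_allele(ann2, geno2)
    assert ann_o.loc[j, "maf_internal"] == pytest.approx(
        ann.loc[j, "maf_internal"]
    )
    np.testing.assert_allclose(
        geno_o.expected_dosage([vid]), geno.expected_dosage([vid])
    )
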