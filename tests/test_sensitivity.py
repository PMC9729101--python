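"""Age matching and propensity weighting, APOE interaction LRT, allelic
balance screening and per-variant validation."""

import numpy as np
import pandas as pd
import pytest

from adburden.containers import GenotypeData
from adburden.prioritize import BurdenSelection, DeleteriousnessThreshold
from adburden.sensitivity import (
    age_match,
    age_matched_comparison,
    allelic_balance_screen,
    apoe_interaction_test,
    validate_variants,
)


def _pheno(outcome, age):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(outcome))],
            "outcome": outcome,
            "status": np.where(outcome > 0, "LOAD", "control"),
            "age_or_onset": age,
        }
    )


def test_ratio_clipping_exact(rng):
    """A 50:1 case:control stratum is downsampled to exactly 10:1."""
    outcome = np.array([1] * 500 + [0] * 10)
    age = np.full(510, 71.0)
    strat = age_match(_pheno(outcome, age), rng=rng)
    row = strat.strata[~strat.strata["excluded"]].iloc[0]
    assert row["n_case_after"] == 100 and row["n_control_after"] == 10


def test_single_group_stratum_excluded(rng):
    outcome = np.array([1] * 20 + [0] * 20)
    age = np.r_[np.full(20, 60.0), np.full(20, 80.0)]
    strat = age_match(_pheno(outcome, age), rng=rng)
    assert strat.strata["excluded"].all()
    assert not strat.kept.any()


def test_weights_balance_age_within_strata(rng):
    """Weighted mean ages agree between cases and controls after matching."""
    n = 4000
    outcome = rng.integers(0, 2, n)
    age = np.where(outcome > 0, rng.normal(72, 6, n), rng.normal(68, 6, n))
    ph = _pheno(outcome, age)
    strat = age_match(ph, rng=rng)
    k = strat.kept
    w = strat.weights
    case = (outcome > 0) & k
    ctrl = (outcome == 0) & k
    mean_case = np.average(age[case], weights=w[case])
    mean_ctrl = np.average(age[ctrl], weights=w[ctrl])
    assert abs(mean_case - mean_ctrl) < 0.2


def test_matched_data_weighting_is_noop(rng):
    """When cases and controls already share the age distribution, the
    weighted OR equals the unweighted OR within Monte-Carlo tolerance."""
    n = 8000
    outcome = rng.integers(0, 2, n)
    age = rng.normal(70, 5, n)
    score = (rng.random(n) < 0.05 + 0.05 * outcome).astype(float)
    ph = _pheno(outcome, age)
    strat = age_match(ph, rng=rng)
    cmp = age_matched_comparison(ph, score, strat)
    assert np.log(cmp["weighted"][0]) == pytest.approx(
        np.log(cmp["unweighted"][0]), abs=0.25
    )
    assert cmp["unweighted"][1] > 1.0  # real signal detected


def test_age_confounded_variant_deconfounded(rng):
    """Cases 10 years older plus an age-driven artifact variant: the
    unweighted OR is inflated, the age-matched weighted CI covers 1."""
    n = 20000
    outcome = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    age = np.where(outcome > 0, rng.normal(78, 5, n), rng.normal(68, 5, n))
    p_carrier = np.clip(0.002 + 0.004 * (age - 60), 0.001, 0.5)
    score = (rng.random(n) < p_carrier).astype(float)
    ph = _pheno(outcome, age)
    strat = age_match(ph, rng=rng)
    cmp = age_matched_comparison(ph, score, strat)
    assert cmp["unweighted"][1] > 1.0  # CI excludes 1: spurious signal
    assert cmp["weighted"][1] < 1.0 < cmp["weighted"][2]


def test_apoe_interaction_null_and_power(rng):
    n = 20000
    score = (rng.random(n) < 0.05).astype(float)
    apoe = rng.binomial(2, 0.2, n)
    # pure additivity
    from scipy.special import expit

    eta = 0.5 * score + 0.4 * apoe
    u = rng.random(n)
    y = (u < expit(eta - 2.0)).astype(int) * 2
    y[(u >= expit(eta - 2.0)) & (u < expit(eta - 0.5))] = 1
    p_add = apoe_interaction_test(y, score, apoe)
    assert p_add > 0.01
    # multiplicative interaction, log-OR ln 2
    eta_i = 0.5 * score + 0.4 * apoe + np.log(2) * score * apoe
    u = rng.random(n)
    yi = (u < expit(eta_i - 2.0)).astype(int) * 2
    yi[(u >= expit(eta_i - 2.0)) & (u < expit(eta_i - 0.5))] = 1
    assert apoe_interaction_test(yi, score, apoe) < 0.05


def test_apoe_interaction_degenerate_inputs():
    y = np.array([0, 1, 2] * 20)
    assert np.isnan(apoe_interaction_test(y, np.ones(60), np.zeros(60)))
    assert apoe_interaction_test(y, np.zeros(60), np.array([0, 1, 2] * 20)) == 1.0


def _geno_with_reads(het_mask, alt_frac, depth=40, rng=None):
    rng = np.random.default_rng(rng)
    n, m = het_mask.shape
    post = np.zeros((n, m, 3))
    post[..., 0] = np.where(het_mask, 0.0, 1.0)
    post[..., 1] = np.where(het_mask, 1.0, 0.0)
    depths = np.full((n, m), depth)
    alts = rng.binomial(depth, np.where(het_mask, alt_frac, 0.0))
    ad = np.stack([depths - alts, alts], axis=-1)
    return GenotypeData(
        samples=np.array([f"S{i}" for i in range(n)]),
        variants=np.array([f"1:{100 + j}:A:C" for j in range(m)]),
        posterior=post,
        depth=depths,
        allele_depths=ad,
        missing=np.zeros((n, m), bool),
    )


def _sel(geno):
    return BurdenSelection(
        gene_id="G",
        threshold=DeleteriousnessThreshold.LOF,
        variant_ids=list(geno.variants),
        cmac=20,
        testable=True,
        maf_internal=np.full(geno.n_variants, 0.005),
    )


def test_allelic_balance_flags_skewed_variant():
    """Pooled 60/400 alt reads: binomial P << 1e-6 and fraction 0.15 ->
    flagged; a balanced variant at 0.5 is not."""
    from scipy.stats import binomtest

    het = np.zeros((10, 2), bool)
    het[:, :] = True
    geno = _geno_with_reads(het, 0.5, depth=40, rng=0)
    # overwrite read counts deterministically
    geno.allele_depths[:, 0, :] = [34, 6]  # 60 alt / 400 total
    geno.allele_depths[:, 1, :] = [20, 20]  # 200 alt / 400 total
    rep = allelic_balance_screen(geno, _sel(geno))
    assert rep.loc[0, "alt_fraction"] == pytest.approx(0.15)
    assert rep.loc[0, "flagged"]
    oracle = binomtest(60, 400, 0.5).pvalue
    assert rep.loc[0, "p"] == pytest.approx(oracle, rel=1e-12)
    assert not rep.loc[1, "flagged"]
    assert rep.loc[1, "alt_fraction"] == pytest.approx(0.5)


def test_allelic_balance_calibrated_on_germline_hets(rng):
    """True germline hets at depth 40: flag rate stays at or below the
    nominal test level."""
    het = rng.random((400, 50)) < 0.2
    geno = _geno_with_reads(het, 0.5, depth=40, rng=1)
    rep = allelic_balance_screen(geno, _sel(geno), alpha=1e-3)
    assert rep["flagged"].mean() <= 0.01


def test_allelic_balance_no_hets_is_na():
    het = np.zeros((5, 1), bool)
    geno = _geno_with_reads(het, 0.5)
    rep = allelic_balance_screen(geno, _sel(geno))
    assert np.isnan(rep.loc[0, "alt_fraction"]) and not rep.loc[0, "flagged"]


def _validation_cohort(split_this, split_rest, n_other=3, rng=None):
    """Build genotypes/phenotypes where variant 0 has the given
    (case, control) carrier split and the remaining variants jointly have
    split_rest."""
    rng = np.random.default_rng(rng)
    n_case = split_this[0] + split_rest[0] + 200
    n_ctrl = split_this[1] + split_rest[1] + 200
    n = n_case + n_ctrl
    outcome = np.r_[np.ones(n_case, int), np.zeros(n_ctrl, int)]
    m = 1 + n_other
    post = np.zeros((n, m, 3))
    post[..., 0] = 1.0

    def set_het(sample_idx, var_idx):
        post[sample_idx, var_idx, 0] = 0.0
        post[sample_idx, var_idx, 1] = 1.0

    set_het(np.arange(split_this[0]), 0)
    set_het(n_case + np.arange(split_this[1]), 0)
    rest_cases = split_this[0] + np.arange(split_rest[0])
    rest_ctrls = n_case + split_this[1] + np.arange(split_rest[1])
    for i, s in enumerate(rest_cases):
        set_het(s, 1 + i % n_other)
    for i, s in enumerate(rest_ctrls):
        set_het(s, 1 + i % n_other)
    geno = GenotypeData(
        samples=np.array([f"S{i}" for i in range(n)]),
        variants=np.array([f"1:{100 + j}:A:C" for j in range(m)]),
        posterior=post,
        depth=np.full((n, m), 40),
        allele_depths=np.zeros((n, m, 2), int),
        missing=np.zeros((n, m), bool),
    )
    pheno = pd.DataFrame(
        {
            "sample_id": geno.samples,
            "outcome": outcome,
            "status": np.where(outcome > 0, "LOAD", "control"),
            "age_or_onset": 70.0,
        }
    )
    sel = BurdenSelection(
        gene_id="G",
        threshold=DeleteriousnessThreshold.LOF,
        variant_ids=list(geno.variants),
        cmac=sum(split_this) + sum(split_rest),
        testable=True,
        maf_internal=np.full(m, 0.005),
    )
    return geno, pheno, sel


def test_validation_keeps_concordant_variant():
    geno, pheno, sel = _validation_cohort((20, 20), (60, 60))
    report, refined = validate_variants(sel, geno, pheno)
    assert (report["decision"] == "keep").all()
    assert refined.cmac == sel.cmac


def test_validation_removes_discordant_variant():
    """Variant carried by 2 cases / 30 controls against a selection at
    300 / 50: Fisher's exact matches the hypergeometric oracle and the
    variant is removed; refinement lowers the cMAC."""
    from math import comb

    geno, pheno, sel = _validation_cohort((2, 30), (300, 50))
    report, refined = validate_variants(sel, geno, pheno)
    row = report.iloc[0]
    # hypergeometric enumeration of the 2x2 table P
    a, b, c, d = 2, 30, 300, 50

    def table_p(x):
        return (
            comb(a + b, x) * comb(c + d, a + c - x)
            / comb(a + b + c + d, a + c)
        )

    p_obs = table_p(a)
    oracle = sum(
        table_p(x)
        for x in range(max(0, a + c - (c + d)), min(a + b, a + c) + 1)
        if table_p(x) <= p_obs * (1 + 1e-9)
    )
    assert row["p_fisher"] == pytest.approx(oracle, rel=1e-9)
    assert row["decision"] == "remove"
    assert refined.cmac < sel.cmac
    assert geno.variants[0] not in refined.variant_ids


def test_validation_single_variant_selection_is_na(small_cohort):
    geno, pheno, _ = small_cohort
    sel = BurdenSelection(
        gene_id="G",
        threshold=DeleteriousnessThreshold.LOF,
        variant_ids=[geno.variants[0]],
        cmac=12,
        testable=True,
        maf_internal=np.array([0.005]),
    )
    report, refined = validate_variants(sel, geno, pheno)
    assert report.loc[0, "reason"] == "no comparison group"
    assert refined is sel


def test_refinement_never_increases_cmac():
    geno, pheno, sel = _validation_cohort((2, 40), (200, 40))
    _, refined = validate_variants(sel, geno, pheno)
    assert refined.cmac <= sel.cmac
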