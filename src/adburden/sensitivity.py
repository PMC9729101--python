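"""Sensitivity analyses: age-matched propensity-weighted re-analysis,
APOE-e4 interaction test, allelic-balance (clonal hematopoiesis) screen and
per-variant validation/refinement of burden selections."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

from .multistage import bh_fdr
from .ordinal import fit_proportional_odds, lrt_p
from .prioritize import BurdenSelection

__all__ = [
    "AgeStratification",
    "age_match",
    "weighted_logistic_or",
    "apoe_interaction_test",
    "allelic_balance_screen",
    "validate_variants",
]


@dataclass
class AgeStratification:
    """Half-open 2.5-year age strata with per-sample analysis weights.

    ``kept`` flags the samples retained after ratio clipping (case:control
    ratio forced into ``ratio_bounds`` by within-stratum downsampling);
    ``weights`` are positive for kept samples and zero otherwise.
    """

    strata: pd.DataFrame
    kept: np.ndarray
    weights: np.ndarray
    width: float
    ratio_bounds: tuple


def age_match(
    phenotypes: pd.DataFrame,
    width: float = 2.5,
    ratio_bounds: tuple = (0.1, 10.0),
    rng=None,
    scheme: str = "overlap",
) -> AgeStratification:
    """Stratify on age/age-at-onset and derive propensity-style weights.

    Cases enter with their onset age, controls with their age at inclusion.
    Strata lie on a fixed grid of ``width`` years.  Within each stratum the
    case:control ratio is clipped into ``ratio_bounds`` by uniform random
    downsampling of the excess group; strata containing a single group are
    excluded.  Weighting schemes:

    - ``overlap``: cases weighted by the stratum control fraction and
      controls by the case fraction (stabilizes extreme strata);
    - ``ip``: inverse-probability weights toward the stratum population.

    Weights are rescaled so they sum to the number of retained samples.
    """
    rng = np.random.default_rng(rng)
    age = phenotypes["age_or_onset"].to_numpy(float)
    is_case = (phenotypes["outcome"].to_numpy() > 0).astype(bool)
    stratum = np.floor(age / width).astype(int)

    kept = np.zeros(len(phenotypes), dtype=bool)
    weights = np.zeros(len(phenotypes))
    rows = []
    lo, hi = ratio_bounds
    for s in np.unique(stratum):
        idx = np.flatnonzero(stratum == s)
        cases = idx[is_case[idx]]
        ctrls = idx[~is_case[idx]]
        n_case0, n_ctrl0 = len(cases), len(ctrls)
        if n_case0 == 0 or n_ctrl0 == 0:
            rows.append(
                {
                    "stratum": s,
                    "age_lo": s * width,
                    "age_hi": (s + 1) * width,
                    "n_case_before": n_case0,
                    "n_control_before": n_ctrl0,
                    "n_case_after": 0,
                    "n_control_after": 0,
                    "excluded": True,
                }
            )
            continue
        if n_case0 > hi * n_ctrl0:
            cases = rng.choice(cases, size=int(hi * n_ctrl0), replace=False)
        if n_ctrl0 > n_case0 / lo:
            ctrls = rng.choice(ctrls, size=int(n_case0 / lo), replace=False)
        n_case, n_ctrl = len(cases), len(ctrls)
        tot = n_case + n_ctrl
        if scheme == "overlap":
            w_case, w_ctrl = n_ctrl / tot, n_case / tot
        elif scheme == "ip":
            w_case, w_ctrl = tot / (2.0 * n_case), tot / (2.0 * n_ctrl)
        else:
            raise ValueError(f"unknown weighting scheme {scheme!r}")
        kept[cases] = kept[ctrls] = True
        weights[cases] = w_case
        weights[ctrls] = w_ctrl
        rows.append(
            {
                "stratum": s,
                "age_lo": s * width,
                "age_hi": (s + 1) * width,
                "n_case_before": n_case0,
                "n_control_before": n_ctrl0,
                "n_case_after": n_case,
                "n_control_after": n_ctrl,
                "excluded": False,
            }
        )
    if kept.any():
        weights[kept] *= kept.sum() / weights[kept].sum()
    return AgeStratification(
        strata=pd.DataFrame(rows),
        kept=kept,
        weights=weights,
        width=width,
        ratio_bounds=ratio_bounds,
    )


def weighted_logistic_or(y, score, weights=None):
    """Case-control logistic OR with optional frequency weights; returns
    (OR, ci_low, ci_high, p)."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(y)), np.asarray(score, float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            np.asarray(y, float),
            X,
            family=sm.families.Binomial(),
            freq_weights=None if weights is None else np.asarray(weights),
        )
        res = model.fit()
    b, se = res.params[1], res.bse[1]
    return (
        float(np.exp(b)),
        float(np.exp(b - 1.96 * se)),
        float(np.exp(b + 1.96 * se)),
        float(res.pvalues[1]),
    )


def age_matched_comparison(phenotypes, score, strat: AgeStratification):
    """Unweighted vs age-matched weighted case-control ORs for a burden
    score; returns a dict with both (OR, lo, hi, p) tuples."""
    y = (phenotypes["outcome"].to_numpy() > 0).astype(float)
    score = np.asarray(score, float)
    unweighted = weighted_logistic_or(y, score)
    k = strat.kept
    weighted = weighted_logistic_or(y[k], score[k], strat.weights[k])
    return {"unweighted": unweighted, "weighted": weighted}


def apoe_interaction_test(
    outcome, burden_score, apoe4_dosage, covariates=None
) -> float:
    """LRT P for a burden x APOE-e4 interaction on the ordinal outcome.

    Compares the additive model (score + dosage) against the model with the
    product term added (chi^2, 1 df).  A constant dosage is untestable
    (NaN); an all-zero burden score returns 1 by convention.
    """
    outcome = np.asarray(outcome)
    score = np.asarray(burden_score, float)
    dosage = np.asarray(apoe4_dosage, float)
    if np.ptp(dosage) == 0:
        return float("nan")
    if np.ptp(score) == 0:
        return 1.0
    base_cols = [score, dosage]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(outcome):
            cov = cov.T
        base_cols.append(cov)
    X_null = np.column_stack(base_cols)
    X_full = np.column_stack([X_null, score * dosage])
    null = fit_proportional_odds(outcome, X_null)
    full = fit_proportional_odds(outcome, X_full)
    return lrt_p(full, null)


def allelic_balance_screen(
    genotypes,
    selection: BurdenSelection,
    reference_fraction: float = 0.5,
    alpha: float = 1e-4,
    flag_below: float = 0.4,
) -> pd.DataFrame:
    """Screen heterozygous calls for skewed alternate-read fractions.

    Pools ref/alt read counts across heterozygous (posterior-mode) carriers
    per variant and applies a two-sided exact binomial test against
    ``reference_fraction``.  A variant is flagged when the test is
    significant at ``alpha`` *and* the pooled alt fraction is below
    ``flag_below`` — the signature of somatic-mosaic rather than germline
    calls.  Variants without heterozygous carriers yield NaN.
    """
    idx = genotypes.variant_index(selection.variant_ids)
    calls = genotypes.hard_calls(selection.variant_ids)
    rows = []
    for k, vid in enumerate(selection.variant_ids):
        het = calls[:, k] == 1
        if not het.any():
            rows.append(
                {
                    "variant_id": vid,
                    "n_het": 0,
                    "alt_reads": 0,
                    "total_reads": 0,
                    "alt_fraction": np.nan,
                    "p": np.nan,
                    "flagged": False,
                }
            )
            continue
        ad = genotypes.allele_depths[het][:, idx[k], :]
        alt = int(ad[:, 1].sum())
        tot = int(ad.sum())
        frac = alt / tot if tot else np.nan
        p = (
            binomtest(alt, tot, reference_fraction).pvalue if tot else np.nan
        )
        rows.append(
            {
                "variant_id": vid,
                "n_het": int(het.sum()),
                "alt_reads": alt,
                "total_reads": tot,
                "alt_fraction": frac,
                "p": p,
                "flagged": bool(tot and p < alpha and frac < flag_below),
            }
        )
    return pd.DataFrame(rows)


def validate_variants(
    selection: BurdenSelection,
    genotypes,
    phenotypes: pd.DataFrame,
    min_carriers: int = 15,
    fdr_threshold: float = 0.1,
) -> tuple[pd.DataFrame, BurdenSelection]:
    """Per-variant validation of a burden selection (Fisher's exact test).

    For every selected variant with at least ``min_carriers`` carriers, the
    2x2 table (variant carriers vs carriers of the remaining selection) x
    (case, control) is tested with Fisher's exact test.  Variants whose
    case fraction is significantly *below* the rest of the selection (BH
    FDR across the gene's evaluated variants) are removed, producing the
    refined selection; refinement never increases the cMAC.
    """
    if len(selection) < 2:
        return (
            pd.DataFrame(
                [
                    {
                        "variant_id": v,
                        "n_carriers": np.nan,
                        "p_fisher": np.nan,
                        "decision": "keep",
                        "reason": "no comparison group",
                    }
                    for v in selection.variant_ids
                ]
            ),
            selection,
        )
    dose = genotypes.expected_dosage(selection.variant_ids)
    is_case = phenotypes["outcome"].to_numpy() > 0
    carrier_mat = dose > 0.5

    rows = []
    for k, vid in enumerate(selection.variant_ids):
        this = carrier_mat[:, k]
        n_car = int(this.sum())
        if n_car < min_carriers:
            rows.append(
                {
                    "variant_id": vid,
                    "n_carriers": n_car,
                    "case_carriers": int((this & is_case).sum()),
                    "control_carriers": int((this & ~is_case).sum()),
                    "p_fisher": np.nan,
                    "odds_ratio": np.nan,
                    "decision": "keep",
                    "reason": "below carrier minimum",
                }
            )
            continue
        rest = carrier_mat[:, np.arange(carrier_mat.shape[1]) != k].any(axis=1)
        rest = rest & ~this
        table = np.array(
            [
                [int((this & is_case).sum()), int((this & ~is_case).sum())],
                [int((rest & is_case).sum()), int((rest & ~is_case).sum())],
            ]
        )
        orat, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "variant_id": vid,
                "n_carriers": n_car,
                "case_carriers": int(table[0, 0]),
                "control_carriers": int(table[0, 1]),
                "p_fisher": float(p),
                "odds_ratio": float(orat),
                "decision": "keep",
                "reason": "",
            }
        )
    report = pd.DataFrame(rows)
    tested = report["p_fisher"].notna()
    if tested.any():
        q = bh_fdr(report.loc[tested, "p_fisher"].to_numpy())
        report.loc[tested, "fdr_q"] = q
        weaker = report["odds_ratio"] < 1.0
        remove = tested & weaker & (report["fdr_q"] < fdr_threshold)
        report.loc[remove, "decision"] = "remove"
        report.loc[remove, "reason"] = "effect reduced vs rest of selection"
    else:
        report["fdr_q"] = np.nan

    keep_ids = report.loc[report["decision"] == "keep", "variant_id"].tolist()
    if len(keep_ids) == len(selection):
        refined = selection
    else:
        keep_mask = np.isin(np.array(selection.variant_ids), keep_ids)
        new_dose = genotypes.expected_dosage(keep_ids)
        refined = replace(
            selection,
            variant_ids=keep_ids,
            cmac=int(np.floor(new_dose.sum() + 0.5)),
            maf_internal=np.asarray(selection.maf_internal)[keep_mask],
        )
        refined.testable = refined.cmac >= 10
    return report, refined


def association_of_excluded_variants(
    annotations: pd.DataFrame,
    selection: BurdenSelection,
    genotypes,
    phenotypes: pd.DataFrame,
    min_carriers: int = 15,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Inclusion candidates: protein-modifying variants of the gene left out
    of the selection, tested for case/control association (logistic) with BH
    FDR across the evaluated variants."""
    gene_ann = annotations[annotations["gene"] == selection.gene_id]
    excluded = gene_ann[
        ~gene_ann["variant_id"].isin(set(selection.variant_ids))
        & gene_ann["functional_class"].isin(["missense", "LOF"])
    ]
    y = (phenotypes["outcome"].to_numpy() > 0).astype(float)
    rows = []
    for _, ann in excluded.iterrows():
        dose = genotypes.expected_dosage([ann["variant_id"]])[:, 0]
        n_car = int((dose > 0.5).sum())
        if n_car < min_carriers:
            continue
        orat, lo, hi, p = weighted_logistic_or(y, dose)
        rows.append(
            {
                "variant_id": ann["variant_id"],
                "n_carriers": n_car,
                "odds_ratio": orat,
                "p": p,
            }
        )
    rep = pd.DataFrame(rows)
    if not rep.empty:
        rep["fdr_q"] = bh_fdr(rep["p"].to_numpy())
        rep["decision"] = np.where(
            rep["fdr_q"] < fdr_threshold, "add-flag", "keep-excluded"
        )
    return rep
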