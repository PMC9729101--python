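"""Published summary statistics used as worked-example inputs.

These are the printed two-stage association results (13 gene x threshold
tests that passed discovery FDR < 0.1) and a handful of mega-sample
descriptive rows (carrier frequencies and per-onset-group odds ratios) from
the large Alzheimer's-disease exome-sequencing case-control study whose
design this package implements.  The raw cohort is access-controlled, so
these table values serve as inputs for deterministic recomputation of the
derived columns: FDR q-values, Holm-adjusted P values, meta-analysis ORs,
stage concordance and attributable fractions.

Stage ORs are case/control reference odds ratios with 95% CIs as printed;
P values are the two-sided ordinal burden-test P values (stage 2 one-sided).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .multistage import StageResult, inverse_variance_meta, se_from_ci

__all__ = [
    "two_stage_table",
    "descriptive_table",
    "M_TOTAL_TESTS",
    "meta_or_from_printed",
]

# number of burden tests performed at discovery (13,222 genes, up to four
# deleteriousness thresholds each)
M_TOTAL_TESTS = 31_204

_TWO_STAGE = [
    # gene, threshold, p1, or1, lo1, hi1, p2_one_sided, or2, lo2, hi2
    ("SORL1", "LOF_REVEL25", 4.8e-6, 1.3, 1.1, 1.5, 1.3e-6, 1.5, 1.2, 1.9),
    ("SORL1", "LOF_REVEL50", 4.0e-18, 2.6, 2.0, 3.2, 1.4e-9, 2.4, 1.7, 3.5),
    ("SORL1", "LOF_REVEL75", 1.1e-14, 3.3, 2.4, 4.6, 5.2e-10, 3.9, 2.3, 6.6),
    ("SORL1", "LOF", 4.7e-15, 15.6, 3.7, 37.3, 1.6e-6, 16.3, 3.8, 35.0),
    ("TREM2", "LOF_REVEL25", 2.6e-16, 3.6, 2.9, 4.6, 1.6e-7, 2.4, 1.6, 3.4),
    ("ABCA7", "LOF_REVEL25", 9.5e-8, 1.4, 1.2, 1.6, 9.8e-8, 1.6, 1.3, 2.0),
    ("ABCA7", "LOF_REVEL75", 4.6e-6, 1.6, 1.3, 2.1, 4.8e-4, 1.8, 1.3, 2.6),
    ("ATP8B4", "LOF_REVEL25", 7.2e-6, 1.5, 1.3, 1.8, 3.3e-3, 1.4, 1.0, 1.8),
    ("ATP8B4", "LOF_REVEL50", 2.8e-5, 1.5, 1.3, 1.9, 1.6e-2, 1.3, 1.0, 1.7),
    ("ATP8B4", "LOF_REVEL75", 3.2e-6, 1.7, 1.4, 2.0, 2.4e-2, 1.3, 1.0, 1.8),
    ("ABCA1", "LOF_REVEL75", 6.1e-6, 1.7, 1.3, 2.2, 6.6e-3, 1.6, 1.1, 2.3),
    ("ADAM10", "LOF_REVEL50", 2.0e-5, 3.2, 1.3, 8.1, 4.0e-2, 8.1, 0.6, 42.6),
    ("ADAM10", "LOF_REVEL75", 2.7e-6, 7.5, 1.4, 46.8, 1.5e-1, 5.6, 0.3, 41.8),
]

_META_P = {
    # meta-analysis two-sided P as printed, per (gene, threshold)
    ("SORL1", "LOF_REVEL25"): 1.5e-10,
    ("SORL1", "LOF_REVEL50"): 8.1e-26,
    ("SORL1", "LOF_REVEL75"): 1.1e-22,
    ("SORL1", "LOF"): 3.3e-18,
    ("TREM2", "LOF_REVEL25"): 5.2e-22,
    ("ABCA7", "LOF_REVEL25"): 4.1e-13,
    ("ABCA7", "LOF_REVEL75"): 7.3e-9,
    ("ATP8B4", "LOF_REVEL25"): 9.6e-9,
    ("ATP8B4", "LOF_REVEL50"): 2.8e-6,
    ("ATP8B4", "LOF_REVEL75"): 5.7e-7,
    ("ABCA1", "LOF_REVEL75"): 2.6e-7,
    ("ADAM10", "LOF_REVEL50"): 2.8e-5,
    ("ADAM10", "LOF_REVEL75"): 4.4e-4,
}


def two_stage_table() -> pd.DataFrame:
    """The 13 published discovery-significant tests with stage ORs/CIs,
    stage P values, printed meta P, and log-OR/SE reconstructed from the
    printed 95% CIs."""
    rows = []
    for gene, thr, p1, o1, l1, h1, p2, o2, l2, h2 in _TWO_STAGE:
        rows.append(
            {
                "gene": gene,
                "threshold": thr,
                "test_id": f"{gene}:{thr}",
                "p_stage1": p1,
                "or_stage1": o1,
                "ci_lo_stage1": l1,
                "ci_hi_stage1": h1,
                "p_stage2_one_sided": p2,
                "or_stage2": o2,
                "ci_lo_stage2": l2,
                "ci_hi_stage2": h2,
                "p_meta": _META_P[(gene, thr)],
                "beta_stage1": np.log(o1),
                "se_stage1": se_from_ci(l1, h1),
                "beta_stage2": np.log(o2),
                "se_stage2": se_from_ci(l2, h2),
            }
        )
    return pd.DataFrame(rows)


def meta_or_from_printed(gene: str, threshold: str) -> float:
    """Fixed-effect inverse-variance meta OR of the two stage ORs, with SEs
    reconstructed from the printed CIs."""
    t = two_stage_table()
    row = t[(t["gene"] == gene) & (t["threshold"] == threshold)].iloc[0]
    meta = inverse_variance_meta(
        [
            StageResult(row["test_id"], row["p_stage1"],
                        row["beta_stage1"], row["se_stage1"], 1),
            StageResult(row["test_id"], row["p_stage2_one_sided"],
                        row["beta_stage2"], row["se_stage2"], 2),
        ]
    )
    return meta.or_meta


_DESCRIPTIVES = [
    # gene, selection, CF EOAD/LOAD/control (%), OR EOAD/ctrl, OR LOAD/ctrl
    ("SORL1", "LOF", 0.78, 0.21, 0.02, 40.7, 11.3),
    ("SORL1", "LOF_REVEL50", 2.75, 1.51, 0.68, 3.3, 2.0),
    ("TREM2", "LOF_refined", 0.16, 0.16, 0.02, 5.8, 5.4),
    ("TREM2", "LOF_REVEL25", 2.27, 1.90, 0.75, 3.3, 2.6),
    ("ABCA7", "LOF_REVEL25", 6.18, 5.04, 3.90, 1.6, 1.3),
    ("ATP8B4", "LOF_REVEL25", 3.56, 3.08, 2.09, 1.5, 1.4),
    ("ABCA1", "LOF_REVEL75", 1.91, 1.50, 1.13, 1.9, 1.5),
    ("CLU", "LOF", 0.12, 0.03, 0.01, 14.2, 3.8),
    ("ZCWPW1", "LOF", 0.15, 0.05, 0.01, 9.1, 2.9),
    ("ACE", "LOF_REVEL75", 0.60, 0.39, 0.20, 2.4, 1.7),
]


def descriptive_table() -> pd.DataFrame:
    """Published mega-sample carrier frequencies (percent) and per-group
    odds ratios for selected gene x selection rows."""
    return pd.DataFrame(
        _DESCRIPTIVES,
        columns=[
            "gene",
            "selection",
            "cf_eoad",
            "cf_load",
            "cf_control",
            "or_eoad",
            "or_load",
        ],
    )
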