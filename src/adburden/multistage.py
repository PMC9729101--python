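"""Two-stage inference: discovery FDR, one-sided confirmation, fixed-effect
inverse-variance meta-analysis, Holm-Bonferroni family-wise correction, and
the genomic-inflation diagnostic.

All multiple-testing routines accept an ``m_total`` larger than the number of
P values supplied: the listed tests are then treated as occupying the
smallest ranks among ``m_total`` tests, with every unlisted test assumed
larger than all listed ones.  This is how adjusted values for a published
top-table can be reproduced without the full result set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "StageResult",
    "MetaAnalysisResult",
    "bh_fdr",
    "holm_adjust",
    "one_sided_confirmation",
    "inverse_variance_meta",
    "genomic_lambda",
    "run_two_stage",
    "run_targeted",
]

CHI2_1_MEDIAN = 0.45493642311957174  # chi^2_1 median


@dataclass
class StageResult:
    test_id: str
    p: float
    beta: float
    se: float
    stage: int = 1


@dataclass
class MetaAnalysisResult:
    test_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    q_stat: float
    p_het: float
    n_studies: int

    @property
    def or_meta(self) -> float:
        return float(np.exp(self.beta_meta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2)
        return (
            float(np.exp(self.beta_meta - z * self.se_meta)),
            float(np.exp(self.beta_meta + z * self.se_meta)),
        )


def _check_pvals(pvals, m_total):
    p = np.asarray(pvals, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m_total is None:
        m_total = len(p)
    if m_total < len(p):
        raise ValueError("m_total smaller than the number of p-values")
    return p, int(m_total)


def bh_fdr(pvals, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m_total / j, capped at 1, with the supplied
    tests occupying ranks 1..len(pvals) of ``m_total``.  Ties are broken by
    stable sort, so equal P values share a q.
    """
    p, m = _check_pvals(pvals, m_total)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    raw = p[order] * m / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    q = np.empty_like(p)
    q[order] = q_sorted
    return q


def holm_adjust(pvals, m_total: int | None = None) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted P values.

    adj_(i) = max_{j <= i} min(1, p_(j) * (m_total - j + 1)), with the listed
    tests treated as the smallest ranks among ``m_total``.
    """
    p, m = _check_pvals(pvals, m_total)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    raw = np.minimum(1.0, p[order] * (m - ranks + 1))
    adj_sorted = np.maximum.accumulate(raw)
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


def one_sided_confirmation(
    p_two_sided: float, beta: float, direction: int, se: float | None = None
) -> float:
    """Stage-2 one-sided P in the direction observed at discovery.

    With an effect estimate available the one-sided P comes from the signed
    Wald statistic: P/2 when the stage-2 sign agrees with the discovery
    direction, 1 - P/2 when it disagrees; a zero effect gives 0.5.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    if se is not None:
        z = beta / se
        return float(norm.sf(direction * z))
    if beta == 0:
        return 0.5
    if np.sign(beta) == direction:
        return p_two_sided / 2.0
    return 1.0 - p_two_sided / 2.0


def inverse_variance_meta(studies: list[StageResult]) -> MetaAnalysisResult:
    """Fixed-effect inverse-variance pooling with Cochran's Q heterogeneity.

    Weights are 1/se^2; the pooled SE is (sum of weights)^(-1/2) and the
    two-sided P is normal.  A single study passes through unchanged with
    undefined heterogeneity.
    """
    if not studies:
        raise ValueError("at least one study required")
    betas = np.array([s.beta for s in studies], float)
    ses = np.array([s.se for s in studies], float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    p_meta = float(2.0 * norm.sf(abs(beta_meta) / se_meta))
    if len(studies) == 1:
        q, p_het = np.nan, np.nan
    else:
        q = float(np.sum(w * (betas - beta_meta) ** 2))
        p_het = float(chi2.sf(q, len(studies) - 1))
    return MetaAnalysisResult(
        test_id=studies[0].test_id,
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_meta=p_meta,
        q_stat=q,
        p_het=p_het,
        n_studies=len(studies),
    )


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Reconstruct the log-OR standard error from a printed OR CI."""
    z = norm.ppf(0.5 + level / 2)
    return float((np.log(upper) - np.log(lower)) / (2.0 * z))


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median observed chi^2_1 statistic over the
    null median 0.4549."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def run_two_stage(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    m_total: int | None = None,
    fdr_threshold: float = 0.1,
    stage2_alpha: float = 0.05,
    holm_alpha: float = 0.05,
) -> pd.DataFrame:
    """Discovery -> confirmation -> meta-analysis -> family-wise gate.

    Both inputs need columns (test_id, p, beta, se).  Stage-1 tests passing
    Benjamini-Hochberg FDR < ``fdr_threshold`` (over ``m_total`` tests) are
    carried to one-sided stage-2 confirmation in the stage-1 direction, then
    meta-analyzed; the meta P values are Holm-adjusted over ``m_total``.
    """
    s1 = stage1.reset_index(drop=True).copy()
    if s1["test_id"].duplicated().any():
        raise ValueError("duplicate test ids in stage 1")
    s1["fdr_q"] = bh_fdr(s1["p"].to_numpy(), m_total)
    s1["selected_stage1"] = s1["fdr_q"] < fdr_threshold
    s2 = stage2.set_index("test_id")

    out = []
    for _, row in s1.iterrows():
        rec = {
            "test_id": row["test_id"],
            "p_stage1": row["p"],
            "fdr_q": row["fdr_q"],
            "beta_stage1": row["beta"],
            "se_stage1": row["se"],
            "selected_stage1": bool(row["selected_stage1"]),
            "p_stage2_one_sided": np.nan,
            "confirmed_stage2": False,
            "beta_meta": np.nan,
            "se_meta": np.nan,
            "p_meta": np.nan,
            "p_het": np.nan,
        }
        if row["selected_stage1"]:
            if row["test_id"] not in s2.index:
                raise KeyError(
                    f"stage-2 result missing for selected test "
                    f"{row['test_id']!r}"
                )
            r2 = s2.loc[row["test_id"]]
            direction = 1 if row["beta"] >= 0 else -1
            p_one = one_sided_confirmation(
                r2["p"], r2["beta"], direction, se=r2["se"]
            )
            rec["p_stage2_one_sided"] = p_one
            rec["confirmed_stage2"] = p_one < stage2_alpha
            meta = inverse_variance_meta(
                [
                    StageResult(row["test_id"], row["p"], row["beta"], row["se"], 1),
                    StageResult(row["test_id"], r2["p"], r2["beta"], r2["se"], 2),
                ]
            )
            rec["beta_meta"] = meta.beta_meta
            rec["se_meta"] = meta.se_meta
            rec["p_meta"] = meta.p_meta
            rec["p_het"] = meta.p_het
        out.append(rec)
    res = pd.DataFrame(out)
    sel = res["selected_stage1"] & res["p_meta"].notna()
    res["holm_p"] = np.nan
    if sel.any():
        res.loc[sel, "holm_p"] = holm_adjust(
            res.loc[sel, "p_meta"].to_numpy(), m_total
        )
    res["significant"] = (
        res["selected_stage1"]
        & res["confirmed_stage2"]
        & (res["holm_p"] < holm_alpha)
    )
    return res.sort_values("p_meta", na_position="last").reset_index(drop=True)


def run_targeted(
    results: pd.DataFrame,
    gene_list,
    fdr_threshold: float = 0.05,
    m_total: int | None = None,
) -> pd.DataFrame:
    """GWAS-locus targeted mode: BH FDR on a supplied gene list in a single
    merged sample, without a separate confirmation stage."""
    sub = results[results["gene"].isin(set(gene_list))].reset_index(drop=True)
    if sub.empty:
        sub["fdr_q"] = []
        sub["selected"] = []
        return sub
    sub["fdr_q"] = bh_fdr(sub["p"].to_numpy(), m_total)
    sub["selected"] = sub["fdr_q"] < fdr_threshold
    return sub.sort_values("p").reset_index(drop=True)
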