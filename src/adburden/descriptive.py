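"""Descriptive epidemiological measures for gene burdens: carrier
frequencies, attributable fractions, onset-age summaries and cross-stage
effect-size concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "carrier_frequency",
    "attributable_fraction",
    "onset_summary",
    "stage_concordance",
]


def carrier_frequency(carrier: np.ndarray, groups: np.ndarray) -> dict:
    """Percent of carriers per outcome group (carriers / group size x 100).

    Empty groups yield NaN.
    """
    carrier = np.asarray(carrier, bool)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        out[g] = float(100.0 * carrier[mask].mean()) if mask.any() else np.nan
    return out


def attributable_fraction(cf_case_pct: float, odds_ratio: float) -> float:
    """Attributable fraction (percent) among cases in an onset stratum:

        AF = CF_case * (OR - 1) / OR

    with the OR approximating the relative risk.  Protective burdens
    (OR < 1) give a negative AF, reported as-is.
    """
    if odds_ratio == 0:
        raise ValueError("odds ratio must be positive")
    return float(cf_case_pct * (odds_ratio - 1.0) / odds_ratio)


def onset_summary(onset_ages) -> dict:
    """Median and interquartile range of case-carrier onset ages
    (linear-interpolation percentiles)."""
    ages = np.asarray(onset_ages, float)
    ages = ages[~np.isnan(ages)]
    if ages.size == 0:
        return {"median": np.nan, "q25": np.nan, "q75": np.nan, "n": 0}
    q25, med, q75 = np.percentile(ages, [25, 50, 75])
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "n": int(ages.size),
    }


def stage_concordance(or_stage1, or_stage2) -> float:
    """Pearson correlation of log odds ratios between two stages.

    Returns NaN for fewer than three pairs.
    """
    a = np.log(np.asarray(or_stage1, float))
    b = np.log(np.asarray(or_stage2, float))
    if len(a) != len(b):
        raise ValueError("stage OR vectors must be paired")
    if len(a) < 3:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def gene_descriptives(
    carrier: np.ndarray,
    phenotypes: pd.DataFrame,
    or_eoad: float | None = None,
    or_load: float | None = None,
) -> dict:
    """Table-style summary for one gene x threshold selection.

    Attributable fractions are filled in when the per-group ORs are
    supplied (they come from the multinomial/reference logistic fits).
    """
    status = phenotypes["status"].to_numpy()
    cf = carrier_frequency(carrier, status)
    case_carrier = np.asarray(carrier, bool) & (status != "control")
    onset = onset_summary(
        phenotypes.loc[case_carrier, "age_or_onset"].to_numpy()
    )
    out = {
        "cf_eoad": cf.get("EOAD", np.nan),
        "cf_load": cf.get("LOAD", np.nan),
        "cf_control": cf.get("control", np.nan),
        "onset_median": onset["median"],
        "onset_q25": onset["q25"],
        "onset_q75": onset["q75"],
        "n_carriers": int(np.asarray(carrier, bool).sum()),
    }
    if or_eoad is not None:
        out["af_eoad"] = attributable_fraction(out["cf_eoad"], or_eoad)
    if or_load is not None:
        out["af_load"] = attributable_fraction(out["cf_load"], or_load)
    return out
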