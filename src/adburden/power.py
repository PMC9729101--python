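"""Simulation-based power analysis for the ordinal burden test.

A gene is summarized by its cumulative minor allele count (cMAC).  Each
simulation allocates that many alleles to the early-onset case, late-onset
case and control groups with multinomial probabilities proportional to
(n_eoad * OR_eoad, n_load * OR_load, n_control), drops them onto distinct
chromosomes within each group (so homozygous carriers arise naturally), and
runs the chosen burden test.  Power is the fraction of simulations with
P below the significance threshold; genes below the cMAC >= 10 testing gate
have power fixed at zero because they are never tested.

Covariate-free simulations collapse to a handful of distinct
(outcome, dosage) rows, so each test is a weighted proportional-odds fit and
large grids run in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .burden import fit_firth_logistic
from .ordinal import fit_proportional_odds, lrt_p

__all__ = ["PowerScenario", "PowerEstimate", "allocate_alleles",
           "estimate_power", "power_grid"]

# discovery-cohort composition used as the default scenario
STAGE1_N_EOAD = 4060
STAGE1_N_LOAD = 8592
STAGE1_N_CONTROL = 8693


@dataclass(frozen=True)
class PowerScenario:
    cmac: int
    or_eoad: float = 10.0
    or_load: float = 3.33
    n_eoad: int = STAGE1_N_EOAD
    n_load: int = STAGE1_N_LOAD
    n_control: int = STAGE1_N_CONTROL
    alpha: float = 1e-6
    n_sims: int = 1000
    test: str = "ordinal"  # ordinal | firth_cc | firth_eoad_vs_rest
    cmac_min: int = 10

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if min(self.or_eoad, self.or_load) <= 0:
            raise ValueError("odds ratios must be positive")
        if min(self.n_eoad, self.n_load, self.n_control) <= 0:
            raise ValueError("group sizes must be positive")


@dataclass
class PowerEstimate:
    scenario: PowerScenario
    power: float
    mc_se: float
    mean_beta: float
    n_failed: int = 0
    n_resampled: int = 0


def allocate_alleles(scenario: PowerScenario, rng) -> tuple[int, int, int]:
    """One multinomial allocation of the gene's alleles to the three groups.

    Allocations that exceed a group's chromosome count (2 x group size) are
    resampled; with rare-variant cMACs this essentially never triggers.
    """
    probs = np.array(
        [
            scenario.n_eoad * scenario.or_eoad,
            scenario.n_load * scenario.or_load,
            scenario.n_control * 1.0,
        ]
    )
    probs /= probs.sum()
    caps = np.array(
        [2 * scenario.n_eoad, 2 * scenario.n_load, 2 * scenario.n_control]
    )
    for attempt in range(1000):
        counts = rng.multinomial(scenario.cmac, probs)
        if np.all(counts <= caps):
            if attempt:
                warnings.warn(f"allele allocation resampled {attempt} times")
            return tuple(int(c) for c in counts), attempt
    raise RuntimeError("could not allocate alleles within group capacities")


def _group_dosage_counts(n_alleles: int, n_samples: int, rng) -> np.ndarray:
    """Place alleles on distinct chromosomes of a diploid group; returns
    (n_het, n_hom) carriers."""
    if n_alleles == 0:
        return np.array([0, 0])
    chroms = rng.choice(2 * n_samples, size=n_alleles, replace=False)
    persons, counts = np.unique(chroms // 2, return_counts=True)
    return np.array([(counts == 1).sum(), (counts == 2).sum()])


def _weighted_rows(alloc, sizes, rng):
    """Collapse a simulated cohort to weighted (outcome, dosage) rows."""
    ys, ds, ws = [], [], []
    for grp, (a, n) in enumerate(zip(alloc, sizes)):
        n_het, n_hom = _group_dosage_counts(a, n, rng)
        n_ref = n - n_het - n_hom
        for dose, cnt in ((0, n_ref), (1, n_het), (2, n_hom)):
            if cnt > 0:
                ys.append(grp)
                ds.append(dose)
                ws.append(cnt)
    return np.array(ys), np.array(ds, float), np.array(ws, float)


def _run_one_test(scenario, y_grp, dose, w):
    """Returns (p, beta) for one simulated data set.

    ``y_grp`` indexes (EOAD, LOAD, control) = (0, 1, 2).
    """
    if scenario.test == "ordinal":
        if np.ptp(dose) == 0:
            return 1.0, 0.0
        y = np.array([2, 1, 0])[y_grp]  # control=0 < LOAD=1 < EOAD=2
        null = fit_proportional_odds(y, None, weights=w)
        full = fit_proportional_odds(y, dose[:, None], weights=w)
        if not full.converged:
            return np.nan, np.nan
        return lrt_p(full, null), float(full.beta[0])
    # Firth variants: the weighted rows expand to small per-row counts
    yy = np.repeat(y_grp, w.astype(int))
    dd = np.repeat(dose, w.astype(int))
    if scenario.test == "firth_cc":
        yb = (yy < 2).astype(float)  # any case vs control
    elif scenario.test == "firth_eoad_vs_rest":
        yb = (yy == 0).astype(float)
    else:
        raise ValueError(f"unknown test {scenario.test!r}")
    beta, _, p = fit_firth_logistic(yb, dd)
    return p, beta


def estimate_power(scenario: PowerScenario, rng=None) -> PowerEstimate:
    """Monte-Carlo power of the burden test under the scenario.

    Genes below the cMAC testing gate are never analyzed, so their power is
    exactly zero by definition.
    """
    rng = np.random.default_rng(rng)
    if scenario.cmac < scenario.cmac_min:
        return PowerEstimate(scenario, 0.0, 0.0, np.nan)
    sizes = (scenario.n_eoad, scenario.n_load, scenario.n_control)
    hits = 0
    betas = []
    n_failed = 0
    n_resampled = 0
    n_used = 0
    for _ in range(scenario.n_sims):
        alloc, resamples = allocate_alleles(scenario, rng)
        n_resampled += resamples
        y_grp, dose, w = _weighted_rows(alloc, sizes, rng)
        p, beta = _run_one_test(scenario, y_grp, dose, w)
        if np.isnan(p):
            n_failed += 1
            continue
        n_used += 1
        if p < scenario.alpha:
            hits += 1
        betas.append(beta)
    if n_used == 0:
        return PowerEstimate(scenario, np.nan, np.nan, np.nan, n_failed)
    power = hits / n_used
    mc_se = float(np.sqrt(power * (1 - power) / n_used))
    return PowerEstimate(
        scenario, float(power), mc_se,
        float(np.mean(betas)) if betas else np.nan,
        n_failed, n_resampled,
    )


def power_grid(
    cmac_values,
    or_pairs,
    template: PowerScenario | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Power over a cMAC x (OR_eoad, OR_load) grid.

    Each grid cell reuses the same random-number stream (common random
    numbers), which smooths monotonicity along both axes.
    """
    if template is None:
        template = PowerScenario(cmac=10)
    rows = []
    for or_eoad, or_load in or_pairs:
        for cmac in cmac_values:
            sc = replace(
                template, cmac=int(cmac), or_eoad=or_eoad, or_load=or_load
            )
            est = estimate_power(sc, rng=np.random.default_rng(seed))
            rows.append(
                {
                    "cMAC": int(cmac),
                    "or_eoad": or_eoad,
                    "or_load": or_load,
                    "power": est.power,
                    "mc_se": est.mc_se,
                    "mean_beta": est.mean_beta,
                }
            )
    return pd.DataFrame(rows)
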