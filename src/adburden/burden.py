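"""Gene burden testing on genotype posteriors.

The burden of a gene is the per-sample sum of minor-allele dosages over the
variants in a deleteriousness selection.  Genotypes are uncertain (posterior
triples over hom-ref/het/hom-alt derived from read support), so the ordinal
burden test is run repeatedly on independently sampled hard genotypes and the
arithmetic mean of the per-repetition likelihood-ratio P values is reported.

Companion estimators: multinomial logistic per age-at-onset bin odds ratios
(for interpretable case/control effect sizes), and Firth (Jeffreys-prior
penalized) logistic regression, which stays finite under complete separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .ordinal import OrdinalModelFit, fit_proportional_odds, lrt_p
from .prioritize import BurdenSelection

__all__ = [
    "BurdenTestResult",
    "AgeBinORs",
    "sample_genotypes",
    "burden_score",
    "carrier_flag",
    "fit_ordinal",
    "averaged_burden_test",
    "fit_multinomial_or",
    "fit_firth_logistic",
    "AGE_BINS",
]

# age-at-onset bins used for descriptive per-bin odds ratios
AGE_BINS = ((-np.inf, 65.0), (65.0, 70.0), (70.0, 80.0), (80.0, np.inf))
AGE_BIN_LABELS = ("<=65", "65-70", "70-80", ">80")


@dataclass
class BurdenTestResult:
    gene_id: str
    threshold: str
    cmac: int
    n_reps: int
    n_reps_used: int
    p_avg: float
    p_sd: float
    beta_avg: float
    se_avg: float
    carriers: dict = field(default_factory=dict)
    direction: int = 0
    converged: bool = True
    message: str = ""

    def to_row(self) -> dict:
        row = {
            "gene": self.gene_id,
            "threshold": self.threshold,
            "cMAC": self.cmac,
            "beta": self.beta_avg,
            "se": self.se_avg,
            "p_avg": self.p_avg,
            "p_sd": self.p_sd,
            "n_reps_used": self.n_reps_used,
            "direction": self.direction,
        }
        for grp, cnt in self.carriers.items():
            row[f"carriers_{grp}"] = cnt
        return row


@dataclass
class AgeBinORs:
    bins: dict  # label -> (or, lo, hi)
    eoad_vs_control: tuple | None = None
    load_vs_control: tuple | None = None


def _prior_from_maf(maf: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype prior at the internal minor allele frequency."""
    maf = np.asarray(maf, float)
    return np.stack(
        [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2], axis=-1
    )


def sample_genotypes(genotypes, selection, rng, prior=None) -> np.ndarray:
    """Draw one integer dosage matrix (n_samples, n_variants) from posteriors.

    Each entry is drawn categorically from its posterior triple; missing
    entries (depth below the calling threshold) are drawn from ``prior``
    (default: Hardy-Weinberg at the variant's internal MAF).
    """
    idx = genotypes.variant_index(selection.variant_ids)
    post = genotypes.posterior[:, idx, :].copy()
    miss = genotypes.missing[:, idx]
    if miss.any():
        if prior is None:
            prior = _prior_from_maf(selection.maf_internal)
        prior = np.broadcast_to(prior, post.shape)
        post[miss] = prior[miss]
    cum = np.cumsum(post, axis=-1)
    cum /= cum[..., -1:]
    u = rng.random(post.shape[:2])
    return (u[..., None] > cum[..., :2]).sum(axis=-1).astype(np.int64)


def burden_score(dosage: np.ndarray) -> np.ndarray:
    """Additive burden: per-sample sum of allele dosages over the selection."""
    dosage = np.atleast_2d(np.asarray(dosage))
    return dosage.sum(axis=1)


def carrier_flag(genotypes, selection, prior=None) -> np.ndarray:
    """Carrier status from expected (posterior-mean) dosages, threshold 0.5.

    A sample is a carrier when its summed expected dosage over the selected
    variants is >= 0.5 (boundary inclusive).
    """
    idx = genotypes.variant_index(selection.variant_ids)
    post = genotypes.posterior[:, idx, :].copy()
    miss = genotypes.missing[:, idx]
    if miss.any():
        if prior is None:
            prior = _prior_from_maf(selection.maf_internal)
        prior = np.broadcast_to(prior, post.shape)
        post[miss] = prior[miss]
    expected = post[..., 1] + 2.0 * post[..., 2]
    return expected.sum(axis=1) >= 0.5


def fit_ordinal(outcome, score, covariates=None, start=None) -> tuple[
    OrdinalModelFit, OrdinalModelFit | None
]:
    """Fit the proportional-odds burden model and its burden-free null.

    Returns ``(full_fit, null_fit)``.  A constant score has no identifiable
    burden coefficient: the full model is then the null model and the caller
    receives ``(null, null)`` so the LRT statistic is exactly zero.
    """
    outcome = np.asarray(outcome)
    score = np.asarray(score, float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(outcome):
            covariates = covariates.T
        X_null = covariates
        X_full = np.column_stack([score, covariates])
    else:
        X_null = None
        X_full = score[:, None]
    if np.ptp(score) == 0:
        null = fit_proportional_odds(outcome, X_null)
        return null, null
    null = fit_proportional_odds(outcome, X_null)
    full = fit_proportional_odds(outcome, X_full, start=start)
    return full, null


def averaged_burden_test(
    genotypes,
    selection: BurdenSelection,
    phenotypes: pd.DataFrame,
    n_reps: int = 25,
    rng=None,
    covariate_cols: tuple | None = None,
    prior=None,
) -> BurdenTestResult:
    """Posterior-averaged ordinal burden test for one gene x threshold.

    Runs the LRT ``n_reps`` times on independently sampled genotypes and
    averages P, beta and SE arithmetically across converged repetitions.
    """
    if not selection.testable:
        raise ValueError(
            f"selection {selection.gene_id}/{selection.threshold} has "
            f"cMAC {selection.cmac} < minimum and is not testable"
        )
    rng = np.random.default_rng(rng)
    outcome = phenotypes["outcome"].to_numpy()
    if covariate_cols is None:
        covariate_cols = [c for c in phenotypes.columns if c.startswith("cov")]
    cov = phenotypes[list(covariate_cols)].to_numpy() if covariate_cols else None

    ps, betas, ses = [], [], []
    n_failed = 0
    start = None
    for _ in range(n_reps):
        dosage = sample_genotypes(genotypes, selection, rng, prior=prior)
        score = burden_score(dosage)
        full, null = fit_ordinal(outcome, score, cov, start=start)
        if full is not null and not full.converged:
            n_failed += 1
            continue
        if full is null:
            ps.append(1.0)
            betas.append(0.0)
            ses.append(np.nan)
            continue
        start = np.concatenate([full.cutpoints, full.beta])
        ps.append(lrt_p(full, null))
        betas.append(full.beta[0])
        ses.append(full.beta_se[0])

    carriers = carrier_flag(genotypes, selection, prior=prior)
    status = phenotypes["status"].to_numpy()
    carrier_counts = {
        grp: int(carriers[status == grp].sum())
        for grp in ("EOAD", "LOAD", "control")
    }
    if not ps:
        return BurdenTestResult(
            gene_id=selection.gene_id,
            threshold=str(selection.threshold),
            cmac=selection.cmac,
            n_reps=n_reps,
            n_reps_used=0,
            p_avg=np.nan,
            p_sd=np.nan,
            beta_avg=np.nan,
            se_avg=np.nan,
            carriers=carrier_counts,
            converged=False,
            message="all repetitions failed to converge",
        )
    beta_avg = float(np.mean(betas))
    return BurdenTestResult(
        gene_id=selection.gene_id,
        threshold=str(selection.threshold),
        cmac=selection.cmac,
        n_reps=n_reps,
        n_reps_used=len(ps),
        p_avg=float(np.mean(ps)),
        p_sd=float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0,
        beta_avg=beta_avg,
        se_avg=float(np.nanmean(ses)),
        carriers=carrier_counts,
        direction=int(np.sign(beta_avg)),
        converged=n_failed < n_reps,
        message=f"{n_failed} repetitions failed" if n_failed else "",
    )


def _binary_logistic_or(y, score, covariates=None):
    import statsmodels.api as sm

    X = np.column_stack(
        [np.ones(len(y)), score]
        + ([covariates] if covariates is not None else [])
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b, se = res.params[1], res.bse[1]
    return float(np.exp(b)), float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))


def fit_multinomial_or(
    phenotypes: pd.DataFrame,
    score,
    covariate_cols: tuple | None = None,
) -> AgeBinORs:
    """Reference case/control ORs per age-at-onset bin vs controls.

    Cases are binned by onset age (<=65, 65-70, 70-80, >80) and a multinomial
    logistic regression with controls as the reference category yields one
    burden-score OR with a Wald 95% CI per bin.  Aggregate EOAD-vs-control and
    LOAD-vs-control ORs come from plain logistic fits on the subset.
    """
    import statsmodels.api as sm

    score = np.asarray(score, float)
    if covariate_cols is None:
        covariate_cols = [c for c in phenotypes.columns if c.startswith("cov")]
    cov = (
        phenotypes[list(covariate_cols)].to_numpy() if covariate_cols else None
    )
    outcome = phenotypes["outcome"].to_numpy()
    onset = phenotypes["age_or_onset"].to_numpy()

    is_case = outcome > 0
    cat = np.zeros(len(outcome), dtype=int)  # 0 = control reference
    labels_present = []
    for b, ((lo, hi), lab) in enumerate(zip(AGE_BINS, AGE_BIN_LABELS), start=1):
        mask = is_case & (onset > lo) & (onset <= hi)
        if mask.sum() == 0:
            warnings.warn(f"age bin {lab} empty; omitted from multinomial fit")
            continue
        cat[mask] = len(labels_present) + 1
        labels_present.append(lab)

    X = np.column_stack(
        [np.ones(len(cat)), score] + ([cov] if cov is not None else [])
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(cat, X).fit(disp=0, maxiter=300, method="newton")
    bins = {}
    for j, lab in enumerate(labels_present):
        b = res.params[1, j]
        se = res.bse[1, j]
        bins[lab] = (
            float(np.exp(b)),
            float(np.exp(b - 1.96 * se)),
            float(np.exp(b + 1.96 * se)),
        )
    out = AgeBinORs(bins=bins)
    ctrl = outcome == 0
    if (outcome == 2).any():
        m = ctrl | (outcome == 2)
        out.eoad_vs_control = _binary_logistic_or(
            (outcome[m] == 2).astype(int), score[m],
            cov[m] if cov is not None else None,
        )
    if (outcome == 1).any():
        m = ctrl | (outcome == 1)
        out.load_vs_control = _binary_logistic_or(
            (outcome[m] == 1).astype(int), score[m],
            cov[m] if cov is not None else None,
        )
    return out


def _firth_penalized_ll(y, X, beta):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    W = p * (1 - p)
    info = X.T @ (W[:, None] * X)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _fit_firth(y, X, max_iter=100, tol=1e-8):
    """Newton iteration on Firth's modified score equations."""
    n, p = X.shape
    beta = np.zeros(p)
    pll = _firth_penalized_ll(y, X, beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        info = X.T @ (W[:, None] * X)
        info_inv = np.linalg.inv(info)
        # hat-matrix diagonal of the W-weighted projection
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            pll_new = _firth_penalized_ll(y, X, cand)
            if pll_new > pll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        pll = _firth_penalized_ll(y, X, beta)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    info = X.T @ (W[:, None] * X)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, pll, converged


def fit_firth_logistic(y, score, covariates=None):
    """Firth bias-reduced logistic regression of a binary outcome on the
    burden score (plus covariates).

    Returns ``(beta, se, p)`` for the score term, with the P value from a
    penalized likelihood-ratio test; estimates stay finite under complete
    separation.
    """
    y = np.asarray(y, float)
    score = np.asarray(score, float)
    cols = [np.ones(len(y)), score]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        cols.append(covariates)
    X = np.column_stack(cols)
    beta, se, pll_full, conv = _fit_firth(y, X)
    X0 = np.delete(X, 1, axis=1)
    _, _, pll_null, conv0 = _fit_firth(y, X0)
    stat = max(0.0, 2.0 * (pll_full - pll_null))
    p = float(chi2.sf(stat, 1))
    if not (conv and conv0):
        warnings.warn("Firth fit hit the iteration cap")
    return float(beta[1]), float(se[1]), p


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal P for a coefficient estimate."""
    return float(2.0 * norm.sf(abs(beta) / se))
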