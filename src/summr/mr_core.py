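"""Two-sample Mendelian randomization estimators and sensitivity analyses.

The causal model: for instrument j, Γ_j = β·γ_j + α_j, where γ_j is the
SNP-exposure effect, Γ_j the SNP-outcome effect, β the causal effect of the
exposure on the outcome, and α_j a (possibly zero) direct pleiotropic
effect.  Estimators:

* ``ivw`` — inverse-variance-weighted regression of Γ on γ through the
  origin; consistent when all instruments are valid.  Multiplicative
  random-effects: the fixed-effect SE is inflated by sqrt(Q/(k−1)) when
  Cochran's Q exceeds its degrees of freedom (floored at 1 by default).
* ``mr_egger`` — weighted regression with intercept; the intercept
  estimates the mean directional pleiotropic effect under InSIDE, the
  slope remains consistent under directional pleiotropy.  t inference
  with k−2 df.
* ``weighted_median`` — weighted median of per-SNP Wald ratios; consistent
  when valid instruments carry >= 50% of the weight.  SE by seeded
  parametric bootstrap.

Also here: leave-one-out diagnostics, Benjamini–Hochberg FDR with the
significant/suggestive tiering rule, and an analytic binary-outcome power
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from .gwas_io import HarmonizedPair

Z95 = 1.96  # conventional two-sided 95% multiplier used throughout reporting

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"


@dataclass
class MRResult:
    """One estimator's causal estimate with diagnostics and FDR tier."""

    exposure: str
    outcome: str
    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    fdr_q: float | None = None
    tier: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - Z95 * self.se))
        self.ci_high = float(np.exp(self.beta + Z95 * self.se))


@dataclass
class LeaveOneOutResult:
    exposure: str
    outcome: str
    rows: pd.DataFrame  # dropped_variant_id, beta, se, pval
    flag_sign_flip: bool
    flag_significance_flip: bool


@dataclass
class PowerInput:
    """Inputs of the analytic binary-outcome power approximation."""

    n_outcome: int
    case_proportion: float
    r2_sum: float
    or_hypothesized: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.case_proportion < 1:
            raise ValidationError("case_proportion must lie in (0,1)")
        if not 0 <= self.r2_sum < 1:
            raise ValidationError("r2_sum must lie in [0,1)")


# ---------------------------------------------------------------------------
# estimator cores on plain arrays (fast path for simulations)

def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float):
    """Single-instrument causal estimate Γ/γ with first-order SE."""
    if gamma == 0:
        raise UndefinedRatioError("Wald ratio undefined for gamma = 0")
    return Gamma / gamma, se_Gamma / abs(gamma)


def ivw_estimate(gamma, se_gamma, Gamma, se_Gamma, floor_overdispersion: bool = True):
    """IVW core: returns (beta, se, pval, Q, q_df, q_pval).

    Weights 1/se_Γ²; beta = Σwγ Γ / Σwγ²; fixed-effect se (Σwγ²)^(−1/2);
    multiplicative random-effects se scaled by sqrt(Q/(k−1)), floored at 1
    unless ``floor_overdispersion`` is False.
    """
    g = np.asarray(gamma, float)
    G = np.asarray(Gamma, float)
    sG = np.asarray(se_Gamma, float)
    w = 1.0 / sG**2
    swg2 = np.sum(w * g**2)
    beta = np.sum(w * g * G) / swg2
    se0 = swg2**-0.5
    q = float(np.sum(w * (G - beta * g) ** 2))
    q_df = g.size - 1
    q_pval = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    scale = np.sqrt(q / q_df) if q_df > 0 else 1.0
    if floor_overdispersion:
        scale = max(1.0, scale)
    se = se0 * scale
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return float(beta), float(se), pval, q, q_df, q_pval


def egger_estimate(gamma, se_gamma, Gamma, se_Gamma):
    """MR-Egger core: returns (slope, slope_se, slope_p, icpt, icpt_se, icpt_p, Q, q_df).

    Signs oriented so every γ_j >= 0; WLS of Γ on γ with intercept,
    weights 1/se_Γ²; SEs scaled by max(1, residual scale); t with k−2 df.
    """
    g = np.asarray(gamma, float).copy()
    G = np.asarray(Gamma, float).copy()
    sG = np.asarray(se_Gamma, float)
    k = g.size
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    flip = g < 0
    g[flip] *= -1
    G[flip] *= -1
    w = 1.0 / sG**2
    X = np.column_stack([np.ones(k), g])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * G))
    resid = G - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = k - 2
    sigma = max(1.0, np.sqrt(q / q_df))
    cov = np.linalg.inv(xtwx) * sigma**2
    ses = np.sqrt(np.diag(cov))
    tvals = coef / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), q_df)
    return (
        float(coef[1]), float(ses[1]), float(pvals[1]),
        float(coef[0]), float(ses[0]), float(pvals[0]),
        q, q_df,
    )


def weighted_median_estimate(gamma, se_gamma, Gamma, se_Gamma, n_boot=1000, seed=None):
    """Weighted-median core: returns (beta, se).

    Ratio estimates b_j = Γ_j/γ_j with weights ∝ γ_j²/se_Γj²; the estimate
    interpolates the weighted empirical distribution at percentile 0.5
    (p_j = S_j − w_j/2 with S the cumulative normalized weights).  SE from a
    parametric bootstrap resampling (γ̂, Γ̂) from normals with their SEs.
    """
    g = np.asarray(gamma, float)
    sg = np.asarray(se_gamma, float)
    G = np.asarray(Gamma, float)
    sG = np.asarray(se_Gamma, float)
    if g.size < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    if seed is None:
        raise ValidationError("weighted_median requires an explicit seed for the bootstrap")
    beta = _weighted_median_point(G / g, g**2 / sG**2)
    rng = np.random.default_rng(seed)
    gb = rng.normal(g, sg, size=(n_boot, g.size))
    Gb = rng.normal(G, sG, size=(n_boot, g.size))
    ests = np.empty(n_boot)
    for i in range(n_boot):
        ests[i] = _weighted_median_point(Gb[i] / gb[i], gb[i] ** 2 / sG**2)
    return float(beta), float(np.std(ests, ddof=1))


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="mergesort")
    b = b[order]
    w = w[order] / np.sum(w)
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, b))


# ---------------------------------------------------------------------------
# HarmonizedPair-level API

def ivw(pair: HarmonizedPair, floor_overdispersion: bool = True) -> MRResult:
    """Random-effects IVW estimate for an exposure–outcome pair.

    Falls back to the Wald ratio (with a note) when only one instrument
    survives QC.
    """
    g, sg, G, sG = pair.arrays()
    if g.size == 0:
        raise InsufficientInstrumentsError("no instruments in pair")
    if g.size == 1:
        b, se = wald_ratio(g[0], sg[0], G[0], sG[0])
        p = float(2.0 * stats.norm.sf(abs(b) / se))
        return MRResult(
            pair.exposure_name, pair.outcome_name, "wald_ratio", 1, b, se, p,
            note="single instrument: IVW fell back to Wald ratio",
        )
    b, se, p, q, q_df, q_p = ivw_estimate(g, sg, G, sG, floor_overdispersion)
    return MRResult(
        pair.exposure_name, pair.outcome_name, "ivw", g.size, b, se, p,
        q_stat=q, q_df=q_df, q_pval=q_p,
    )


def mr_egger(pair: HarmonizedPair) -> MRResult:
    g, sg, G, sG = pair.arrays()
    slope, slope_se, slope_p, icpt, icpt_se, icpt_p, q, q_df = egger_estimate(g, sg, G, sG)
    return MRResult(
        pair.exposure_name, pair.outcome_name, "egger", g.size,
        slope, slope_se, slope_p,
        q_stat=q, q_df=q_df, q_pval=float(stats.chi2.sf(q, q_df)),
        egger_intercept=icpt, egger_intercept_se=icpt_se, egger_intercept_pval=icpt_p,
    )


def weighted_median(pair: HarmonizedPair, n_boot: int = 1000, seed: int | None = None) -> MRResult:
    g, sg, G, sG = pair.arrays()
    b, se = weighted_median_estimate(g, sg, G, sG, n_boot=n_boot, seed=seed)
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else 0.0
    return MRResult(pair.exposure_name, pair.outcome_name, "weighted_median", g.size, b, se, p)


def leave_one_out(pair: HarmonizedPair) -> LeaveOneOutResult:
    """Re-estimate IVW omitting each instrument in turn.

    Flags are raised when any omission flips the sign of the estimate or
    moves its p-value across 0.05.
    """
    g, sg, G, sG = pair.arrays()
    k = g.size
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full_b, _, full_p, *_ = ivw_estimate(g, sg, G, sG)
    rows = []
    sign_flip = sig_flip = False
    for i in range(k):
        mask = np.arange(k) != i
        b, se, p, *_ = ivw_estimate(g[mask], sg[mask], G[mask], sG[mask])
        rows.append(
            {"dropped_variant_id": pair.data["variant_id"].iloc[i], "beta": b, "se": se, "pval": p}
        )
        if np.sign(b) != np.sign(full_b) and full_b != 0 and b != 0:
            sign_flip = True
        if (p < 0.05) != (full_p < 0.05):
            sig_flip = True
    return LeaveOneOutResult(
        pair.exposure_name, pair.outcome_name, pd.DataFrame(rows), sign_flip, sig_flip
    )


def bh_fdr(pvals, tiers: bool = True, q_threshold: float = 0.05, p_threshold: float = 0.05):
    """Benjamini–Hochberg q-values with significant/suggestive tiering.

    The family is one exposure's tests across all outcomes.  Tier rule:
    significant if q < 0.05; suggestive if p < 0.05 <= q; otherwise null.
    """
    p = np.asarray(pvals, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if not tiers:
        return q, None
    labels = np.where(
        q < q_threshold, TIER_SIGNIFICANT, np.where(p < p_threshold, TIER_SUGGESTIVE, TIER_NULL)
    )
    return q, list(labels)


def attach_fdr(results: list[MRResult]) -> list[MRResult]:
    """Assign fdr_q and tier across a family of MRResults (in place)."""
    if not results:
        return results
    q, labels = bh_fdr([r.pval for r in results])
    for r, qi, ti in zip(results, q, labels):
        r.fdr_q = float(qi)
        r.tier = ti
    return results


def power_binary(inp: PowerInput) -> float:
    """Analytic power of two-sample MR with a binary outcome.

    power = Φ(|ln OR|·sqrt(N·R²·K·(1−K)) − z_{1−α/2}) with K the case
    proportion and R² the summed instrument variance explained.
    """
    z_crit = stats.norm.isf(inp.alpha / 2)
    if inp.r2_sum == 0:
        import warnings

        warnings.warn("r2_sum = 0: power equals the alpha-level tail", stacklevel=2)
        return float(stats.norm.cdf(-z_crit))
    ncp = abs(np.log(inp.or_hypothesized)) * np.sqrt(
        inp.n_outcome * inp.r2_sum * inp.case_proportion * (1 - inp.case_proportion)
    )
    return float(stats.norm.cdf(ncp - z_crit))


def run_all_estimators(
    pair: HarmonizedPair, n_boot: int = 1000, seed: int | None = 0
) -> list[MRResult]:
    """IVW, MR-Egger, and weighted median on one pair (skips those whose
    instrument minimum is not met, noting the skip on the IVW result)."""
    out = [ivw(pair)]
    if pair.n_snp >= 3:
        out.append(mr_egger(pair))
        out.append(weighted_median(pair, n_boot=n_boot, seed=seed))
    else:
        out[0].note = (out[0].note + "; " if out[0].note else "") + (
            "egger/weighted_median skipped (<3 instruments)"
        )
    return out
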