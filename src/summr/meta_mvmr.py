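"""Fixed-effect meta-analysis and multivariable MR.

Meta-analysis pools one exposure–outcome estimate across independent GWAS
cohorts under a single-true-effect assumption (inverse-variance weights).

Multivariable MR (MVMR) regresses SNP-outcome effects jointly on the
per-exposure SNP-effect matrix (weighted, no intercept), yielding each
exposure's direct effect conditional on the others.  Collinear exposure
sets are reduced beforehand by a weighted lasso with cross-validated
penalty (1-SE rule).  Comparing an exposure's total effect (univariable
MR) with its direct effect (MVMR conditioning on a candidate mediator)
indicates mediation when the two differ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .errors import CollinearityError, UnderdeterminedModelError, ValidationError
from .gwas_io import AssociationTable, LDMatrix, harmonize_pair
from .instruments import SelectionParams, build_instrument_set, ld_clump
from .mr_core import Z95, MRResult

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    estimates_in: list[tuple[float, float, str]]
    pooled_beta: float
    pooled_se: float
    pooled_pval: float
    heterogeneity_q: float
    het_pval: float
    pooled_or: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.pooled_or = float(np.exp(self.pooled_beta))
        self.ci_low = float(np.exp(self.pooled_beta - Z95 * self.pooled_se))
        self.ci_high = float(np.exp(self.pooled_beta + Z95 * self.pooled_se))


@dataclass
class MVMRResult:
    """Per-exposure direct effects conditional on the other columns."""

    outcome: str
    table: pd.DataFrame  # exposure, direct_beta, se, or_, ci_low, ci_high, pval
    retained_exposures: list[str]
    n_snp: int
    conditioned_on: list[str] = field(default_factory=list)

    def row(self, exposure: str) -> pd.Series:
        hit = self.table[self.table["exposure"] == exposure]
        if hit.empty:
            raise ValidationError(f"exposure {exposure!r} not in MVMR fit")
        return hit.iloc[0]


@dataclass
class MediationGap:
    """Total (univariable) minus direct (multivariable) effect."""

    exposure: str
    outcome: str
    mediator_name: str
    total_beta: float
    direct_beta: float
    gap: float
    gap_se: float  # independent-estimates approximation (conservative)


def meta_fixed(estimates: list[tuple[float, float] | tuple[float, float, str]]) -> MetaResult:
    """Fixed-effects inverse-variance pooling across cohorts.

    A single estimate passes through unchanged with a warning; Cochran's Q
    across cohorts (k−1 df) quantifies between-cohort heterogeneity.
    """
    if not estimates:
        raise ValidationError("meta_fixed needs at least one estimate")
    labeled = [
        (float(e[0]), float(e[1]), e[2] if len(e) > 2 else f"cohort_{i + 1}")
        for i, e in enumerate(estimates)
    ]
    if any(se <= 0 for _, se, _ in labeled):
        raise ValidationError("all standard errors must be positive")
    b = np.array([x[0] for x in labeled])
    se = np.array([x[1] for x in labeled])
    if len(labeled) == 1:
        warnings.warn("meta_fixed called with a single estimate: passthrough", stacklevel=2)
        p = float(2 * stats.norm.sf(abs(b[0]) / se[0]))
        return MetaResult(labeled, float(b[0]), float(se[0]), p, 0.0, 1.0)
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - pooled) ** 2))
    het_p = float(stats.chi2.sf(q, len(labeled) - 1))
    p = float(2 * stats.norm.sf(abs(pooled) / pooled_se))
    return MetaResult(labeled, pooled, pooled_se, p, q, het_p)


def mvmr_fit(
    design: pd.DataFrame,
    Gamma: np.ndarray,
    se_Gamma: np.ndarray,
    outcome_name: str = "outcome",
    conditioned_on: list[str] | None = None,
) -> MVMRResult:
    """Weighted multiple regression of Γ on the SNP × exposure matrix.

    No intercept; weights 1/se_Γ²; SEs scaled by max(1, residual scale);
    p two-sided normal.  All-zero columns are tolerated (minimum-norm fit,
    estimate 0, warning); any other rank deficiency raises
    CollinearityError directing the caller to lasso_select_exposures.
    """
    X = design.to_numpy(float)
    names = list(design.columns)
    G = np.asarray(Gamma, float)
    sG = np.asarray(se_Gamma, float)
    k, p = X.shape
    if k <= p:
        raise UnderdeterminedModelError(
            f"{k} instruments for {p} exposures: model underdetermined"
        )
    w = 1.0 / sG**2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Gw = G * sw
    rank = np.linalg.matrix_rank(Xw)
    zero_cols = np.all(X == 0, axis=0)
    if rank < p:
        if zero_cols.any() and np.linalg.matrix_rank(Xw[:, ~zero_cols]) == (~zero_cols).sum():
            warnings.warn(
                f"all-zero exposure column(s) {[n for n, z in zip(names, zero_cols) if z]}: "
                "minimum-norm fit, estimate 0",
                stacklevel=2,
            )
            coef, *_ = np.linalg.lstsq(Xw, Gw, rcond=None)
            cov0 = np.linalg.pinv(Xw.T @ Xw)
        else:
            raise CollinearityError(
                "rank-deficient MVMR design: pre-select exposures with lasso_select_exposures"
            )
    else:
        xtx = Xw.T @ Xw
        coef = np.linalg.solve(xtx, Xw.T @ Gw)
        cov0 = np.linalg.inv(xtx)
    resid = Gw - Xw @ coef
    q = float(resid @ resid)
    df = k - rank
    sigma = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov0)) * sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2.0 * stats.norm.sf(np.abs(coef) / ses)
    rows = pd.DataFrame(
        {
            "exposure": names,
            "direct_beta": coef,
            "se": ses,
            "or_": np.exp(coef),
            "ci_low": np.exp(coef - Z95 * ses),
            "ci_high": np.exp(coef + Z95 * ses),
            "pval": pvals,
        }
    )
    return MVMRResult(outcome_name, rows, names, k, conditioned_on or [])


def build_mvmr_design(
    exposures: list[AssociationTable],
    outcome: AssociationTable,
    ld: LDMatrix | None = None,
    params: SelectionParams = SelectionParams(),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Union-of-instruments design for MVMR.

    Per-exposure selection, union of ids, joint re-clump (ascending best
    p across exposures), then harmonization of every id against each
    exposure and the outcome.  Returns (design, Γ, se_Γ, variant_ids).
    """
    union: dict[str, float] = {}
    for tab in exposures:
        iset = build_instrument_set(tab, ld, params)
        sub = tab.data.set_index("variant_id")
        for vid in iset.variant_ids:
            pv = float(sub.loc[vid, "pval"])
            union[vid] = min(pv, union.get(vid, 1.0))
    if not union:
        raise ValidationError("no instruments selected for any exposure")
    # joint re-clump on a synthetic table carrying each id's best p
    ref = exposures[0].data.set_index("variant_id")
    rows = []
    for vid, pv in union.items():
        for tab in exposures:
            t = tab.data.set_index("variant_id")
            if vid in t.index:
                src = t.loc[vid]
                break
        rows.append(
            {
                "variant_id": vid, "chrom": src["chrom"], "pos": src["pos"],
                "effect_allele": src["effect_allele"], "other_allele": src["other_allele"],
                "eaf": src["eaf"], "beta": src["beta"], "se": src["se"],
                "pval": pv, "n": src["n"],
            }
        )
    union_table = AssociationTable("union", "quantitative", pd.DataFrame(rows))
    kept = ld_clump(
        list(union_table.data["variant_id"]), union_table, ld,
        params.clump_r2, params.clump_window_bp,
    )
    # harmonize every exposure and the outcome to the first exposure's orientation
    anchor = exposures[0]
    pairs = [harmonize_pair(anchor, tab, kept) for tab in exposures[1:]]
    out_pair = harmonize_pair(anchor, outcome, kept)
    shared = set(out_pair.data["variant_id"])
    for pr in pairs:
        shared &= set(pr.data["variant_id"])
    anchor_sub = anchor.data.set_index("variant_id")
    ids = [v for v in kept if v in shared and v in anchor_sub.index]
    design = pd.DataFrame(index=ids)
    design[anchor.trait_name] = [float(anchor_sub.loc[v, "beta"]) for v in ids]
    for tab, pr in zip(exposures[1:], pairs):
        sub = pr.data.set_index("variant_id")
        design[tab.trait_name] = [float(sub.loc[v, "Gamma"]) for v in ids]
    osub = out_pair.data.set_index("variant_id")
    G = np.array([float(osub.loc[v, "Gamma"]) for v in ids])
    sG = np.array([float(osub.loc[v, "se_Gamma"]) for v in ids])
    return design, G, sG, ids


def mvmr_ivw(
    exposures: list[AssociationTable],
    outcome: AssociationTable,
    ld: LDMatrix | None = None,
    params: SelectionParams = SelectionParams(),
    conditioned_on: list[str] | None = None,
) -> MVMRResult:
    """End-to-end MVMR: instrument union construction + weighted fit."""
    design, G, sG, _ = build_mvmr_design(exposures, outcome, ld, params)
    return mvmr_fit(design, G, sG, outcome.trait_name, conditioned_on)


def lasso_select_exposures(
    design: pd.DataFrame,
    response: np.ndarray,
    weights: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> list[str]:
    """Exposure columns surviving a weighted lasso at the 1-SE penalty.

    Columns are standardized; the weighted problem is solved on the
    sqrt-weight-transformed design; the penalty is the largest one whose
    cross-validated error is within one standard error of the minimum.
    At least one exposure is always retained (smallest-penalty fallback).
    """
    names = list(design.columns)
    if len(names) < 2:
        return names
    X = design.to_numpy(float)
    y = np.asarray(response, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    sd = Xw.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xw / sd

    # the lasso solution is non-unique for exactly duplicated columns:
    # resolve perfect collinearity deterministically (keep the first)
    keep_idx: list[int] = []
    for j in range(Xs.shape[1]):
        dup = any(np.allclose(Xs[:, j], Xs[:, i], atol=1e-12)
                  or np.allclose(Xs[:, j], -Xs[:, i], atol=1e-12) for i in keep_idx)
        if not dup:
            keep_idx.append(j)
    if len(keep_idx) < len(names):
        logger.warning("lasso: %d perfectly collinear column(s) dropped up front",
                       len(names) - len(keep_idx))
        names = [names[j] for j in keep_idx]
        Xs = Xs[:, keep_idx]
        if len(names) == 1:
            return names

    n = len(yw)
    alpha_max = np.max(np.abs(Xs.T @ yw)) / n
    alphas = alpha_max * np.logspace(0, -3, 50)
    folds = min(n_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = np.zeros((len(alphas), folds))
    for fi, (tr, te) in enumerate(kf.split(Xs)):
        for ai, a in enumerate(alphas):
            model = Lasso(alpha=a, fit_intercept=False, max_iter=5000)
            model.fit(Xs[tr], yw[tr])
            errs[ai, fi] = np.mean((yw[te] - Xs[te] @ model.coef_) ** 2)
    mean_err = errs.mean(axis=1)
    se_err = errs.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_err))
    cutoff = mean_err[best] + se_err[best]
    chosen = 0  # alphas descend: index 0 is the largest penalty
    while mean_err[chosen] > cutoff:
        chosen += 1
    model = Lasso(alpha=alphas[chosen], fit_intercept=False, max_iter=10000)
    model.fit(Xs, yw)
    retained = [n_ for n_, c in zip(names, model.coef_) if c != 0.0]
    if not retained:
        model = Lasso(alpha=alphas[-1], fit_intercept=False, max_iter=10000)
        model.fit(Xs, yw)
        order = np.argsort(-np.abs(model.coef_))
        retained = [names[order[0]]]
        logger.warning("lasso retained nothing at 1-SE penalty; keeping strongest column")
    return retained


def total_vs_direct(total: MRResult, direct_row: pd.Series, mediator_name: str) -> MediationGap:
    """Gap between univariable (total) and multivariable (direct) effects.

    gap_se treats the two estimates as independent — conservative, since
    both are computed from overlapping instrument sets.
    """
    gap = float(total.beta - direct_row["direct_beta"])
    gap_se = float(np.sqrt(total.se**2 + direct_row["se"] ** 2))
    return MediationGap(
        exposure=total.exposure,
        outcome=total.outcome,
        mediator_name=mediator_name,
        total_beta=float(total.beta),
        direct_beta=float(direct_row["direct_beta"]),
        gap=gap,
        gap_se=gap_se,
    )
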