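"""Two-step MR mediation through plasma proteins, and Bayesian colocalization.

Two-step MR: step 1 estimates each protein's effect on disease using its
cis-pQTL instruments (FDR < 0.05 across the protein panel defines "risk
proteins"); step 2 estimates each pollutant's effect on those proteins.
The mediated (indirect) effect is the product beta1·beta2 with a
first-order delta-method standard error
sqrt(beta1²·se2² + beta2²·se1²).

Colocalization: for a ±1 Mb region around a lead variant, per-SNP
approximate Bayes factors (Wakefield) for each trait are combined into
posterior probabilities of five hypotheses — H0 no association, H1/H2
association with one trait only, H3 two distinct causal variants, H4 one
shared causal variant.  A region colocalizes when PP(H4) > 0.8.  All sums
of Bayes factors run in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateRegionError, ValidationError
from .mr_core import MRResult, bh_fdr

CIS_WINDOW_BP = 1_000_000

#: coloc prior probabilities: per-SNP association with trait 1, trait 2, both
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: prior effect variance W: sd 0.2 for quantitative traits, 0.15 for log-OR
PRIOR_W_QUANT = 0.04
PRIOR_W_BINARY = 0.0225


def classify_cis_trans(records: pd.DataFrame, window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Set cis_flag: variant within ±window of the encoding gene (inclusive).

    Expects columns chrom, pos, gene_chrom, gene_start, gene_end.  A variant
    on a different chromosome is trans regardless of position.
    """
    out = records.copy()
    same = out["chrom"].astype(str) == out["gene_chrom"].astype(str)
    within = (out["pos"] >= out["gene_start"] - window_bp) & (
        out["pos"] <= out["gene_end"] + window_bp
    )
    out["cis_flag"] = same & within
    return out


def delta_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order delta-method SE of the product beta1·beta2."""
    return float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))


@dataclass
class MediationResult:
    pollutant: str
    protein: str
    disease: str
    beta1: float  # protein -> disease
    se1: float
    beta2: float  # pollutant -> protein
    se2: float
    step1_fdr_q: float
    indirect: float = field(init=False)
    indirect_se: float = field(init=False)
    indirect_pval: float = field(init=False)

    def __post_init__(self) -> None:
        self.indirect = self.beta1 * self.beta2
        self.indirect_se = delta_se(self.beta1, self.se1, self.beta2, self.se2)
        if self.indirect_se > 0:
            self.indirect_pval = float(2 * stats.norm.sf(abs(self.indirect) / self.indirect_se))
        else:
            self.indirect_pval = 1.0 if self.indirect == 0 else 0.0


def two_step_mediation(
    step1: list[MRResult],
    step2: list[MRResult],
    fdr_threshold: float = 0.05,
    step2_p_threshold: float = 0.05,
) -> list[MediationResult]:
    """Combine protein→disease (step 1) and pollutant→protein (step 2) MR.

    Step-1 p-values are BH-adjusted within each disease's protein panel;
    proteins with FDR < ``fdr_threshold`` are risk proteins.  For every
    (pollutant, protein) step-2 result with p < ``step2_p_threshold`` whose
    protein is a risk protein for some disease, the mediated effect
    beta1·beta2 is reported with its delta-method SE.  An empty survivor
    set yields an empty list.
    """
    by_disease: dict[str, list[MRResult]] = {}
    for r in step1:
        by_disease.setdefault(r.outcome, []).append(r)
    survivors: dict[tuple[str, str], tuple[MRResult, float]] = {}
    for disease, results in by_disease.items():
        q, _ = bh_fdr([r.pval for r in results], tiers=False)
        for r, qi in zip(results, q):
            r.fdr_q = float(qi)
            if qi < fdr_threshold:
                survivors[(r.exposure, disease)] = (r, float(qi))
    out: list[MediationResult] = []
    for s2 in step2:
        if s2.pval >= step2_p_threshold:
            continue
        protein = s2.outcome
        for (prot, disease), (s1, q1) in survivors.items():
            if prot != protein:
                continue
            out.append(
                MediationResult(
                    pollutant=s2.exposure, protein=protein, disease=disease,
                    beta1=s1.beta, se1=s1.se, beta2=s2.beta, se2=s2.se,
                    step1_fdr_q=q1,
                )
            )
    return out


def wakefield_labf(beta: float, se: float, prior_w: float) -> float:
    """Log approximate Bayes factor for a single-SNP association.

    With V = se², z = beta/se and shrinkage r = W/(V + W):
    labf = 0.5·[ln(1 − r) + r·z²].
    """
    if se <= 0:
        raise ValidationError("se must be positive")
    if prior_w <= 0:
        raise ValidationError("prior_w must be positive")
    V = se**2
    z = beta / se
    r = prior_w / (V + prior_w)
    return float(0.5 * (np.log1p(-r) + r * z**2))


@dataclass
class ColocResult:
    region: tuple[str, int, int]
    lead_variant: str
    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: tuple[float, float, float] = DEFAULT_PRIORS

    @property
    def colocalized(self) -> bool:
        return self.pph4 > 0.8

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def coloc_abf(
    beta1,
    se1,
    beta2,
    se2,
    variant_ids: list[str] | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_w1: float = PRIOR_W_QUANT,
    prior_w2: float = PRIOR_W_QUANT,
    region: tuple[str, int, int] = ("NA", 0, 0),
    lead_variant: str = "",
) -> ColocResult:
    """Posterior colocalization probabilities for a two-trait region.

    Inputs are effect/SE vectors over an identical, identically ordered
    variant list for both traits.  Under a single-causal-variant model per
    trait, the unnormalized hypothesis weights are

        H0: 1,  H1: p1·S1,  H2: p2·S2,  H3: p1·p2·(S1·S2 − S12),  H4: p12·S12

    with S1 = Σ exp(labf1), S2 = Σ exp(labf2), S12 = Σ exp(labf1+labf2),
    all evaluated via log-sum-exp.  A single-SNP region has no distinct-
    variant configuration (S3 = 0, with a warning).
    """
    b1 = np.asarray(beta1, float)
    s1 = np.asarray(se1, float)
    b2 = np.asarray(beta2, float)
    s2 = np.asarray(se2, float)
    m = b1.size
    if not (s1.size == b2.size == s2.size == m):
        raise ValidationError("coloc inputs must share one variant list")
    if m == 0:
        raise DegenerateRegionError("empty region")
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValidationError("all SEs must be positive")
    if m == 1:
        warnings.warn("single-SNP region: H3 computed with S3 = 0", stacklevel=2)

    l1 = _labf_vec(b1, s1, prior_w1)
    l2 = _labf_vec(b2, s2, prior_w2)
    p1, p2, p12 = priors
    logS1 = logsumexp(l1)
    logS2 = logsumexp(l2)
    logS12 = logsumexp(l1 + l2)
    # S3 = S1*S2 - S12 >= 0 (cross terms only); log-difference, guarded
    log_prod = logS1 + logS2
    if m == 1 or log_prod <= logS12 + 1e-12:
        logS3 = -np.inf
    else:
        logS3 = log_prod + np.log1p(-np.exp(logS12 - log_prod))
    logs = np.array(
        [
            0.0,
            np.log(p1) + logS1,
            np.log(p2) + logS2,
            np.log(p1) + np.log(p2) + logS3,
            np.log(p12) + logS12,
        ]
    )
    post = np.exp(logs - logsumexp(logs))
    post /= post.sum()
    if variant_ids is None:
        variant_ids = [f"snp_{i + 1}" for i in range(m)]
    lead = lead_variant or variant_ids[int(np.argmax(np.abs(b1 / s1)))]
    return ColocResult(region, lead, m, *map(float, post), priors=priors)


def _labf_vec(beta: np.ndarray, se: np.ndarray, prior_w: float) -> np.ndarray:
    V = se**2
    z = beta / se
    r = prior_w / (V + prior_w)
    return 0.5 * (np.log1p(-r) + r * z**2)


def extract_region(
    table: pd.DataFrame, chrom: str, center_pos: int, window_bp: int = CIS_WINDOW_BP
) -> pd.DataFrame:
    """Rows of a summary table within ±window of a position (inclusive)."""
    mask = (table["chrom"].astype(str) == str(chrom)) & (
        (table["pos"] >= center_pos - window_bp) & (table["pos"] <= center_pos + window_bp)
    )
    return table[mask].reset_index(drop=True)


def coloc_tables(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    prior_w1: float = PRIOR_W_QUANT,
    prior_w2: float = PRIOR_W_QUANT,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> ColocResult:
    """Colocalize two region tables (columns variant_id, chrom, pos, beta, se).

    The variant intersection is taken in trait-1 order; the lead variant is
    trait 1's largest |z|.
    """
    t1 = trait1.set_index("variant_id")
    t2 = trait2.set_index("variant_id")
    shared = [v for v in trait1["variant_id"] if v in t2.index]
    if len(shared) < 2:
        raise DegenerateRegionError(f"only {len(shared)} shared variant(s) in region")
    b1 = t1.loc[shared, "beta"].to_numpy(float)
    s1 = t1.loc[shared, "se"].to_numpy(float)
    b2 = t2.loc[shared, "beta"].to_numpy(float)
    s2 = t2.loc[shared, "se"].to_numpy(float)
    chrom = str(t1.loc[shared[0], "chrom"])
    lo = int(t1.loc[shared, "pos"].min())
    hi = int(t1.loc[shared, "pos"].max())
    return coloc_abf(
        b1, s1, b2, s2, variant_ids=shared, priors=priors,
        prior_w1=prior_w1, prior_w2=prior_w2, region=(chrom, lo, hi),
    )
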