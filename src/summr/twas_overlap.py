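"""Gene-level TWAS association and direction-concordant overlap ranking.

A gene's TWAS statistic combines per-variant GWAS z-scores through its
expression-model weights w and the LD matrix R of the weight variants:

    z_twas = (w·z) / sqrt(wᵀ R w)

A gene "overlaps" a pollutant when both the disease and the pollutant TWAS
are nominally significant with the same z sign.  Evidence across the
disease and each pollutant is combined with Fisher's method; per-pollutant
combined p-values are in turn combined into a single cross-pollutant
statistic, and genes are ranked (1-based, dense) by ascending combined p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateWeightsError, ValidationError
from .gwas_io import LDMatrix


@dataclass
class GeneWeights:
    """Expression-model coefficients for one gene's cis variants."""

    gene: str
    variant_ids: list[str]
    weights: np.ndarray
    region: tuple[str, int, int] = ("NA", 0, 0)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.variant_ids) != self.weights.size or self.weights.size < 1:
            raise ValidationError(f"gene {self.gene}: ids and weights must align, >= 1")
        if np.all(self.weights == 0):
            raise ValidationError(f"gene {self.gene}: all weights zero")


@dataclass
class GeneAssociation:
    gene: str
    trait: str
    z_twas: float
    pval: float


def twas_association(
    weights: GeneWeights, gwas_z: dict[str, float] | pd.Series, ld: LDMatrix
) -> GeneAssociation:
    """LD-aware weighted combination of GWAS z-scores for one gene."""
    z = np.array([float(gwas_z[v]) for v in weights.variant_ids])
    R = ld.subset(weights.variant_ids).r
    w = weights.weights
    denom = float(w @ R @ w)
    if denom <= 1e-12:
        raise DegenerateWeightsError(f"gene {weights.gene}: w'Rw = {denom:.3g}")
    zt = float(w @ z / np.sqrt(denom))
    return GeneAssociation(weights.gene, "", zt, float(2 * stats.norm.sf(abs(zt))))


def fisher_combined(pvals) -> float:
    """Fisher's combined probability: X = −2Σln p ~ chi²(2k)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0,1] (floor zeros upstream)")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


def concordant_overlap_and_rank(
    disease_twas: list[GeneAssociation],
    pollutant_twas: dict[str, list[GeneAssociation]],
    alpha: float = 0.05,
    fcp_all_rule: str = "pairwise",
) -> pd.DataFrame:
    """Overlap genes, pairwise Fisher-combined p, and cross-pollutant ranks.

    A gene overlaps a pollutant iff both TWAS p < ``alpha`` and the z signs
    agree.  Per pair, fcp = Fisher(disease_p, pollutant_p) (4 df).  The
    cross-pollutant value combines the per-pair fcps (8 df for four
    pollutants) under the default ``pairwise`` rule, or all raw p-values
    (2·(1+n_pollutants) df) under ``raw``.  A gene enters the
    cross-pollutant column only when it overlaps every pollutant.  Ranks
    are dense, 1-based, ascending within each column.
    """
    if fcp_all_rule not in ("pairwise", "raw"):
        raise ValidationError(f"unknown fcp_all_rule {fcp_all_rule!r}")
    dis = {a.gene: a for a in disease_twas}
    pols = sorted(pollutant_twas)
    rows = []
    for gene, d in dis.items():
        if d.pval >= alpha:
            continue
        row: dict[str, object] = {"gene": gene, "disease_p": d.pval}
        n_overlap = 0
        for pol in pols:
            match = next((a for a in pollutant_twas[pol] if a.gene == gene), None)
            if match is None or match.pval >= alpha or np.sign(match.z_twas) != np.sign(d.z_twas):
                row[f"twas_p_{pol}"] = match.pval if match is not None else np.nan
                row[f"fcp_{pol}"] = np.nan
                continue
            row[f"twas_p_{pol}"] = match.pval
            row[f"fcp_{pol}"] = fisher_combined([d.pval, match.pval])
            n_overlap += 1
        if n_overlap == 0:
            continue
        if n_overlap == len(pols):
            if fcp_all_rule == "pairwise":
                row["fcp_all"] = fisher_combined([row[f"fcp_{p}"] for p in pols])
            else:
                row["fcp_all"] = fisher_combined(
                    [d.pval] + [row[f"twas_p_{p}"] for p in pols]
                )
        else:
            row["fcp_all"] = np.nan
        rows.append(row)
    cols = (
        ["gene", "disease_p"]
        + [c for p in pols for c in (f"twas_p_{p}", f"fcp_{p}")]
        + ["fcp_all"]
    )
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return df
    for pol in pols:
        df[f"rank_{pol}"] = df[f"fcp_{pol}"].rank(method="dense").astype("Int64")
    df["rank_all"] = df["fcp_all"].rank(method="dense").astype("Int64")
    return df
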