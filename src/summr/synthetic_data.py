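"""Seeded generators for every input the pipeline consumes, with ground truth.

All generators work at the summary-statistic level: effect estimates are
drawn from the normal sampling distributions implied by sample size and
allele frequency, never from individual-level genotypes.  That is exactly
the regime every estimator in this package operates in, and it makes
thousands of replicates cheap.

The two-sample generator implements the identifying model

    Γ_j = β·γ_j + α_j

with per-SNP pleiotropic effects α_j drawn according to a configurable
regime (none, balanced, directional, or InSIDE-violating, i.e. correlated
with instrument strength).  Exposure and outcome samples are
non-overlapping by construction.

Defaults mirror the study conditions this package was designed around:
~80 instruments per exposure selected at p < 5e-6 from a biobank-scale
exposure GWAS (N ≈ 456,000), instrument strength |z| in [4.5, 8.2]
(F ≈ z² between ~20 and ~67), and case-control outcome GWAS of
autoimmune-disease scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gwas_io import AssociationTable, LDMatrix
from .twas_overlap import GeneWeights

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class SimConfig:
    """Knobs of all generators; ``seed`` is mandatory."""

    seed: int
    # two-sample MR
    n_snp: int = 80
    n_exposure_sample: int = 456_380
    n_outcome_sample: int = 100_000
    eaf_range: tuple[float, float] = (0.05, 0.5)
    true_beta: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_mean: float = 0.05
    pleiotropy_sd: float = 0.02
    instrument_z_range: tuple[float, float] = (4.5, 8.2)
    n_null_snp: int = 0
    invalid_fraction: float = 0.0
    invalid_effect: float = 0.05
    gamma_sign: str = "random"  # "positive" fixes instrument orientation
    # colocalization regions
    n_region_snp: int = 200
    ar1_rho: float = 0.9
    causal_config: str = "shared"  # shared | distinct | null_one_trait | null_both
    causal_z: float = 8.0
    n_region_sample: int = 50_000
    # multivariable MR
    n_exposures: int = 2
    n_snp_per_block: int = 30
    direct_betas: tuple[float, ...] = (0.3, -0.2)
    cross_loading: float = 0.1
    duplicate_exposure: bool = False
    # mediation chain and proteome
    n_proteins: int = 20
    n_mediating: int = 3
    beta1: float = 0.4  # protein -> disease
    beta2: float = 0.3  # pollutant -> protein
    n_protein_sample: int = 35_559
    n_cis_per_protein: int = 5
    # TWAS weights
    n_genes: int = 12
    n_concordant_genes: int = 4
    n_weight_snp: int = 10
    weight_sparsity: float = 0.3
    twas_target_z: float = 4.0
    pollutant_names: tuple[str, ...] = ("NO2", "NOX", "PM2.5", "PM10")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        if min(self.n_exposure_sample, self.n_outcome_sample) < 2:
            raise ValidationError("sample sizes must be >= 2")
        if not abs(self.ar1_rho) < 1:
            raise ValidationError("|ar1_rho| must be < 1")


@dataclass
class TruthRecord:
    """Everything needed to recompute expected estimates analytically."""

    seed: int
    config: dict = field(default_factory=dict)
    true_beta: float | None = None
    gamma_true: np.ndarray | None = None
    alpha_true: np.ndarray | None = None
    causal_indices: dict | None = None
    direct_betas: tuple[float, ...] | None = None
    mediating_proteins: list[str] | None = None
    beta1: float | None = None
    beta2: float | None = None
    concordant_genes: list[str] | None = None


def _se_from_eaf(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _make_table(rng, name, trait_type, vids, chrom, pos, alleles, eaf, beta, se, n):
    ea = [a[0] for a in alleles]
    oa = [a[1] for a in alleles]
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": np.clip(_two_sided_p(np.asarray(beta) / np.asarray(se)), 1e-300, 1.0),
            "n": n,
        }
    )
    return AssociationTable(name, trait_type, df)


def _draw_alleles(rng, k):
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    return [_ALLELE_PAIRS[i] for i in idx]


def _draw_two_sample(config: SimConfig, rng: np.random.Generator) -> dict:
    """Shared draw of the two-sample model's summary-level arrays."""
    k = config.n_snp + config.n_null_snp
    eaf = rng.uniform(*config.eaf_range, size=k)
    se_g = _se_from_eaf(eaf, config.n_exposure_sample)
    signs = (
        np.ones(k) if config.gamma_sign == "positive"
        else rng.choice([-1.0, 1.0], size=k)
    )
    z_target = rng.uniform(*config.instrument_z_range, size=k) * signs
    gamma_true = z_target * se_g
    gamma_true[config.n_snp:] = 0.0
    gamma_hat = gamma_true + rng.normal(0.0, se_g)

    mode = config.pleiotropy_mode
    if mode == "none":
        alpha = np.zeros(k)
    elif mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=k)
    elif mode == "directional":
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
    elif mode == "inside_violating":
        # alpha correlated with gamma_true at r = 0.5
        gs = (gamma_true - gamma_true.mean()) / (gamma_true.std() or 1.0)
        noise = rng.normal(0.0, 1.0, size=k)
        alpha = config.pleiotropy_mean + config.pleiotropy_sd * (
            0.5 * gs + np.sqrt(1 - 0.25) * noise
        )
    else:
        raise ValidationError(f"unknown pleiotropy_mode {mode!r}")

    invalid_idx = np.array([], dtype=int)
    if config.invalid_fraction > 0:
        n_invalid = int(round(config.invalid_fraction * config.n_snp))
        invalid_idx = rng.choice(config.n_snp, size=n_invalid, replace=False)
        alpha = alpha.copy()
        alpha[invalid_idx] += config.invalid_effect

    se_G = _se_from_eaf(eaf, config.n_outcome_sample)
    Gamma_true = config.true_beta * gamma_true + alpha
    Gamma_hat = Gamma_true + rng.normal(0.0, se_G)
    return {
        "eaf": eaf, "se_g": se_g, "gamma_true": gamma_true, "gamma_hat": gamma_hat,
        "alpha": alpha, "se_G": se_G, "Gamma_hat": Gamma_hat, "invalid_idx": invalid_idx,
        "k": k,
    }


def simulate_harmonized_pair(config: SimConfig):
    """Fast path: the two-sample draw already aligned as a HarmonizedPair.

    Identical model to :func:`simulate_two_sample` but skips allele coding
    and table construction — the natural input for estimator replicate
    studies, where harmonization is not under test.
    """
    from .gwas_io import pair_from_arrays

    rng = np.random.default_rng(config.seed)
    d = _draw_two_sample(config, rng)
    pair = pair_from_arrays(
        d["gamma_hat"], d["se_g"], d["Gamma_hat"], d["se_G"],
        eaf=d["eaf"], n_exposure=config.n_exposure_sample,
        n_outcome=config.n_outcome_sample,
    )
    truth = TruthRecord(
        seed=config.seed, config=asdict(config), true_beta=config.true_beta,
        gamma_true=d["gamma_true"], alpha_true=d["alpha"],
    )
    return pair, truth


def simulate_two_sample(config: SimConfig):
    """Exposure + outcome summary tables under Γ = β·γ + α, with truth.

    Instrument SNPs reach |z| within ``instrument_z_range`` in expectation
    at the exposure sample size; ``n_null_snp`` extra SNPs carry no
    exposure effect.  The outcome table's allele coding is shuffled
    (swap effect/other, negate beta, complement EAF) on a seeded coin flip
    per SNP, so harmonization is exercised end to end.
    """
    rng = np.random.default_rng(config.seed)
    d = _draw_two_sample(config, rng)
    k = d["k"]
    eaf, se_g, gamma_hat = d["eaf"], d["se_g"], d["gamma_hat"]
    gamma_true, alpha = d["gamma_true"], d["alpha"]
    se_G, Gamma_hat = d["se_G"], d["Gamma_hat"]

    vids = [f"rs{config.seed % 1000:03d}{i:05d}" for i in range(k)]
    pos = 1 + 20_000_000 * np.arange(k)
    alleles = _draw_alleles(rng, k)
    exposure = _make_table(
        rng, "exposure", "quantitative", vids, "1", pos, alleles, eaf,
        gamma_hat, se_g, config.n_exposure_sample,
    )
    # outcome table: same variants, coding shuffled per SNP
    swap = rng.random(k) < 0.5
    out_alleles = [(o, e) if s else (e, o) for (e, o), s in zip(alleles, swap)]
    out_beta = np.where(swap, -Gamma_hat, Gamma_hat)
    out_eaf = np.where(swap, 1.0 - eaf, eaf)
    outcome = _make_table(
        rng, "outcome", "binary", vids, "1", pos, out_alleles, out_eaf,
        out_beta, se_G, config.n_outcome_sample,
    )
    truth = TruthRecord(
        seed=config.seed, config=asdict(config), true_beta=config.true_beta,
        gamma_true=gamma_true, alpha_true=alpha,
    )
    return exposure, outcome, truth


def _ar1_matrix(rho: float, m: int) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_coloc_region(config: SimConfig):
    """AR(1)-LD region for two traits with shared/distinct/null causals.

    Marginal z-scores follow z = R·λ·√n + MVN(0, R); betas and SEs are
    backed out with unit-variance scaling (se = 1/√n).  Under ``distinct``
    the two causal indices are placed so their LD r² < 0.01.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_region_snp
    R = _ar1_matrix(config.ar1_rho, m)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    def draw(causal_idx: int | None) -> np.ndarray:
        lam = np.zeros(m)
        if causal_idx is not None:
            lam[causal_idx] = config.causal_z  # λ·√n
        return R @ lam + L @ rng.standard_normal(m)

    cfg = config.causal_config
    if cfg == "shared":
        c = int(rng.integers(m // 4, 3 * m // 4))
        c1 = c2 = c
    elif cfg == "distinct":
        # separation large enough that rho^d has r² < 0.01
        d_min = int(np.ceil(np.log(0.1) / np.log(abs(config.ar1_rho)))) + 1
        c1 = int(rng.integers(0, m - d_min - 1))
        c2 = c1 + d_min + int(rng.integers(0, max(1, m - c1 - d_min - 1)))
    elif cfg == "null_one_trait":
        c1, c2 = int(rng.integers(m)), None
    elif cfg == "null_both":
        c1 = c2 = None
    else:
        raise ValidationError(f"unknown causal_config {cfg!r}")

    z1 = draw(c1)
    z2 = draw(c2)
    se = 1.0 / np.sqrt(config.n_region_sample)
    vids = [f"rs{config.seed % 1000:03d}{i:05d}" for i in range(m)]
    pos = 1_000_000 + 5_000 * np.arange(m)

    def table(z):
        return pd.DataFrame(
            {"variant_id": vids, "chrom": "1", "pos": pos, "beta": z * se, "se": se}
        )

    ld = LDMatrix(vids, R)
    truth = TruthRecord(
        seed=config.seed, config=asdict(config),
        causal_indices={"trait1": c1, "trait2": c2},
    )
    return table(z1), table(z2), ld, truth


def simulate_mvmr(config: SimConfig):
    """Block-structured multi-exposure instrument sets with known directs.

    Each block of SNPs loads mainly on one exposure (cross-loadings scaled
    by ``cross_loading``); the outcome is built from the per-exposure true
    direct effects.  ``duplicate_exposure`` appends an exact copy of the
    first exposure to exercise lasso collinearity handling.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_exposures
    if len(config.direct_betas) != p:
        raise ValidationError("direct_betas length must equal n_exposures")
    k = p * config.n_snp_per_block
    eaf = rng.uniform(*config.eaf_range, size=k)
    se_g = _se_from_eaf(eaf, config.n_exposure_sample)
    z_main = rng.uniform(*config.instrument_z_range, size=k) * rng.choice([-1.0, 1.0], size=k)
    G_true = np.zeros((k, p))
    for e in range(p):
        block = slice(e * config.n_snp_per_block, (e + 1) * config.n_snp_per_block)
        G_true[block, e] = (z_main * se_g)[block]
        for other in range(p):
            if other != e:
                G_true[block, other] = (
                    config.cross_loading * rng.normal(0.0, (np.abs(z_main) * se_g).mean(),
                                                      config.n_snp_per_block)
                )
    G_hat = G_true + rng.normal(0.0, se_g[:, None], size=(k, p))
    se_out = _se_from_eaf(eaf, config.n_outcome_sample)
    Gamma_true = G_true @ np.asarray(config.direct_betas)
    Gamma_hat = Gamma_true + rng.normal(0.0, se_out)

    vids = [f"rs{config.seed % 1000:03d}{i:05d}" for i in range(k)]
    pos = 1 + 20_000_000 * np.arange(k)
    alleles = _draw_alleles(rng, k)
    exposures = [
        _make_table(
            rng, f"exposure_{e + 1}", "quantitative", vids, "1", pos, alleles, eaf,
            G_hat[:, e], se_g, config.n_exposure_sample,
        )
        for e in range(p)
    ]
    if config.duplicate_exposure:
        dup = exposures[0].data.copy()
        exposures.append(AssociationTable("exposure_1_dup", "quantitative", dup))
    outcome = _make_table(
        rng, "outcome", "binary", vids, "1", pos, alleles, eaf,
        Gamma_hat, se_out, config.n_outcome_sample,
    )
    truth = TruthRecord(
        seed=config.seed, config=asdict(config), direct_betas=config.direct_betas,
        gamma_true=G_true,
    )
    return exposures, outcome, truth


def simulate_proteome_and_weights(config: SimConfig):
    """Proteome panel with planted mediation chains, plus TWAS weight sets.

    Returns a dict bundle:

    - ``proteins``: per-protein cis-pQTL AssociationTable (gene coords in
      ``gene_coords``), strong instruments at deCODE-panel sample size;
    - ``disease_at_pqtl``: disease effects at every protein's cis SNPs,
      built as beta1·γ_protein (+ sampling noise) for mediating proteins;
    - ``pollutant`` / ``protein_at_pollutant``: pollutant instruments and
      protein effects at them (beta2·γ_pollutant for mediating proteins);
    - ``gene_weights`` / ``gwas_z`` / ``ld``: sparse per-gene expression
      weights, disease and per-pollutant z-score Series over the weight
      variants, and their LD — planted genes are concordant-significant;
    - ``truth``: mediating proteins, beta1/beta2, concordant gene names.
    """
    rng = np.random.default_rng(config.seed)
    mediating = [f"PROT{i + 1}" for i in range(config.n_mediating)]
    all_prot = [f"PROT{i + 1}" for i in range(config.n_proteins)]

    proteins: dict[str, AssociationTable] = {}
    gene_coords: dict[str, tuple[str, int, int]] = {}
    disease_rows = []
    for pi, prot in enumerate(all_prot):
        nc = config.n_cis_per_protein
        gene_start = 2_000_000 + pi * 10_000_000
        gene_end = gene_start + 50_000
        gene_coords[prot] = ("1", gene_start, gene_end)
        eaf = rng.uniform(*config.eaf_range, size=nc)
        se_g = _se_from_eaf(eaf, config.n_protein_sample)
        z = rng.uniform(6.0, 10.0, size=nc) * rng.choice([-1.0, 1.0], size=nc)
        gamma_true = z * se_g
        gamma_hat = gamma_true + rng.normal(0.0, se_g)
        vids = [f"rs{pi:03d}c{j:02d}" for j in range(nc)]
        pos = gene_start + np.arange(nc) * 1_000
        alleles = _draw_alleles(rng, nc)
        proteins[prot] = _make_table(
            rng, prot, "quantitative", vids, "1", pos, alleles, eaf,
            gamma_hat, se_g, config.n_protein_sample,
        )
        b1 = config.beta1 if prot in mediating else 0.0
        se_d = _se_from_eaf(eaf, config.n_outcome_sample)
        Gamma = b1 * gamma_true + rng.normal(0.0, se_d)
        disease_rows.append(
            _make_table(
                rng, "disease", "binary", vids, "1", pos, alleles, eaf,
                Gamma, se_d, config.n_outcome_sample,
            ).data
        )
    disease_at_pqtl = AssociationTable(
        "disease", "binary", pd.concat(disease_rows, ignore_index=True)
    )

    # pollutant instruments and protein effects at them
    ts_cfg = SimConfig(seed=config.seed + 1, n_snp=config.n_snp,
                       n_exposure_sample=config.n_exposure_sample,
                       instrument_z_range=config.instrument_z_range,
                       eaf_range=config.eaf_range, true_beta=0.0)
    pollutant, _, ts_truth = simulate_two_sample(ts_cfg)
    pollutant = AssociationTable("pollutant", "quantitative", pollutant.data)
    protein_at_pollutant: dict[str, AssociationTable] = {}
    eaf_p = pollutant.data["eaf"].to_numpy()
    se_pp = _se_from_eaf(eaf_p, config.n_protein_sample)
    for prot in all_prot:
        b2 = config.beta2 if prot in mediating else 0.0
        eff = b2 * ts_truth.gamma_true + rng.normal(0.0, se_pp)
        tab = pollutant.data.copy()
        tab["beta"] = eff
        tab["se"] = se_pp
        tab["pval"] = np.clip(_two_sided_p(eff / se_pp), 1e-300, 1.0)
        tab["n"] = config.n_protein_sample
        protein_at_pollutant[prot] = AssociationTable(prot, "quantitative", tab)

    # TWAS: sparse weights per gene; planted genes concordant-significant
    concordant = [f"GENE{i + 1}" for i in range(config.n_concordant_genes)]
    genes = [f"GENE{i + 1}" for i in range(config.n_genes)]
    gene_weights: list[GeneWeights] = []
    gwas_z: dict[str, pd.Series] = {t: {} for t in ("disease", *config.pollutant_names)}
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    for gi, gene in enumerate(genes):
        mw = config.n_weight_snp
        vids = [f"rs{gi:03d}w{j:02d}" for j in range(mw)]
        w = np.zeros(mw)
        nz = max(1, int(round(config.weight_sparsity * mw)))
        w[rng.choice(mw, size=nz, replace=False)] = rng.normal(0.0, 1.0, size=nz)
        if np.all(w == 0):
            w[0] = 1.0
        R = _ar1_matrix(0.5, mw)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(mw))
        direction = float(rng.choice([-1.0, 1.0]))
        unit = R @ w / np.sqrt(w @ R @ w)
        for trait in gwas_z:
            target = config.twas_target_z if gene in concordant else 0.0
            z = direction * target * unit + L @ rng.standard_normal(mw)
            for v, zv in zip(vids, z):
                gwas_z[trait][v] = float(zv)
        start = 1_000_000 + gi * 2_000_000
        gene_weights.append(GeneWeights(gene, vids, w, ("2", start, start + 50_000)))
        ld_ids.extend(vids)
        ld_blocks.append(R)
    full = np.zeros((len(ld_ids), len(ld_ids)))
    off = 0
    for R in ld_blocks:
        m = R.shape[0]
        full[off:off + m, off:off + m] = R
        off += m
    ld = LDMatrix(ld_ids, full)
    gwas_z = {t: pd.Series(d) for t, d in gwas_z.items()}

    truth = TruthRecord(
        seed=config.seed, config=asdict(config),
        mediating_proteins=mediating, beta1=config.beta1, beta2=config.beta2,
        concordant_genes=concordant,
    )
    return {
        "proteins": proteins,
        "gene_coords": gene_coords,
        "disease_at_pqtl": disease_at_pqtl,
        "pollutant": pollutant,
        "protein_at_pollutant": protein_at_pollutant,
        "gene_weights": gene_weights,
        "gwas_z": gwas_z,
        "ld": ld,
        "truth": truth,
    }
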