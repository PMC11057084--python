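"""Config-driven orchestration of the full analysis chain.

Stages, in order: instrument selection → two-sample MR with FDR tiers →
fixed-effect meta-analysis of significant pairs across cohorts →
multivariable MR with lasso exposure selection → two-step protein
mediation → colocalization → TWAS overlap.  Stages whose inputs are
absent from the config are skipped (and logged), not failed: the analyses
are separable.

Inputs come either from summary-statistic files or from ``simulate``
blocks handled by :mod:`summr.synthetic_data`.  One global seed fans out
to per-stage child seeds by fixed offsets, so adding a stage never
perturbs an earlier stage's randomness.

Instrument scoring inside the pipeline uses the sample-size-normalized
variance-explained formula (R² = z²/(z² + N − 2), F ≈ z²): the unnormalized
textbook form exceeds 1 for any genome-wide instrument at biobank sample
sizes and would flag every row invalid (see docs/methods.md).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SummrError
from .gwas_io import harmonize_pair, read_association_table
from .instruments import SelectionParams, build_instrument_set, drop_outcome_associated
from .mediation_coloc import coloc_tables, two_step_mediation, PRIOR_W_BINARY, PRIOR_W_QUANT
from .meta_mvmr import lasso_select_exposures, meta_fixed, mvmr_fit, build_mvmr_design
from .mr_core import attach_fdr, ivw, leave_one_out, run_all_estimators
from .synthetic_data import (
    SimConfig,
    simulate_coloc_region,
    simulate_mvmr,
    simulate_proteome_and_weights,
    simulate_two_sample,
)
from .twas_overlap import concordant_overlap_and_rank, twas_association

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "tsmr": 1_000,
    "meta": 2_000,
    "mvmr": 3_000,
    "mediation": 4_000,
    "coloc": 5_000,
    "twas": 6_000,
}

REPORT_SCHEMAS = {
    "tsmr_results": ["exposure", "outcome", "method", "n_snp", "beta", "se", "or_",
                     "ci_low", "ci_high", "pval", "fdr_q", "tier"],
    "sensitivity": ["exposure", "outcome", "q_stat", "q_df", "q_pval", "egger_intercept",
                    "egger_intercept_pval", "loo_sign_flip", "loo_significance_flip"],
    "meta": ["exposure", "outcome", "pooled_beta", "pooled_se", "pooled_or", "ci_low",
             "ci_high", "pooled_pval", "het_q", "het_pval"],
    "mvmr": ["exposure", "model", "outcome", "or_", "ci_low", "ci_high", "pval",
             "direct_beta", "se", "n_snp"],
    "mediation": ["pollutant", "protein", "disease", "beta1", "se1", "beta2", "se2",
                  "indirect", "indirect_se", "indirect_pval", "step1_fdr_q"],
    "coloc": ["region", "lead_variant", "n_snps", "pph0", "pph1", "pph2", "pph3",
              "pph4", "colocalized"],
}

DEFAULT_THRESHOLDS = {
    "p_threshold": 5e-6,
    "clump_r2": 0.001,
    "clump_window_bp": 10_000_000,
    "f_min": 10.0,
    "outcome_p_exclusion": 5e-8,
    "pqtl_p": 1e-5,
    "pqtl_clump_kb": 10_000,
    "pqtl_clump_r2": 0.001,
    "fdr": 0.05,
    "pph4": 0.8,
    "alpha": 0.05,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SummrError(f"{path}: config must be a mapping")
    return cfg


def _thresholds(cfg: dict) -> dict:
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(cfg.get("thresholds") or {})
    return thr


def _selection_params(thr: dict) -> SelectionParams:
    return SelectionParams(
        p_threshold=thr["p_threshold"],
        clump_r2=thr["clump_r2"],
        clump_window_bp=int(thr["clump_window_bp"]),
        f_min=thr["f_min"],
        outcome_p_exclusion=thr["outcome_p_exclusion"],
        r2_formula="normalized",
    )


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> int:
    """Execute all configured stages; returns 0 iff no stage errored.

    Emits into ``out_dir``: tsmr_results.tsv, sensitivity.tsv, meta.tsv,
    mvmr.tsv, mediation.tsv, coloc.tsv, twas_overlap.tsv, run_log.txt.
    Partial outputs are preserved on stage failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    thr = _thresholds(config)
    params = _selection_params(thr)
    log_lines = [
        f"summr {__version__}",
        f"seed {seed}",
        "thresholds " + " ".join(f"{k}={v}" for k, v in sorted(thr.items())),
    ]
    failed: list[str] = []

    def note(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")
        logger.info("[%s] %s", stage, msg)

    # ---- stage: TSMR (+ sensitivity, FDR tiers) -------------------------
    tsmr_rows, sens_rows = [], []
    significant_pairs: list[tuple[str, str, float, float]] = []
    try:
        pairs = _collect_tsmr_pairs(config, seed, params)
        if not pairs:
            note("tsmr", "skipped: no exposures/outcomes configured")
        by_exposure: dict[str, list] = {}
        for exposure_name, outcome_name, pair in pairs:
            pair = drop_outcome_associated(pair, thr["outcome_p_exclusion"])
            if pair.n_snp == 0:
                note("tsmr", f"{exposure_name}->{outcome_name}: no instruments survived")
                continue
            results = run_all_estimators(pair, seed=seed + 17)
            by_exposure.setdefault(exposure_name, []).append((outcome_name, pair, results))
        for exposure_name, triples in by_exposure.items():
            ivw_results = [r for _, _, res in triples for r in res if r.method in ("ivw", "wald_ratio")]
            attach_fdr(ivw_results)
            for outcome_name, pair, results in triples:
                for r in results:
                    tsmr_rows.append(
                        {
                            "exposure": r.exposure, "outcome": r.outcome, "method": r.method,
                            "n_snp": r.n_snp, "beta": r.beta, "se": r.se, "or_": r.or_,
                            "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
                            "fdr_q": r.fdr_q, "tier": r.tier,
                        }
                    )
                primary = results[0]
                loo_flags = (False, False)
                if pair.n_snp >= 3:
                    loo = leave_one_out(pair)
                    loo_flags = (loo.flag_sign_flip, loo.flag_significance_flip)
                egger = next((r for r in results if r.method == "egger"), None)
                sens_rows.append(
                    {
                        "exposure": exposure_name, "outcome": outcome_name,
                        "q_stat": primary.q_stat, "q_df": primary.q_df, "q_pval": primary.q_pval,
                        "egger_intercept": egger.egger_intercept if egger else np.nan,
                        "egger_intercept_pval": egger.egger_intercept_pval if egger else np.nan,
                        "loo_sign_flip": loo_flags[0], "loo_significance_flip": loo_flags[1],
                    }
                )
                if primary.tier == "significant":
                    significant_pairs.append((exposure_name, outcome_name, primary.beta, primary.se))
        note("tsmr", f"{len(tsmr_rows)} result rows")
    except SummrError as exc:
        failed.append("tsmr")
        note("tsmr", f"FAILED: {exc}")
    _write(out / "tsmr_results.tsv", pd.DataFrame(tsmr_rows, columns=REPORT_SCHEMAS["tsmr_results"]), seed)
    _write(out / "sensitivity.tsv", pd.DataFrame(sens_rows, columns=REPORT_SCHEMAS["sensitivity"]), seed)

    # ---- stage: meta-analysis across cohorts ----------------------------
    meta_rows = []
    try:
        sim_block = _sim_block(config, "two_sample")
        if sim_block is None or not significant_pairs:
            note("meta", "skipped: no validation cohorts or no significant pairs")
        else:
            for i, (expo, outc, beta, se) in enumerate(significant_pairs):
                vcfg = _sim_config(sim_block, seed + STAGE_SEED_OFFSETS["meta"] + i)
                vexp, vout, _ = simulate_two_sample(vcfg)
                iset = build_instrument_set(vexp, None, params)
                vpair = harmonize_pair(vexp, vout, iset.variant_ids)
                vres = ivw(vpair)
                pooled = meta_fixed([(beta, se, "discovery"), (vres.beta, vres.se, "validation")])
                meta_rows.append(
                    {
                        "exposure": expo, "outcome": outc,
                        "pooled_beta": pooled.pooled_beta, "pooled_se": pooled.pooled_se,
                        "pooled_or": pooled.pooled_or, "ci_low": pooled.ci_low,
                        "ci_high": pooled.ci_high, "pooled_pval": pooled.pooled_pval,
                        "het_q": pooled.heterogeneity_q, "het_pval": pooled.het_pval,
                    }
                )
            note("meta", f"{len(meta_rows)} pooled pairs")
    except SummrError as exc:
        failed.append("meta")
        note("meta", f"FAILED: {exc}")
    _write(out / "meta.tsv", pd.DataFrame(meta_rows, columns=REPORT_SCHEMAS["meta"]), seed)

    # ---- stage: MVMR ----------------------------------------------------
    mvmr_rows = []
    try:
        block = _sim_block(config, "mvmr")
        if block is None:
            note("mvmr", "skipped: no mvmr block")
        else:
            mcfg = _sim_config(block, seed + STAGE_SEED_OFFSETS["mvmr"])
            exposures, outcome, _ = simulate_mvmr(mcfg)
            design, G, sG, _ids = build_mvmr_design(exposures, outcome, None, params)
            retained = lasso_select_exposures(design, G, 1.0 / sG**2, seed=seed)
            fit = mvmr_fit(design[retained], G, sG, outcome.trait_name)
            model = "+".join(retained)
            for _, row in fit.table.iterrows():
                mvmr_rows.append(
                    {
                        "exposure": row["exposure"], "model": model, "outcome": fit.outcome,
                        "or_": row["or_"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                        "pval": row["pval"], "direct_beta": row["direct_beta"], "se": row["se"],
                        "n_snp": fit.n_snp,
                    }
                )
            note("mvmr", f"{len(retained)}/{design.shape[1]} exposures retained, {fit.n_snp} SNPs")
    except SummrError as exc:
        failed.append("mvmr")
        note("mvmr", f"FAILED: {exc}")
    _write(out / "mvmr.tsv", pd.DataFrame(mvmr_rows, columns=REPORT_SCHEMAS["mvmr"]), seed)

    # ---- stage: two-step mediation + coloc + TWAS (proteome bundle) -----
    mediation_rows, coloc_rows = [], []
    twas_df = pd.DataFrame()
    bundle = None
    try:
        block = _sim_block(config, "proteome")
        if block is None:
            note("mediation", "skipped: no proteome block")
        else:
            pcfg = _sim_config(block, seed + STAGE_SEED_OFFSETS["mediation"])
            bundle = simulate_proteome_and_weights(pcfg)
            pqtl_params = SelectionParams(
                p_threshold=thr["pqtl_p"], clump_r2=thr["pqtl_clump_r2"],
                clump_window_bp=int(thr["pqtl_clump_kb"]) * 1_000,
                f_min=thr["f_min"], r2_formula="normalized",
            )
            step1 = []
            for prot, tab in bundle["proteins"].items():
                iset = build_instrument_set(tab, None, pqtl_params)
                if len(iset) == 0:
                    continue
                pair = harmonize_pair(tab, bundle["disease_at_pqtl"], iset.variant_ids)
                if pair.n_snp:
                    step1.append(ivw(pair))
            pol = bundle["pollutant"]
            pol_iset = build_instrument_set(pol, None, params)
            step2 = []
            for prot, tab in bundle["protein_at_pollutant"].items():
                pair = harmonize_pair(pol, tab, pol_iset.variant_ids)
                if pair.n_snp:
                    step2.append(ivw(pair))
            results = two_step_mediation(step1, step2, thr["fdr"], thr["alpha"])
            for r in results:
                mediation_rows.append(
                    {
                        "pollutant": r.pollutant, "protein": r.protein, "disease": r.disease,
                        "beta1": r.beta1, "se1": r.se1, "beta2": r.beta2, "se2": r.se2,
                        "indirect": r.indirect, "indirect_se": r.indirect_se,
                        "indirect_pval": r.indirect_pval, "step1_fdr_q": r.step1_fdr_q,
                    }
                )
            note("mediation", f"{len(mediation_rows)} mediated chains")
    except SummrError as exc:
        failed.append("mediation")
        note("mediation", f"FAILED: {exc}")
    _write(out / "mediation.tsv", pd.DataFrame(mediation_rows, columns=REPORT_SCHEMAS["mediation"]), seed)

    try:
        block = _sim_block(config, "coloc")
        if block is None:
            note("coloc", "skipped: no coloc block")
        else:
            n_regions = int(block.get("n_regions", 3))
            for i in range(n_regions):
                ccfg = _sim_config(block, seed + STAGE_SEED_OFFSETS["coloc"] + i,
                                   drop={"n_regions"})
                t1, t2, _ld, _truth = simulate_coloc_region(ccfg)
                res = coloc_tables(t1, t2, PRIOR_W_QUANT, PRIOR_W_BINARY)
                coloc_rows.append(
                    {
                        "region": f"{res.region[0]}:{res.region[1]}-{res.region[2]}",
                        "lead_variant": res.lead_variant, "n_snps": res.n_snps,
                        "pph0": res.pph0, "pph1": res.pph1, "pph2": res.pph2,
                        "pph3": res.pph3, "pph4": res.pph4,
                        "colocalized": res.pph4 > thr["pph4"],
                    }
                )
            note("coloc", f"{len(coloc_rows)} regions")
    except SummrError as exc:
        failed.append("coloc")
        note("coloc", f"FAILED: {exc}")
    _write(out / "coloc.tsv", pd.DataFrame(coloc_rows, columns=REPORT_SCHEMAS["coloc"]), seed)

    try:
        if bundle is None:
            note("twas", "skipped: no proteome/weights block")
        else:
            ld = bundle["ld"]
            per_trait: dict[str, list] = {}
            for trait, zser in bundle["gwas_z"].items():
                assocs = []
                for gw in bundle["gene_weights"]:
                    a = twas_association(gw, zser, ld)
                    a.trait = trait
                    assocs.append(a)
                per_trait[trait] = assocs
            pollutants = {t: a for t, a in per_trait.items() if t != "disease"}
            twas_df = concordant_overlap_and_rank(per_trait["disease"], pollutants, thr["alpha"])
            note("twas", f"{len(twas_df)} overlap genes")
    except SummrError as exc:
        failed.append("twas")
        note("twas", f"FAILED: {exc}")
    _write(out / "twas_overlap.tsv", twas_df, seed)

    log_lines.append("failed_stages " + (",".join(failed) if failed else "none"))
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return 1 if failed else 0


def _write(path: Path, df: pd.DataFrame, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# summr {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _sim_block(config: dict, name: str):
    sim = config.get("simulate") or {}
    block = sim.get(name)
    if block is None:
        return None
    if block.get("enabled", True) is False:
        return None
    return dict(block)


_SIM_FIELDS = set(SimConfig.__dataclass_fields__)


def _sim_config(block: dict, seed: int, drop: set | None = None) -> SimConfig:
    kwargs = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in block.items()
        if k in _SIM_FIELDS and k != "seed" and k not in (drop or set())
    }
    unknown = [k for k in block if k not in _SIM_FIELDS
               and k not in ("enabled", "n_outcomes", "n_regions") and k not in (drop or set())]
    if unknown:
        raise SummrError(f"unknown simulate keys: {unknown}")
    return SimConfig(seed=seed, **kwargs)


def _collect_tsmr_pairs(config: dict, seed: int, params: SelectionParams):
    """Exposure–outcome HarmonizedPairs from files and/or simulate blocks."""
    pairs = []
    for spec in config.get("exposure_outcome_files") or []:
        exposure = read_association_table(
            spec["exposure_path"], spec.get("exposure_name", "exposure"),
            spec.get("exposure_type", "quantitative"),
        )
        outcome = read_association_table(
            spec["outcome_path"], spec.get("outcome_name", "outcome"),
            spec.get("outcome_type", "binary"),
        )
        iset = build_instrument_set(exposure, None, params)
        pairs.append(
            (exposure.trait_name, outcome.trait_name,
             harmonize_pair(exposure, outcome, iset.variant_ids))
        )
    block = _sim_block(config, "two_sample")
    if block is not None:
        n_expo = int(block.get("n_exposures", 1))
        n_outc = int(block.get("n_outcomes", 1))
        for e in range(n_expo):
            for o in range(n_outc):
                child = seed + STAGE_SEED_OFFSETS["tsmr"] + 100 * e + o
                cfg = _sim_config(block, child)
                exposure, outcome, _ = simulate_two_sample(cfg)
                ename, oname = f"exposure_{e + 1}", f"outcome_{o + 1}"
                iset = build_instrument_set(exposure, None, params)
                pair = harmonize_pair(exposure, outcome, iset.variant_ids)
                pair.exposure_name, pair.outcome_name = ename, oname
                pairs.append((ename, oname, pair))
    return pairs


def describe_config(config: dict) -> str:
    thr = _thresholds(config)
    return yaml.safe_dump({"thresholds": thr, "simulate": config.get("simulate")})
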