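"""Instrument selection and quality control.

The selection protocol: variants associated with the exposure at
p < 5e-6, pruned to approximate linkage independence (pairwise r² < 0.001
within 10 Mb, greedy by ascending p), scored for variance explained and
per-instrument F statistic, with weak instruments (F < 10) and variants
strongly associated with the outcome (p < 5e-8) removed.

Two variance-explained formulas are available.  The ``verbatim`` form
R² = 2·EAF·(1−EAF)·(beta/SE)² has no sample-size normalization and can
exceed 1 for strong instruments; rows where that happens are flagged
invalid rather than clamped.  The ``normalized`` form
R² = z²/(z² + N − K − 1) is bounded in (0,1) and yields F ≈ z².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gwas_io import AssociationTable, HarmonizedPair, LDMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the instrument-selection protocol (study defaults)."""

    p_threshold: float = 5e-6
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    outcome_p_exclusion: float = 5e-8
    k_per_instrument: int = 1
    r2_formula: str = "verbatim"  # or "normalized"


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure with per-row R² and F."""

    exposure_name: str
    data: pd.DataFrame  # variant_id, gamma, se_gamma, eaf, n, r2_explained, f_stat
    params: SelectionParams = field(default_factory=SelectionParams)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data["variant_id"])

    @property
    def r2_sum(self) -> float:
        """Set-level variance explained (sum over instruments); feeds power."""
        return float(self.data["r2_explained"].sum())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class FStatResult:
    r2: float
    f: float
    valid: bool


def select_by_pvalue(table: AssociationTable, p_threshold: float = 5e-6) -> list[str]:
    """Ids with p strictly below threshold, ascending p (ties by id)."""
    df = table.data
    hits = df.loc[df["pval"] < p_threshold, ["variant_id", "pval"]]
    hits = hits.sort_values(["pval", "variant_id"], kind="mergesort")
    return list(hits["variant_id"])


def ld_clump(
    candidates: list[str],
    table: AssociationTable,
    ld: LDMatrix | None,
    clump_r2: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    A candidate is kept iff no already-kept variant on the same chromosome
    lies within ``window_bp`` with pairwise r² >= ``clump_r2``.  LD pairs
    absent from ``ld`` are treated as r = 0 (counted and logged once);
    ``ld=None`` treats all pairs as unlinked.
    """
    idx = table.data.set_index("variant_id")
    absent = [v for v in candidates if v not in idx.index]
    if absent:
        raise ValidationError(f"clump candidate(s) absent from table: {absent[:5]}")
    order = sorted(candidates, key=lambda v: (idx.loc[v, "pval"], v))
    kept: list[str] = []
    n_missing = 0
    for vid in order:
        chrom, pos = idx.loc[vid, "chrom"], idx.loc[vid, "pos"]
        conflict = False
        for kv in kept:
            if idx.loc[kv, "chrom"] != chrom:
                continue
            if abs(int(idx.loc[kv, "pos"]) - int(pos)) > window_bp:
                continue
            r2 = ld.r2(vid, kv) if ld is not None else None
            if r2 is None:
                n_missing += 1
                continue
            if r2 >= clump_r2:
                conflict = True
                break
        if not conflict:
            kept.append(vid)
    if n_missing:
        logger.warning("ld_clump: %d within-window pairs missing from LD (r=0 assumed)", n_missing)
    return kept


def variance_explained_and_f(
    beta: float,
    se: float,
    eaf: float,
    n: int,
    k: int = 1,
    formula: str = "verbatim",
) -> FStatResult:
    """Per-instrument variance explained and F statistic.

    F = (R²/K) / [(1−R²)/(N−K−1)].  Under the verbatim R² formula a strong
    instrument can produce R² >= 1; the result is then flagged invalid and
    carries the computed values unchanged (never clamped).
    """
    if not 0 < eaf < 1:
        raise ValidationError(f"eaf {eaf} outside (0,1)")
    if se <= 0:
        raise ValidationError(f"se {se} <= 0")
    if n <= k + 1:
        raise ValidationError(f"n={n} must exceed k+1={k + 1}")
    z = beta / se
    if formula == "verbatim":
        r2 = 2.0 * eaf * (1.0 - eaf) * z**2
    elif formula == "normalized":
        r2 = z**2 / (z**2 + n - k - 1)
    else:
        raise ValidationError(f"unknown r2_formula {formula!r}")
    if r2 >= 1.0:
        f = (r2 / k) / ((1.0 - r2) / (n - k - 1)) if r2 != 1.0 else np.inf
        return FStatResult(r2=r2, f=f, valid=False)
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return FStatResult(r2=r2, f=f, valid=True)


def score_instruments(
    table: AssociationTable,
    variant_ids: list[str],
    params: SelectionParams = SelectionParams(),
) -> InstrumentSet:
    """Attach R² and F to the given variants of an exposure table.

    Rows whose verbatim R² reaches 1 are excluded (flagged upstream of the
    weak-instrument filter) with a warning.
    """
    sub = table.subset(variant_ids).data
    rows, n_invalid = [], 0
    for _, r in sub.iterrows():
        res = variance_explained_and_f(
            r["beta"], r["se"], r["eaf"], int(r["n"]),
            k=params.k_per_instrument, formula=params.r2_formula,
        )
        if not res.valid:
            n_invalid += 1
            continue
        rows.append(
            {
                "variant_id": r["variant_id"],
                "gamma": r["beta"],
                "se_gamma": r["se"],
                "eaf": r["eaf"],
                "n": int(r["n"]),
                "r2_explained": res.r2,
                "f_stat": res.f,
            }
        )
    if n_invalid:
        logger.warning("score_instruments: %d row(s) with R² >= 1 flagged invalid", n_invalid)
    cols = ["variant_id", "gamma", "se_gamma", "eaf", "n", "r2_explained", "f_stat"]
    return InstrumentSet(table.trait_name, pd.DataFrame(rows, columns=cols), params)


def filter_weak(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Retain rows with F >= f_min (boundary F = f_min is kept)."""
    kept = instruments.data[instruments.data["f_stat"] >= f_min].reset_index(drop=True)
    return replace(instruments, data=kept)


def drop_outcome_associated(
    pair: HarmonizedPair, outcome_p_threshold: float = 5e-8
) -> HarmonizedPair:
    """Remove instruments genome-wide associated with the outcome.

    Outcome p recomputed as a two-sided normal tail of Gamma/se_Gamma; the
    pair's log records each removal.
    """
    if len(pair) == 0:
        return pair
    z = pair.data["Gamma"].to_numpy(float) / pair.data["se_Gamma"].to_numpy(float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    keep = p >= outcome_p_threshold
    log = dict(pair.log)
    for vid in pair.data.loc[~keep, "variant_id"]:
        log[vid] = "dropped-outcome-associated"
    return HarmonizedPair(
        pair.exposure_name, pair.outcome_name,
        pair.data[keep].reset_index(drop=True), log,
    )


def build_instrument_set(
    table: AssociationTable,
    ld: LDMatrix | None = None,
    params: SelectionParams = SelectionParams(),
) -> InstrumentSet:
    """Full selection chain: p-threshold → LD clump → score → weak filter."""
    candidates = select_by_pvalue(table, params.p_threshold)
    kept = ld_clump(candidates, table, ld, params.clump_r2, params.clump_window_bp)
    scored = score_instruments(table, kept, params)
    return filter_weak(scored, params.f_min)


def read_instrument_table(path, exposure_name: str = "", f_column: str = "f_stat") -> InstrumentSet:
    """Read a serialized instrument table (one row per instrument with F)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if f_column not in df.columns:
        raise ValidationError(f"{path}: no F-statistic column {f_column!r}")
    df = df.rename(columns={f_column: "f_stat"})
    return InstrumentSet(exposure_name, df)
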