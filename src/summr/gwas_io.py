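"""Reading, validation, and allele harmonization of GWAS summary statistics.

Every downstream stage consumes one of three containers defined here:

``AssociationTable``
    Per-variant summary statistics for a single trait (beta, SE, EAF, p, N).
``LDMatrix``
    Signed pairwise correlation (r) between variants; r-squared on demand.
``HarmonizedPair``
    Allele-aligned SNP-exposure / SNP-outcome effect pairs restricted to a
    set of instruments — the unit of all MR estimation.

Tables are tab-separated text with a fixed nine-column schema; gzip is
handled transparently by extension.  Variants are matched across tables by
identifier only (rsID-keyed summary files), never by position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError, ValidationError

REQUIRED_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Harmonization actions recorded per instrument.
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_MISSING = "dropped-missing"
DROPPED_IRRECONCILABLE = "dropped-irreconcilable"


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC_PAIRS


@dataclass
class AssociationTable:
    """Validated per-variant GWAS summary statistics for one trait.

    Parameters
    ----------
    trait_name
        Label carried into every result that uses this table.
    trait_type
        ``"binary"`` (beta is a log odds ratio) or ``"quantitative"``
        (beta in SD units).
    data
        DataFrame with the nine required columns; row order is preserved.
    """

    trait_name: str
    trait_type: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValidationError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.data = self.data.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        problems: list[str] = []

        def offending(mask: pd.Series, what: str) -> None:
            rows = np.flatnonzero(mask.to_numpy())
            if rows.size:
                lines = ", ".join(str(i + 1) for i in rows[:20])
                more = "" if rows.size <= 20 else f" (+{rows.size - 20} more)"
                problems.append(f"{what} at row(s) {lines}{more}")

        if len(df):
            offending(~(df["se"] > 0), "se <= 0")
            offending(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0,1)")
            offending(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0,1]")
            offending(~(df["pos"] >= 1), "pos < 1")
            offending(~(df["n"] > 0), "n <= 0")
            for col in ("effect_allele", "other_allele"):
                offending(~df[col].isin(list(_BASES)), f"non-ACGT {col}")
            offending(
                df["effect_allele"] == df["other_allele"], "identical alleles"
            )
            dup = df["variant_id"].duplicated(keep=False)
            offending(dup, "duplicate variant_id")
        if problems:
            raise ValidationError(
                f"invalid association table {self.trait_name!r}: " + "; ".join(problems)
            )

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, variant_ids: list[str]) -> "AssociationTable":
        """Rows for the given ids, in the given order (all must exist)."""
        idx = self.data.set_index("variant_id")
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise ValidationError(f"variant(s) absent from table: {missing[:5]}")
        sub = idx.loc[variant_ids].reset_index()
        return AssociationTable(self.trait_name, self.trait_type, sub[list(REQUIRED_COLUMNS)])


def read_association_table(
    path,
    trait_name: str,
    trait_type: str,
    column_map: dict[str, str] | None = None,
) -> AssociationTable:
    """Read a GWAS summary TSV (gzip-transparent) into a validated table.

    ``column_map`` maps file column names to the canonical schema, e.g.
    ``{"SNP": "variant_id", "P": "pval"}``.  Parse failures are reported
    with 1-based data line numbers.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", compression="infer", dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) after mapping: {', '.join(missing)}"
        )
    df = df[list(REQUIRED_COLUMNS)]
    for col, kind in (("pos", "Int64"), ("n", "Int64")):
        try:
            df[col] = df[col].astype(kind).astype("int64" if len(df) else "int64")
        except (TypeError, ValueError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            rows = [str(i + 1) for i in np.flatnonzero(bad.to_numpy())[:10]]
            raise SchemaError(
                f"{path}: non-integer {col} at data line(s) {', '.join(rows)}"
            ) from exc
    return AssociationTable(trait_name, trait_type, df)


def write_association_table(table: AssociationTable, path, seed: int | None = None) -> None:
    """Write TSV with a commented provenance header (version + seed)."""
    buf = io.StringIO()
    buf.write(f"# summr {__version__} trait={table.trait_name} type={table.trait_type}")
    if seed is not None:
        buf.write(f" seed={seed}")
    buf.write("\n")
    table.data.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValidationError(f"LD matrix shape {self.r.shape} != ({m},{m})")
        if m == 0:
            self._index = {}
            return
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValidationError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValidationError("LD correlation with |r| > 1")
        evals = np.linalg.eigvalsh(self.r)
        if evals.min() < -1e-8:
            raise ValidationError(
                f"LD matrix not PSD (min eigenvalue {evals.min():.3g})"
            )
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float | None:
        """Squared correlation, or None if either variant is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    def subset(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LDMatrix:
    """Square TSV, header row and first column both variant ids, signed r."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: LD matrix row/column ids differ")
    return LDMatrix([str(v) for v in df.columns], df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# summr {__version__} ld_matrix")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
            fh, sep="\t", float_format="%.12g"
        )


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effects for a set of instruments.

    ``data`` columns: variant_id, gamma, se_gamma, Gamma, se_Gamma, eaf
    (exposure side), n_exposure, n_outcome.  ``log`` records one action per
    requested instrument.
    """

    exposure_name: str
    outcome_name: str
    data: pd.DataFrame
    log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data):
            if not (self.data["se_gamma"] > 0).all() or not (self.data["se_Gamma"] > 0).all():
                raise ValidationError("harmonized pair with non-positive SE")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.data
        return (
            d["gamma"].to_numpy(float),
            d["se_gamma"].to_numpy(float),
            d["Gamma"].to_numpy(float),
            d["se_Gamma"].to_numpy(float),
        )


def pair_from_arrays(
    gamma, se_gamma, Gamma, se_Gamma, exposure_name="exposure", outcome_name="outcome",
    variant_ids=None, eaf=None, n_exposure=0, n_outcome=0,
) -> HarmonizedPair:
    """Build a HarmonizedPair directly from effect arrays (no allele logic)."""
    gamma = np.asarray(gamma, float)
    k = gamma.size
    if variant_ids is None:
        variant_ids = [f"snp_{i + 1}" for i in range(k)]
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gamma": gamma,
            "se_gamma": np.asarray(se_gamma, float),
            "Gamma": np.asarray(Gamma, float),
            "se_Gamma": np.asarray(se_Gamma, float),
            "eaf": np.full(k, 0.5) if eaf is None else np.asarray(eaf, float),
            "n_exposure": n_exposure,
            "n_outcome": n_outcome,
        }
    )
    return HarmonizedPair(exposure_name, outcome_name, df, {v: KEPT for v in variant_ids})


def harmonize_pair(
    exposure: AssociationTable,
    outcome: AssociationTable,
    instrument_ids: list[str],
    palindrome_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect-allele orientation.

    For each instrument present in both tables: matching allele labels keep
    the outcome beta; swapped labels negate it (and complement the outcome
    EAF); a strand flip (complementing both outcome alleles) is attempted
    before declaring the pair irreconcilable.  Palindromic variants (A/T or
    C/G) carry no label information, so strand is inferred from EAF — and
    the variant is dropped whenever either trait's EAF falls inside
    ``palindrome_band`` (or the outcome EAF is missing).
    """
    exp_idx = exposure.data.set_index("variant_id")
    out_idx = outcome.data.set_index("variant_id")
    unknown = [v for v in instrument_ids if v not in exp_idx.index]
    if unknown:
        raise ValidationError(f"instrument(s) absent from exposure table: {unknown[:5]}")

    lo, hi = palindrome_band
    rows = []
    log: dict[str, str] = {}
    for vid in instrument_ids:
        e = exp_idx.loc[vid]
        if vid not in out_idx.index:
            log[vid] = DROPPED_MISSING
            continue
        o = out_idx.loc[vid]
        ea, oa = e["effect_allele"], e["other_allele"]
        oea, ooa = o["effect_allele"], o["other_allele"]
        for a in (ea, oa, oea, ooa):
            if a not in _BASES:
                raise ValidationError(f"non-ACGT allele {a!r} at {vid}")

        if _is_palindromic(ea, oa):
            if frozenset((oea, ooa)) != frozenset((ea, oa)):
                log[vid] = DROPPED_IRRECONCILABLE
                continue
            eaf_o = o["eaf"]
            if pd.isna(eaf_o) or lo < e["eaf"] < hi or lo < eaf_o < hi:
                log[vid] = DROPPED_PALINDROMIC
                continue
            # Labels are strand-ambiguous: align by minor-allele side only.
            if (e["eaf"] - 0.5) * (eaf_o - 0.5) > 0:
                action, beta_o = KEPT, o["beta"]
            else:
                action, beta_o = FLIPPED, -o["beta"]
        else:
            if (oea, ooa) == (ea, oa):
                action, beta_o = KEPT, o["beta"]
            elif (oea, ooa) == (oa, ea):
                action, beta_o = FLIPPED, -o["beta"]
            else:
                cea, coa = _COMPLEMENT[oea], _COMPLEMENT[ooa]
                if (cea, coa) == (ea, oa):
                    action, beta_o = KEPT, o["beta"]
                elif (cea, coa) == (oa, ea):
                    action, beta_o = FLIPPED, -o["beta"]
                else:
                    log[vid] = DROPPED_IRRECONCILABLE
                    continue

        log[vid] = action
        rows.append(
            {
                "variant_id": vid,
                "gamma": float(e["beta"]),
                "se_gamma": float(e["se"]),
                "Gamma": float(beta_o),
                "se_Gamma": float(o["se"]),
                "eaf": float(e["eaf"]),
                "n_exposure": int(e["n"]),
                "n_outcome": int(o["n"]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gamma", "se_gamma", "Gamma", "se_Gamma",
            "eaf", "n_exposure", "n_outcome",
        ],
    )
    return HarmonizedPair(exposure.trait_name, outcome.trait_name, df, log)
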