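"""Reading, validating and writing GWAS/eQTL summary statistics and LD matrices.

File dialect
------------
Summary statistics are tab-delimited text with a header row and columns

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``pos`` is a 1-based base-pair coordinate. ``eaf`` and ``n`` may be missing,
rendered as ``NA``. Foreign headers are handled through a ``column_map``
from the canonical names above to the names found in the file.

LD matrices are square labelled tab-delimited tables of pairwise r²: the
first row and first column carry SNP identifiers, the body is numeric. The
matrix is consumed (from a reference panel product), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import SnpLookupError, SumstatsFormatError, SumstatsValidationError

VALID_ALLELES = {"A", "C", "G", "T"}

#: canonical column order of the on-disk and in-memory tables
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-trait association — the atomic unit of every input table."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def validate(self, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"alleles must be single bases A/C/G/T, got {ea!r}/{oa!r}{where}"
            )
        if ea == oa:
            raise SumstatsValidationError(f"effect and other allele identical{where}")
        if not self.se > 0:
            raise SumstatsValidationError(f"se must be > 0, got {self.se}{where}")
        if self.eaf is not None and not np.isnan(self.eaf):
            if not 0.0 <= self.eaf <= 1.0:
                raise SumstatsValidationError(f"eaf outside [0, 1]: {self.eaf}{where}")
        if not (0.0 < self.pval <= 1.0):
            raise SumstatsValidationError(f"pval outside (0, 1]: {self.pval}{where}")


def records_to_frame(records: list[SummaryStatRecord]) -> pd.DataFrame:
    """Pack records into the canonical DataFrame layout."""
    data = {f.name: [getattr(r, f.name) for r in records] for f in fields(SummaryStatRecord)}
    df = pd.DataFrame(data, columns=COLUMNS)
    if len(df) == 0:
        df = pd.DataFrame(columns=COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    out = []
    for t in df.itertuples(index=False):
        d = t._asdict()
        out.append(SummaryStatRecord(**{k: d[k] for k in COLUMNS}))
    return out


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistics table row by row.

    Raises :class:`SumstatsValidationError` citing the 1-based row number of
    the first offending row. Alleles are upper-cased in place; indels
    (multi-base alleles) are rejected — this pipeline is SNP-only.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    for num_col in ("eaf", "beta", "se", "pval", "n"):
        df[num_col] = pd.to_numeric(df[num_col], errors="coerce")
    df["pos"] = df["pos"].astype(np.int64)
    for i, rec in enumerate(frame_to_records(df), start=1):
        eaf = None if pd.isna(rec.eaf) else float(rec.eaf)
        n = None if pd.isna(rec.n) else float(rec.n)
        SummaryStatRecord(
            rec.snp_id, rec.chrom, int(rec.pos), rec.effect_allele, rec.other_allele,
            eaf, float(rec.beta), float(rec.se), float(rec.pval), n,
        ).validate(row=i)
    return df


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical table.

    Parameters
    ----------
    path
        Tab-delimited text file with a header row.
    column_map
        Optional mapping ``{canonical_name: file_column_name}`` for foreign
        headers; unmapped canonical names are looked up verbatim.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str},
                      na_values=["NA"], keep_default_na=False)
    column_map = column_map or {}
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SumstatsFormatError(
                f"column '{src}' (for field '{canon}') not found in {path}"
            )
        rename[src] = canon
    df = raw.rename(columns=rename)[COLUMNS]
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical table as tab-delimited text, missing values as NA."""
    out = df[COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over a labelled SNP set."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise SumstatsFormatError(
                f"LD matrix shape {r2.shape} does not match {k} SNP ids"
            )
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise SumstatsValidationError("LD matrix diagonal must be 1")
        if np.nanmax(np.abs(r2 - r2.T)) > 1e-8:
            raise SumstatsValidationError("LD matrix is not symmetric")
        if np.nanmin(r2) < -1e-12 or np.nanmax(r2) > 1.0 + 1e-8:
            raise SumstatsValidationError("LD r² entries must lie in [0, 1]")

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        idx = self.index
        for s in (a, b):
            if s not in idx:
                raise SnpLookupError(f"SNP '{s}' absent from LD matrix")
        return float(self.r2[idx[a], idx[b]])

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        idx = self.index
        missing = [s for s in ids if s not in idx]
        if missing:
            raise SnpLookupError(f"SNP(s) absent from LD matrix: {', '.join(missing)}")
        sel = [idx[s] for s in ids]
        return LDMatrix(tuple(ids), self.r2[np.ix_(sel, sel)])


def read_ld_matrix(path) -> LDMatrix:
    """Read a square labelled r² matrix; symmetrize tiny (≤1e-8) asymmetries."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SumstatsFormatError(f"LD matrix is not square: {df.shape}")
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise SumstatsFormatError("LD matrix row and column labels disagree")
    r2 = df.to_numpy(dtype=float)
    asym = np.max(np.abs(r2 - r2.T)) if r2.size else 0.0
    if asym > 1e-8:
        raise SumstatsValidationError(f"LD matrix asymmetric beyond 1e-8 ({asym:.3g})")
    r2 = 0.5 * (r2 + r2.T)
    # clamp round-trip noise at the boundaries, not genuine violations
    if np.min(r2) > -1e-12:
        r2 = np.clip(r2, 0.0, None)
    return LDMatrix(tuple(ids), r2)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")
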