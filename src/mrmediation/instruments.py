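"""Instrument selection for two-sample MR.

Genetic instruments for a GWAS exposure are chosen by (1) an association
p-value filter, (2) greedy LD clumping — within a distance window on the
same chromosome, keep the SNP with the smallest p-value among pairs whose
r² is at or above the clumping threshold — and (3) a per-SNP instrument
strength (F-statistic) filter. Gene-expression exposures use the cis-eQTL
variant: restrict to a window around the gene, then prune on r² alone with
no distance window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError, SnpLookupError
from .sumstats import LDMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline.

    Defaults: candidate SNPs at P < 1e-5; clumping at r² < 0.01 within a
    30 kb window; per-SNP F > 10; cis-eQTL window ±1 Mb around the gene
    with pruning at r² < 0.30.
    """

    p_threshold: float = 1.0e-5
    clump_r2: float = 0.01
    clump_window_kb: float = 30.0
    f_min: float = 10.0
    cis_window_bp: int = 1_000_000
    eqtl_r2: float = 0.30

    def __post_init__(self):
        for name in ("p_threshold", "clump_r2", "clump_window_kb", "f_min", "cis_window_bp", "eqtl_r2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("clump_r2", "eqtl_r2"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def compute_f_stat(beta: float, se: float, *, eaf: float | None = None,
                   n: float | None = None, method: str = "wald") -> float:
    """Per-SNP instrument-strength statistic.

    ``wald`` (default): F = (beta/se)², the squared Wald z — the standard
    summary-data approximation. ``r2``: F = (n−2)·R²/(1−R²) with
    R² = 2p(1−p)β², requiring ``eaf`` and ``n`` (standardized traits).
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    if method == "wald":
        return float((beta / se) ** 2)
    if method == "r2":
        if eaf is None or n is None:
            raise ValueError("method='r2' requires eaf and n")
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
        if r2 >= 1:
            raise ValueError("implied R² ≥ 1; check the scale of beta")
        return float((n - 2) * r2 / (1 - r2))
    raise ValueError(f"unknown F-statistic method {method!r}")


def _greedy_prune(df: pd.DataFrame, ld: LDMatrix, r2_threshold: float,
                  window_bp: float | None) -> pd.DataFrame:
    """Greedy index-SNP pruning.

    Rank by p ascending (ties: smaller position, then snp_id). Repeatedly
    promote the best remaining SNP and discard remaining SNPs in conflict
    with it: r² ≥ ``r2_threshold`` and, when ``window_bp`` is given, on the
    same chromosome within that distance. ``window_bp=None`` applies the r²
    rule genome-wide. Retained rows come back in original input order.
    """
    idx = ld.index
    missing = [s for s in df["snp_id"] if s not in idx]
    if missing:
        raise SnpLookupError(f"SNP(s) absent from LD matrix: {', '.join(missing)}")

    order = df.sort_values(["pval", "pos", "snp_id"], kind="mergesort").index.to_list()
    alive = set(order)
    kept: set = set()
    while order:
        head = order.pop(0)
        if head not in alive:
            continue
        kept.add(head)
        alive.discard(head)
        h = df.loc[head]
        for other in list(alive):
            o = df.loc[other]
            if window_bp is not None:
                if o["chrom"] != h["chrom"] or abs(int(o["pos"]) - int(h["pos"])) > window_bp:
                    continue
            if ld.r2[idx[h["snp_id"]], idx[o["snp_id"]]] >= r2_threshold:
                alive.discard(other)
    return df.loc[[i for i in df.index if i in kept]]


def ld_clump(candidates: pd.DataFrame, ld: LDMatrix, config: SelectionConfig) -> pd.DataFrame:
    """Greedy LD clumping at ``clump_r2`` within ``clump_window_kb``."""
    return _greedy_prune(candidates, ld, config.clump_r2, config.clump_window_kb * 1000.0)


def _attach_f(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    return df


def select_instruments(sumstats: pd.DataFrame, ld: LDMatrix,
                       config: SelectionConfig | None = None) -> pd.DataFrame:
    """P-filter → LD clump → F-filter; returns instruments with ``f_stat``.

    Raises :class:`NoInstrumentsError` when nothing survives — downstream
    estimators require at least one SNP.
    """
    config = config or SelectionConfig()
    cand = sumstats[sumstats["pval"] < config.p_threshold]
    log.info("p < %.3g: %d of %d SNPs retained", config.p_threshold, len(cand), len(sumstats))
    if len(cand) == 0:
        raise NoInstrumentsError(
            f"no SNP passes p < {config.p_threshold:g} ({len(sumstats)} candidates)"
        )
    clumped = ld_clump(cand, ld, config)
    log.info("LD clump (r² < %g, %g kb): %d retained", config.clump_r2,
             config.clump_window_kb, len(clumped))
    strong = _attach_f(clumped)
    strong = strong[strong["f_stat"] > config.f_min]
    log.info("F > %g: %d retained", config.f_min, len(strong))
    if len(strong) == 0:
        raise NoInstrumentsError("no instrument survives the F-statistic filter")
    return strong


def select_cis_eqtls(eqtl_stats: pd.DataFrame, gene_chrom: str, gene_start: int,
                     gene_end: int, ld: LDMatrix,
                     config: SelectionConfig | None = None) -> pd.DataFrame:
    """Select cis-eQTL instruments for a gene-expression exposure.

    Restrict to SNPs within ``cis_window_bp`` of the gene body on its
    chromosome, p-filter, greedy-prune at ``eqtl_r2`` (no distance window),
    then F-filter.
    """
    config = config or SelectionConfig()
    lo = gene_start - config.cis_window_bp
    hi = gene_end + config.cis_window_bp
    cis = eqtl_stats[
        (eqtl_stats["chrom"].astype(str) == str(gene_chrom))
        & (eqtl_stats["pos"] >= lo)
        & (eqtl_stats["pos"] <= hi)
    ]
    log.info("cis window %s:%d-%d: %d of %d SNPs", gene_chrom, lo, hi, len(cis), len(eqtl_stats))
    cand = cis[cis["pval"] < config.p_threshold]
    if len(cand) == 0:
        raise NoInstrumentsError("no cis-eQTL passes the p-value threshold")
    pruned = _greedy_prune(cand, ld, config.eqtl_r2, None)
    strong = _attach_f(pruned)
    strong = strong[strong["f_stat"] > config.f_min]
    if len(strong) == 0:
        raise NoInstrumentsError("no cis-eQTL instrument survives the F filter")
    return strong
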