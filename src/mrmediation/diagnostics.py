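"""Sensitivity analyses for a fitted MR instrument table.

Cochran's Q heterogeneity among per-SNP Wald ratios, the MR-Egger intercept
test for directional pleiotropy, an MR-PRESSO-style simulation test for
pleiotropic outliers (global RSS test plus per-SNP outlier p-values;
no distortion test), leave-one-out IVW, and plot-ready scatter/funnel data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, _arrays, _ratio_arrays, ivw, mr_egger


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios against the fixed-effects IVW.

    ``i2`` (Higgins' I² = max(0, (Q−df)/Q)) is reported as a convenience
    alongside Q; it is an extra of this implementation.
    """

    q: float
    df: int
    pval: float

    @property
    def i2(self) -> float:
        return max(0.0, (self.q - self.df) / self.q) if self.q > 0 else 0.0


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test and per-SNP outlier flags."""

    global_rss: float
    global_p: float
    outlier_pvals: pd.Series  # Bonferroni-adjusted, indexed by snp_id
    outlier_ids: tuple[str, ...]
    n_sim: int
    seed: int


def cochran_q(table: pd.DataFrame, order: str = "first") -> HeterogeneityResult:
    """Q = Σ wⱼ(βⱼ − β̂_fixed)², chi-square(J−1) under homogeneity."""
    bx, sx, by, sy, _ = _arrays(table)
    if bx.size < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 SNPs")
    r, se_r, w = _ratio_arrays(bx, sx, by, sy, order)
    beta = (w * r).sum() / w.sum()
    q = float((w * (r - beta) ** 2).sum())
    df = r.size - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(table: pd.DataFrame) -> tuple[float, float, float]:
    """(estimate, se, p) of the MR-Egger intercept — average pleiotropy."""
    fit = mr_egger(table)
    return fit.extra["intercept"], fit.extra["intercept_se"], fit.extra["intercept_pval"]


def _loo_ivw_fixed(bx, by, w):
    """Leave-one-out fixed-effects IVW slopes; w on the outcome scale (se_out⁻²)."""
    num = (w * bx * by).sum() - w * bx * by
    den = (w * bx * bx).sum() - w * bx * bx
    return num / den


def mr_presso(table: pd.DataFrame, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Simulation-based residual-sum-of-squares pleiotropy test.

    The observed statistic is Σⱼ wⱼ(β_outⱼ − β̂₋ⱼ·β_expⱼ)² with β̂₋ⱼ the
    leave-one-out fixed-effects IVW and wⱼ = se_outⱼ⁻² (residuals live on
    the outcome scale). The null distribution is built by redrawing both
    sides from their reported sampling distributions; the empirical p uses
    add-one smoothing so it is never exactly 0. Per-SNP outlier p-values are
    the empirical tails of each SNP's residual, Bonferroni-multiplied by J.
    """
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    bx, sx, by, sy, ids = _arrays(table)
    j = bx.size
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 SNPs")
    w = sy ** -2.0

    loo = _loo_ivw_fixed(bx, by, w)
    res_obs = w * (by - loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_sim, j))
    bys = rng.normal(loo * bx, sy, size=(n_sim, j))
    ws = np.broadcast_to(w, (n_sim, j))
    num = (ws * bxs * bys).sum(axis=1, keepdims=True) - ws * bxs * bys
    den = (ws * bxs * bxs).sum(axis=1, keepdims=True) - ws * bxs * bxs
    loo_s = num / den
    res_sim = ws * (bys - loo_s * bxs) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    tail = (1 + (res_sim >= res_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    adj = np.minimum(tail * j, 1.0)
    pvals = pd.Series(adj, index=pd.Index(ids, name="snp_id"))
    outliers = tuple(pvals.index[pvals < outlier_alpha])
    return PressoResult(rss_obs, global_p, pvals, outliers, n_sim, seed)


def leave_one_out(table: pd.DataFrame, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-fit excluding each SNP in turn, plus the all-SNP fit ('All')."""
    bx, sx, by, sy, ids = _arrays(table)
    if bx.size < 2:
        raise InsufficientInstrumentsError("leave-one-out needs at least 2 SNPs")
    keep_cols = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]
    t = table[~table["action"].str.startswith("dropped")][keep_cols] \
        if "action" in table.columns else table[keep_cols]
    rows = []
    for snp in ids:
        sub = t[t["snp_id"] != snp]
        est = ivw(sub, model=model)
        rows.append({"excluded": snp, "beta": est.beta, "se": est.se,
                     "pval": est.pval, "n_snps": est.n_snps})
    full = ivw(t, model=model)
    rows.append({"excluded": "All", "beta": full.beta, "se": full.se,
                 "pval": full.pval, "n_snps": full.n_snps})
    return pd.DataFrame(rows)


def funnel_and_scatter_data(table: pd.DataFrame,
                            methods: dict[str, MREstimate] | None = None,
                            order: str = "first") -> dict[str, pd.DataFrame]:
    """Plot-ready tables behind the scatter and funnel diagnostics.

    ``scatter`` holds per-SNP (β_exp, β_out) with SE bars plus one row per
    fitted method (slope, intercept); ``funnel`` holds each SNP's ratio
    against its precision 1/se_ratio.
    """
    bx, sx, by, sy, ids = _arrays(table)
    r, se_r, w = _ratio_arrays(bx, sx, by, sy, order)
    scatter = pd.DataFrame({"snp_id": ids, "beta_exp": bx, "se_exp": sx,
                            "beta_out": by, "se_out": sy})
    fits = []
    for name, est in (methods or {}).items():
        fits.append({"method": name, "slope": est.beta,
                     "intercept": est.extra.get("intercept", 0.0)})
    funnel = pd.DataFrame({"snp_id": ids, "ratio": r, "precision": 1.0 / se_r})
    return {"scatter": scatter, "fits": pd.DataFrame(fits, columns=["method", "slope", "intercept"]),
            "funnel": funnel}
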