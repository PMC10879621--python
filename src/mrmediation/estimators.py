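"""Two-sample MR causal-effect estimators.

Given a harmonized instrument table (per-SNP exposure and outcome effects
aligned to a common effect allele), the per-SNP Wald ratio β_out/β_exp is
combined by:

* **IVW** — inverse-variance-weighted meta-analysis of the ratios; with
  first-order ratio SEs this is identical to weighted least squares of
  β_out on β_exp through the origin with weights se_out⁻². The default is
  multiplicative random effects with the scale floored at 1.
* **MR-Egger** — weighted regression with an unconstrained intercept; the
  intercept estimates the average directional pleiotropy, the slope the
  causal effect. SNPs are oriented so β_exp ≥ 0 before fitting.
* **Weighted median** — the weighted 50th percentile of the ratios;
  consistent while valid instruments carry more than half the weight.
* **Simple / weighted mode** — the argmax of a normal-kernel density over
  the ratios (unweighted or IVW-weighted), with a modified Silverman
  bandwidth.
* **SMR** — single top-eQTL instrument for a gene-expression exposure with
  a chi-square test on the ratio.

Standard errors for the median and mode estimators come from a parametric
bootstrap (per-SNP effects resampled from their reported SEs); the seed is
a mandatory argument — there is no hidden global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError, NoInstrumentsError
from .sumstats import SummaryStatRecord

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio β_out/β_exp with its SE and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio ** -2


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log/SD scale, with OR and 95% CI."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    def as_row(self) -> dict:
        return {
            "method": self.method, "n_snps": self.n_snps, "beta": self.beta,
            "se": self.se, "pval": self.pval, "or": self.or_,
            "or_ci_low": self.ci_low, "or_ci_high": self.ci_high,
            **{k: v for k, v in self.extra.items() if np.isscalar(v)},
        }


def make_table(beta_exp, se_exp, beta_out, se_out, snp_id=None) -> pd.DataFrame:
    """Assemble a minimal harmonized table from parallel arrays (test/sim aid)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    if snp_id is None:
        snp_id = [f"snp{i + 1}" for i in range(beta_exp.size)]
    return pd.DataFrame({
        "snp_id": snp_id,
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, dtype=float),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.asarray(se_out, dtype=float),
    })


def _arrays(table: pd.DataFrame):
    t = table
    if "action" in t.columns:
        t = t[~t["action"].str.startswith("dropped")]
    return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float),
            t["snp_id"].astype(str).to_numpy() if "snp_id" in t.columns
            else np.array([f"snp{i+1}" for i in range(len(t))]))


def _require(table, k: int, method: str):
    bx, sx, by, sy, ids = _arrays(table)
    if bx.size == 0:
        raise NoInstrumentsError(f"{method}: empty instrument table")
    if bx.size < k:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {k} SNPs, got {bx.size}"
        )
    return bx, sx, by, sy, ids


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               order: str = "first", snp_id: str = "snp") -> RatioEstimate:
    """Per-SNP Wald ratio with first- or second-order standard error."""
    if beta_exp == 0:
        raise ZeroDivisionError(f"beta_exp is 0 for SNP {snp_id}")
    ratio = beta_out / beta_exp
    if order == "first":
        se = se_out / abs(beta_exp)
    elif order == "second":
        se = np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    return RatioEstimate(snp_id, float(ratio), float(se))


def ratio_estimates(table: pd.DataFrame, order: str = "first") -> list[RatioEstimate]:
    bx, sx, by, sy, ids = _arrays(table)
    return [wald_ratio(bx[j], sx[j], by[j], sy[j], order=order, snp_id=ids[j])
            for j in range(bx.size)]


def _ratio_arrays(bx, sx, by, sy, order="first"):
    r = by / bx
    if order == "first":
        se = sy / np.abs(bx)
    else:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return r, se, se**-2


def _two_sided_z(beta, se):
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def ivw(table: pd.DataFrame, model: str = "multiplicative_random",
        order: str = "first") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    ``model='fixed'`` uses se = (Σw)^(−1/2); ``'multiplicative_random'``
    (default) multiplies it by max(1, sqrt(Q/(J−1))) for J ≥ 2.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, sx, by, sy, _ = _require(table, 1, "IVW")
    r, se_r, w = _ratio_arrays(bx, sx, by, sy, order)
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    se_fixed = float(sw ** -0.5)
    q = float((w * (r - beta) ** 2).sum())
    j = r.size
    scale = 1.0
    if model == "multiplicative_random" and j >= 2:
        scale = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * scale
    return MREstimate("ivw_" + ("fixed" if model == "fixed" else "mre"), beta, se,
                      _two_sided_z(beta, se), j,
                      extra={"q": q, "model": model, "scale": scale,
                             "se_fixed": se_fixed})


def mr_egger(table: pd.DataFrame, order: str = "first") -> MREstimate:
    """MR-Egger weighted regression with intercept (pleiotropy) and slope.

    SNPs are oriented so β_exp ≥ 0; weights are se_out⁻²; coefficient SEs
    are scaled by max(1, sqrt(RSS_w/(J−2))) and tested against t(J−2).
    """
    bx, sx, by, sy, _ = _require(table, 3, "MR-Egger")
    flip = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * flip, by * flip
    w = sy ** -2.0
    # weighted normal equations for y = b0 + b1 x
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    j = x.size
    rss = float((w * resid**2).sum())
    sigma = max(1.0, np.sqrt(rss / (j - 2)))
    cov = np.linalg.inv(xtwx) * sigma**2
    se_b0, se_b1 = np.sqrt(np.diag(cov))
    p_b1 = float(2.0 * stats.t.sf(abs(coef[1]) / se_b1, df=j - 2))
    p_b0 = float(2.0 * stats.t.sf(abs(coef[0]) / se_b0, df=j - 2))
    return MREstimate("mr_egger", float(coef[1]), float(se_b1), p_b1, j,
                      extra={"intercept": float(coef[0]),
                             "intercept_se": float(se_b0),
                             "intercept_pval": p_b0,
                             "rss": rss, "sigma": sigma})


def _weighted_median_1d(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, J) ratio and weight arrays."""
    order = np.argsort(r, axis=1, kind="stable")
    r = np.take_along_axis(r, order, axis=1)
    w = np.take_along_axis(w, order, axis=1)
    s = np.cumsum(w, axis=1)
    p = (s - 0.5 * w) / s[:, -1:]
    below = p < 0.5
    k = below.sum(axis=1)  # index of first p >= 0.5
    B, J = r.shape
    out = np.empty(B)
    rows = np.arange(B)
    at_edge_lo = k == 0
    at_edge_hi = k == J
    out[at_edge_lo] = r[at_edge_lo, 0]
    out[at_edge_hi] = r[at_edge_hi, -1]
    mid = ~(at_edge_lo | at_edge_hi)
    if mid.any():
        kk = k[mid]
        rm, pm = r[mid], p[mid]
        rowm = np.arange(mid.sum())
        p0, p1 = pm[rowm, kk - 1], pm[rowm, kk]
        r0, r1 = rm[rowm, kk - 1], rm[rowm, kk]
        frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
        out[mid] = r0 + frac * (r1 - r0)
    return out


def _parametric_boot(bx, sx, by, sy, n_boot, seed, statistic):
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, bx.size))
    bys = rng.normal(by, sy, size=(n_boot, by.size))
    # guard exact zeros in the resampled exposure effects
    bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
    r = bys / bxs
    w = (sy / np.abs(bxs)) ** -2.0
    return statistic(r, w)


def weighted_median(table: pd.DataFrame, n_boot: int = 1000, seed: int | None = None,
                    order: str = "first") -> MREstimate:
    """Weighted-median MR estimate with parametric-bootstrap SE."""
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy, _ = _require(table, 3, "weighted median")
    r, se_r, w = _ratio_arrays(bx, sx, by, sy, order)
    beta = _weighted_median_1d(r, w)
    reps = _parametric_boot(bx, sx, by, sy, n_boot, seed, _weighted_median_rows)
    se = float(np.std(reps, ddof=1))
    return MREstimate("weighted_median", beta, se, _two_sided_z(beta, se), r.size,
                      extra={"n_boot": n_boot})


def _silverman_bw(r: np.ndarray, factor: float) -> float:
    j = r.size
    sd = np.std(r, ddof=1)
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 0.9 * s * j ** (-0.2) * factor
    return float(max(h, 1e-12))


def _mode_1d(r: np.ndarray, w: np.ndarray, factor: float) -> float:
    h = _silverman_bw(r, factor)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(table: pd.DataFrame, weighted: bool = False,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None, order: str = "first") -> MREstimate:
    """Simple (unweighted) or weighted mode-based MR estimate.

    The estimate is the argmax of a normal-kernel density over the per-SNP
    ratios on a 512-point grid spanning the ratio range ± 3 bandwidths, with
    a modified Silverman bandwidth 0.9·min(sd, IQR/1.349)·J^(−1/5).
    """
    if seed is None:
        raise ValueError("mode_estimate requires an explicit seed")
    bx, sx, by, sy, _ = _require(table, 3, "mode")
    r, se_r, w = _ratio_arrays(bx, sx, by, sy, order)
    wk = w if weighted else np.ones_like(r)
    beta = _mode_1d(r, wk, bandwidth_factor)

    def stat(rs, ws):
        if not weighted:
            ws = np.ones_like(rs)
        return np.array([_mode_1d(rs[b], ws[b], bandwidth_factor)
                         for b in range(rs.shape[0])])

    reps = _parametric_boot(bx, sx, by, sy, n_boot, seed, stat)
    se = float(np.std(reps, ddof=1))
    name = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(name, beta, se, _two_sided_z(beta, se), r.size,
                      extra={"n_boot": n_boot, "bandwidth_factor": bandwidth_factor})


def smr(top_eqtl: SummaryStatRecord, gwas: SummaryStatRecord) -> MREstimate:
    """Summary-data MR with a single top eQTL instrument.

    b_xy = β_GWAS/β_eQTL; T_SMR = z_GWAS²·z_eQTL²/(z_GWAS² + z_eQTL²) tested
    against chi-square(1); se = |b_xy|/sqrt(T_SMR). Assumes the two records
    are already on the same effect allele.
    """
    if top_eqtl.beta == 0:
        raise ZeroDivisionError(f"eQTL beta is 0 for SNP {top_eqtl.snp_id}")
    b_xy = gwas.beta / top_eqtl.beta
    z_g = gwas.beta / gwas.se
    z_e = top_eqtl.beta / top_eqtl.se
    if z_g == 0:
        t = 0.0
        se = np.inf
    else:
        t = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
        se = abs(b_xy) / np.sqrt(t)
    p = float(stats.chi2.sf(t, df=1)) if t > 0 else 1.0
    return MREstimate("smr", float(b_xy), float(se), p, 1,
                      extra={"t_smr": float(t), "snp_id": top_eqtl.snp_id})


#: registry used by the pipeline and CLI method lists
METHODS = {
    "ivw": lambda t, seed, n_boot: ivw(t),
    "ivw_fixed": lambda t, seed, n_boot: ivw(t, model="fixed"),
    "egger": lambda t, seed, n_boot: mr_egger(t),
    "wmedian": lambda t, seed, n_boot: weighted_median(t, n_boot=n_boot, seed=seed),
    "smode": lambda t, seed, n_boot: mode_estimate(t, weighted=False, n_boot=n_boot, seed=seed),
    "wmode": lambda t, seed, n_boot: mode_estimate(t, weighted=True, n_boot=n_boot, seed=seed),
}
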