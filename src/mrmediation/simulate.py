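"""Truth-known synthetic summary statistics for the whole pipeline.

The generator emulates the statistical shape of the study's real inputs —
a modest exposure GWAS, a large outcome GWAS and a cis-eQTL study for a
mediating gene-expression trait — without any individual-level data. For a
standardized (unit-variance) trait measured in n samples, the sampling SE
of a per-allele effect at minor-allele frequency p is (2p(1−p)n)^(−1/2);
observed effects are drawn from normals centred on the structural truth:

* exposure SNP j:  β_exp ~ N(γⱼ, se²),  β_med ~ N(a·γⱼ, se²),
  β_out ~ N((c′ + a·b)·γⱼ + αⱼ, se²) with pleiotropy αⱼ ~ N(μ_α, σ_α²);
* cis-eQTL SNP k (disjoint set, inside a declared gene window):
  β_eqtl ~ N(δₖ, se²), β_out ~ N(b·δₖ, se²);
* outcome-specific SNP m (disjoint set): β_out ~ N(ηₘ, se²), no effect on
  exposure or mediator — these give the reverse-MR arm genuine instruments.

Per-SNP true effects are scaled so each instrument set explains a target
fraction of trait variance. Alleles and frequencies are emitted, and a
perturbation flag scrambles a fraction of outcome records (orientation
swaps, strand complements, palindromic strand flips) in ways harmonization
must undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterizationError, SnpLookupError
from .sumstats import COLUMNS, LDMatrix

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationTruth:
    """Structural parameters of a simulated mediation study.

    Defaults encode the reference study conditions used throughout the test
    bed: a = 0.4, b = 0.5, c′ = 0.3 (so c = 0.5 and proportion mediated
    0.4), 30 exposure instruments, three studies of n = 50,000, balanced
    pleiotropy with sd 0.02.
    """

    a_true: float = 0.4
    b_true: float = 0.5
    c_prime_true: float = 0.3
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    j_exp: int = 30
    j_med: int = 10
    j_out: int = 15
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    seed: int = 0
    # instrument-set variance-explained targets (standardized traits)
    r2_exposure: float = 0.10
    r2_eqtl: float = 0.10
    r2_outcome: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindrome_fraction: float = 0.15
    perturb_fraction: float = 0.20
    perturb: bool = True
    noiseless: bool = False
    # gene window for the cis-eQTL set
    gene_chrom: str = "9"
    gene_start: int = 95_000_000
    gene_end: int = 95_100_000
    # LD structure: SNPs grouped into blocks of this size with constant r²
    ld_block_size: int = 1
    ld_within_r2: float = 0.0

    @property
    def c_true(self) -> float:
        return self.c_prime_true + self.a_true * self.b_true

    @property
    def proportion_true(self) -> float:
        return self.a_true * self.b_true / self.c_true

    def __post_init__(self):
        for name in ("n_exp", "n_med", "n_out", "j_exp", "j_med"):
            if not getattr(self, name) > 0:
                raise ParameterizationError(f"{name} must be positive")
        for name in ("r2_exposure", "r2_eqtl", "r2_outcome"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterizationError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.ld_within_r2 < 1:
            raise ParameterizationError("ld_within_r2 must lie in [0, 1)")


@dataclass(frozen=True)
class StudyBundle:
    """Everything a full pipeline run needs, plus the generating truth."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    eqtl: pd.DataFrame
    ld: LDMatrix
    truth: SimulationTruth

    @property
    def gene(self) -> tuple[str, int, int]:
        t = self.truth
        return (t.gene_chrom, t.gene_start, t.gene_end)


def simulate_ld_matrix(n_snps: int, block_sizes: list[int], within_r2: float,
                       seed: int | None = None,
                       snp_ids: list[str] | None = None) -> LDMatrix:
    """Block-diagonal r² matrix: ``within_r2`` inside blocks, 0 across.

    Positive semidefinite by construction for ``within_r2`` < 1. ``seed``
    is accepted for interface symmetry with the other generators; the
    structure is fully determined by the arguments.
    """
    if sum(block_sizes) != n_snps:
        raise ParameterizationError(
            f"block sizes sum to {sum(block_sizes)}, expected {n_snps}"
        )
    if not 0 <= within_r2 < 1:
        raise ParameterizationError("within_r2 must lie in [0, 1)")
    r2 = np.zeros((n_snps, n_snps))
    start = 0
    for b in block_sizes:
        r2[start:start + b, start:start + b] = within_r2
        start += b
    np.fill_diagonal(r2, 1.0)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1:04d}" for i in range(n_snps)]
    return LDMatrix(tuple(snp_ids), r2)


def _scaled_effects(rng, maf, r2_target):
    """Draw per-SNP effects and rescale so Σ 2p(1−p)γ² = r2_target."""
    raw = rng.normal(0.0, 1.0, size=maf.size)
    # avoid a degenerate all-zero draw at tiny J
    while np.allclose(raw, 0):
        raw = rng.normal(0.0, 1.0, size=maf.size)
    var = (2.0 * maf * (1.0 - maf) * raw**2).sum()
    return raw * np.sqrt(r2_target / var)


def _alleles(rng, k, palindrome_fraction):
    pal = rng.random(k) < palindrome_fraction
    pairs = []
    for is_pal in pal:
        pool = _PALINDROMIC_PAIRS if is_pal else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs


def _sumstat_frame(ids, chroms, pos, pairs, eaf, true_beta, n, rng, noiseless):
    maf = np.asarray(eaf, dtype=float)
    se = (2.0 * maf * (1.0 - maf) * n) ** -0.5
    beta = np.asarray(true_beta, float) if noiseless else rng.normal(true_beta, se)
    z = beta / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "snp_id": ids, "chrom": chroms, "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": maf, "beta": beta, "se": se, "pval": pval,
        "n": float(n),
    }, columns=COLUMNS)


def _perturb_outcome(df: pd.DataFrame, rng, fraction: float) -> pd.DataFrame:
    """Scramble a fraction of records in harmonization-recoverable ways."""
    df = df.copy()
    hit = np.flatnonzero(rng.random(len(df)) < fraction)
    for i in hit:
        ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
        if _COMPLEMENT[ea] == oa:
            # palindrome: report the other strand — labels unchanged, the
            # effect allele now names the complementary (other-frequency) base
            df.at[i, "beta"] = -df.at[i, "beta"]
            df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
            continue
        mode = rng.integers(3)
        if mode in (0, 2):  # swap orientation
            df.at[i, "effect_allele"], df.at[i, "other_allele"] = oa, ea
            df.at[i, "beta"] = -df.at[i, "beta"]
            df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
        if mode in (1, 2):  # strand complement
            df.at[i, "effect_allele"] = _COMPLEMENT[df.at[i, "effect_allele"]]
            df.at[i, "other_allele"] = _COMPLEMENT[df.at[i, "other_allele"]]
    return df


def simulate_mediation_study(truth: SimulationTruth | None = None) -> StudyBundle:
    """Generate a complete summary-level mediation study with known truth."""
    truth = truth or SimulationTruth()
    rng = np.random.default_rng(truth.seed)
    t = truth

    j_total = t.j_exp + t.j_med + t.j_out
    maf = rng.uniform(*t.maf_range, size=j_total)
    pairs = _alleles(rng, j_total, t.palindrome_fraction)
    sl_exp = slice(0, t.j_exp)
    sl_med = slice(t.j_exp, t.j_exp + t.j_med)
    sl_out = slice(t.j_exp + t.j_med, j_total)

    ids = np.array(
        [f"rsE{k + 1:04d}" for k in range(t.j_exp)]
        + [f"rsQ{k + 1:04d}" for k in range(t.j_med)]
        + [f"rsO{k + 1:04d}" for k in range(t.j_out)]
    )
    block = max(1, t.ld_block_size)
    within_kb, between_kb = 10_000, 500_000

    def _positions(k, base):
        pos = []
        for i in range(k):
            b, off = divmod(i, block)
            pos.append(base + b * between_kb + off * within_kb)
        return np.array(pos, dtype=np.int64)

    pos = np.concatenate([
        _positions(t.j_exp, 1_000_000),
        np.sort(rng.integers(t.gene_start - 500_000, t.gene_end + 500_000,
                             size=t.j_med)),
        _positions(t.j_out, 1_000_000),
    ])
    chroms = np.array(["1"] * t.j_exp + [t.gene_chrom] * t.j_med + ["2"] * t.j_out)

    gamma = _scaled_effects(rng, maf[sl_exp], t.r2_exposure)
    delta = _scaled_effects(rng, maf[sl_med], t.r2_eqtl)
    eta = _scaled_effects(rng, maf[sl_out], t.r2_outcome)
    alpha = rng.normal(t.pleiotropy_mean, t.pleiotropy_sd, size=t.j_exp) \
        if t.pleiotropy_sd > 0 else np.full(t.j_exp, t.pleiotropy_mean)

    zeros_med = np.zeros(t.j_med)
    zeros_out = np.zeros(t.j_out)
    true_exp = np.concatenate([gamma, zeros_med, zeros_out])
    true_med = np.concatenate([t.a_true * gamma, delta, zeros_out])
    true_out = np.concatenate([t.c_true * gamma + alpha, t.b_true * delta, eta])

    exposure = _sumstat_frame(ids, chroms, pos, pairs, maf, true_exp, t.n_exp, rng, t.noiseless)
    mediator = _sumstat_frame(ids, chroms, pos, pairs, maf, true_med, t.n_med, rng, t.noiseless)
    outcome = _sumstat_frame(ids, chroms, pos, pairs, maf, true_out, t.n_out, rng, t.noiseless)
    # independent eQTL study of the same expression trait (cis SNPs only)
    eqtl = _sumstat_frame(ids[sl_med], chroms[sl_med], pos[sl_med],
                          [pairs[i] for i in range(*sl_med.indices(j_total))],
                          maf[sl_med], delta, t.n_med, rng, t.noiseless)

    if t.perturb and t.perturb_fraction > 0:
        outcome = _perturb_outcome(outcome, rng, t.perturb_fraction)

    def _blocks(k):
        sizes = [block] * (k // block)
        if k % block:
            sizes.append(k % block)
        return sizes
    block_sizes = _blocks(t.j_exp) + _blocks(t.j_med) + _blocks(t.j_out)
    ld = simulate_ld_matrix(j_total, block_sizes, t.ld_within_r2,
                            snp_ids=list(ids))
    return StudyBundle(exposure, mediator, outcome, eqtl, ld, truth)


def simulate_mr_table(j: int = 30, theta: float = 0.5,
                      gamma_range: tuple[float, float] = (0.05, 0.15),
                      se_exp: float = 0.01, se_out: float = 0.02,
                      pleiotropy_mean: float = 0.0, pleiotropy_sd: float = 0.0,
                      invalid_fraction: float = 0.0, invalid_theta: float = 0.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Directly simulate a harmonized instrument table (estimator test bed).

    True SNP-exposure effects γⱼ ~ U(gamma_range); a leading fraction of
    SNPs can be made invalid (their outcome effect follows
    ``invalid_theta``·γⱼ instead of ``theta``·γⱼ); per-SNP pleiotropy adds
    αⱼ ~ N(μ, σ²) to the outcome effect.
    """
    if seed is None:
        raise ValueError("simulate_mr_table requires an explicit seed")
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*gamma_range, size=j)
    theta_j = np.full(j, float(theta))
    n_invalid = int(round(invalid_fraction * j))
    theta_j[:n_invalid] = invalid_theta
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=j) if pleiotropy_sd > 0 \
        else np.full(j, pleiotropy_mean)
    bx = rng.normal(gamma, se_exp)
    by = rng.normal(theta_j * gamma + alpha, se_out)
    return pd.DataFrame({
        "snp_id": [f"snp{i + 1}" for i in range(j)],
        "beta_exp": bx, "se_exp": np.full(j, se_exp),
        "beta_out": by, "se_out": np.full(j, se_out),
    })


def inject_outlier(sumstats: pd.DataFrame, snp_id: str, shift_in_ses: float) -> pd.DataFrame:
    """Shift one SNP's beta by ``shift_in_ses``·se; everything else unchanged."""
    hit = sumstats["snp_id"] == snp_id
    if not hit.any():
        raise SnpLookupError(f"SNP '{snp_id}' not present in table")
    out = sumstats.copy()
    out.loc[hit, "beta"] = out.loc[hit, "beta"] + shift_in_ses * out.loc[hit, "se"]
    return out


def with_truth(**kwargs) -> SimulationTruth:
    """Convenience: the default truth with selected fields replaced."""
    return replace(SimulationTruth(), **kwargs)
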