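"""Study orchestration: the full bidirectional + mediation analysis.

``run_study`` executes, from one config: (1) forward MR exposure→outcome
(total effect c), (2) reverse MR outcome→exposure (d), (3) MR
exposure→mediator (a), (4) cis-eQTL MR and SMR mediator→outcome (b),
(5) the two-step mediation decomposition, and (6) the sensitivity battery
for every fit — writing per-fit estimate, diagnostic, leave-one-out,
per-SNP, scatter and funnel tables plus a single summary table. Every
random step consumes a seed derived deterministically from the config
seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from .errors import InsufficientInstrumentsError, MRError, StageError
from .estimators import METHODS, MREstimate, smr
from .harmonize import harmonize, retained
from .instruments import SelectionConfig, select_cis_eqtls, select_instruments
from .mediation import two_step_mediation
from .sumstats import SummaryStatRecord, read_ld_matrix, read_sumstats
from .simulate import StudyBundle

log = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "wmedian", "smode", "wmode")


@dataclass
class StudyConfig:
    """Paths, thresholds and run options of a full study."""

    exposure: str
    mediator: str
    outcome: str
    eqtl: str
    ld: str
    gene_chrom: str
    gene_start: int
    gene_end: int
    outdir: str
    selection: SelectionConfig = dfield(default_factory=SelectionConfig)
    eqtl_selection: SelectionConfig = dfield(default_factory=SelectionConfig)
    reverse_selection: SelectionConfig | None = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 1000
    n_presso: int = 1000
    seed: int = 0
    alpha: float = 0.05
    b_source: str = "ivw"  # which estimate feeds the mediation algebra: ivw|smr
    eaf_ambiguity: float = 0.08

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.b_source not in ("ivw", "smr"):
            raise ValueError("b_source must be 'ivw' or 'smr'")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gene = raw.pop("gene")
        sel = SelectionConfig(**raw.pop("selection", {}))
        esel = SelectionConfig(**raw.pop("eqtl_selection", {}))
        rsel = raw.pop("reverse_selection", None)
        return cls(
            gene_chrom=str(gene["chrom"]), gene_start=int(gene["start"]),
            gene_end=int(gene["end"]), selection=sel, eqtl_selection=esel,
            reverse_selection=SelectionConfig(**rsel) if rsel else None,
            methods=tuple(raw.pop("methods", DEFAULT_METHODS)), **raw,
        )


def _fit_methods(table, methods, seed, n_boot) -> dict[str, MREstimate]:
    out = {}
    for i, m in enumerate(methods):
        out[m] = METHODS[m](table, seed + i, n_boot)
    return out


def _top_eqtl_smr(table: pd.DataFrame) -> MREstimate:
    """SMR on the strongest retained eQTL (largest exposure |z|)."""
    t = retained(table) if "action" in table.columns else table
    z2 = (t["beta_exp"] / t["se_exp"]) ** 2
    row = t.loc[z2.idxmax()]
    mk = lambda b, s: SummaryStatRecord(str(row["snp_id"]), "0", 1, "A", "G",
                                        None, float(b), float(s), 1.0)
    return smr(mk(row["beta_exp"], row["se_exp"]), mk(row["beta_out"], row["se_out"]))


def _diagnose(table, fits, n_presso, seed) -> dict:
    out = {}
    t = retained(table) if "action" in table.columns else table
    j = len(t)
    try:
        out["q"] = diag.cochran_q(t)
    except InsufficientInstrumentsError:
        out["q"] = None
    if j >= 3:
        out["egger_intercept"] = diag.egger_intercept_test(t)
    if j >= 4:
        out["presso"] = diag.mr_presso(t, n_sim=n_presso, seed=seed)
    if j >= 2:
        out["loo"] = diag.leave_one_out(t)
    out["plots"] = diag.funnel_and_scatter_data(t, fits)
    return out


def _estimates_frame(fits: dict[str, MREstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in fits.values()])


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def _diag_frame(d: dict) -> pd.DataFrame:
    rows = []
    q = d.get("q")
    if q is not None:
        rows.append({"diagnostic": "cochran_q", "statistic": q.q, "df": q.df,
                     "pval": q.pval, "extra": f"i2={q.i2:.6g}"})
    if "egger_intercept" in d:
        est, se, p = d["egger_intercept"]
        rows.append({"diagnostic": "egger_intercept", "statistic": est,
                     "df": np.nan, "pval": p, "extra": f"se={se:.6g}"})
    if "presso" in d:
        pr = d["presso"]
        rows.append({"diagnostic": "mr_presso_global", "statistic": pr.global_rss,
                     "df": np.nan, "pval": pr.global_p,
                     "extra": "outliers=" + (",".join(pr.outlier_ids) or "none")})
    return pd.DataFrame(rows, columns=["diagnostic", "statistic", "df", "pval", "extra"])


def run_study_frames(exposure, mediator, outcome, eqtl, ld, config: StudyConfig,
                     outdir: str | Path | None = None) -> dict:
    """Run the full study on in-memory tables; see module docstring."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sel = config.selection
    rsel = config.reverse_selection or sel
    seeds = {name: config.seed + 1000 * k for k, name in enumerate(
        ["forward", "reverse", "a", "b", "presso"], start=1)}
    bundle: dict = {"config": config, "arms": {}, "log": []}

    def note(msg):
        bundle["log"].append(msg)
        log.info(msg)

    def arm(name, exp_stats, out_stats, selector, seed):
        try:
            inst = selector(exp_stats)
            note(f"{name}: {len(inst)} instrument(s) selected")
            table = harmonize(inst, out_stats, eaf_ambiguity=config.eaf_ambiguity)
            kept = retained(table)
            note(f"{name}: {len(kept)} of {len(table)} matched SNP(s) retained "
                 "after harmonization")
            methods = [m for m in config.methods
                       if len(kept) >= {"ivw": 1, "ivw_fixed": 1}.get(m, 3)]
            fits = _fit_methods(kept, methods, seed, config.n_boot)
            d = _diagnose(table, fits, config.n_presso, seeds["presso"] + seed)
            bundle["arms"][name] = {"table": table, "fits": fits, "diag": d}
            _write(table, outdir / f"harmonized_{name}.tsv")
            _write(_estimates_frame(fits), outdir / f"estimates_{name}.tsv")
            _write(_diag_frame(d), outdir / f"diagnostics_{name}.tsv")
            if "loo" in d:
                _write(d["loo"], outdir / f"leave_one_out_{name}.tsv")
            _write(d["plots"]["scatter"], outdir / f"scatter_{name}.tsv")
            _write(d["plots"]["funnel"], outdir / f"funnel_{name}.tsv")
            persnp = d["plots"]["funnel"].rename(columns={"ratio": "beta"})
            _write(persnp[["snp_id", "beta"]], outdir / f"per_snp_{name}.tsv")
        except MRError as err:
            raise StageError(name, err) from err

    arm("forward", exposure, outcome,
        lambda s: select_instruments(s, ld, sel), seeds["forward"])
    arm("reverse", outcome, exposure,
        lambda s: select_instruments(s, ld, rsel), seeds["reverse"])
    arm("exposure_to_mediator", exposure, mediator,
        lambda s: select_instruments(s, ld, sel), seeds["a"])
    arm("mediator_to_outcome", eqtl, outcome,
        lambda s: select_cis_eqtls(s, config.gene_chrom, config.gene_start,
                                   config.gene_end, ld, config.eqtl_selection),
        seeds["b"])

    try:
        b_table = retained(bundle["arms"]["mediator_to_outcome"]["table"])
        smr_fit = _top_eqtl_smr(b_table)
        bundle["arms"]["mediator_to_outcome"]["fits"]["smr"] = smr_fit
        est = bundle["arms"]["mediator_to_outcome"]["fits"]
        _write(_estimates_frame(est), outdir / "estimates_mediator_to_outcome.tsv")

        if "ivw" in config.methods:
            c_fit = bundle["arms"]["forward"]["fits"]["ivw"]
            a_fit = bundle["arms"]["exposure_to_mediator"]["fits"]["ivw"]
            b_fit = smr_fit if config.b_source == "smr" else est["ivw"]
            med = two_step_mediation(a_fit, b_fit, c_fit)
            bundle["mediation"] = med
            _write(pd.DataFrame([med.as_row()]), outdir / "mediation.tsv")
        else:
            note("mediation skipped: no IVW fit requested")
    except MRError as err:
        raise StageError("mediation", err) from err

    rows = []
    for name, armd in bundle["arms"].items():
        for mname, est in armd["fits"].items():
            rows.append({"arrow": name, **est.as_row(),
                         "significant": est.pval < config.alpha})
    summary = pd.DataFrame(rows)
    bundle["summary"] = summary
    _write(summary, outdir / "summary.tsv")
    (outdir / "run_log.txt").write_text("\n".join(bundle["log"]) + "\n")
    return bundle


def run_study(config: StudyConfig) -> dict:
    """Load the configured input files and run the full study."""
    try:
        exposure = read_sumstats(config.exposure)
        mediator = read_sumstats(config.mediator)
        outcome = read_sumstats(config.outcome)
        eqtl = read_sumstats(config.eqtl)
        ld = read_ld_matrix(config.ld)
    except (OSError, MRError) as err:
        raise StageError("load_inputs", err) from err
    return run_study_frames(exposure, mediator, outcome, eqtl, ld, config)


def run_study_bundle(bundle: StudyBundle, config: StudyConfig | None = None,
                     outdir: str | Path = "study_out", **overrides) -> dict:
    """Run the full study directly on a simulated :class:`StudyBundle`."""
    gene = bundle.gene
    if config is None:
        config = StudyConfig(
            exposure="<mem>", mediator="<mem>", outcome="<mem>", eqtl="<mem>",
            ld="<mem>", gene_chrom=gene[0], gene_start=gene[1], gene_end=gene[2],
            outdir=str(outdir), **overrides,
        )
    return run_study_frames(bundle.exposure, bundle.mediator, bundle.outcome,
                            bundle.eqtl, bundle.ld, config, outdir=outdir)


def render_report(bundle: dict) -> str:
    """Deterministic human-readable summary of a study bundle."""
    out = io.StringIO()
    cfg: StudyConfig = bundle["config"]
    print("Two-sample MR mediation study report", file=out)
    print("=" * 38, file=out)
    print(f"alpha = {cfg.alpha}; seed = {cfg.seed}; b from {cfg.b_source}", file=out)
    for line in bundle["log"]:
        print(f"  [log] {line}", file=out)
    for name, armd in bundle["arms"].items():
        print(f"\n## {name}", file=out)
        for mname, est in armd["fits"].items():
            flag = "*" if est.pval < cfg.alpha else " "
            print(f"  {mname:<16} J={est.n_snps:<3d} beta={est.beta: .6f} "
                  f"se={est.se:.6f} OR={est.or_:.4f} "
                  f"[{est.ci_low:.4f}, {est.ci_high:.4f}] p={est.pval:.3e}{flag}",
                  file=out)
        d = armd["diag"]
        if d.get("q") is not None:
            q = d["q"]
            print(f"  Cochran Q={q.q:.4f} (df {q.df}) p={q.pval:.4f} I2={q.i2:.3f}",
                  file=out)
        if "egger_intercept" in d:
            e, se, p = d["egger_intercept"]
            print(f"  Egger intercept={e:.6f} se={se:.6f} p={p:.4f}", file=out)
        if "presso" in d:
            pr = d["presso"]
            print(f"  MR-PRESSO global RSS={pr.global_rss:.4f} p={pr.global_p:.4f} "
                  f"outliers: {', '.join(pr.outlier_ids) or 'none'}", file=out)
    if "mediation" in bundle:
        m = bundle["mediation"]
        print("\n## mediation decomposition", file=out)
        print(f"  a={m.a:.6f} (se {m.a_se:.6f}); b={m.b:.6f} (se {m.b_se:.6f}); "
              f"c={m.c:.6f} (se {m.c_se:.6f})", file=out)
        print(f"  indirect a*b={m.indirect:.6f} (se {m.indirect_se:.6f}); "
              f"direct c'={m.c_prime:.6f} (se {m.c_prime_se:.6f})", file=out)
        print(f"  proportion mediated={m.proportion:.4f} "
              f"[{m.proportion_ci[0]:.4f}, {m.proportion_ci[1]:.4f}]", file=out)
    print("\nNote: arrows are tested at plain alpha with no multiple-testing "
          "correction across arrows.", file=out)
    return out.getvalue()
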