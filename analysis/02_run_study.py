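#!/usr/bin/env python
"""Run the full MR mediation study on the simulated bundle.

Executes forward and reverse MR between exposure and outcome, the
exposure→mediator and cis-eQTL mediator→outcome arms (including SMR), the
two-step mediation decomposition, and the sensitivity battery for every
fit. Reads results/sim_study/ (from 01_simulate_study.py) and writes the
estimate/diagnostic tables, report and figures under results/study/.
"""

import argparse
from pathlib import Path

from mrmediation.pipeline import StudyConfig, render_report, run_study
from mrmediation.plots import render_all

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--indir", type=Path, default=ROOT / "results" / "sim_study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    cfg = StudyConfig(
        exposure=str(args.indir / "exposure.tsv"),
        mediator=str(args.indir / "mediator.tsv"),
        outcome=str(args.indir / "outcome.tsv"),
        eqtl=str(args.indir / "eqtl.tsv"),
        ld=str(args.indir / "ld.tsv"),
        gene_chrom="9", gene_start=95_000_000, gene_end=95_100_000,
        outdir=str(args.out), seed=args.seed,
    )
    bundle = run_study(cfg)
    report = render_report(bundle)
    (args.out / "report.txt").write_text(report)
    if args.plots:
        render_all(bundle, args.out / "figures")
    print(report)
    m = bundle["mediation"]
    print(f"finding: the forward arrow is significant, the decomposition "
          f"attributes {100 * m.proportion:.1f}% "
          f"[{100 * m.proportion_ci[0]:.1f}%, {100 * m.proportion_ci[1]:.1f}%] "
          "of the total effect to the expression mediator "
          "(generator truth: 40%).")


if __name__ == "__main__":
    main()
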