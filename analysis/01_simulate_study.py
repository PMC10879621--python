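#!/usr/bin/env python
"""Generate the reference synthetic mediation study.

Emulates the shape of the real inputs — a modest-powered exposure GWAS, a
large outcome GWAS, and a cis-eQTL study for the mediating gene-expression
trait — with known structural truth a = 0.4, b = 0.5, c' = 0.3 (total
effect 0.5, proportion mediated 0.4). Writes the summary-stat TSVs, the LD
matrix and the truth file under results/sim_study/.
"""

import argparse
import dataclasses
from pathlib import Path

from mrmediation import simulate_mediation_study, with_truth
from mrmediation.sumstats import write_ld_matrix, write_sumstats

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "sim_study")
    args = ap.parse_args()

    truth = with_truth(seed=args.seed)
    bundle = simulate_mediation_study(truth)
    args.out.mkdir(parents=True, exist_ok=True)
    for name in ("exposure", "mediator", "outcome", "eqtl"):
        write_sumstats(getattr(bundle, name), args.out / f"{name}.tsv")
    write_ld_matrix(bundle.ld, args.out / "ld.tsv")
    rows = [f"{k}\t{v}" for k, v in dataclasses.asdict(truth).items()]
    rows += [f"c_true\t{truth.c_true}", f"proportion_true\t{truth.proportion_true}"]
    (args.out / "truth.tsv").write_text("key\tvalue\n" + "\n".join(rows) + "\n")

    print(f"wrote study bundle (seed {args.seed}) to {args.out}")
    print(f"  exposure GWAS: {len(bundle.exposure)} SNPs, n = {truth.n_exp:,}")
    print(f"  outcome GWAS:  {len(bundle.outcome)} SNPs, n = {truth.n_out:,}")
    print(f"  cis-eQTLs:     {len(bundle.eqtl)} SNPs around "
          f"{truth.gene_chrom}:{truth.gene_start}-{truth.gene_end}")
    print(f"  truth: a={truth.a_true} b={truth.b_true} c'={truth.c_prime_true} "
          f"-> c={truth.c_true}, proportion mediated={truth.proportion_true}")


if __name__ == "__main__":
    main()
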