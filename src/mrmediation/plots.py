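"""Matplotlib renderings of the standard MR diagnostics.

Each function takes the plot-ready tables produced by the diagnostics and
pipeline modules and writes one PNG. Plotting is optional everywhere; the
numeric tables are the primary artifacts.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def forest_plot(estimates: pd.DataFrame, path, title: str = "MR estimates"):
    """Forest plot of per-method ORs with 95% CIs."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(estimates) + 1.5))
    y = range(len(estimates))
    ax.errorbar(estimates["or"], y,
                xerr=[estimates["or"] - estimates["or_ci_low"],
                      estimates["or_ci_high"] - estimates["or"]],
                fmt="s", color="black", capsize=3)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y), estimates["method"])
    ax.set_xlabel("OR (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(scatter: pd.DataFrame, fits: pd.DataFrame, path,
                 title: str = "SNP effects"):
    """Per-SNP exposure vs outcome effects with fitted method lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(scatter["beta_exp"], scatter["beta_out"],
                xerr=scatter["se_exp"], yerr=scatter["se_out"],
                fmt="o", ms=3, color="tab:blue", alpha=0.7, lw=0.8)
    xs = scatter["beta_exp"]
    for row in fits.itertuples(index=False):
        ax.plot(xs, row.intercept + row.slope * xs, label=row.method, lw=1)
    if len(fits):
        ax.legend(fontsize=7)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(funnel: pd.DataFrame, ivw_beta: float | None, path,
                title: str = "Funnel"):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(funnel["ratio"], funnel["precision"], s=12, color="tab:blue")
    if ivw_beta is not None:
        ax.axvline(ivw_beta, color="black", lw=0.8)
    ax.set_xlabel("per-SNP Wald ratio")
    ax.set_ylabel("precision (1/se)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def loo_plot(loo: pd.DataFrame, path, title: str = "Leave-one-out"):
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(loo) + 1.5))
    y = range(len(loo))
    ax.errorbar(loo["beta"], y, xerr=1.96 * loo["se"], fmt="o", ms=3,
                color="black", capsize=2)
    ax.set_yticks(list(y), loo["excluded"], fontsize=6)
    ax.axvline(float(loo[loo["excluded"] == "All"]["beta"].iloc[0]),
               color="grey", lw=0.8, ls="--")
    ax.set_xlabel("IVW beta excluding the labelled SNP")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(bundle: dict, outdir) -> list[str]:
    """Render the figure set for every arm of a study bundle; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, armd in bundle["arms"].items():
        est = pd.DataFrame([e.as_row() for e in armd["fits"].values()])
        p = outdir / f"forest_{name}.png"
        forest_plot(est, p, title=f"{name}: MR estimates")
        written.append(str(p))
        d = armd["diag"]
        plots = d["plots"]
        p = outdir / f"scatter_{name}.png"
        scatter_plot(plots["scatter"], plots["fits"], p, title=name)
        written.append(str(p))
        ivw_beta = armd["fits"].get("ivw")
        p = outdir / f"funnel_{name}.png"
        funnel_plot(plots["funnel"], ivw_beta.beta if ivw_beta else None, p, title=name)
        written.append(str(p))
        if "loo" in d:
            p = outdir / f"loo_{name}.png"
            loo_plot(d["loo"], p, title=f"{name}: leave-one-out")
            written.append(str(p))
    return written
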