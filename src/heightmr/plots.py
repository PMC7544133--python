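"""Diagnostic plots: MR scatter, funnel, forest, and PheWAS Manhattan."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mr import MREstimate

_METHOD_COLORS = {"ivw": "tab:red", "weighted_median": "tab:green",
                  "egger": "tab:blue"}


def mr_scatter(harmonized, estimates: dict[str, MREstimate], path=None):
    """Per-SNP exposure vs outcome effects with method fit lines."""
    fig, ax = plt.subplots(figsize=(6, 5))
    bx = harmonized["beta_exposure"].to_numpy()
    by = harmonized["beta_outcome"].to_numpy()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    ax.errorbar(bx, by, xerr=harmonized["se_exposure"],
                yerr=harmonized["se_outcome"], fmt="o", ms=3, lw=0.5,
                color="0.4", alpha=0.6)
    xs = np.array([0, bx.max() * 1.05])
    for name, est in estimates.items():
        if est is None:
            continue
        intercept = est.egger_intercept or 0.0
        ax.plot(xs, intercept + est.beta * xs,
                color=_METHOD_COLORS.get(name, "0.2"), label=name)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (log-odds)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def funnel_plot(harmonized, estimates: dict[str, MREstimate], path=None):
    """Per-SNP Wald ratios against their precision."""
    fig, ax = plt.subplots(figsize=(6, 5))
    bx = harmonized["beta_exposure"].to_numpy()
    by = harmonized["beta_outcome"].to_numpy()
    sy = harmonized["se_outcome"].to_numpy()
    ratios = by / bx
    precision = np.abs(bx) / sy
    ax.plot(ratios, precision, "o", ms=3, color="0.4", alpha=0.6)
    for name, est in estimates.items():
        if est is None:
            continue
        ax.axvline(est.beta, color=_METHOD_COLORS.get(name, "0.2"),
                   label=name)
    ax.set_xlabel("per-SNP causal estimate (log-odds/SD)")
    ax.set_ylabel("precision (|beta_x| / se_y)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def forest_plot(estimates: list[MREstimate], labels: list[str] | None = None,
                path=None):
    """Odds ratios with 95% CIs, one row per estimate."""
    labels = labels or [e.method for e in estimates]
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(estimates) + 1.5))
    ypos = np.arange(len(estimates))[::-1]
    for y, est in zip(ypos, estimates):
        ax.plot([est.or_ci_low, est.or_ci_high], [y, y], "-", color="0.3")
        ax.plot(est.odds_ratio, y, "s", color="tab:red")
    ax.axvline(1.0, color="0.6", ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels)
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def manhattan_plot(phewas_table, threshold: float, path=None):
    """−log10 p per phecode with the Bonferroni and nominal lines."""
    fig, ax = plt.subplots(figsize=(8, 4))
    tab = phewas_table.sort_values("phecode",
                                   key=lambda s: s.astype(float))
    x = np.arange(len(tab))
    logp = -np.log10(np.clip(tab["pvalue"].to_numpy(), 1e-300, 1.0))
    up = tab["beta"] > 0
    ax.scatter(x[up], logp[up], marker="^", s=18, color="tab:blue")
    ax.scatter(x[~up], logp[~up], marker="v", s=18, color="tab:blue")
    ax.axhline(-np.log10(threshold), color="red", lw=1,
               label="Bonferroni")
    ax.axhline(-np.log10(0.05), color="blue", lw=1, ls="--", label="nominal")
    ax.set_xticks(x)
    ax.set_xticklabels(tab["phecode"], rotation=90, fontsize=6)
    ax.set_ylabel("−log10 p")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
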