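"""QC and MR diagnostic plots (matplotlib, optional outputs)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .mr import InstrumentSet, MRResult  # noqa: E402

__all__ = ["pca_scatter", "mr_scatter", "funnel_plot"]


def pca_scatter(scores, groups, path, pcs=(0, 1)):
    """Scatter of two PCs; cohort samples as points, panels as triangles."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    for grp in np.unique(groups):
        m = groups == grp
        marker = "^" if str(grp).startswith("panel") else "o"
        ax.scatter(scores[m, pcs[0]], scores[m, pcs[1]], s=12, marker=marker, label=str(grp),
                   alpha=0.7)
    ax.set_xlabel(f"PC{pcs[0] + 1}")
    ax.set_ylabel(f"PC{pcs[1] + 1}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mr_scatter(inst: InstrumentSet, results: dict[str, MRResult], path):
    """SNP-exposure vs SNP-outcome effects with fitted estimator lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    o = inst.oriented()
    ax.errorbar(o.gamma, o.big_gamma, yerr=1.96 * o.se_big_gamma, fmt="o", ms=4, alpha=0.6)
    xs = np.linspace(0, o.gamma.max() * 1.05, 50)
    for name, res in results.items():
        icept = res.egger_intercept or 0.0
        ax.plot(xs, icept + res.beta_hat * xs, label=f"{name} (OR/1% {res.odds_ratio:.3f})")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("SNP effect on ancestry (% per allele)")
    ax.set_ylabel("SNP effect on disease (log OR)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(inst: InstrumentSet, beta_hat: float, path):
    """Per-instrument ratio estimates against their precision."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(inst.ratio, np.sqrt(inst.weights), s=14, alpha=0.7)
    ax.axvline(beta_hat, color="C1", label="IVW estimate")
    ax.set_xlabel("Wald ratio (log OR per 1% ancestry)")
    ax.set_ylabel("sqrt(first-order weight)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
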