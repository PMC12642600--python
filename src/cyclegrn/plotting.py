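"""Minimal figure writers: PR curve and AUPR-ratio barplot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .benchmark import PRResult


def plot_pr_curve(result: PRResult, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.recall, result.precision, drawstyle="default")
    ax.axhline(result.rho, color="red", linestyle="--", linewidth=1, label=f"random ({result.rho:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.02)
    ax.set_title(title or f"AUPR={result.aupr:.3f}, ratio={result.aupr_ratio:.2f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_aupr_ratio_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Barplot of AUPR ratios per (method, ordering), baseline at 1."""
    df = summary.dropna(subset=["aupr_ratio"]) if "aupr_ratio" in summary else summary
    labels = [f"{m}\n{o}" for m, o in zip(df["method"], df["ordering"])]
    fig, ax = plt.subplots(figsize=(1 + 0.9 * len(df), 3.5))
    ax.bar(labels, df["aupr_ratio"], color="steelblue")
    ax.axhline(1.0, color="red", linestyle="--", linewidth=1)
    ax.set_ylabel("AUPR ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
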