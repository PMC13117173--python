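"""Figure output: ROC curves, Kaplan-Meier panels, and the risk heat-table.

Minimal matplotlib renderings of the pipeline's summary artifacts; all
functions write a file and return its path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

UNIT_COLOR_RGB = {
    "red": "#d62728",
    "orange": "#ff9f40",
    "blue": "#3b6fb6",
}


def plot_roc(curve: pd.DataFrame, auc: float, title: str, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], color="#d62728", lw=2,
            label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_km(curves: dict[str, pd.DataFrame], title: str, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in sorted(curves.items()):
        ax.step(curve["time"], curve["survival"], where="post", label=str(group))
    ax.set_xlabel("Months after resection")
    ax.set_ylabel("Recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_risk_table(risk: pd.DataFrame, path: str | Path) -> Path:
    """Heat-table of per-unit colors plus scores, one row per case.

    Cases flagged by the early-recurrence rule get a gray row label,
    mirroring the temporal-stratification display convention.
    """
    unit_cols = [c for c in risk.columns if c.startswith("color_")]
    n = len(risk)
    fig, ax = plt.subplots(figsize=(1.2 * len(unit_cols) + 3, 0.28 * n + 1.2))
    for i, (_, row) in enumerate(risk.iterrows()):
        for j, col in enumerate(unit_cols):
            ax.add_patch(plt.Rectangle((j, n - 1 - i), 1, 1,
                                       color=UNIT_COLOR_RGB[row[col]]))
        label_color = "gray" if row.get("early_recurrence", False) else "black"
        ax.text(-0.2, n - 1 - i + 0.5, str(row["case_id"]), ha="right",
                va="center", fontsize=6, color=label_color)
        extras = f"AI {row['ai_score']}"
        if "total_score" in row:
            extras += f" / total {row['total_score']} ({row['total_group']})"
        ax.text(len(unit_cols) + 0.2, n - 1 - i + 0.5, extras, ha="left",
                va="center", fontsize=6)
    for j, col in enumerate(unit_cols):
        ax.text(j + 0.5, n + 0.2, col.removeprefix("color_"), ha="center",
                va="bottom", fontsize=7, rotation=45)
    ax.set_xlim(-2.5, len(unit_cols) + 4)
    ax.set_ylim(-0.2, n + 1.2)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
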