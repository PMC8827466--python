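"""Trend panels for the indicator table (optional, matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

PANELS = [
    ("M", "Modal age at death M (years)"),
    ("sd_above_M", "SD(M+) (years)"),
    ("e65", "e65, attained age (years)"),
    ("p_surv_M", "Proportion surviving 31 → M"),
    ("p_surv_65", "Proportion surviving 31 → 65"),
    ("p_surv_75", "Proportion surviving 31 → 75"),
]


def plot_trends(table: pd.DataFrame, path: str) -> None:
    """One line per stratum per panel, written to ``path``."""
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    for ax, (col, label) in zip(axes.ravel(), PANELS):
        for stratum, sub in table.groupby("stratum"):
            ax.plot(sub["year"], sub[col], label=stratum, lw=1.2)
        ax.set_ylabel(label)
        ax.set_xlabel("calendar year")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
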