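"""Figure-style rendering of grid results (accuracy curves, sweep bars)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import GridResult

__all__ = ["plot_grid_result"]


def plot_grid_result(result: GridResult, path: str | Path) -> Path:
    """Render mean +/- std test accuracy per cell and condition to SVG/PNG."""
    summary = result.summary
    acc = summary[summary["metric"] == "test_accuracy"]
    fig, ax = plt.subplots(figsize=(6, 4))
    numeric_cells = all(
        isinstance(c, (int, float)) and not isinstance(c, bool)
        for c in acc["cell"].unique()
    )
    for cond, block in acc.groupby("condition"):
        block = block.sort_values("cell")
        if numeric_cells:
            ax.errorbar(block["cell"], block["mean"], yerr=block["std"],
                        marker="o", capsize=3, label=cond)
        else:
            ax.bar(block["cell"].astype(str), block["mean"],
                   yerr=block["std"], capsize=3, label=cond, alpha=0.7)
    for _, row in result.reference.iterrows():
        if row["metric"] == "test_accuracy" and row["value"] is not None:
            ax.axhline(row["value"], linestyle=":", alpha=0.7, label=row["condition"])
    if numeric_cells:
        ax.set_xscale("log")
        ax.set_xlabel("train set size (new modality)")
    else:
        ax.set_xlabel("cell")
        ax.tick_params(axis="x", rotation=60)
    ax.set_ylabel("test accuracy")
    ax.set_title(result.experiment)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
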