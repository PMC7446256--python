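"""Optional heatmap rendering of cohort resection matrices.

Presentation only: the tested artifact is the numeric matrix export. Needs
matplotlib (install the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

from .cohort import CohortMatrix


def plot_resection_heatmap(
    matrix: CohortMatrix,
    path: str | Path,
    annotate: bool = False,
    cmap: str = "Blues",
) -> None:
    """Write a region×patient resected-area heatmap figure.

    Darker cells mark larger resections; with ``annotate`` each cell shows
    the absolute resected area rounded to whole cm².
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.values
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.4 * len(df.columns) + 2), max(8.0, 0.25 * len(df.index)))
    )
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=7)
    ax.set_xlabel("patient")
    ax.set_ylabel("region")
    fig.colorbar(im, ax=ax, label="resected area (cm$^2$)")
    if annotate:
        vmax = float(df.to_numpy().max()) or 1.0
        for i in range(len(df.index)):
            for j in range(len(df.columns)):
                v = df.iat[i, j]
                if v > 0:
                    ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=5,
                            color="white" if v > 0.6 * vmax else "black")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
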