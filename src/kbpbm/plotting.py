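"""Optional plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

from typing import Sequence

from .intensity_processing import BindingProfile
from .profile_analysis import Dendrogram, heatmap_matrix


def plot_heatmap(profiles: Sequence[BindingProfile], dendrogram: Dendrogram, path):
    """Yellow/black/blue binding heat map with columns in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix, _, col_order = heatmap_matrix(profiles, dendrogram)
    fig, ax = plt.subplots(figsize=(2 + 0.5 * len(col_order), 6))
    vmax = float(abs(matrix.to_numpy()).max())
    im = ax.imshow(
        matrix.to_numpy(), aspect="auto", cmap="RdYlBu_r", vmin=-vmax, vmax=vmax
    )
    ax.set_xticks(range(len(col_order)), col_order, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{len(matrix)} probes (mean z, descending)")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
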