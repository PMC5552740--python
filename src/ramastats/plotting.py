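"""Basic plots: density heatmaps, distance-matrix heatmap, cost curves."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_density(dist, ax=None, log: bool = True):
    """Heatmap of one residue's Ramachandran probability distribution."""
    ax = _get_ax(ax)
    p = dist.probabilities
    data = np.log10(p + 1e-12) if log else p
    ax.imshow(
        data.T, origin="lower", extent=(-180, 180, -180, 180), aspect="equal",
        cmap="viridis",
    )
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("psi (deg)")
    ax.set_title(dist.residue)
    return ax


def plot_distance_matrix(matrix, topology=None, ax=None):
    """Distance-matrix heatmap, rows ordered open-sets-first when given."""
    ax = _get_ax(ax)
    labels = list(matrix.labels)
    if topology is not None and topology.open_sets:
        ordered: list[str] = []
        for s in topology.open_sets:
            for r in sorted(s):
                if r not in ordered:
                    ordered.append(r)
        ordered += [r for r in labels if r not in ordered]
        idx = [labels.index(r) for r in ordered]
        values = matrix.values[np.ix_(idx, idx)]
        labels = ordered
    else:
        values = matrix.values
    im = ax.imshow(values, cmap="viridis_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="city-block distance")
    return ax


def plot_cost_curve(sweep, ax=None):
    """MISE cost C(Delta) against bins-per-axis for one sweep."""
    ax = _get_ax(ax)
    ax.plot(sweep.candidates["k"], sweep.candidates["cost"], lw=1)
    ax.axvline(sweep.k_min, color="red", ls="--", lw=0.8)
    ax.set_xlabel("bins per axis k")
    ax.set_ylabel("cost C(360/k)")
    ax.set_title(f"{sweep.residue} (optimum k={sweep.k_min})")
    return ax
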