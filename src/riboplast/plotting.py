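"""Optional profile figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pausing import NormalizedProfile, Peak, codon_density


def plot_profile(
    profile: NormalizedProfile,
    peaks: Sequence[Peak] = (),
    path: str | Path | None = None,
):
    """Codon-resolution density along one ORF with called peaks marked."""
    dens = codon_density(profile.density)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.fill_between(np.arange(1, dens.size + 1), dens, step="mid", alpha=0.7)
    for pk in peaks:
        ax.annotate(
            pk.label.split("-")[-1],
            (pk.codon_index, pk.height * 3),
            ha="center", fontsize=8,
        )
    ax.set_xlabel("codon")
    ax.set_ylabel("density / codon")
    ax.set_title(f"{profile.gene_id} ({profile.sample_id})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
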