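"""Ribo-seq library QC: footprint-length distribution and 3-nt periodicity.

A good chloroplast ribosome-profiling library shows (i) a footprint length
histogram peaking at 31-33 nt and (ii) strong 3-nt periodicity of 5' ends,
the signature of codon-by-codon translocation. Both summaries here are per
sample.

Frame fractions: for each footprint whose 5' end lies inside a triplet-length
ORF on the matching strand, the frame is ``(rel5 + psite_offset) mod 3``
where ``rel5`` is the 5' end in ORF-relative coordinates, measured from the
gene's own start codon in its own orientation (minus-strand genes use their
own reading frame, not the genome frame). f0 is the fraction in the canonical
frame. The P-site offset is an explicit, reported parameter (default 12 nt);
footprints overlapping an ORF boundary count by their 5' end only, the same
single rule used for assignment.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import QCError
from .io import OrfRecord
from .quantify import assign_to_orfs
from .simulate import P_SITE_OFFSET_NT


@dataclasses.dataclass(frozen=True)
class LengthHistogram:
    """Footprint-length histogram; ``mode_length`` is None for empty input
    (ties resolved to the smallest length)."""

    counts: dict[int, int]
    total: int
    mode_length: int | None

    @classmethod
    def from_lengths(cls, lengths: np.ndarray) -> "LengthHistogram":
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.size == 0:
            return cls(counts={}, total=0, mode_length=None)
        values, counts = np.unique(lengths, return_counts=True)
        mode = int(values[np.argmax(counts)])  # np.argmax: first max = smallest length
        return cls(
            counts={int(v): int(c) for v, c in zip(values, counts)},
            total=int(lengths.size),
            mode_length=mode,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length_nt": list(self.counts), "count": list(self.counts.values())}
        )


@dataclasses.dataclass(frozen=True)
class FrameFractions:
    """Fractions of footprints 0/1/2 nt off the canonical reading frame."""

    f0: float
    f1: float
    f2: float
    n_used: int

    def __post_init__(self) -> None:
        if self.n_used > 0:
            total = self.f0 + self.f1 + self.f2
            if abs(total - 1.0) > 1e-9:
                raise QCError(f"frame fractions sum to {total}, not 1")


def length_distribution(footprints: pd.DataFrame) -> LengthHistogram:
    """Histogram of footprint lengths (empty input gives an empty histogram)."""
    return LengthHistogram.from_lengths(footprints["length"].to_numpy())


def frame_periodicity(
    footprints: pd.DataFrame,
    orfs: Sequence[OrfRecord],
    psite_offset: int = P_SITE_OFFSET_NT,
) -> FrameFractions:
    """3-nt periodicity of 5' ends over triplet-length ORFs (see module doc).

    Raises :class:`QCError` when no footprint is usable (QC impossible).
    """
    if psite_offset < 0:
        raise QCError("psite_offset must be >= 0")
    triplet_orfs = [o for o in orfs if o.is_triplet]
    if not triplet_orfs:
        raise QCError("no triplet-length ORFs: periodicity QC impossible")
    result = assign_to_orfs(footprints, triplet_orfs)
    mask = result.gene_id.notna().to_numpy()
    if not mask.any():
        raise QCError("no footprints usable for periodicity QC")
    by_id = {o.gene_id: o for o in triplet_orfs}
    fp5 = footprints["five_prime"].to_numpy()[mask]
    genes = result.gene_id.to_numpy()[mask]
    starts = np.array([by_id[g].start for g in genes], dtype=np.int64)
    ends = np.array([by_id[g].end for g in genes], dtype=np.int64)
    plus = np.array([by_id[g].strand == "+" for g in genes])
    rel5 = np.where(plus, fp5 - starts, (ends - 1) - fp5)
    frame = (rel5 + psite_offset) % 3
    n = int(frame.size)
    counts = np.bincount(frame, minlength=3)
    return FrameFractions(
        f0=counts[0] / n, f1=counts[1] / n, f2=counts[2] / n, n_used=n
    )
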