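"""Per-ORF coverage profiles, major-peak calling, and mutant/WT peak ratios.

This module implements the stall-site analysis: footprint 5' ends are piled
up along each ORF (in the gene's own 5'->3' orientation), each profile is
normalised by its own total so genotypes with different sequencing depth or
overall occupancy are comparable, peaks are called on the pooled wild-type
profile, and each peak's height is re-measured in every sample to form the
mutant/WT relative-height statistic with replicate mean +/- SD. A ratio above
one at a peak means ribosomes dwell there for a larger *fraction* of the
gene's translation time in the mutant — the signature of a stall — even when
absolute footprint counts moved in either direction.

Peak calling operates at codon resolution (nucleotide-level maxima are 3-nt
frame artifacts): the density is summed per codon, smoothed by a centred
moving average (truncated at the ORF ends, so edge codons average over the
codons that exist), and local maxima are kept if their topographic prominence
reaches ``min_prominence_frac`` of the global smoothed maximum. Conventions
pinned here, and mirrored by the brute-force oracle in the test suite:

* a plateau of equal values is represented by its 5'-most codon;
* ORF-terminal codons may be peaks (the initiation pause sits near the 5'
  end) — a side of the signal that does not exist imposes no constraint on
  prominence;
* maxima closer than ``min_sep_codons`` are merged keeping the higher one
  (ties keep the 5'-most); the ``top_k`` by height survive and are then
  relabelled with roman numerals in 5'->3' order (psbB-V is the fifth peak
  of psbB in position order, not the fifth tallest).

Tunnel mapping translates a peak's P-site codon into the residue emerging
from the ribosomal exit tunnel (``codon - tunnel_len_codons``); with a
user-supplied table of transmembrane-domain residue intervals it reports
which TMD (or loop) is emerging at the stall.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import roman
from .errors import ProfileError, RiboplastError
from .io import OrfRecord
from .quantify import DEFAULT_MIN_READS, count_by_gene

logger = logging.getLogger(__name__)

#: Ribosomal exit tunnel length in codons (configurable; ~30-40 residues).
DEFAULT_TUNNEL_LEN_CODONS = 33


@dataclasses.dataclass
class PeakParams:
    """Peak-calling and ratio parameters (all stamped into output metadata)."""

    smooth_codons: int = 3
    min_prominence_frac: float = 0.25
    min_sep_codons: int = 9
    top_k: int = 6
    match_window_codons: int = 1

    def __post_init__(self) -> None:
        if self.smooth_codons < 1 or self.smooth_codons % 2 == 0:
            raise ProfileError("smooth_codons must be a positive odd integer")
        if not (0.0 < self.min_prominence_frac <= 1.0):
            raise ProfileError("min_prominence_frac must be in (0, 1]")
        if self.min_sep_codons < 1:
            raise ProfileError("min_sep_codons must be >= 1")
        if self.top_k < 1:
            raise ProfileError("top_k must be >= 1")
        if self.match_window_codons < 0:
            raise ProfileError("match_window_codons must be >= 0")

    def as_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CoverageProfile:
    """Raw per-nucleotide 5'-end counts along one ORF (gene orientation)."""

    gene_id: str
    sample_id: str
    values: np.ndarray  # int64, length L_g
    n_out_of_range: int = 0

    @property
    def total(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class NormalizedProfile:
    """Per-nucleotide footprint density along one ORF, summing to 1."""

    gene_id: str
    sample_id: str
    density: np.ndarray


@dataclasses.dataclass(frozen=True)
class Peak:
    """A called major peak; ``codon_index`` is 1-based, ``label`` is the gene
    plus a roman numeral in 5'->3' order (e.g. ``psbB-V``)."""

    gene_id: str
    position_nt: int
    codon_index: int
    height: float
    rank: int
    label: str


@dataclasses.dataclass
class PeakRatio:
    """Mutant/WT relative peak height with replicate mean +/- sample SD."""

    label: str
    gene_id: str
    codon_index: int
    genotype: str
    ratios: tuple[float, ...]
    mean: float
    sd: float | None
    n_replicates: int


@dataclasses.dataclass(frozen=True)
class TunnelMapping:
    """Peak mapped to the residue emerging from the ribosomal exit tunnel."""

    peak: Peak
    psite_codon: int
    emerging_residue: int | None
    emerging_feature: str | None


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def build_profile(
    footprints: pd.DataFrame, orf: OrfRecord, offset_nt: int = 0,
    *, sample_id: str | None = None,
) -> CoverageProfile:
    """Pile up footprint 5' ends along one ORF.

    Only strand-matched footprints whose 5' end lies inside the ORF
    contribute; ``offset_nt`` (a P-site offset) shifts each 5' end downstream
    before binning, and positions falling outside ``[0, L_g)`` after the
    shift are dropped and counted in ``n_out_of_range``.
    """
    if offset_nt < 0:
        raise ProfileError("offset_nt must be >= 0")
    L = orf.length_nt
    values = np.zeros(L, dtype=np.int64)
    if sample_id is None:
        ids = footprints["sample_id"].unique() if len(footprints) else []
        sample_id = str(ids[0]) if len(ids) == 1 else "pooled"
    sub = footprints[
        (footprints["seq_id"] == orf.seq_id)
        & (footprints["strand"] == orf.strand)
        & (footprints["five_prime"] >= orf.start)
        & (footprints["five_prime"] < orf.end)
    ]
    rel = orf.relative_position(sub["five_prime"].to_numpy())
    pos = rel + offset_nt
    ok = (pos >= 0) & (pos < L)
    np.add.at(values, pos[ok], 1)
    return CoverageProfile(
        gene_id=orf.gene_id, sample_id=sample_id, values=values,
        n_out_of_range=int((~ok).sum()),
    )


def normalize_profile(profile: CoverageProfile) -> NormalizedProfile:
    """Divide by the profile total; zero-coverage profiles are an error."""
    total = profile.total
    if total == 0:
        raise ProfileError(
            f"no coverage: gene {profile.gene_id!r}, sample "
            f"{profile.sample_id!r}"
        )
    return NormalizedProfile(
        gene_id=profile.gene_id, sample_id=profile.sample_id,
        density=profile.values / total,
    )


def pool_profiles(profiles: Sequence[CoverageProfile]) -> CoverageProfile:
    """Sum replicate coverage profiles (used to define peaks on pooled WT)."""
    if not profiles:
        raise ProfileError("no profiles to pool")
    genes = {p.gene_id for p in profiles}
    if len(genes) != 1:
        raise ProfileError(f"cannot pool profiles of different genes: {genes}")
    values = np.sum([p.values for p in profiles], axis=0)
    return CoverageProfile(
        gene_id=profiles[0].gene_id, sample_id="pooled", values=values,
        n_out_of_range=sum(p.n_out_of_range for p in profiles),
    )


def codon_density(density: np.ndarray) -> np.ndarray:
    """Sum a per-nucleotide density into per-codon density."""
    density = np.asarray(density, dtype=float)
    if density.size % 3 != 0:
        raise ProfileError(
            f"profile length {density.size} is not a whole number of codons"
        )
    return density.reshape(-1, 3).sum(axis=1)


def smooth_density(codon_values: np.ndarray, smooth_codons: int) -> np.ndarray:
    """Centred moving average, truncated at the ends (a true mean over the
    codons that exist in the window)."""
    if smooth_codons < 1 or smooth_codons % 2 == 0:
        raise ProfileError("smooth_codons must be a positive odd integer")
    v = np.asarray(codon_values, dtype=float)
    if smooth_codons == 1:
        return v.copy()
    h = (smooth_codons - 1) // 2
    n = v.size
    # accumulate window members 5'->3' so each window sums in a fixed,
    # position-independent order (bit-reproducible regardless of vector
    # length or implementation detail)
    total = np.zeros(n)
    count = np.zeros(n)
    for dk in range(-h, h + 1):
        lo, hi = max(0, -dk), min(n, n - dk)
        total[lo:hi] += v[lo + dk:hi + dk]
        count[lo:hi] += 1
    return total / count


def smoothed_codon_profile(
    profile: NormalizedProfile, smooth_codons: int
) -> np.ndarray:
    return smooth_density(codon_density(profile.density), smooth_codons)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def _local_maxima(v: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus yield their 5'-most index, and
    boundary codons qualify when no higher neighbour exists on the side that
    does exist. An all-flat signal has no maxima."""
    n = v.size
    if n == 0 or np.all(v == v[0]):
        return []
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return out


def _prominence(v: np.ndarray, p: int) -> float:
    """Topographic prominence of the maximum at index p: height above the
    higher of the two side minima, each taken between the peak and the
    nearest strictly higher point (or the signal end). A side with no samples
    imposes no constraint."""
    side_minima = []
    k = p - 1
    m = np.inf
    while k >= 0:
        if v[k] > v[p]:
            break
        m = min(m, v[k])
        k -= 1
    if p > 0:
        side_minima.append(m)
    k = p + 1
    m = np.inf
    while k < v.size:
        if v[k] > v[p]:
            break
        m = min(m, v[k])
        k += 1
    if p < v.size - 1:
        side_minima.append(m)
    if not side_minima:
        return float(v[p])
    return float(v[p] - max(side_minima))


def call_major_peaks(
    profile: NormalizedProfile, params: PeakParams | None = None
) -> list[Peak]:
    """Call the major peaks of one normalised profile (see module docstring).

    Returns peaks sorted 5'->3' with consecutive roman-numeral labels;
    ``rank`` orders them by height (1 = tallest). A flat profile yields an
    empty list, not an error.
    """
    params = params or PeakParams()
    smoothed = smoothed_codon_profile(profile, params.smooth_codons)
    gmax = smoothed.max() if smoothed.size else 0.0
    if smoothed.size == 0 or gmax == smoothed.min():
        return []
    candidates = [
        c for c in _local_maxima(smoothed)
        if _prominence(smoothed, c) >= params.min_prominence_frac * gmax
    ]
    # merge close maxima: greedy from the highest (ties -> 5'-most)
    kept: list[int] = []
    for c in sorted(candidates, key=lambda c: (-smoothed[c], c)):
        if all(abs(c - k) >= params.min_sep_codons for k in kept):
            kept.append(c)
    kept = sorted(kept, key=lambda c: (-smoothed[c], c))[: params.top_k]
    by_height = {c: r + 1 for r, c in enumerate(kept)}
    peaks = []
    for order, c in enumerate(sorted(kept), start=1):
        peaks.append(
            Peak(
                gene_id=profile.gene_id,
                position_nt=3 * c,
                codon_index=c + 1,
                height=float(smoothed[c]),
                rank=by_height[c],
                label=f"{profile.gene_id}-{roman(order)}",
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Peak height ratios
# ---------------------------------------------------------------------------

def peak_height(
    profile: NormalizedProfile, codon_index: int, match_window_codons: int,
    smooth_codons: int,
) -> float:
    """Height of a peak in one sample: the maximum smoothed codon density
    within +/-``match_window_codons`` of the peak codon (1-based)."""
    smoothed = smoothed_codon_profile(profile, smooth_codons)
    c = codon_index - 1
    lo = max(0, c - match_window_codons)
    hi = min(smoothed.size, c + match_window_codons + 1)
    if lo >= hi:
        raise ProfileError(f"peak codon {codon_index} outside profile")
    return float(smoothed[lo:hi].max())


def peak_ratio(
    wt_profiles: Sequence[NormalizedProfile],
    mut_profiles: Sequence[NormalizedProfile],
    peak: Peak,
    genotype: str,
    params: PeakParams | None = None,
) -> PeakRatio:
    """Mutant/WT relative height of one peak.

    Every profile is individually normalised; the WT reference is the mean of
    the WT replicate heights, each mutant replicate contributes
    ``h_mut,r / WT_ref``, and the replicate mean and sample SD (n-1) are
    reported. A zero WT reference (peak absent in WT) is an error.
    """
    params = params or PeakParams()
    if not wt_profiles or not mut_profiles:
        raise ProfileError("need >=1 WT and >=1 mutant profile")
    h = lambda p: peak_height(
        p, peak.codon_index, params.match_window_codons, params.smooth_codons
    )
    wt_ref = float(np.mean([h(p) for p in wt_profiles]))
    if wt_ref == 0:
        raise ProfileError(f"peak {peak.label} absent in WT (zero height)")
    ratios = tuple(h(p) / wt_ref for p in mut_profiles)
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) >= 2 else None
    return PeakRatio(
        label=peak.label, gene_id=peak.gene_id, codon_index=peak.codon_index,
        genotype=genotype, ratios=ratios, mean=mean, sd=sd,
        n_replicates=len(ratios),
    )


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def genome_wide_scan(
    footprints: pd.DataFrame,
    orfs: Sequence[OrfRecord],
    sample_sheet: pd.DataFrame,
    params: PeakParams | None = None,
    *,
    offset_nt: int = 0,
    min_reads: int = DEFAULT_MIN_READS,
    wt_genotype: str = "WT",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call peaks on pooled WT for every eligible ORF and compute per-genotype
    relative-height ratios for each peak.

    Genes are eligible when triplet-length and above ``min_reads`` assigned
    footprints in every sample (the same rule quantification uses). Returns
    ``(ratios, exclusions)``; ratios are sorted by mean descending within
    genotype. An empty mutant sample set yields an empty table with a warning.
    """
    params = params or PeakParams()
    samples = list(sample_sheet["sample_id"])
    wt_samples = sample_sheet.loc[
        sample_sheet["genotype"] == wt_genotype, "sample_id"
    ].tolist()
    if not wt_samples:
        raise RiboplastError(f"no {wt_genotype!r} samples in the sample sheet")
    mut_sheet = sample_sheet[sample_sheet["genotype"] != wt_genotype]
    if mut_sheet.empty:
        logger.warning("no non-%s samples: scan table is empty", wt_genotype)

    counts, _ = count_by_gene(footprints, orfs, sample_ids=samples)
    min_per_gene = counts.groupby("gene_id")["n"].min()

    exclusions = []
    rows = []
    for orf in orfs:
        if not orf.is_triplet:
            exclusions.append((orf.gene_id, "non-triplet ORF length"))
            continue
        if min_per_gene.get(orf.gene_id, 0) < min_reads:
            exclusions.append(
                (orf.gene_id, f"reads below {min_reads} in >=1 sample")
            )
            continue
        per_sample = {
            sid: build_profile(
                footprints[footprints["sample_id"] == sid], orf, offset_nt,
                sample_id=sid,
            )
            for sid in samples
        }
        pooled_wt = normalize_profile(
            pool_profiles([per_sample[s] for s in wt_samples])
        )
        peaks = call_major_peaks(pooled_wt, params)
        if not peaks:
            exclusions.append((orf.gene_id, "no major peaks in pooled WT"))
            continue
        wt_norm = [normalize_profile(per_sample[s]) for s in wt_samples]
        for genotype, gsheet in mut_sheet.groupby("genotype", sort=True):
            mut_norm = [
                normalize_profile(per_sample[s]) for s in gsheet["sample_id"]
            ]
            for peak in peaks:
                pr = peak_ratio(wt_norm, mut_norm, peak, genotype, params)
                rows.append(
                    {
                        "gene_id": pr.gene_id,
                        "label": pr.label,
                        "codon_index": pr.codon_index,
                        "genotype": pr.genotype,
                        "mean_ratio": pr.mean,
                        "sd_ratio": pr.sd if pr.sd is not None else np.nan,
                        "n_replicates": pr.n_replicates,
                        "replicate_ratios": ",".join(
                            f"{r:.6g}" for r in pr.ratios
                        ),
                    }
                )
    ratio_df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "label", "codon_index", "genotype", "mean_ratio",
            "sd_ratio", "n_replicates", "replicate_ratios",
        ],
    )
    if not ratio_df.empty:
        ratio_df = (
            ratio_df.sort_values(
                ["genotype", "mean_ratio", "label"],
                ascending=[True, False, True],
            ).reset_index(drop=True)
        )
    excl_df = pd.DataFrame(exclusions, columns=["gene_id", "reason"])
    return ratio_df, excl_df


# ---------------------------------------------------------------------------
# Exit-tunnel mapping
# ---------------------------------------------------------------------------

def load_tmd_table(path: str | Path) -> pd.DataFrame:
    """Read a TMD table TSV: tmd_label, start_residue, end_residue (1-based,
    inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"tmd_label", "start_residue", "end_residue"}
    if not needed.issubset(df.columns):
        raise RiboplastError(
            f"{path}: TMD table needs columns {sorted(needed)}"
        )
    return df


def _validate_tmd_table(tmd_table: pd.DataFrame, protein_length: int | None) -> None:
    t = tmd_table.sort_values("start_residue").reset_index(drop=True)
    for row in t.itertuples(index=False):
        if row.start_residue < 1 or row.end_residue < row.start_residue:
            raise RiboplastError(
                f"TMD {row.tmd_label!r}: invalid interval "
                f"[{row.start_residue}, {row.end_residue}]"
            )
        if protein_length is not None and row.end_residue > protein_length:
            raise RiboplastError(
                f"TMD {row.tmd_label!r} extends past the protein "
                f"({row.end_residue} > {protein_length})"
            )
    ends = t["end_residue"].to_numpy()
    starts = t["start_residue"].to_numpy()
    if (starts[1:] <= ends[:-1]).any():
        raise RiboplastError("TMD table intervals overlap")


def map_peak_to_tunnel(
    peak: Peak,
    tunnel_len_codons: int = DEFAULT_TUNNEL_LEN_CODONS,
    tmd_table: pd.DataFrame | None = None,
    protein_length: int | None = None,
) -> TunnelMapping:
    """Map a peak's P-site codon to the nascent-chain residue emerging from
    the exit tunnel; with a TMD table, report which TMD (or loop) that is.

    ``emerging_residue = codon_index - tunnel_len_codons`` when positive;
    earlier peaks have no emerged residue yet.
    """
    if tunnel_len_codons < 0:
        raise RiboplastError("tunnel_len_codons must be >= 0")
    emerging = peak.codon_index - tunnel_len_codons
    if emerging <= 0:
        return TunnelMapping(
            peak=peak, psite_codon=peak.codon_index,
            emerging_residue=None, emerging_feature=None,
        )
    feature = None
    if tmd_table is not None:
        _validate_tmd_table(tmd_table, protein_length)
        hit = tmd_table[
            (tmd_table["start_residue"] <= emerging)
            & (emerging <= tmd_table["end_residue"])
        ]
        feature = str(hit["tmd_label"].iloc[0]) if not hit.empty else "loop"
    return TunnelMapping(
        peak=peak, psite_codon=peak.codon_index,
        emerging_residue=int(emerging), emerging_feature=feature,
    )
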