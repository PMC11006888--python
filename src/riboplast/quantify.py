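"""Footprint-to-ORF assignment, cpRPKM quantification and genotype ratios.

Assignment follows the 5'-end rule: a footprint belongs to the ORF that
contains the genomic coordinate of its 5' end on the same strand. Where
plastid ORFs overlap and a 5' end falls inside more than one, the footprint
goes to the ORF whose start codon is nearest upstream (in the gene's own
orientation), ties broken by lexicographic gene id; every such multi-candidate
assignment is counted and logged, so overlap resolution is auditable.

cpRPKM is the plastid-restricted RPKM variant: reads per kilobase of ORF per
million reads mapped to the total chloroplast ORFs of that sample,

    cpRPKM_g = n_g / ((L_g / 1000) * (N_total / 1e6)),

with ``N_total`` the sum of ORF-assigned counts in the sample (unassigned
reads do not enter the denominator). The definition telescopes:
``sum_g cpRPKM_g * L_g(kb) = 1e6`` exactly for every sample, a conservation
identity the test suite checks.

Mutant/WT ratios are computed per gene and genotype on the cpRPKM scale:
the WT reference is the mean cpRPKM over WT replicates (``ratio_mode
"mean_ref"``; ``"paired"`` divides replicate-by-replicate instead), each
mutant replicate contributes ``log2(cpRPKM_mut,r / WT_ref)``, and the table
reports the replicate mean and sample standard deviation (n-1). Genes with
fewer than ``min_reads`` raw assigned counts in any sample are flagged
excluded — not silently dropped — mirroring the low-count exclusion rule
(default threshold 200 reads).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import QuantError
from .io import OrfRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 200

RATIO_MODES = ("mean_ref", "paired")


@dataclasses.dataclass
class AssignmentResult:
    """Per-footprint gene assignment plus bookkeeping counts."""

    gene_id: pd.Series  # aligned to the input frame; None where unassigned
    n_assigned: int
    n_unassigned: int
    n_multi_candidate: int


def assign_to_orfs(
    footprints: pd.DataFrame, orfs: Sequence[OrfRecord]
) -> AssignmentResult:
    """Assign each footprint to the ORF containing its 5' end, strand-matched.

    Returns an :class:`AssignmentResult`; ``n_assigned + n_unassigned`` always
    equals the number of input footprints.
    """
    n = len(footprints)
    gene = np.full(n, None, dtype=object)
    if n == 0:
        return AssignmentResult(pd.Series(gene, index=footprints.index), 0, 0, 0)
    fp5 = footprints["five_prime"].to_numpy()
    strand = footprints["strand"].to_numpy()
    seq = footprints["seq_id"].to_numpy()
    best_dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    n_candidates = np.zeros(n, dtype=np.int64)
    for orf in orfs:
        inside = (
            (seq == orf.seq_id)
            & (strand == orf.strand)
            & (fp5 >= orf.start)
            & (fp5 < orf.end)
        )
        if not inside.any():
            continue
        # distance from the ORF's own start codon, in gene orientation
        dist = np.where(
            strand == "+", fp5 - orf.start, (orf.end - 1) - fp5
        ).astype(np.int64)
        n_candidates += inside
        better = inside & (
            (dist < best_dist)
            | ((dist == best_dist) & (np.asarray([g is None or orf.gene_id < g for g in gene])))
        )
        gene[better] = orf.gene_id
        best_dist[better] = dist[better]
    n_multi = int((n_candidates > 1).sum())
    if n_multi:
        logger.info(
            "%d footprints had 5' ends inside more than one ORF; assigned to "
            "the nearest-upstream start codon (ties by gene id)", n_multi,
        )
    assigned = pd.Series(gene, index=footprints.index, name="gene_id")
    n_assigned = int(assigned.notna().sum())
    return AssignmentResult(assigned, n_assigned, n - n_assigned, n_multi)


def count_by_gene(
    footprints: pd.DataFrame, orfs: Sequence[OrfRecord],
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-(gene, sample) assigned footprint counts.

    Returns a long DataFrame ``(gene_id, sample_id, n)`` that is complete —
    every annotated gene appears for every sample, with zeros where no
    footprint was assigned — plus the number of unassigned footprints.
    """
    result = assign_to_orfs(footprints, orfs)
    assigned = footprints.assign(gene_id=result.gene_id).dropna(subset=["gene_id"])
    counts = (
        assigned.groupby(["gene_id", "sample_id"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    if sample_ids is None:
        sample_ids = sorted(footprints["sample_id"].unique())
    full = pd.MultiIndex.from_product(
        [sorted(o.gene_id for o in orfs), list(sample_ids)],
        names=["gene_id", "sample_id"],
    )
    counts = (
        counts.set_index(["gene_id", "sample_id"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    counts["n"] = counts["n"].astype(np.int64)
    return counts, result.n_unassigned


def compute_cp_rpkm(
    gene_counts: pd.DataFrame, orfs: Sequence[OrfRecord]
) -> pd.DataFrame:
    """cpRPKM per gene and sample from a long count table.

    Raises :class:`QuantError` for a sample with no ORF-assigned reads.
    """
    lengths = pd.Series({o.gene_id: o.length_nt for o in orfs}, name="length_nt")
    unknown = set(gene_counts["gene_id"]) - set(lengths.index)
    if unknown:
        raise QuantError(f"counts refer to unannotated genes: {sorted(unknown)}")
    df = gene_counts.copy()
    df["length_nt"] = df["gene_id"].map(lengths)
    totals = df.groupby("sample_id")["n"].transform("sum")
    empty = df.loc[totals == 0, "sample_id"].unique()
    if len(empty):
        raise QuantError(
            f"sample(s) with zero ORF-assigned reads: {sorted(empty)}"
        )
    df["cp_rpkm"] = df["n"] / ((df["length_nt"] / 1000.0) * (totals / 1e6))
    return df[["gene_id", "sample_id", "n", "length_nt", "cp_rpkm"]]


def genotype_log2_ratios(
    quants: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    ratio_mode: str = "mean_ref",
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Per-gene mutant/WT cpRPKM log2 ratios with replicate mean and SD.

    One row per (gene, non-WT genotype): columns ``mean_log2``, ``sd_log2``
    (NaN when fewer than two usable replicates), ``n_replicates``,
    ``replicate_log2_ratios`` (comma-joined), ``excluded`` and ``reason``.
    Exclusion flags (low counts, zero WT reference, zero mutant replicate)
    annotate rather than remove rows.
    """
    if ratio_mode not in RATIO_MODES:
        raise QuantError(f"ratio_mode must be one of {RATIO_MODES}, got {ratio_mode!r}")
    if min_reads < 0:
        raise QuantError("min_reads must be >= 0")
    sheet = sample_sheet.set_index("sample_id")
    unknown = set(quants["sample_id"]) - set(sheet.index)
    if unknown:
        raise QuantError(f"samples missing from the sample sheet: {sorted(unknown)}")
    q = quants.merge(
        sheet[["genotype", "replicate"]], left_on="sample_id", right_index=True
    )
    wt = q[q["genotype"] == wt_genotype]
    if wt.empty:
        raise QuantError(f"no {wt_genotype!r} samples: cannot form ratios")

    low = q.groupby("gene_id")["n"].min() < min_reads
    wt_ref = wt.groupby("gene_id")["cp_rpkm"].mean()
    wt_by_rep = wt.pivot(index="gene_id", columns="replicate", values="cp_rpkm")

    rows = []
    for genotype, sub in q[q["genotype"] != wt_genotype].groupby("genotype", sort=True):
        for gene_id, g in sub.groupby("gene_id", sort=True):
            g = g.sort_values("replicate")
            reasons = []
            if bool(low.get(gene_id, False)):
                reasons.append(f"reads below {min_reads} in >=1 sample")
            if ratio_mode == "mean_ref":
                ref = np.full(len(g), wt_ref.get(gene_id, np.nan))
            else:  # paired: match replicate indices
                ref = wt_by_rep.reindex([gene_id]).iloc[0].reindex(
                    g["replicate"]
                ).to_numpy()
                if np.isnan(ref).any():
                    raise QuantError(
                        f"paired ratio_mode: gene {gene_id!r}, genotype "
                        f"{genotype!r} has replicates without a WT partner"
                    )
            mut = g["cp_rpkm"].to_numpy(dtype=float)
            if np.all(ref == 0) or np.isnan(ref).all():
                reasons.append("WT zero")
                ratios = np.full(len(g), np.nan)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios = mut / ref
                if (ratios <= 0).any() or np.isnan(ratios).any():
                    reasons.append("mutant zero")
            with np.errstate(divide="ignore", invalid="ignore"):
                log2r = np.log2(ratios)
            usable = np.isfinite(log2r)
            n_rep = int(usable.sum())
            mean = float(np.mean(log2r[usable])) if n_rep else np.nan
            sd = float(np.std(log2r[usable], ddof=1)) if n_rep >= 2 else np.nan
            rows.append(
                {
                    "gene_id": gene_id,
                    "genotype": genotype,
                    "mean_log2": mean,
                    "sd_log2": sd,
                    "n_replicates": n_rep,
                    "replicate_log2_ratios": ",".join(
                        f"{v:.6g}" for v in log2r[usable]
                    ),
                    "excluded": bool(reasons),
                    "reason": ";".join(reasons),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "genotype", "mean_log2", "sd_log2", "n_replicates",
            "replicate_log2_ratios", "excluded", "reason",
        ],
    )
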