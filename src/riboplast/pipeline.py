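"""End-to-end pipeline orchestration: load -> QC -> quantify -> peaks -> scan.

Every output TSV starts with '#' metadata lines recording the tool version
and the full parameter set (never timestamps: identical runs are
byte-identical), and a JSON run manifest records the effective merged
configuration plus SHA-256 checksums of all inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import sha256_file
from .config import PipelineConfig
from .errors import RiboplastError
from .io import (
    load_annotation,
    load_footprints,
    load_sample_sheet,
    write_table,
)
from .pausing import (
    build_profile,
    call_major_peaks,
    genome_wide_scan,
    map_peak_to_tunnel,
    normalize_profile,
    peak_ratio,
    pool_profiles,
)
from .qc import frame_periodicity, length_distribution
from .quantify import compute_cp_rpkm, count_by_gene, genotype_log2_ratios

logger = logging.getLogger(__name__)


#: path-like config keys stay out of table metadata (the run manifest records
#: them); only parameters go into the '#' header so identical analyses of the
#: same data are byte-identical regardless of where they are written.
_PATH_KEYS = ("genome", "gff", "sample_sheet", "outdir")


def _metadata(config: PipelineConfig, **extra) -> dict[str, object]:
    meta: dict[str, object] = {"riboplast_version": __version__}
    meta.update(
        (k, v)
        for k, v in dataclasses.asdict(config).items()
        if v is not None and k not in _PATH_KEYS
    )
    meta.update(extra)
    return meta


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write the output directory of TSVs + manifest.

    Fatal errors from any stage propagate as :class:`RiboplastError`
    subclasses with module context; the CLI converts them to a non-zero exit.
    """
    for key in ("genome", "gff", "sample_sheet"):
        if getattr(config, key) is None:
            raise RiboplastError(f"config is missing required path {key!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    orfs, genome = load_annotation(config.gff, config.genome)
    sheet = load_sample_sheet(config.sample_sheet)
    sheet_dir = Path(config.sample_sheet).parent

    # --- load footprints -------------------------------------------------
    frames = []
    qc_rows = []
    for row in sheet.itertuples(index=False):
        bed = Path(row.path)
        if not bed.is_absolute():
            bed = sheet_dir / bed
        fp, n_dropped = load_footprints(
            bed, row.sample_id, config.length_min, config.length_max
        )
        frames.append(fp)
        qc_rows.append((row.sample_id, len(fp), n_dropped))
    footprints = pd.concat(frames, ignore_index=True)

    # --- QC ---------------------------------------------------------------
    hist_rows = []
    frame_rows = []
    for (sid, n_kept, n_dropped), fp in zip(qc_rows, frames):
        hist = length_distribution(fp)
        for length, count in sorted(hist.counts.items()):
            hist_rows.append((sid, length, count))
        ff = frame_periodicity(fp, orfs, config.psite_offset)
        frame_rows.append(
            (sid, ff.f0, ff.f1, ff.f2, ff.n_used, n_kept, n_dropped,
             hist.mode_length)
        )
    write_table(
        pd.DataFrame(hist_rows, columns=["sample_id", "length_nt", "count"]),
        outdir / "length_hist.tsv", _metadata(config),
    )
    write_table(
        pd.DataFrame(
            frame_rows,
            columns=["sample_id", "f0", "f1", "f2", "n_used",
                     "n_footprints", "n_length_filtered", "mode_length"],
        ),
        outdir / "frame_fractions.tsv", _metadata(config),
    )

    # --- quantify ---------------------------------------------------------
    counts, n_unassigned = count_by_gene(
        footprints, orfs, sample_ids=list(sheet["sample_id"])
    )
    quants = compute_cp_rpkm(counts, orfs)
    ratios = genotype_log2_ratios(
        quants, sheet, min_reads=config.min_reads, ratio_mode=config.ratio_mode
    )
    meta_q = _metadata(config, n_unassigned=n_unassigned)
    write_table(counts, outdir / "gene_counts.tsv", meta_q)
    write_table(
        quants.pivot(index="gene_id", columns="sample_id", values="cp_rpkm")
        .reset_index(),
        outdir / "cp_rpkm.tsv", meta_q,
    )
    write_table(ratios, outdir / "log2_ratios.tsv", meta_q)

    # --- peaks (per-gene profiles on pooled WT) ---------------------------
    params = config.peak_params()
    wt_samples = sheet.loc[sheet["genotype"] == "WT", "sample_id"].tolist()
    peak_rows = []
    tunnel_rows = []
    profile_dir = outdir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    min_per_gene = counts.groupby("gene_id")["n"].min()
    for orf in orfs:
        if not orf.is_triplet or min_per_gene.get(orf.gene_id, 0) < config.min_reads:
            continue
        per_sample = {
            sid: build_profile(
                footprints[footprints["sample_id"] == sid], orf,
                config.profile_offset, sample_id=sid,
            )
            for sid in sheet["sample_id"]
        }
        pooled = normalize_profile(
            pool_profiles([per_sample[s] for s in wt_samples])
        )
        for sid, prof in per_sample.items():
            dens = normalize_profile(prof).density if prof.total else np.zeros(
                orf.length_nt
            )
            write_table(
                pd.DataFrame(
                    {
                        "position_nt": np.arange(orf.length_nt),
                        "count": prof.values,
                        "density": dens,
                    }
                ),
                profile_dir / f"{orf.gene_id}.{sid}.tsv",
                _metadata(config, gene_id=orf.gene_id, sample_id=sid),
            )
        for peak in call_major_peaks(pooled, params):
            peak_rows.append(
                (peak.gene_id, peak.label, peak.codon_index, peak.position_nt,
                 peak.height, peak.rank)
            )
            tm = map_peak_to_tunnel(peak, config.tunnel_len_codons)
            tunnel_rows.append(
                (peak.label, tm.psite_codon,
                 tm.emerging_residue if tm.emerging_residue is not None else "",
                 tm.emerging_feature or "")
            )
    write_table(
        pd.DataFrame(
            peak_rows,
            columns=["gene_id", "label", "codon_index", "position_nt",
                     "height", "rank"],
        ),
        outdir / "peaks.tsv", _metadata(config),
    )
    write_table(
        pd.DataFrame(
            tunnel_rows,
            columns=["label", "psite_codon", "emerging_residue",
                     "emerging_feature"],
        ),
        outdir / "tunnel_map.tsv", _metadata(config),
    )

    # --- genome-wide scan --------------------------------------------------
    scan_df, excl_df = genome_wide_scan(
        footprints, orfs, sheet, params,
        offset_nt=config.profile_offset, min_reads=config.min_reads,
    )
    write_table(scan_df, outdir / "peak_ratios.tsv", _metadata(config))
    write_table(excl_df, outdir / "scan_exclusions.tsv", _metadata(config))

    # --- manifest ----------------------------------------------------------
    manifest = {
        "riboplast_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            "genome": sha256_file(config.genome),
            "gff": sha256_file(config.gff),
            "sample_sheet": sha256_file(config.sample_sheet),
        },
        "n_footprints": int(len(footprints)),
        "n_unassigned": int(n_unassigned),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
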