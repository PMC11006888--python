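"""Synthetic ribosome-footprint generator with known pause architecture.

The generator emulates the structure of a chloroplast ribosome-profiling
experiment: a handful of genotypes (wild type plus mutants) with biological
replicates, footprints whose length distribution peaks at 31-33 nt, strong
but imperfect 3-nt periodicity, and gene-specific codon-level pause sites
whose height can depend on genotype. Because every pause multiplier is known,
downstream peak calling and ratio statistics can be tested against ground
truth.

Generative model, per gene and sample:

* the footprint count is Poisson with mean ``depth_per_gene`` (optionally
  scaled per genotype and gene by ``genotype_depth_effects``);
* each footprint's P-site codon is drawn from per-codon weights
  ``baseline x pause_map x genotype_effects``; each multiplier is perturbed
  once per replicate by multiplicative lognormal noise with coefficient of
  variation ``replicate_noise_cv`` (mean-1 lognormal), which is what spreads
  the replicate-to-replicate ratios that the mean +/- SD statistics summarise;
* the 5' end sits ``psite_offset`` nt upstream of the P-site codon; with
  probability ``1 - frame_fidelity`` it is shifted +/-1 nt (equiprobably),
  degrading the 3-nt periodicity;
* the footprint length is drawn from ``length_dist``; the interval is placed
  on the gene's strand.

Because pause multipliers act on sampling weights *before* normalisation, a
stall at one codon slightly depresses density everywhere else — the same
shrinkage that per-gene normalisation imposes on real profiles. The helper
:func:`expected_peak_height_ratio` (and its inverse
:func:`calibrate_stall_effect`) make that shrinkage explicit.

The RNG stream is a pure function of ``(seed, genotype, replicate)`` (CRC32
of the genotype name; no process-salted hashing), so identical configurations
are byte-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import stable_text_hash
from .errors import SimulationError
from .io import (
    GenomeSequence,
    OrfRecord,
    empty_footprints,
    footprint_frame,
    write_annotation,
    write_footprints_bed,
    write_genome,
    write_sample_sheet,
)

#: Distance from a footprint's 5' end to its P-site codon, in nt.
#: Conventional for ~31-nt plant chloroplast footprints.
P_SITE_OFFSET_NT = 12

#: Default footprint length distribution: mode 32, support 28-36, with most
#: mass on 31-33 as observed for chloroplast ribosome footprints.
DEFAULT_LENGTH_DIST: dict[int, float] = {
    28: 0.02, 29: 0.04, 30: 0.10, 31: 0.20, 32: 0.28,
    33: 0.20, 34: 0.10, 35: 0.04, 36: 0.02,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOP_CODONS = ("TAA", "TAG", "TGA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class SimulationConfig:
    """Full generative description of a synthetic footprint dataset.

    Parameters
    ----------
    genome, orfs
        The annotation the reads are simulated on (see
        :func:`make_toy_annotation`).
    depth_per_gene
        Expected footprint count per gene per sample.
    baseline_weights
        Optional per-gene arrays of per-codon relative occupancy
        (default: uniform).
    pause_map
        ``gene_id -> {codon_index (0-based) -> stall multiplier}``; applies to
        every genotype (the gene's intrinsic pause architecture).
    genotype_effects
        ``genotype -> {(gene_id, codon_index) -> extra multiplier}``; the
        wild type carries no entries.
    genotype_depth_effects
        ``genotype -> {gene_id -> depth multiplier}``; models genotype-level
        changes in overall ribosome occupancy of a gene (footprint abundance),
        which codon-weight multipliers alone cannot produce because the
        per-gene count is drawn independently of codon weights.
    replicate_noise_cv
        Coefficient of variation of the mean-1 lognormal factor applied to
        each pause/genotype multiplier once per replicate.
    length_dist
        Discrete footprint length distribution (must sum to 1).
    frame_fidelity
        Probability that a 5' end falls exactly ``psite_offset`` nt upstream
        of its codon; otherwise it is shifted +/-1 nt equiprobably.
    psite_offset
        5' end to P-site distance in nt.
    seed
        Base seed; the per-sample stream is derived from
        ``(seed, genotype, replicate)``.
    """

    genome: GenomeSequence
    orfs: list[OrfRecord]
    depth_per_gene: float = 5000.0
    baseline_weights: dict[str, np.ndarray] | None = None
    pause_map: dict[str, dict[int, float]] = dataclasses.field(default_factory=dict)
    genotype_effects: dict[str, dict[tuple[str, int], float]] = dataclasses.field(
        default_factory=dict
    )
    genotype_depth_effects: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    replicate_noise_cv: float = 0.05
    length_dist: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    frame_fidelity: float = 0.9
    psite_offset: int = P_SITE_OFFSET_NT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_gene < 0:
            raise SimulationError("depth_per_gene must be >= 0")
        if not (0.0 <= self.frame_fidelity <= 1.0):
            raise SimulationError("frame_fidelity must be in [0, 1]")
        if self.psite_offset < 0:
            raise SimulationError("psite_offset must be >= 0")
        if self.replicate_noise_cv < 0:
            raise SimulationError("replicate_noise_cv must be >= 0")
        total = float(sum(self.length_dist.values()))
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"length_dist must sum to 1, sums to {total}")
        if any(l <= 0 for l in self.length_dist):
            raise SimulationError("footprint lengths must be positive")
        known = {o.gene_id for o in self.orfs}
        for gene in self.pause_map:
            if gene not in known:
                raise SimulationError(
                    f"pause_map gene {gene!r} is absent from the annotation"
                )
        for genotype, effects in self.genotype_effects.items():
            for (gene, _codon), mult in effects.items():
                if gene not in known:
                    raise SimulationError(
                        f"genotype_effects[{genotype!r}] gene {gene!r} is "
                        "absent from the annotation"
                    )
                if mult <= 0:
                    raise SimulationError("genotype effect multipliers must be > 0")
        for pauses in self.pause_map.values():
            if any(m <= 0 for m in pauses.values()):
                raise SimulationError("stall multipliers must be > 0")

    # -- weight bookkeeping -------------------------------------------------

    def orf_by_id(self, gene_id: str) -> OrfRecord:
        for orf in self.orfs:
            if orf.gene_id == gene_id:
                return orf
        raise SimulationError(f"gene {gene_id!r} is absent from the annotation")

    def expected_weights(self, gene_id: str, genotype: str) -> np.ndarray:
        """Noise-free per-codon sampling weights for one gene and genotype."""
        orf = self.orf_by_id(gene_id)
        n_codons = orf.length_codons
        if self.baseline_weights and gene_id in self.baseline_weights:
            w = np.asarray(self.baseline_weights[gene_id], dtype=float).copy()
            if w.shape != (n_codons,):
                raise SimulationError(
                    f"baseline_weights[{gene_id!r}] has shape {w.shape}, "
                    f"expected ({n_codons},)"
                )
        else:
            w = np.ones(n_codons, dtype=float)
        for codon, mult in self.pause_map.get(gene_id, {}).items():
            if not (0 <= codon < n_codons):
                raise SimulationError(
                    f"pause codon {codon} outside gene {gene_id!r} "
                    f"({n_codons} codons)"
                )
            w[codon] *= mult
        for (gene, codon), mult in self.genotype_effects.get(genotype, {}).items():
            if gene == gene_id:
                if not (0 <= codon < n_codons):
                    raise SimulationError(
                        f"genotype effect codon {codon} outside gene {gene_id!r}"
                    )
                w[codon] *= mult
        return w


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0 or n == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def sample_rng(seed: int, genotype: str, replicate: int) -> np.random.Generator:
    """Deterministic RNG stream for one (seed, genotype, replicate)."""
    ss = np.random.SeedSequence((int(seed), stable_text_hash(genotype), int(replicate)))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Toy annotation
# ---------------------------------------------------------------------------

def make_toy_annotation(
    n_genes: int = 3,
    lengths_codons: Sequence[int] = (100, 508, 80),
    spacer_nt: int = 50,
    seed: int = 0,
    *,
    seq_id: str = "toyplastid",
    gene_ids: Sequence[str] | None = None,
) -> tuple[GenomeSequence, list[OrfRecord]]:
    """Lay out a deterministic toy plastid genome with ``n_genes`` ORFs.

    Genes alternate strands and are separated by ``spacer_nt`` of intergenic
    sequence (also flanking both ends), so the genome length is
    ``(n_genes + 1) * spacer_nt + 3 * sum(lengths_codons)``. Each ORF is a
    proper reading frame: ATG, random sense codons without internal stops,
    and a final TAA, reverse-complemented for minus-strand genes. The default
    lengths include a 508-codon gene matching the scale of the CP47 ORF, with
    room for stall-injection experiments.
    """
    if n_genes != len(lengths_codons):
        raise SimulationError(
            f"n_genes={n_genes} but {len(lengths_codons)} lengths given"
        )
    if n_genes < 1:
        raise SimulationError("need at least one gene")
    if spacer_nt < 0:
        raise SimulationError("spacer_nt must be >= 0")
    bad = [l for l in lengths_codons if l < 50]
    if bad:
        raise SimulationError(
            f"gene lengths below the 50-codon minimum (peak calling needs "
            f"room): {bad}"
        )
    if gene_ids is None:
        gene_ids = [f"g{i + 1:02d}" for i in range(n_genes)]
    if len(set(gene_ids)) != n_genes or len(gene_ids) != n_genes:
        raise SimulationError("gene_ids must be unique, one per gene")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA110C)))
    bases = np.array(list("ACGT"))
    sense_codons = np.array(
        [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in _STOP_CODONS]
    )

    def spacer() -> str:
        return "".join(rng.choice(bases, size=spacer_nt))

    parts: list[str] = []
    orfs: list[OrfRecord] = []
    pos = 0
    parts.append(spacer())
    pos += spacer_nt
    for i, (gene_id, n_codons) in enumerate(zip(gene_ids, lengths_codons)):
        body = "".join(rng.choice(sense_codons, size=n_codons - 2))
        cds = "ATG" + body + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        parts.append(cds if strand == "+" else _revcomp(cds))
        orfs.append(
            OrfRecord(
                gene_id=gene_id, seq_id=seq_id,
                start=pos, end=pos + 3 * n_codons, strand=strand,
            )
        )
        pos += 3 * n_codons
        parts.append(spacer())
        pos += spacer_nt
    genome = GenomeSequence(seq_id=seq_id, sequence="".join(parts))
    assert genome.length == pos
    return genome, orfs


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------

def simulate_footprints(
    config: SimulationConfig, genotype: str, replicate: int,
    *, sample_id: str | None = None,
) -> pd.DataFrame:
    """Simulate one sample's footprints (see the module docstring).

    Footprints that would extend past either end of the (linear) genome are
    dropped; with the default toy layout (50 nt spacers) this cannot happen
    except for pathological offsets.
    """
    if replicate < 1:
        raise SimulationError("replicate index must be >= 1")
    if sample_id is None:
        sample_id = f"{genotype}_{replicate}"
    rng = sample_rng(config.seed, genotype, replicate)
    lengths_support = np.array(sorted(config.length_dist), dtype=np.int64)
    lengths_p = np.array([config.length_dist[l] for l in lengths_support])
    lengths_p = lengths_p / lengths_p.sum()

    frames = []
    for orf in config.orfs:
        gene = orf.gene_id
        if not orf.is_triplet:
            raise SimulationError(
                f"cannot simulate on non-triplet ORF {gene!r}"
            )
        w = config.expected_weights(gene, genotype)
        # one lognormal perturbation per multiplier entry per replicate
        pause_codons = sorted(
            set(config.pause_map.get(gene, {}))
            | {c for (g, c) in config.genotype_effects.get(genotype, {}) if g == gene}
        )
        noise = _lognormal_factors(rng, config.replicate_noise_cv, len(pause_codons))
        for codon, factor in zip(pause_codons, noise):
            w[codon] *= factor
        depth = config.depth_per_gene * (
            config.genotype_depth_effects.get(genotype, {}).get(gene, 1.0)
        )
        n = int(rng.poisson(depth))
        if n == 0:
            continue
        codons = rng.choice(len(w), size=n, p=w / w.sum())
        five_rel = 3 * codons - config.psite_offset
        if config.frame_fidelity < 1.0:
            miss = rng.random(n) >= config.frame_fidelity
            shifts = rng.integers(0, 2, size=n) * 2 - 1  # +/-1 equiprobable
            five_rel = five_rel + np.where(miss, shifts, 0)
        lengths = rng.choice(lengths_support, size=n, p=lengths_p)
        if orf.strand == "+":
            g5 = orf.start + five_rel
            start, end = g5, g5 + lengths
        else:
            g5 = (orf.end - 1) - five_rel
            start, end = g5 + 1 - lengths, g5 + 1
        ok = (start >= 0) & (end <= config.genome.length)
        frames.append(
            footprint_frame(
                config.genome.seq_id, start[ok], end[ok],
                np.full(int(ok.sum()), orf.strand, dtype=object), sample_id,
            )
        )
    if not frames:
        return empty_footprints()
    out = pd.concat(frames, ignore_index=True)
    return out


def simulate_experiment(
    config: SimulationConfig,
    genotypes: Sequence[str] = ("WT", "fpb1", "pam68"),
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full genotype x replicate design in memory.

    Returns ``(footprints, sample_sheet)`` where the sample sheet's ``path``
    column is empty (filled by :func:`write_dataset` when files are written).
    """
    frames = []
    rows = []
    for genotype in genotypes:
        for rep in range(1, n_replicates + 1):
            sid = f"{genotype}_{rep}"
            frames.append(
                simulate_footprints(config, genotype, rep, sample_id=sid)
            )
            rows.append((sid, genotype, rep, ""))
    footprints = (
        pd.concat(frames, ignore_index=True) if frames else empty_footprints()
    )
    sheet = pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate", "path"])
    return footprints, sheet


def write_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    genotypes: Sequence[str] = ("WT", "fpb1", "pam68"),
    n_replicates: int = 3,
) -> Path:
    """Write a complete synthetic dataset: FASTA + GFF3 + one BED6 per sample
    + sample sheet. Returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(config.genome, outdir / "genome.fasta")
    write_annotation(config.orfs, outdir / "annotation.gff3")
    footprints, sheet = simulate_experiment(config, genotypes, n_replicates)
    paths = []
    for sid in sheet["sample_id"]:
        bed = outdir / f"{sid}.bed"
        write_footprints_bed(
            footprints.loc[footprints["sample_id"] == sid], bed
        )
        paths.append(bed.name)
    sheet = sheet.assign(path=paths)
    write_sample_sheet(sheet, outdir / "samples.tsv")
    return outdir


# ---------------------------------------------------------------------------
# Analytic expectations / calibration
# ---------------------------------------------------------------------------

def expected_peak_height_ratio(
    config: SimulationConfig, genotype: str, gene_id: str, codon: int,
    smooth_codons: int = 3,
) -> float:
    """Expected mutant/WT ratio of normalised smoothed peak height at a codon.

    Normalising each profile by its own total shrinks the apparent stall: a
    multiplier ``m`` on a codon whose baseline density share is ``d0`` yields
    an observed height ratio ``m / (1 + (m - 1) * d0)``, and smoothing over
    ``smooth_codons`` further mixes in the (unchanged) neighbouring codons.
    This closed form is the ground truth recovery tests compare against.
    """
    w_wt = config.expected_weights(gene_id, "WT")
    w_mut = config.expected_weights(gene_id, genotype)
    h = (smooth_codons - 1) // 2
    lo, hi = max(0, codon - h), min(len(w_wt), codon + h + 1)
    num_wt = w_wt[lo:hi].sum() / w_wt.sum()
    num_mut = w_mut[lo:hi].sum() / w_mut.sum()
    return float(num_mut / num_wt)


def calibrate_stall_effect(
    config: SimulationConfig, gene_id: str, codon: int, target_ratio: float,
    smooth_codons: int = 3,
) -> float:
    """Extra genotype multiplier at ``codon`` so the expected normalised
    smoothed height ratio (see :func:`expected_peak_height_ratio`) equals
    ``target_ratio``. Purely analytic inversion of the renormalisation."""
    w = config.expected_weights(gene_id, "WT")
    W = float(w.sum())
    wc = float(w[codon])
    h = (smooth_codons - 1) // 2
    lo, hi = max(0, codon - h), min(len(w), codon + h + 1)
    s = float(w[lo:hi].sum()) - wc  # neighbours inside the smoothing window
    rho = float(target_ratio)
    denom = wc * (W - rho * (wc + s))
    if denom <= 0:
        raise SimulationError(
            f"target ratio {rho} is not attainable for gene {gene_id!r} "
            f"codon {codon} (renormalisation bound exceeded)"
        )
    e = (rho * (wc + s) * (W - wc) - s * W) / denom
    if e <= 0:
        raise SimulationError("calibrated effect is non-positive")
    return e


def expected_assigned_share(config: SimulationConfig, genotype: str) -> pd.Series:
    """Expected share of ORF-assigned footprints per gene for one genotype.

    Accounts for the 5'-end assignment rule: footprints whose P-site codon
    lies within ``psite_offset`` nt of the start codon have their 5' end
    upstream of the ORF and are not assignable.
    """
    lost_codons = int(np.ceil(config.psite_offset / 3))
    shares = {}
    for orf in config.orfs:
        w = config.expected_weights(orf.gene_id, genotype)
        frac_assignable = w[lost_codons:].sum() / w.sum()
        depth = config.depth_per_gene * (
            config.genotype_depth_effects.get(genotype, {}).get(orf.gene_id, 1.0)
        )
        shares[orf.gene_id] = depth * frac_assignable
    s = pd.Series(shares)
    return s / s.sum()


def calibrate_depth_effect(
    config: SimulationConfig, gene_id: str, target_cp_rpkm_ratio: float,
) -> float:
    """Depth multiplier for ``gene_id`` so its expected mutant/WT cpRPKM
    ratio equals ``target_cp_rpkm_ratio``.

    cpRPKM normalises by the sample's total ORF-assigned reads, so raising one
    gene's depth by ``delta`` raises its cpRPKM by only
    ``delta / (1 + s * (delta - 1))`` where ``s`` is that gene's share of the
    total; this inverts that relation.
    """
    t = expected_assigned_share(config, "WT")
    s = float(t[gene_id])
    rho = float(target_cp_rpkm_ratio)
    denom = 1.0 - rho * s
    if denom <= 0:
        raise SimulationError(
            f"cpRPKM ratio {rho} unattainable: gene {gene_id!r} share {s:.3f} "
            "too large"
        )
    return rho * (1.0 - s) / denom


# ---------------------------------------------------------------------------
# The bundled study-like configuration
# ---------------------------------------------------------------------------

#: Intrinsic pause architecture of the 508-codon CP47-like gene: five pause
#: sites, one near the start codon (translation initiation) and four placed
#: where nascent-chain transmembrane segments 2, 4, 5 and 6 emerge from the
#: ribosomal exit tunnel (TMD end + ~33 codons).
PSBB_PAUSE_CODONS: dict[int, float] = {6: 8.0, 148: 5.0, 253: 6.0, 290: 5.0, 455: 6.0}

#: The stalled pause in the mutants: the fifth peak, at TMD VI emergence.
PSBB_STALL_CODON = 455


def psbB_like_study(
    seed: int = 0,
    depth_per_gene: float = 5000.0,
    stall_ratio_targets: Mapping[str, float] | None = None,
    abundance_ratio_target: float = 2.0,
    smooth_codons: int = 3,
) -> tuple[SimulationConfig, tuple[str, ...]]:
    """The bundled synthetic study: a 12-gene toy plastid genome whose second
    gene, ``psbB``, is a 508-codon CP47-like ORF with five intrinsic pause
    sites; two mutant genotypes (*fpb1*, *pam68*) stall harder at the fifth
    pause (TMD VI emergence) and carry roughly doubled psbB ribosome
    occupancy.

    Effect sizes are calibrated analytically (never against measured output)
    so the *expected* normalised psbB-V height ratios are the published
    1.310 (fpb1) and 1.420 (pam68) and the expected psbB footprint-abundance
    cpRPKM ratio is ~2.
    """
    if stall_ratio_targets is None:
        stall_ratio_targets = {"fpb1": 1.310, "pam68": 1.420}
    lengths = [120, 508, 80, 150, 210, 95, 130, 300, 105, 160, 85, 250]
    gene_ids = [
        "g01", "psbB", "g03", "g04", "g05", "g06",
        "g07", "g08", "g09", "g10", "g11", "g12",
    ]
    genome, orfs = make_toy_annotation(
        n_genes=len(lengths), lengths_codons=lengths, spacer_nt=50,
        seed=seed, gene_ids=gene_ids,
    )
    pause_map = {
        "psbB": dict(PSBB_PAUSE_CODONS),
        # modest pauses elsewhere so the genome-wide scan has structure
        "g04": {60: 4.0},
        "g08": {200: 5.0, 40: 4.0},
    }
    config = SimulationConfig(
        genome=genome, orfs=orfs, depth_per_gene=depth_per_gene,
        pause_map=pause_map, seed=seed,
    )
    genotype_effects: dict[str, dict[tuple[str, int], float]] = {}
    depth_effects: dict[str, dict[str, float]] = {}
    for genotype, rho in stall_ratio_targets.items():
        e = calibrate_stall_effect(
            config, "psbB", PSBB_STALL_CODON, rho, smooth_codons=smooth_codons
        )
        genotype_effects[genotype] = {("psbB", PSBB_STALL_CODON): e}
        depth_effects[genotype] = {
            "psbB": calibrate_depth_effect(config, "psbB", abundance_ratio_target)
        }
    config.genotype_effects = genotype_effects
    config.genotype_depth_effects = depth_effects
    return config, ("WT",) + tuple(stall_ratio_targets)
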