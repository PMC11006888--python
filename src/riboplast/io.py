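"""Reading and writing the pipeline's external formats.

Formats handled here: FASTA (plastid genome), GFF3 (plastid ORF annotation),
BED6 (one ribosome footprint per record), TSV sample sheet, and the TSV result
tables every stage writes.

All internal coordinates are 0-based, half-open. GFF3 is 1-based inclusive and
is converted at this boundary, in both directions, so the rest of the package
never sees a 1-based number. The plastid genome is treated as linear: an ORF
running past the sequence end (e.g. one wrapping the origin of the circular
molecule) is rejected.

Footprint collections are held as :class:`pandas.DataFrame` objects with the
columns in :data:`FOOTPRINT_COLUMNS`; ``five_prime`` is the genomic coordinate
of the footprint's 5' end (``start`` on the plus strand, ``end - 1`` on the
minus strand), the single position every downstream assignment uses.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AnnotationError, FootprintError, SampleSheetError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (upper case).
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

#: Column order of every footprint DataFrame in the package.
FOOTPRINT_COLUMNS = (
    "seq_id", "start", "end", "strand", "length", "five_prime", "sample_id",
)

#: Default footprint length filter, from the sequenced insert-size range.
DEFAULT_LENGTH_MIN = 20
DEFAULT_LENGTH_MAX = 40


@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    """A single (plastid) genome sequence."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise AnnotationError(f"genome sequence {self.seq_id!r} is empty")
        bad = set(self.sequence.upper()) - IUPAC_NT
        if bad:
            raise AnnotationError(
                f"genome sequence {self.seq_id!r} contains non-IUPAC "
                f"characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """One plastid protein-coding ORF; 0-based half-open genomic interval."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"ORF {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"ORF {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def is_triplet(self) -> bool:
        """True when the ORF length is a whole number of codons.

        Non-triplet ORFs are loaded but flagged; codon-level operations
        (frame QC, profiles, peak calling) refuse them.
        """
        return self.length_nt % 3 == 0

    @property
    def length_codons(self) -> int:
        if not self.is_triplet:
            raise AnnotationError(
                f"ORF {self.gene_id!r} has non-triplet length {self.length_nt}"
            )
        return self.length_nt // 3

    @property
    def five_prime_start(self) -> int:
        """Genomic coordinate of the first nt of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    def relative_position(self, genomic_pos) -> "int | np.ndarray":
        """ORF-relative coordinate (0 = first nt of start codon, 5'->3')."""
        if self.strand == "+":
            return genomic_pos - self.start
        return (self.end - 1) - genomic_pos


@dataclasses.dataclass(frozen=True)
class Footprint:
    """One ribosome-protected fragment as a genomic interval.

    Collections are held as DataFrames (:data:`FOOTPRINT_COLUMNS`); this
    record type is the single-row view of the same fields.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FootprintError(
                f"footprint has start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FootprintError(f"invalid strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic 5' end: ``start`` on '+', ``end - 1`` on '-'."""
        return self.start if self.strand == "+" else self.end - 1


def footprints_from_records(records: Iterable[Footprint]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return empty_footprints()
    return footprint_frame(
        [r.seq_id for r in records],
        [r.start for r in records],
        [r.end for r in records],
        [r.strand for r in records],
        [r.sample_id for r in records],
    )


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a single-sequence genome FASTA."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise AnnotationError(f"{fasta_path}: no FASTA records found")
    if len(records) > 1:
        raise AnnotationError(
            f"{fasta_path}: expected a single plastid genome sequence, "
            f"found {len(records)} records"
        )
    rec = records[0]
    return GenomeSequence(seq_id=rec.id, sequence=str(rec.seq).upper())


def write_genome(genome: GenomeSequence, fasta_path: str | Path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


_GFF_ID_RE = re.compile(r"([^=;\s]+)\s*=\s*([^;]+)")


def _parse_gff_attributes(field: str) -> dict[str, str]:
    return {m.group(1): m.group(2).strip() for m in _GFF_ID_RE.finditer(field)}


def load_annotation(
    gff_path: str | Path,
    genome_path: str | Path | None = None,
    *,
    feature_types: Sequence[str] = ("CDS",),
    id_attributes: Sequence[str] = ("ID", "gene_id", "Name", "Parent"),
) -> tuple[list[OrfRecord], GenomeSequence | None]:
    """Load plastid ORFs from GFF3 (plus, optionally, the genome FASTA).

    GFF3 coordinates (1-based inclusive) are converted to the package's
    0-based half-open convention here. Features are selected by type
    (default ``CDS``) and identified by the first attribute key present
    among *id_attributes*.

    Returns ORFs sorted by genomic start. Each gene must be a single CDS
    interval (plastid ORFs with introns must be supplied pre-spliced);
    a duplicated gene id is rejected for that reason.
    """
    genome = load_genome(genome_path) if genome_path is not None else None
    orfs: list[OrfRecord] = []
    seen: set[str] = set()
    wanted = set(feature_types)
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated GFF3 "
                    f"columns, got {len(fields)}"
                )
            seq_id, _source, ftype, start1, end1, _score, strand, _frame, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: non-integer coordinates "
                    f"{start1!r}/{end1!r}"
                ) from None
            attr_map = _parse_gff_attributes(attrs)
            gene_id = next(
                (attr_map[k] for k in id_attributes if k in attr_map), None
            )
            if gene_id is None:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: feature has none of the ID "
                    f"attributes {tuple(id_attributes)}"
                )
            if gene_id in seen:
                raise AnnotationError(
                    f"{gff_path}:{lineno}: duplicate gene id {gene_id!r} "
                    "(multi-interval/spliced ORFs are not supported; supply "
                    "one pre-spliced CDS interval per gene)"
                )
            seen.add(gene_id)
            if genome is not None:
                if seq_id != genome.seq_id:
                    raise AnnotationError(
                        f"{gff_path}:{lineno}: seq_id {seq_id!r} does not match "
                        f"genome {genome.seq_id!r}"
                    )
                if end1i > genome.length:
                    raise AnnotationError(
                        f"{gff_path}:{lineno}: ORF {gene_id!r} extends past the "
                        f"end of the (linear) genome ({end1i} > {genome.length}); "
                        "origin-wrapping ORFs are not supported"
                    )
            # GFF3 1-based inclusive -> 0-based half-open
            orf = OrfRecord(
                gene_id=gene_id, seq_id=seq_id, start=start1i - 1, end=end1i,
                strand=strand,
            )
            if not orf.is_triplet:
                logger.warning(
                    "ORF %s has non-triplet length %d nt; codon-level "
                    "operations will refuse it", gene_id, orf.length_nt,
                )
            orfs.append(orf)
    orfs.sort(key=lambda o: (o.start, o.gene_id))
    return orfs, genome


def write_annotation(
    orfs: Iterable[OrfRecord], gff_path: str | Path, *, source: str = "riboplast"
) -> None:
    """Write ORFs as GFF3 (converting back to 1-based inclusive)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                "\t".join(
                    (
                        orf.seq_id, source, "CDS",
                        str(orf.start + 1), str(orf.end), ".",
                        orf.strand, "0", f"ID={orf.gene_id}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Footprints (BED6)
# ---------------------------------------------------------------------------

def empty_footprints() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "length": pd.Series(dtype=np.int64),
            "five_prime": pd.Series(dtype=np.int64),
            "sample_id": pd.Series(dtype=object),
        }
    )


def footprint_frame(
    seq_id, start, end, strand, sample_id
) -> pd.DataFrame:
    """Assemble a footprint DataFrame from parallel arrays, deriving
    ``length`` and the strand-aware ``five_prime`` coordinate."""
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    strand = np.asarray(strand, dtype=object)
    df = pd.DataFrame(
        {
            "seq_id": np.broadcast_to(np.asarray(seq_id, dtype=object), start.shape).copy(),
            "start": start,
            "end": end,
            "strand": strand,
            "length": end - start,
            "five_prime": np.where(strand == "+", start, end - 1),
            "sample_id": np.broadcast_to(np.asarray(sample_id, dtype=object), start.shape).copy(),
        }
    )
    return df


def load_footprints(
    bed_path: str | Path,
    sample_id: str,
    length_min: int = DEFAULT_LENGTH_MIN,
    length_max: int = DEFAULT_LENGTH_MAX,
) -> tuple[pd.DataFrame, int]:
    """Load one sample's footprints from BED6, applying the length filter.

    Returns ``(footprints, n_length_filtered)``; records whose length falls
    outside ``[length_min, length_max]`` are dropped and counted, and the
    count is logged (it also reaches the QC output via the caller).
    """
    if not (1 <= length_min <= length_max):
        raise FootprintError(
            f"invalid length filter [{length_min}, {length_max}]"
        )
    seq_ids: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FootprintError(
                    f"{bed_path}:{lineno}: BED6 requires 6 columns "
                    f"(strand in column 6), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FootprintError(
                    f"{bed_path}:{lineno}: non-integer coordinates"
                ) from None
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FootprintError(
                    f"{bed_path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            if start >= end:
                raise FootprintError(
                    f"{bed_path}:{lineno}: start {start} >= end {end}"
                )
            seq_ids.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    if not starts:
        logger.warning("%s: no footprint records", bed_path)
        return empty_footprints(), 0
    df = footprint_frame(seq_ids, starts, ends, strands, sample_id)
    keep = (df["length"] >= length_min) & (df["length"] <= length_max)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d footprints outside length filter [%d, %d]",
            bed_path, n_dropped, len(df), length_min, length_max,
        )
    return df.loc[keep].reset_index(drop=True), n_dropped


def write_footprints_bed(footprints: pd.DataFrame, bed_path: str | Path) -> None:
    """Write footprints as BED6 (name = sample_id, score = 0)."""
    with open(bed_path, "w") as fh:
        for row in footprints.itertuples(index=False):
            fh.write(
                f"{row.seq_id}\t{row.start}\t{row.end}\t{row.sample_id}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "replicate", "path")


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load the sample sheet TSV: sample_id, genotype, replicate, path."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(
            f"{path}: sample sheet is missing columns {missing}; header must "
            f"contain {SAMPLE_SHEET_COLUMNS}"
        )
    df = df[list(SAMPLE_SHEET_COLUMNS)].copy()
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError:
        raise SampleSheetError(f"{path}: replicate column must be integer") from None
    if (df["replicate"] < 1).any():
        raise SampleSheetError(f"{path}: replicate indices must be >= 1")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SampleSheetError(f"{path}: duplicate sample_id {dup!r}")
    pairs = df[["genotype", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise SampleSheetError(
            f"{path}: (genotype, replicate) pairs must be unique"
        )
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(SAMPLE_SHEET_COLUMNS))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a result TSV with '#'-prefixed metadata lines before the header.

    Metadata never includes timestamps, so identical runs produce
    byte-identical files.
    """
    with open(path, "w") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
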