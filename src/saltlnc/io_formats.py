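"""Readers/writers for the external formats the pipeline touches.

Coordinate convention
---------------------
Internally every interval is 0-based half-open ``[start, end)``.  GFF3/GTF
use 1-based closed coordinates and are converted exactly once, at the I/O
boundary (:func:`gff_to_internal` / :func:`internal_to_gff`).  BED shares the
internal convention, so BED export is a straight copy of internal
coordinates.

Transcript models carry two attributes that standard GTF does not define --
assembler read ``coverage`` and ``samples_detected`` (the number of samples
the transcript was assembled in) -- so they travel in a TSV sidecar keyed by
transcript id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-")
DEFAULT_CATEGORY_KEY = "mapman_bin"
UNASSIGNED_CATEGORY = "unassigned"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed GFF/GTF interval to 0-based half-open."""
    if start < 1 or end < start:
        raise FormatError(f"invalid GFF interval {start}..{end}")
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to 1-based closed."""
    if start < 0 or end <= start:
        raise FormatError(f"invalid internal interval [{start}, {end})")
    return start + 1, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """An annotated protein-coding gene (span-level; internal coordinates)."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    functional_category: str = UNASSIGNED_CATEGORY

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.id}: invalid span [{self.start}, {self.end})")

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Chromosome table plus one span-level record per gene."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise FormatError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if g.chrom in lengths and g.end > lengths[g.chrom]:
                raise FormatError(
                    f"gene {g.id} extends past end of {g.chrom} "
                    f"({g.end} > {lengths[g.chrom]})"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {name: [] for name, _ in self.chromosomes}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass
class TranscriptModel:
    """An assembled transcript: exon structure, spliced sequence, support.

    ``exons`` are internal-coordinate, sorted, non-overlapping intervals;
    ``sequence`` is the spliced sense-strand sequence, 5'->3'.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str
    coverage: float
    samples_detected: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"transcript {self.id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise FormatError(f"transcript {self.id}: invalid exon [{s}, {e})")
            if s < prev_end:
                raise FormatError(f"transcript {self.id}: exons overlap or are unsorted")
            prev_end = e
        if self.coverage < 0:
            raise FormatError(f"transcript {self.id}: negative coverage")
        if self.samples_detected < 0:
            raise FormatError(f"transcript {self.id}: negative samples_detected")
        if len(self.sequence) != self.spliced_length:
            raise FormatError(
                f"transcript {self.id}: sequence length {len(self.sequence)} "
                f"!= summed exon length {self.spliced_length}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def _validate_gff_lines(path: str | Path) -> None:
    """Pre-validate column structure so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end < start ({end} < {start})")


def _read_sequence_regions(path: str | Path) -> dict[str, int]:
    regions: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    regions[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return regions


def read_annotation(
    path: str | Path,
    category_key: str = DEFAULT_CATEGORY_KEY,
) -> GenomeAnnotation:
    """Read a GFF3 or GTF annotation into span-level gene records.

    GFF3 ``gene`` features are used directly.  For GTF (no explicit gene
    features) the gene span is the union of its transcripts, introns
    included, as inferred by gffutils.  The functional category is taken
    from the attribute ``category_key`` (default ``mapman_bin``), falling
    back to ``unassigned``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gff_lines(path)
    if path.stat().st_size == 0 or not any(
        not l.startswith("#") and l.strip() for l in open(path)
    ):
        return GenomeAnnotation(chromosomes=[], genes=[])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )

    genes: list[GeneRecord] = []
    max_end: dict[str, int] = {}
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        start, end = gff_to_internal(f.start, f.end)
        category = UNASSIGNED_CATEGORY
        if category_key in f.attributes:
            category = f.attributes[category_key][0]
        else:
            # GTF-inferred genes carry no attributes; look at their children.
            for child in db.children(f):
                if category_key in child.attributes:
                    category = child.attributes[category_key][0]
                    break
        genes.append(
            GeneRecord(
                id=f.id, chrom=f.seqid, strand=f.strand,
                start=start, end=end, functional_category=category,
            )
        )
        max_end[f.seqid] = max(max_end.get(f.seqid, 0), end)

    lengths = _read_sequence_regions(path)
    for chrom, end in max_end.items():
        lengths.setdefault(chrom, end)
    chromosomes = sorted(lengths.items())
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_annotation(
    annotation: GenomeAnnotation,
    path: str | Path,
    category_key: str = DEFAULT_CATEGORY_KEY,
) -> None:
    """Write gene records as GFF3 with sequence-region pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            start, end = internal_to_gff(g.start, g.end)
            attrs = f"ID={g.id};{category_key}={g.functional_category}"
            fh.write(
                f"{g.chrom}\tsaltlnc\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# transcripts: GTF + FASTA + sidecar TSV
# ---------------------------------------------------------------------------

SIDECAR_COLUMNS = ("transcript_id", "coverage", "samples_detected")


def read_sidecar(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sidecar missing columns {sorted(missing)}")
    return df.set_index("transcript_id")


def read_transcripts(
    gtf_path: str | Path,
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> list[TranscriptModel]:
    """Assemble transcript models from a GTF, a spliced FASTA and a sidecar.

    Every transcript id in the GTF must appear in both the FASTA and the
    sidecar; the spliced sequence length must equal the summed exon length.
    """
    _validate_gff_lines(gtf_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(gtf_path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sidecar = read_sidecar(sidecar_path)

    exons_by_tid: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        exons_by_tid.setdefault(tid, []).append(gff_to_internal(f.start, f.end))
        meta[tid] = (f.seqid, f.strand)

    missing_fa = sorted(set(exons_by_tid) - set(seqs))
    missing_sc = sorted(set(exons_by_tid) - set(sidecar.index))
    if missing_fa or missing_sc:
        raise FormatError(
            f"transcript ids missing from FASTA: {missing_fa}; "
            f"missing from sidecar: {missing_sc}"
        )

    models = []
    for tid in exons_by_tid:
        chrom, strand = meta[tid]
        row = sidecar.loc[tid]
        models.append(
            TranscriptModel(
                id=tid, chrom=chrom, strand=strand,
                exons=sorted(exons_by_tid[tid]),
                sequence=seqs[tid],
                coverage=float(row["coverage"]),
                samples_detected=int(row["samples_detected"]),
            )
        )
    models.sort(key=lambda t: t.id)
    return models


def write_transcripts(
    transcripts: Sequence[TranscriptModel],
    gtf_path: str | Path,
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    with open(gtf_path, "w") as fh:
        for t in transcripts:
            g1, g2 = internal_to_gff(t.start, t.end)
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            fh.write(f"{t.chrom}\tsaltlnc\ttranscript\t{g1}\t{g2}\t.\t{t.strand}\t.\t{attrs}\n")
            for s, e in t.exons:
                e1, e2 = internal_to_gff(s, e)
                fh.write(f"{t.chrom}\tsaltlnc\texon\t{e1}\t{e2}\t.\t{t.strand}\t.\t{attrs}\n")
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.id for t in transcripts],
            "coverage": [t.coverage for t in transcripts],
            "samples_detected": [t.samples_detected for t in transcripts],
        }
    ).to_csv(sidecar_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6 / SIF / counts
# ---------------------------------------------------------------------------

def write_bed(features: Iterable, path: str | Path) -> None:
    """Write BED6 lines (0-based half-open, strand in column 6).

    Accepts anything with chrom/start/end/id/strand attributes
    (TranscriptModel, GeneRecord, LncRNA).
    """
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def write_network(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (source, relation, target) triples as SIF rows."""
    with open(path, "w") as fh:
        for source, relation, target in edges:
            fh.write(f"{source}\t{relation}\t{target}\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples count matrix (TSV, header row of sample ids).

    Counts must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise FormatError(f"{path}: non-numeric count entries")
    if (numeric < 0).any().any():
        raise FormatError(f"{path}: negative counts")
    if not (numeric == numeric.round()).all().all():
        raise FormatError(f"{path}: non-integer counts")
    return numeric.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
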