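"""Basic filtering cascade reducing assembled transcripts to lncRNA candidates.

A transcript survives iff it was assembled in at least ``min_samples``
samples, does not overlap any annotated gene on the same strand, is at least
``min_len`` nt long, has assembler read coverage of at least ``min_cov``,
and its longest open reading frame is at most ``max_orf`` nt.  Thresholds
are chosen so the boundary values themselves survive (discard is strict:
length < 200, coverage < 3, ORF > 300).

ORF convention: ATG-to-stop on the spliced sense strand only (the library
is strand-specific), across all three frames; length counts nucleotides
including the stop codon; an ATG with no in-frame stop before the sequence
end is not an ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from saltlnc.io_formats import GenomeAnnotation, TranscriptModel

# canonical cascade order, also the reporting order of failed filters
FILTER_ORDER = ("recurrence", "same_strand_overlap", "length", "coverage", "orf_length")

_STOPS = ("TAA", "TAG", "TGA")
_VALID = set("ACGTN")


@dataclass(frozen=True)
class OrfCall:
    """Longest sense-strand ORF of a spliced transcript sequence."""

    start: int = 0
    end: int = 0
    length: int = 0
    frame: int = 0
    found: bool = False


@dataclass
class FilterDecision:
    transcript_id: str
    retained: bool
    failed_filters: list[str]
    orf: OrfCall


def find_longest_orf(sequence: str) -> OrfCall:
    """Longest ATG->stop ORF over the three sense frames.

    Ties are broken by the smallest start offset.  Length is in nucleotides
    and includes the stop codon.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")

    n = len(seq)
    best = OrfCall()
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                length = pos + 3 - start
                if length > best.length or (length == best.length and start < best.start):
                    best = OrfCall(start=start, end=pos + 3, length=length,
                                   frame=frame, found=True)
                start = None
    return best


def _gene_trees(annotation: GenomeAnnotation) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation.genes:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g.id)
    return trees


def overlaps_same_strand(
    transcript: TranscriptModel,
    annotation: GenomeAnnotation,
    _trees: dict[tuple[str, str], IntervalTree] | None = None,
) -> bool:
    """True iff the transcript span intersects >= 1 bp of a same-strand gene span."""
    known = {name for name, _ in annotation.chromosomes}
    if known and transcript.chrom not in known:
        raise ValueError(f"transcript {transcript.id}: unknown chromosome {transcript.chrom}")
    trees = _trees if _trees is not None else _gene_trees(annotation)
    tree = trees.get((transcript.chrom, transcript.strand))
    if tree is None:
        return False
    return bool(tree.overlap(transcript.start, transcript.end))


def apply_basic_filters(
    transcripts: list[TranscriptModel],
    annotation: GenomeAnnotation,
    min_len: int = 200,
    min_cov: float = 3,
    max_orf: int = 300,
    min_samples: int = 2,
) -> list[FilterDecision]:
    """Run the five-step cascade and report every violated filter per transcript."""
    if min(min_len, min_cov, max_orf, min_samples) <= 0:
        raise ValueError("filter thresholds must be positive")
    ids = [t.id for t in transcripts]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dupes}")

    trees = _gene_trees(annotation)
    decisions = []
    for t in transcripts:
        orf = find_longest_orf(t.sequence)
        failed = []
        if t.samples_detected < min_samples:
            failed.append("recurrence")
        if overlaps_same_strand(t, annotation, _trees=trees):
            failed.append("same_strand_overlap")
        if t.spliced_length < min_len:
            failed.append("length")
        if t.coverage < min_cov:
            failed.append("coverage")
        if orf.length > max_orf:
            failed.append("orf_length")
        decisions.append(
            FilterDecision(
                transcript_id=t.id,
                retained=not failed,
                failed_filters=failed,
                orf=orf,
            )
        )
    return decisions


def retained_ids(decisions: list[FilterDecision]) -> list[str]:
    return [d.transcript_id for d in decisions if d.retained]
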