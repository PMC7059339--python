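"""Positional classification of surviving lncRNAs and cohort summaries.

An lncRNA overlapping (>= 1 bp, gene-span level) a protein-coding gene on
the opposite strand is antisense; one overlapping no gene on either strand
is intergenic.  Same-strand overlappers cannot occur here: the basic
filter cascade removed them, and finding one is an upstream contract
violation.  When several opposite-strand genes overlap, the gene with the
largest overlap is recorded (ties break to the lexicographically smaller
gene id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from saltlnc.io_formats import GenomeAnnotation, TranscriptModel

CLASSES = ("antisense", "intergenic")


@dataclass
class LncRNA:
    """A classified lncRNA (span-level positional class)."""

    transcript: TranscriptModel
    lncrna_class: str
    overlapped_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.lncrna_class not in CLASSES:
            raise ValueError(f"unknown class {self.lncrna_class!r}")
        if (self.lncrna_class == "antisense") != (self.overlapped_gene_id is not None):
            raise ValueError("antisense <=> overlapped_gene_id set")

    # convenience passthroughs for BED export
    @property
    def id(self) -> str:
        return self.transcript.id

    @property
    def chrom(self) -> str:
        return self.transcript.chrom

    @property
    def strand(self) -> str:
        return self.transcript.strand

    @property
    def start(self) -> int:
        return self.transcript.start

    @property
    def end(self) -> int:
        return self.transcript.end


def classify(
    candidates: list[TranscriptModel],
    annotation: GenomeAnnotation,
) -> list[LncRNA]:
    """Assign exactly one positional class to every candidate."""
    trees: dict[str, IntervalTree] = {}
    genes = {g.id: g for g in annotation.genes}
    for g in annotation.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, (g.strand, g.id))

    out = []
    for t in candidates:
        tree = trees.get(t.chrom)
        hits = tree.overlap(t.start, t.end) if tree is not None else set()
        same = [iv for iv in hits if iv.data[0] == t.strand]
        if same:
            raise ValueError(
                f"candidate {t.id} overlaps gene {same[0].data[1]} on the same "
                "strand; the basic filter cascade should have removed it"
            )
        opposite = [iv.data[1] for iv in hits]
        if opposite:
            def overlap_bp(gene_id: str) -> int:
                g = genes[gene_id]
                return min(t.end, g.end) - max(t.start, g.start)

            best = sorted(opposite, key=lambda gid: (-overlap_bp(gid), gid))[0]
            out.append(LncRNA(t, "antisense", best))
        else:
            out.append(LncRNA(t, "intergenic"))
    return out


def summarize_features(
    lncrnas: list[LncRNA],
    fpkm: pd.DataFrame,
    length_bin_width: int = 200,
    fpkm_threshold: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Per-class cohort summaries: chromosome proportions, exon-count and
    length histograms, median length, per-sample expressed fraction.

    Length bins are ``length_bin_width``-nt wide starting at 201 nt (the
    lncRNA length floor); the first bin also absorbs anything shorter.
    Returns a dict of tidy frames; empty cohorts give empty frames.
    """
    missing = [l.id for l in lncrnas if l.id not in fpkm.index]
    if missing:
        raise KeyError(f"lncRNA ids missing from FPKM matrix: {missing}")

    rows = [
        {
            "id": l.id,
            "class": l.lncrna_class,
            "chrom": l.chrom,
            "n_exons": len(l.transcript.exons),
            "length": l.transcript.spliced_length,
        }
        for l in lncrnas
    ]
    if not rows:
        empty = pd.DataFrame()
        return {k: empty for k in
                ("chromosome", "exons", "length", "median_length", "expressed")}
    df = pd.DataFrame(rows)

    chrom = pd.crosstab(df["class"], df["chrom"], normalize="index")
    exons = pd.crosstab(df["class"], df["n_exons"], normalize="index")

    max_len = int(df["length"].max())
    edges = [0] + list(range(200, max_len + length_bin_width, length_bin_width))
    labels = [f"<={edges[i + 1]}" for i in range(len(edges) - 1)]
    df["length_bin"] = pd.cut(df["length"], bins=edges, labels=labels)
    length = (
        df.groupby("class")["length_bin"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    median_length = df.groupby("class")["length"].median().to_frame("median_length")

    expressed = {}
    for cls, sub in df.groupby("class"):
        vals = fpkm.loc[sub["id"]]
        expressed[cls] = (vals > fpkm_threshold).mean(axis=0)
    expressed = pd.DataFrame(expressed).T

    return {
        "chromosome": chrom,
        "exons": exons,
        "length": length,
        "median_length": median_length,
        "expressed": expressed,
    }
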