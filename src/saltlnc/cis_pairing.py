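"""Cis-regulation candidates: DE genes near DE lncRNAs, scored by correlation.

A gene is a cis candidate of an lncRNA if its span lies within 10 kb on
the lncRNA's 5' (upstream) side or within 100 kb on its 3' (downstream)
side.  Sides follow the lncRNA's strand: for a minus-strand lncRNA the
genomic left is downstream.  Distance is the gap between the nearest span
boundaries (number of bases strictly between the spans, 0 when the spans
touch); overlapping spans get distance 0 and side "downstream".  Window
boundaries are inclusive.  A candidate passes when the Pearson
correlation of the two 12-sample FPKM vectors satisfies |r| >= r_min
(default 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from saltlnc.io_formats import GeneRecord, GenomeAnnotation
from saltlnc.lncrna_classify import LncRNA

DEFAULT_WINDOW_UP = 10_000
DEFAULT_WINDOW_DOWN = 100_000


@dataclass
class CisPair:
    lncrna_id: str
    gene_id: str
    side: str            # upstream | downstream, relative to the lncRNA
    distance: int        # bp between nearest boundaries, >= 0
    r: float = np.nan
    passes: bool = False


def pair_geometry(
    lnc_start: int, lnc_end: int, lnc_strand: str, gene_start: int, gene_end: int
) -> tuple[str, int]:
    """(side, distance) of a gene span relative to an lncRNA span."""
    if gene_start < lnc_end and gene_end > lnc_start:  # overlap
        return "downstream", 0
    if gene_start >= lnc_end:  # gene to the genomic right
        gap = gene_start - lnc_end
        side = "downstream" if lnc_strand == "+" else "upstream"
    else:
        gap = lnc_start - gene_end
        side = "upstream" if lnc_strand == "+" else "downstream"
    return side, gap


def find_cis_candidates(
    lncrnas: list[LncRNA],
    genes: list[GeneRecord] | GenomeAnnotation,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> list[CisPair]:
    """All (lncRNA, gene) pairs whose geometry falls inside the windows.

    Callers pass the DE subsets; the scan itself is agnostic to DE status.
    """
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs = []
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chrom, []):
            side, distance = pair_geometry(
                lnc.start, lnc.end, lnc.strand, g.start, g.end
            )
            window = window_up if side == "upstream" else window_down
            if distance <= window:
                pairs.append(
                    CisPair(lncrna_id=lnc.id, gene_id=g.id, side=side, distance=distance)
                )
    pairs.sort(key=lambda p: (p.lncrna_id, p.distance, p.gene_id))
    return pairs


def score_cis_pairs(
    candidates: list[CisPair],
    fpkm: pd.DataFrame,
    gene_to_feature: dict[str, str] | None = None,
    r_min: float = 0.8,
) -> list[CisPair]:
    """Attach the expression correlation and the pass flag to each candidate.

    ``gene_to_feature`` maps gene ids to FPKM row ids when transcripts are
    quantified rather than genes.  A constant expression vector leaves r
    undefined: the pair cannot pass and a warning is emitted.
    """
    scored = []
    for pair in candidates:
        gene_key = (gene_to_feature or {}).get(pair.gene_id, pair.gene_id)
        for key in (pair.lncrna_id, gene_key):
            if key not in fpkm.index:
                raise KeyError(f"feature {key} missing from the FPKM matrix")
        x = fpkm.loc[pair.lncrna_id].to_numpy(dtype=float)
        y = fpkm.loc[gene_key].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(
                f"constant expression vector in pair ({pair.lncrna_id}, {pair.gene_id}); "
                "correlation undefined",
                UserWarning,
            )
            scored.append(
                CisPair(pair.lncrna_id, pair.gene_id, pair.side, pair.distance,
                        r=np.nan, passes=False)
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        scored.append(
            CisPair(pair.lncrna_id, pair.gene_id, pair.side, pair.distance,
                    r=r, passes=abs(r) >= r_min)
        )
    return scored


def to_table(pairs: list[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "side": [p.side for p in pairs],
            "distance": [p.distance for p in pairs],
            "r": [p.r for p in pairs],
            "passes": [p.passes for p in pairs],
        }
    )
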