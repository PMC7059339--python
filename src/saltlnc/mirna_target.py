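"""miRNA target prediction by ungapped complementarity scanning.

The mature miRNA is aligned antiparallel to every window of the target:
miRNA position k pairs with window position L-1-k.  A:U and G:C pairs are
Watson-Crick matches, G:U in either orientation is a wobble, anything
else is a mismatch.  A window is an accepted target site when it has at
most 2 mismatches (the "< 3 mismatches" rule) and at most ``max_wobble``
G:U pairs (default 4; wobbles are tolerated but a cap avoids degenerate
GU-rich hits).  T and U are interchangeable throughout.

Downstream utilities collapse miRNAs into families (miR156a-5p ->
miR156), tabulate targeting-degree histograms, and export the
lncRNA-miRNA-mRNA network.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import networkx as nx

_CANON = str.maketrans("acgtuU", "ACGTTT")
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

_FAMILY_RE = re.compile(r"^([A-Za-z-]*?[mM][iI][rR][a-zA-Z]*\d+)")


@dataclass(frozen=True)
class MirnaTargetHit:
    mirna_id: str
    mirna_family: str
    target_id: str
    target_kind: str      # lncRNA | mRNA
    offset: int           # 0-based on the target, 5'->3'
    n_mismatch: int
    n_wobble: int
    accepted: bool


def canonicalize(seq: str) -> str:
    return seq.translate(_CANON).upper()


def pair_positions(mirna_seq: str, target_window: str) -> tuple[int, int]:
    """(n_mismatch, n_wobble) of an antiparallel miRNA/window alignment.

    Both sequences are given 5'->3'; position k of the miRNA pairs with
    position L-1-k of the window.
    """
    m = canonicalize(mirna_seq)
    w = canonicalize(target_window)
    if len(m) != len(w):
        raise ValueError(f"length mismatch: miRNA {len(m)} vs window {len(w)}")
    L = len(m)
    n_mismatch = n_wobble = 0
    for k in range(L):
        pair = (m[k], w[L - 1 - k])
        if pair in _WC:
            continue
        if pair in _WOBBLE:
            n_wobble += 1
        else:
            n_mismatch += 1
    return n_mismatch, n_wobble


def mirna_family(mirna_id: str) -> str:
    """Family = identifier prefix through the number (miR156a-5p -> miR156)."""
    match = _FAMILY_RE.match(mirna_id)
    return match.group(1) if match else mirna_id


def scan_target(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    target_kind: str = "lncRNA",
    max_mismatch: int = 2,
    max_wobble: int = 4,
) -> list[MirnaTargetHit]:
    """Evaluate every offset of the target; report sites within the mismatch
    budget, flagging those within the wobble cap as accepted.

    Overlapping sites are all reported; hits sort by (mismatches, wobbles,
    offset).  A target shorter than the miRNA yields no hits.
    """
    m = canonicalize(mirna_seq)
    t = canonicalize(target_seq)
    L = len(m)
    family = mirna_family(mirna_id)
    hits = []
    for offset in range(0, len(t) - L + 1):
        n_mismatch, n_wobble = pair_positions(m, t[offset : offset + L])
        if n_mismatch <= max_mismatch:
            hits.append(
                MirnaTargetHit(
                    mirna_id=mirna_id, mirna_family=family,
                    target_id=target_id, target_kind=target_kind,
                    offset=offset, n_mismatch=n_mismatch, n_wobble=n_wobble,
                    accepted=n_wobble <= max_wobble,
                )
            )
    hits.sort(key=lambda h: (h.n_mismatch, h.n_wobble, h.offset))
    return hits


def scan_all(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str = "lncRNA",
    max_mismatch: int = 2,
    max_wobble: int = 4,
) -> list[MirnaTargetHit]:
    hits = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            hits.extend(
                scan_target(mid, mseq, tid, tseq, target_kind, max_mismatch, max_wobble)
            )
    return hits


def degree_tables(hits: list[MirnaTargetHit]) -> dict[str, dict[int, int]]:
    """Histograms over accepted hits: targets per miRNA, miRNAs per target,
    and families per target (duplicate sites on one pair count once)."""
    accepted = [h for h in hits if h.accepted]
    pairs = {(h.mirna_id, h.target_id) for h in accepted}
    fam_pairs = {(h.mirna_family, h.target_id) for h in accepted}
    targets_per_mirna = Counter(m for m, _ in pairs)
    mirnas_per_target = Counter(t for _, t in pairs)
    families_per_target = Counter(t for _, t in fam_pairs)
    return {
        "targets_per_mirna": dict(Counter(targets_per_mirna.values())),
        "mirnas_per_target": dict(Counter(mirnas_per_target.values())),
        "families_per_target": dict(Counter(families_per_target.values())),
    }


def build_network(
    lncrna_hits: list[MirnaTargetHit],
    mrna_hits: list[MirnaTargetHit] | None = None,
) -> nx.DiGraph:
    """Directed miRNA -> target network over accepted hits; no duplicate
    edges; node attribute ``kind`` in {miRNA, lncRNA, mRNA}, ``degree``
    attached after construction."""
    net = nx.DiGraph()
    for hit in [*lncrna_hits, *(mrna_hits or [])]:
        if not hit.accepted:
            continue
        net.add_node(hit.mirna_id, kind="miRNA")
        net.add_node(hit.target_id, kind=hit.target_kind)
        net.add_edge(hit.mirna_id, hit.target_id, relation="targets")
    for node in net.nodes:
        net.nodes[node]["degree"] = net.degree(node)
    return net


def network_edges(net: nx.DiGraph) -> list[tuple[str, str, str]]:
    """Deterministically ordered (source, relation, target) triples for SIF."""
    return sorted(
        (u, d.get("relation", "targets"), v) for u, v, d in net.edges(data=True)
    )
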