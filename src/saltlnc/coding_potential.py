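"""Coding-potential scoring for lncRNA candidate filtering.

Three scorers are combined by a conservative consensus: a transcript must
look noncoding to all of them to survive.

* Fickett TESTCODE statistic: weighted sum of eight looked-up
  probabilities (four base-position asymmetries, four base contents),
  lookup tables embedded as constants from Fickett, Nucleic Acids Res.
  10:5303 (1982).
* In-frame hexamer usage bias: mean log-ratio of coding vs noncoding
  hexamer frequencies over the longest ORF, stepping by codons.
* A logistic combiner over (ORF length, ORF coverage, Fickett, hexamer),
  fit by iteratively reweighted least squares on labelled training
  sequences.

A fourth, orthogonal step removes transcripts with known protein-domain
hits supplied as a precomputed table (domain search itself happens
outside this package).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from saltlnc.lncrna_filter import OrfCall, find_longest_orf

# --- Fickett (1982) TESTCODE lookup tables ---------------------------------
# rows: intervals of the parameter value; first interval whose lower bound
# the value reaches wins.
_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

_HEXAMER_K = 6
_N_HEXAMERS = 4 ** _HEXAMER_K
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _lookup(value: float, para: tuple, probs: tuple) -> float:
    for idx, bound in enumerate(para):
        if value >= bound:
            return probs[idx]
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """TESTCODE statistic of a nucleotide sequence (case-insensitive).

    Position parameter of base B: max over the three codon positions of
    B's count, divided by (min + 1).  Content parameter: B's fraction of
    the sequence.  Both are mapped to probabilities through the published
    interval tables and summed with the published weights.  Values above
    ~0.95 indicate protein-coding character.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    total = sum(seq.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    score = 0.0
    for base in "ACGT":
        phased = [seq[i::3].count(base) for i in range(3)]
        position = max(phased) / (min(phased) + 1.0)
        content = seq.count(base) / total
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# hexamer model
# ---------------------------------------------------------------------------

def _hexamer_index(hexamer: str) -> int | None:
    idx = 0
    for ch in hexamer:
        b = _BASE_INDEX.get(ch)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def _count_hexamers(sequences, step: int) -> np.ndarray:
    counts = np.zeros(_N_HEXAMERS)
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        for pos in range(0, len(seq) - _HEXAMER_K + 1, step):
            idx = _hexamer_index(seq[pos : pos + _HEXAMER_K])
            if idx is not None:
                counts[idx] += 1
    return counts


@dataclass
class HexamerModel:
    """In-frame hexamer frequency tables for coding and noncoding sequences."""

    f_coding: np.ndarray
    f_noncoding: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name, table in (("coding", self.f_coding), ("noncoding", self.f_noncoding)):
            if abs(table.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} hexamer table does not sum to 1")
            if np.any(table <= 0):
                raise ValueError(f"{name} hexamer table has non-positive entries")

    def swapped(self) -> "HexamerModel":
        return HexamerModel(self.f_noncoding.copy(), self.f_coding.copy(), self.pseudocount)


def train_hexamer_model(coding_seqs, noncoding_seqs, pseudocount: float = 1.0) -> HexamerModel:
    """Count in-frame hexamers (codon steps) in coding sequences and sliding
    hexamers in noncoding ones; normalize with a pseudocount."""
    tables = []
    for seqs, step in ((coding_seqs, 3), (noncoding_seqs, 1)):
        counts = _count_hexamers(seqs, step) + pseudocount
        tables.append(counts / counts.sum())
    return HexamerModel(tables[0], tables[1], pseudocount)


def hexamer_bias(orf_sequence: str, model: HexamerModel | None) -> float:
    """Mean per-hexamer log(f_coding / f_noncoding) over in-frame hexamers.

    Hexamers step by 3 nt (codon frame).  Sequences shorter than 6 nt
    return 0 by convention.
    """
    if model is None:
        raise ValueError("hexamer model is untrained")
    seq = orf_sequence.upper().replace("U", "T")
    if len(seq) < _HEXAMER_K:
        return 0.0
    log_ratio = np.log(model.f_coding / model.f_noncoding)
    values = [
        log_ratio[idx]
        for pos in range(0, len(seq) - _HEXAMER_K + 1, 3)
        if (idx := _hexamer_index(seq[pos : pos + _HEXAMER_K])) is not None
    ]
    if not values:
        return 0.0
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# logistic combiner (IRLS)
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer")


@dataclass
class CombinerWeights:
    """Standardization constants plus logistic coefficients (intercept first)."""

    coef: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    converged: bool = True


def train_combiner(
    features: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> CombinerWeights:
    """Fit a logistic model by IRLS on standardized features.

    Converges when the largest coefficient update falls below ``tol``.  A
    tiny ridge keeps the Newton step defined on separable data (where the
    MLE diverges; predictions still saturate correctly).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are misaligned")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if min((y == c).sum() for c in classes) < 10:
        raise ValueError("need at least 10 examples per class")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = np.column_stack([np.ones(len(X)), (X - means) / sds])

    w = np.zeros(Z.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = Z @ w
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        W = np.clip(p * (1 - p), 1e-10, None)
        H = Z.T @ (Z * W[:, None]) + ridge * np.eye(Z.shape[1])
        grad = Z.T @ (y - p) - ridge * w
        delta = np.linalg.solve(H, grad)
        w = w + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not converge; using last iterate", RuntimeWarning)
    return CombinerWeights(coef=w, feature_means=means, feature_sds=sds, converged=converged)


def combined_probability(features: np.ndarray, weights: CombinerWeights) -> np.ndarray:
    """P(coding) under the logistic combiner; accepts one row or a matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Z = np.column_stack(
        [np.ones(len(X)), (X - weights.feature_means) / weights.feature_sds]
    )
    p = 1.0 / (1.0 + np.exp(-np.clip(Z @ weights.coef, -30, 30)))
    return p if p.size > 1 else float(p[0])


# ---------------------------------------------------------------------------
# scoring + consensus
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {"p": 0.5, "fickett": 0.95, "hexamer": 0.0}


@dataclass
class CodingPotentialModel:
    hexamer: HexamerModel
    combiner: CombinerWeights
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "f_coding": self.hexamer.f_coding.tolist(),
            "f_noncoding": self.hexamer.f_noncoding.tolist(),
            "pseudocount": self.hexamer.pseudocount,
            "coef": self.combiner.coef.tolist(),
            "feature_means": self.combiner.feature_means.tolist(),
            "feature_sds": self.combiner.feature_sds.tolist(),
            "thresholds": self.thresholds,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodingPotentialModel":
        d = json.loads(Path(path).read_text())
        return cls(
            hexamer=HexamerModel(
                np.array(d["f_coding"]), np.array(d["f_noncoding"]), d["pseudocount"]
            ),
            combiner=CombinerWeights(
                np.array(d["coef"]), np.array(d["feature_means"]), np.array(d["feature_sds"])
            ),
            thresholds=d["thresholds"],
        )


def extract_features(sequence: str, model: HexamerModel) -> tuple[np.ndarray, OrfCall]:
    """(orf_length nt, orf_coverage, fickett, hexamer bias) for one sequence."""
    orf = find_longest_orf(sequence)
    orf_seq = sequence[orf.start : orf.end] if orf.found else ""
    feats = np.array(
        [
            float(orf.length),
            orf.length / len(sequence) if sequence else 0.0,
            fickett_score(sequence),
            hexamer_bias(orf_seq, model),
        ]
    )
    return feats, orf


def consensus_call(
    p_combined: float,
    fickett: float,
    hexamer: float,
    thresholds: dict | None = None,
) -> str:
    """'coding' iff ANY scorer exceeds its threshold; survival as noncoding
    requires unanimity (the conservative exclusion rule)."""
    thr = thresholds or DEFAULT_THRESHOLDS
    coding = (
        p_combined > thr["p"]
        or fickett > thr["fickett"]
        or hexamer > thr["hexamer"]
    )
    return "coding" if coding else "noncoding"


def score_transcripts(
    sequences: dict[str, str],
    model: CodingPotentialModel,
) -> pd.DataFrame:
    """Score every sequence and attach the consensus label.

    Returns a frame indexed by transcript id with columns orf_length,
    orf_coverage, fickett, hexamer, p_coding, label.
    """
    rows = []
    for tid, seq in sequences.items():
        feats, _ = extract_features(seq, model.hexamer)
        p = combined_probability(feats, model.combiner)
        rows.append(
            {
                "transcript_id": tid,
                "orf_length": feats[0],
                "orf_coverage": feats[1],
                "fickett": feats[2],
                "hexamer": feats[3],
                "p_coding": p,
                "label": consensus_call(p, feats[2], feats[3], model.thresholds),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def train_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    pseudocount: float = 1.0,
    thresholds: dict | None = None,
) -> CodingPotentialModel:
    """Train hexamer tables and the logistic combiner from labelled sequences."""
    hexamer = train_hexamer_model(coding_seqs, noncoding_seqs, pseudocount)
    feats, labels = [], []
    for seq in coding_seqs:
        feats.append(extract_features(seq, hexamer)[0])
        labels.append(1.0)
    for seq in noncoding_seqs:
        feats.append(extract_features(seq, hexamer)[0])
        labels.append(0.0)
    combiner = train_combiner(np.array(feats), np.array(labels))
    return CodingPotentialModel(
        hexamer=hexamer,
        combiner=combiner,
        thresholds=dict(thresholds or DEFAULT_THRESHOLDS),
    )


def default_training_set(seed: int = 12345, n_per_class: int = 800):
    """Synthetic labelled training sequences: codon-biased CDS vs AT-rich
    noncoding sequences with suppressed ORFs."""
    from saltlnc import synthetic_data as sd

    rng = sd._rng(seed, "codepot-train")
    coding = [sd.random_cds(rng, int(rng.integers(100, 400))) for _ in range(n_per_class)]
    noncoding = [
        sd._noncoding_seq(rng, int(np.clip(rng.lognormal(np.log(430), 0.45), 200, 1500)))
        for _ in range(n_per_class)
    ]
    return coding, noncoding


def train_default_model(seed: int = 12345, n_per_class: int = 800) -> CodingPotentialModel:
    coding, noncoding = default_training_set(seed, n_per_class)
    return train_model(coding, noncoding)


# ---------------------------------------------------------------------------
# domain-hit filter and a shuffle utility
# ---------------------------------------------------------------------------

def filter_by_domain_hits(transcript_ids: list[str], hit_ids) -> list[str]:
    """Drop transcripts with precomputed protein-domain hits; order preserved."""
    hits = set(hit_ids)
    unknown = hits - set(transcript_ids)
    if unknown:
        warnings.warn(
            f"{len(unknown)} domain-hit ids not among the input transcripts",
            UserWarning,
        )
    return [tid for tid in transcript_ids if tid not in hits]


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (random Eulerian walk on
    the dinucleotide transition multigraph, Altschul-Erikson style)."""
    seq = sequence.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(1000):
        # pick a random final out-edge per vertex; require they form paths to `last`
        trial = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices if v != last}
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = set(), v
            while cur != last and cur in trial and cur not in seen:
                seen.add(cur)
                cur = trial[cur]
            if cur != last:
                ok = False
                break
        if not ok:
            continue
        pool = {v: list(edges[v]) for v in vertices}
        for v, e in trial.items():
            pool[v].remove(e)
        for v in pool:
            rng.shuffle(pool[v])
        for v, e in trial.items():
            pool[v].append(e)
        out, cur = [seq[0]], seq[0]
        counts = {v: 0 for v in pool}
        try:
            while True:
                nxt = pool[cur][counts[cur]]
                counts[cur] += 1
                out.append(nxt)
                cur = nxt
        except (IndexError, KeyError):
            pass
        if len(out) == len(seq):
            return "".join(out)
    return seq  # degenerate composition; give back the original
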