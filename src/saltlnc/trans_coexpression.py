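"""Trans-function prediction by co-expression modules and category enrichment.

DE lncRNAs and DE genes are pooled, their four-condition mean profiles are
Z-scored, and a weighted co-expression network is built: soft adjacency
a_ij = |cor(x_i, x_j)|^beta smoothed into a topological overlap matrix
(TOM).  Average-linkage hierarchical clustering on 1 - TOM with a static
cut yields modules; small clusters are merged into the module whose
centroid they correlate with best.  Each module is labelled with the
temporal archetype (M1..M6) whose canonical Z-profile best matches its
centroid, and per-module functional-category enrichment is tested with
one-sided Fisher's exact tests, BH-adjusted within the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from saltlnc.expression_de import bh_adjust
from saltlnc.synthetic_data import ARCHETYPE_MULTIPLIERS, CONDITIONS


@dataclass
class CoexpressionModule:
    module_id: str
    members: list[str]
    centroid: np.ndarray
    archetype: str = "unassigned"


@dataclass
class EnrichmentResult:
    module_id: str
    category: str
    k: int   # module members in category
    K: int   # module size
    n: int   # background members in category
    N: int   # background size
    p: float
    fdr: float = np.nan


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score of condition-mean profiles.

    Constant rows cannot be scaled and become all-zero, with a warning.
    """
    mat = profiles.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant profiles z-scored to all-zero rows",
            UserWarning,
        )
    sd[sd == 0] = 1.0
    return pd.DataFrame((mat - mean) / sd, index=profiles.index, columns=profiles.columns)


def soft_adjacency(profiles: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor|^beta with zero diagonal.

    Zero-variance profiles are excluded (with a warning) before the
    correlation.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 conditions for a correlation network")
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    mat = profiles.to_numpy(dtype=float)
    keep = mat.std(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance profiles from the network",
            UserWarning,
        )
    kept = profiles.index[keep]
    cor = np.corrcoef(mat[keep])
    cor = np.atleast_2d(cor)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=kept, columns=kept)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); diag 1."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1)
    numerator = a @ a + a
    min_k = np.minimum.outer(k, k)
    tom = numerator / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    profiles: pd.DataFrame,
    min_module_size: int = 10,
    cut_height: float = 0.25,
) -> list[CoexpressionModule]:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_module_size`` are merged into the retained module
    whose centroid correlates best with theirs; if no cluster reaches the
    minimum size, everything collapses into one module.  Module ids are
    assigned in decreasing size order.
    """
    ids = list(tom.index)
    prof = profiles.loc[ids].to_numpy(dtype=float)
    if len(ids) == 0:
        return []
    if len(ids) == 1:
        return [CoexpressionModule("module_1", ids, prof[0].copy())]

    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    linkage = average(squareform(dissim, checks=False))
    labels = fcluster(linkage, t=cut_height, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    big = {lab: mem for lab, mem in clusters.items() if len(mem) >= min_module_size}
    small = {lab: mem for lab, mem in clusters.items() if lab not in big}
    if not big:
        members = list(range(len(ids)))
        return [
            CoexpressionModule("module_1", [ids[i] for i in members],
                               prof[members].mean(axis=0))
        ]

    def centroid(member_idx: list[int]) -> np.ndarray:
        return prof[member_idx].mean(axis=0)

    def safe_cor(x: np.ndarray, y: np.ndarray) -> float:
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    for mem in small.values():
        c = centroid(mem)
        target = max(big, key=lambda lab: safe_cor(c, centroid(big[lab])))
        big[target] = big[target] + mem

    ordered = sorted(big.values(), key=lambda mem: (-len(mem), min(mem)))
    return [
        CoexpressionModule(
            f"module_{rank + 1}",
            [ids[i] for i in sorted(mem)],
            centroid(sorted(mem)),
        )
        for rank, mem in enumerate(ordered)
    ]


def archetype_references(
    multipliers: dict[str, tuple] | None = None,
) -> pd.DataFrame:
    """Canonical Z-scored temporal shapes of the six archetypes."""
    mult = multipliers or ARCHETYPE_MULTIPLIERS
    frame = pd.DataFrame(
        {name: list(values) for name, values in sorted(mult.items())},
        index=list(CONDITIONS),
    ).T
    return zscore_profiles(frame)


def assign_archetypes(
    modules: list[CoexpressionModule],
    min_correlation: float = 0.7,
    multipliers: dict[str, tuple] | None = None,
) -> list[CoexpressionModule]:
    """Label each module with the best-correlating canonical archetype.

    A module whose centroid reaches no archetype at ``min_correlation``
    stays unassigned.  Labels are written in place and returned.
    """
    refs = archetype_references(multipliers)
    for module in modules:
        c = np.asarray(module.centroid, dtype=float)
        if c.std() == 0:
            module.archetype = "unassigned"
            continue
        cors = {
            name: float(np.corrcoef(c, refs.loc[name].to_numpy())[0, 1])
            for name in refs.index
        }
        best = max(sorted(cors), key=lambda name: cors[name])
        module.archetype = best if cors[best] >= min_correlation else "unassigned"
    return modules


def enrich_categories(
    module: CoexpressionModule,
    categories: dict[str, str],
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact over-representation test per category.

    Background = every feature in ``categories`` (features without a
    category assignment simply do not appear there).  BH adjustment runs
    across the categories of this module.
    """
    background = list(categories)
    N = len(background)
    members = [m for m in module.members if m in categories]
    K = len(members)
    if K > N:
        raise ValueError("module is larger than the enrichment background")
    member_set = set(members)

    results = []
    for category in sorted(set(categories.values())):
        in_cat = [f for f in background if categories[f] == category]
        n = len(in_cat)
        k = sum(1 for f in in_cat if f in member_set)
        if k > n or k > K:
            raise ValueError("inconsistent background for category " + category)
        table = [[k, K - k], [n - k, N - K - n + k]]
        _, p = fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                module_id=module.module_id, category=category,
                k=k, K=K, n=n, N=N, p=float(p),
            )
        )
    fdrs = bh_adjust([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def significant_categories(
    results: list[EnrichmentResult], fdr_threshold: float = 0.05
) -> list[str]:
    return [r.category for r in results if r.fdr < fdr_threshold]
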