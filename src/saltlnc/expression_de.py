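"""Expression quantification and negative-binomial differential expression.

Counts from the 12-sample design (H0/H6/H12/H24 x 3 replicates) are
normalized by median-of-ratios size factors; expression level is reported
as FPKM.  Differential expression between two conditions uses an exact
negative-binomial test: conditioning on the summed count of both groups,
the p-value adds up the probabilities of all splits (a, b) of that sum
that are no more probable than the observed one, with per-group totals
modeled as NB with moment-matched mean and variance.  The per-feature
dispersion comes from a method-of-moments estimate pooled over the
within-group variances (floored at zero, i.e. Poisson).  Multiple testing
uses Benjamini-Hochberg; a feature is called DE at |log2FC| > 1 and
FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

CONDITION_ORDER = ("H0", "H6", "H12", "H24")
DEFAULT_COMPARISONS = tuple(
    f"{a}_{b}" for a, b in combinations(CONDITION_ORDER, 2)
)
VENN_COMPARISONS = ("H0_H6", "H0_H12", "H0_H24")


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM_ij = counts_ij / (length_i/1e3 * N_j/1e6), N_j the column total."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("missing transcript lengths for some features")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts / np.outer(lengths / 1e3, totals / 1e6)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over all-positive features of counts_ij / geomean_i.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; a pseudo-reference "
            "would be required for these data"
        )
    logs = np.log(mat[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_s = np.median(log_ratios, axis=0)
    log_s -= log_s.mean()  # geometric mean of s_j = 1
    return pd.Series(np.exp(log_s), index=counts.columns)


def estimate_dispersion(
    norm_a: np.ndarray, norm_b: np.ndarray
) -> float:
    """Method-of-moments NB dispersion pooled over the two groups' replicate
    variability, floored at 0 (Poisson)."""
    num, den = 0.0, 0.0
    for grp in (np.asarray(norm_a, float), np.asarray(norm_b, float)):
        if len(grp) < 2:
            continue
        mu = grp.mean()
        if mu <= 0:
            continue
        var = grp.var(ddof=1)
        df = len(grp) - 1
        num += df * (var - mu) / mu**2
        den += df
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _total_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """Log-pmf of a group total with moment-matched NB (Poisson if var<=mu)."""
    if var <= mu or mu <= 0:
        return poisson.logpmf(k, max(mu, 1e-300))
    r = mu**2 / (var - mu)
    p = mu / var
    return nbinom.logpmf(k, r, p)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    s_a: np.ndarray,
    s_b: np.ndarray,
    alpha: float | None = None,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Exact NB test for one feature between two replicate groups.

    Returns (log2fc, p).  log2fc compares size-factor-normalized group
    means with a pseudocount (B over A); the p-value conditions on the
    total count of both groups.
    """
    counts_a = np.asarray(counts_a, float)
    counts_b = np.asarray(counts_b, float)
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("need at least two replicates per group")

    norm_a = counts_a / s_a
    norm_b = counts_b / s_b
    log2fc = float(np.log2((norm_b.mean() + pseudocount) / (norm_a.mean() + pseudocount)))

    if alpha is None:
        alpha = estimate_dispersion(norm_a, norm_b)
    elif alpha < 0:
        warnings.warn("negative dispersion clamped to 0 (Poisson)", RuntimeWarning)
        alpha = 0.0

    k_a = int(round(counts_a.sum()))
    k_b = int(round(counts_b.sum()))
    k = k_a + k_b
    if k == 0:
        return log2fc, 1.0
    q = k / (s_a.sum() + s_b.sum())  # pooled mean per normalized unit

    def group_moments(s: np.ndarray) -> tuple[float, float]:
        mu_j = q * s
        return float(mu_j.sum()), float((mu_j + alpha * mu_j**2).sum())

    mu_a, var_a = group_moments(s_a)
    mu_b, var_b = group_moments(s_b)

    a = np.arange(k + 1)
    joint = _total_logpmf(a, mu_a, var_a) + _total_logpmf(k - a, mu_b, var_b)
    observed = joint[k_a]
    denom = logsumexp(joint)
    keep = joint <= observed + 1e-12
    p = float(np.exp(logsumexp(joint[keep]) - denom))
    return log2fc, min(1.0, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pairwise_de(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    size_factors: pd.Series | None = None,
    comparisons=DEFAULT_COMPARISONS,
    alpha: float | None = None,
    moderate: bool = True,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Exact test for every feature in every requested condition pair.

    BH adjustment runs within each comparison.  ``alpha=None`` estimates
    dispersion per feature; with ``moderate=True`` (default) each
    per-feature estimate is floored at the median estimate across all
    features, which stabilizes the very noisy 3-vs-3 moment estimates
    (an unstabilized estimate of 0 makes the test anti-conservative).
    A float ``alpha`` fixes the dispersion globally.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    samples_by_cond: dict[str, list[str]] = {}
    for sample, cond in conditions.items():
        samples_by_cond.setdefault(cond, []).append(sample)

    frames = []
    for comparison in comparisons:
        cond_a, cond_b = comparison.split("_")
        cols_a = samples_by_cond[cond_a]
        cols_b = samples_by_cond[cond_b]
        s_a = size_factors[cols_a].to_numpy()
        s_b = size_factors[cols_b].to_numpy()
        mat_a = counts[cols_a].to_numpy()
        mat_b = counts[cols_b].to_numpy()
        if alpha is None:
            disp = np.array(
                [
                    estimate_dispersion(mat_a[i] / s_a, mat_b[i] / s_b)
                    for i in range(len(counts))
                ]
            )
            if moderate and len(disp):
                disp = np.maximum(disp, np.median(disp))
        else:
            disp = np.full(len(counts), float(alpha))
        lfc = np.empty(len(counts))
        pval = np.empty(len(counts))
        for i in range(len(counts)):
            lfc[i], pval[i] = nb_exact_test(mat_a[i], mat_b[i], s_a, s_b, alpha=disp[i])
        fdr = bh_adjust(pval)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": counts.index,
                    "comparison": comparison,
                    "log2fc": lfc,
                    "p": pval,
                    "fdr": fdr,
                    "is_de": (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def de_ids(results: pd.DataFrame, comparison: str | None = None) -> set[str]:
    sub = results if comparison is None else results[results["comparison"] == comparison]
    return set(sub.loc[sub["is_de"], "feature_id"])


def de_overlaps(
    results: pd.DataFrame,
    comparisons=VENN_COMPARISONS,
) -> dict[str, int]:
    """Sizes of the seven Venn regions of three DE sets, plus the union."""
    if len(comparisons) != 3:
        raise ValueError("Venn breakdown is defined for exactly three comparisons")
    a, b, c = (de_ids(results, comp) for comp in comparisons)
    names = list(comparisons)
    return {
        f"{names[0]}_only": len(a - b - c),
        f"{names[1]}_only": len(b - a - c),
        f"{names[2]}_only": len(c - a - b),
        f"{names[0]}_{names[1]}": len((a & b) - c),
        f"{names[0]}_{names[2]}": len((a & c) - b),
        f"{names[1]}_{names[2]}": len((b & c) - a),
        "all_three": len(a & b & c),
        "union": len(a | b | c),
    }


@dataclass
class ExpressionMatrix:
    """Counts with their sample->condition design, size factors and FPKM."""

    counts: pd.DataFrame
    conditions: dict[str, str]
    lengths: pd.Series
    size_factors: pd.Series = field(default=None)
    fpkm: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.conditions):
            raise ValueError("sample ids in counts and condition map differ")
        if self.size_factors is None:
            self.size_factors = estimate_size_factors(self.counts)
        if self.fpkm is None:
            self.fpkm = compute_fpkm(self.counts, self.lengths)

    def condition_means(self, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
        """Mean of (by default) FPKM per condition, columns in time order."""
        mat = self.fpkm if matrix is None else matrix
        groups: dict[str, list[str]] = {}
        for sample, cond in self.conditions.items():
            groups.setdefault(cond, []).append(sample)
        cols = [c for c in CONDITION_ORDER if c in groups]
        return pd.DataFrame({c: mat[groups[c]].mean(axis=1) for c in cols})
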