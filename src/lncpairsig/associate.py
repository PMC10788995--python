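"""Association analyses between risk groups and external features.

High- vs low-risk comparisons of expression (immune checkpoints, EMT/stemness
genes) and drug IC50s use the two-sample Wilcoxon rank-sum (Mann-Whitney)
test: exact by enumeration of label assignments for small samples, otherwise
the normal approximation with tie-corrected variance and continuity
correction.  Score-feature relationships use Spearman/Pearson correlation,
clinical proportions a Pearson chi-square, and immune-subtype contrasts a
Kruskal-Wallis test with BH-adjusted pairwise rank-sum follow-ups.  Rare
subtype levels (fewer than ``min_n`` samples) are dropped before testing, as
done for the C5/C6 immune classes that are absent from HCC cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError
from .screen import bh_adjust
from .evaluate import RiskStratification

logger = logging.getLogger("lncpairsig")

__all__ = [
    "GroupComparison",
    "SubtypeComparison",
    "GENE_ALIASES",
    "wilcoxon_rank_sum",
    "score_correlation",
    "chi_square_proportions",
    "subtype_comparison",
    "drug_sensitivity_compare",
    "expression_group_compare",
]

#: Protein-level figure labels resolved to the gene symbols used in matrices.
GENE_ALIASES = {
    "PD1": "PDCD1",
    "PD-1": "PDCD1",
    "PDL1": "CD274",
    "PD-L1": "CD274",
    "TIM3": "HAVCR2",
    "TIM-3": "HAVCR2",
    "CD39": "ENTPD1",
}

EXACT_MAX_N = 20


@dataclass
class GroupComparison:
    feature: str
    n_high: int
    n_low: int
    statistic: float  # rank-sum W of the high group
    p: float
    direction: str  # {"higher_in_high", "higher_in_low", "none"}
    fdr: float | None = None


@dataclass
class SubtypeComparison:
    levels: list[str]
    kruskal_h: float
    p: float
    pairwise: list[tuple[str, str, float]]  # (level_i, level_j, BH-adjusted p)


def _exact_rank_sum_p(ranks: np.ndarray, n_high: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all high-group label assignments.

    The null distribution of the rank-sum W is symmetric about
    n_high*(N+1)/2 only without ties; with mid-ranks we therefore use the
    deviation form P(|W - E[W]| >= |w_obs - E[W]|) over all C(N, n_high)
    assignments.
    """
    n = len(ranks)
    mu = n_high * ranks.sum() / n
    dev = abs(w_obs - mu) - 1e-9
    count = 0
    total = 0
    for idx in combinations(range(n), n_high):
        w = ranks[list(idx)].sum()
        count += abs(w - mu) >= dev
        total += 1
    return count / total


def wilcoxon_rank_sum(
    values_high: np.ndarray | pd.Series,
    values_low: np.ndarray | pd.Series,
    feature: str = "feature",
) -> GroupComparison:
    """Two-sample rank-sum test with mid-rank ties and two-sided p.

    Exact enumeration when the combined sample size is at most 20, otherwise
    the normal approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    vh = np.asarray(values_high, dtype=float)
    vl = np.asarray(values_low, dtype=float)
    if vh.size == 0 or vl.size == 0:
        raise ValidationError("rank-sum test requires two non-empty groups")
    n1, n2 = vh.size, vl.size
    n = n1 + n2
    pooled = np.concatenate([vh, vl])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())

    if np.ptp(pooled) == 0:
        p = 1.0
    elif n <= EXACT_MAX_N:
        p = _exact_rank_sum_p(ranks, n1, w)
    else:
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)))

    med_h, med_l = float(np.median(vh)), float(np.median(vl))
    if med_h > med_l:
        direction = "higher_in_high"
    elif med_h < med_l:
        direction = "higher_in_low"
    else:
        direction = "none"
    if p == 1.0 and np.ptp(pooled) == 0:
        direction = "none"
    return GroupComparison(feature, n1, n2, w, float(p), direction)


def score_correlation(
    scores: pd.Series | np.ndarray,
    feature: pd.Series | np.ndarray,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation of a feature with the risk score, two-sided t-transform p."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(feature, dtype=float)
    if x.size != y.size:
        raise ValidationError("scores and feature must be paired")
    if x.size < 3:
        raise ValidationError("correlation requires >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def chi_square_proportions(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2 x C table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValidationError(f"expected a 2 x C contingency table, got shape {arr.shape}")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency table must hold nonnegative integers")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero marginal row/column")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"chi-square approximation is poor: {int((expected < 5).sum())} "
            "expected counts below 5",
            UserWarning,
            stacklevel=2,
        )
    return float(chi2), int(df), float(p)


def subtype_comparison(
    scores: pd.Series, subtypes: pd.Series, min_n: int = 3
) -> SubtypeComparison:
    """Kruskal-Wallis across subtype levels plus BH-adjusted pairwise rank-sums."""
    subtypes = subtypes.reindex(scores.index)
    mask = subtypes.notna()
    scores, subtypes = scores[mask], subtypes[mask]
    counts = subtypes.value_counts()
    retained = sorted(counts.index[counts >= min_n])
    dropped = sorted(set(counts.index) - set(retained))
    if dropped:
        logger.info("subtype_comparison: levels %s dropped (fewer than %d samples)", dropped, min_n)
    if len(retained) < 2:
        raise ValidationError(
            f"need >= 2 subtype levels with >= {min_n} samples, got {retained}"
        )
    groups = [scores[subtypes == lv].to_numpy(dtype=float) for lv in retained]
    h, p = stats.kruskal(*groups)
    raw = []
    pairs = list(combinations(range(len(retained)), 2))
    for i, j in pairs:
        raw.append(wilcoxon_rank_sum(groups[i], groups[j]).p)
    adj = bh_adjust(raw)
    pairwise = [(retained[i], retained[j], float(q)) for (i, j), q in zip(pairs, adj)]
    return SubtypeComparison(levels=retained, kruskal_h=float(h), p=float(p), pairwise=pairwise)


def drug_sensitivity_compare(
    ic50: pd.DataFrame, strat: RiskStratification
) -> list[GroupComparison]:
    """Per-drug high-vs-low IC50 rank-sum tests, BH-adjusted across drugs."""
    shared = [s for s in strat.sample_ids if s in ic50.columns]
    if not shared:
        raise ValidationError("no shared samples between IC50 matrix and stratification")
    labels = strat.labels.loc[shared]
    high = labels.index[labels == "high"].tolist()
    low = labels.index[labels == "low"].tolist()
    if len(high) < 2 or len(low) < 2:
        raise ValidationError("each risk group needs >= 2 samples with IC50 values")
    results = []
    for drug in ic50.index:
        row = ic50.loc[drug]
        results.append(wilcoxon_rank_sum(row[high], row[low], feature=str(drug)))
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.fdr = float(q)
    return results


def expression_group_compare(
    expr: ExpressionMatrix,
    strat: RiskStratification,
    genes: list[str],
) -> list[GroupComparison]:
    """High-vs-low expression comparisons for named genes (aliases resolved)."""
    resolved = {}
    for g in genes:
        symbol = GENE_ALIASES.get(g, g)
        if symbol not in expr.values.index:
            raise ValidationError(f"gene {g!r} (resolved to {symbol!r}) not in matrix")
        resolved[g] = symbol
    shared = [s for s in strat.sample_ids if s in expr.values.columns]
    labels = strat.labels.loc[shared]
    high = labels.index[labels == "high"].tolist()
    low = labels.index[labels == "low"].tolist()
    results = []
    for g, symbol in resolved.items():
        row = expr.values.loc[symbol]
        cmp = wilcoxon_rank_sum(row[high], row[low], feature=g)
        results.append(cmp)
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.fdr = float(q)
    return results


def comparisons_frame(results: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "n_high": [r.n_high for r in results],
            "n_low": [r.n_low for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("feature")
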