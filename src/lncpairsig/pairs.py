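"""The 0-or-1 lncRNA-pair matrix and its validity filter.

Each unordered pair (A, B) of DElncRNAs yields one binary feature per sample:
X = 1 when A is expressed above B in that sample, else 0 (ties score 0).
Because X compares two genes *within* a sample, it is invariant to any
per-sample monotone transform of the expression values — the property that
lets the signature work without absolute expression levels or cross-batch
normalization.

A pair is informative only if both indicator classes are populated: the
validity filter keeps a pair iff its fraction of ones lies strictly inside
(min_frac, 1 - min_frac), default (0.2, 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("lncpairsig")

__all__ = ["PairMatrix", "pair_id", "build_pair_matrix", "filter_valid_pairs"]


def pair_id(lnc_a: str, lnc_b: str) -> str:
    return f"{lnc_a}|{lnc_b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, _, b = pid.partition("|")
    if not a or not b:
        raise ValidationError(f"malformed pair ID {pid!r}")
    return a, b


@dataclass
class PairMatrix:
    """Binary pair-indicator x sample matrix.

    ``indicators`` is a DataFrame with one row per pair (index "A|B") and one
    0/1 column per sample.
    """

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        if self.indicators.index.has_duplicates:
            dups = self.indicators.index[self.indicators.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate pair IDs: {dups}")
        arr = self.indicators.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("pair indicators must be 0 or 1")
        seen: set[frozenset[str]] = set()
        for pid in self.indicators.index:
            a, b = split_pair_id(pid)
            if a == b:
                raise ValidationError(f"degenerate pair {pid!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"pair {pid!r} duplicates its reverse orientation")
            seen.add(key)

    @property
    def pair_ids(self) -> list[str]:
        return self.indicators.index.tolist()

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [split_pair_id(p) for p in self.indicators.index]

    @property
    def sample_ids(self) -> list[str]:
        return self.indicators.columns.tolist()

    @property
    def frac_one(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def subset_pairs(self, pair_ids: list[str]) -> "PairMatrix":
        missing = [p for p in pair_ids if p not in self.indicators.index]
        if missing:
            raise ValidationError(f"pairs not in matrix: {missing}")
        return PairMatrix(self.indicators.loc[list(pair_ids)])

    def to_tsv(self, path) -> None:
        out = self.indicators.astype(int).copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PairMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def build_pair_matrix(expr: ExpressionMatrix, strict: bool = True) -> PairMatrix:
    """Cyclically pair the K input genes into K(K-1)/2 binary features.

    Pairs are oriented (a, b) with a preceding b in the input gene order, and
    X_s = 1 iff expr(a, s) > expr(b, s); ties score 0 (``strict=False`` counts
    ties as 1, i.e. uses >=).
    """
    genes = expr.gene_ids
    k = len(genes)
    if k < 2:
        raise ValidationError(f"pairing requires >= 2 genes, got {k}")
    arr = expr.values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValidationError("expression must be finite for pairing")
    iu, ju = np.triu_indices(k, k=1)
    if strict:
        x = (arr[iu] > arr[ju]).astype(np.int8)
    else:
        x = (arr[iu] >= arr[ju]).astype(np.int8)
    index = pd.Index([pair_id(genes[i], genes[j]) for i, j in zip(iu, ju)], name="pair_id")
    return PairMatrix(pd.DataFrame(x, index=index, columns=expr.sample_ids))


def filter_valid_pairs(pm: PairMatrix, min_frac: float = 0.2) -> PairMatrix:
    """Keep pairs whose fraction of ones lies strictly in (min_frac, 1 - min_frac).

    Constant indicators (all 0 or all 1) never survive; order is preserved.
    Pairs sitting exactly on a boundary are dropped and logged, since the
    strict/inclusive choice matters only there.
    """
    if not 0.0 < min_frac < 0.5:
        raise ValidationError(f"min_frac must lie in (0, 0.5), got {min_frac}")
    if len(pm.pair_ids) == 0:
        raise ValidationError("empty pair matrix")
    frac = pm.frac_one
    keep = (frac > min_frac) & (frac < 1.0 - min_frac)
    boundary = frac.index[(frac == min_frac) | (frac == 1.0 - min_frac)].tolist()
    if boundary:
        logger.info(
            "filter_valid_pairs: %d pairs exactly on the %.0f%% boundary dropped: %s",
            len(boundary),
            min_frac * 100,
            boundary[:10],
        )
    logger.info(
        "filter_valid_pairs: kept %d/%d pairs at min_frac=%.2f",
        int(keep.sum()),
        len(keep),
        min_frac,
    )
    return PairMatrix(pm.indicators.loc[keep[keep].index.tolist()])
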