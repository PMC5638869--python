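"""Univariate feature ranking by class association significance.

Three interchangeable scorers are provided: pooled-variance two-sample
t-test (the default consumed by the incremental search), two-group
one-way ANOVA F-test, and the Wilcoxon rank-sum test.  Each returns a
total ordering of the features, most significant first, with ties broken
stably by original feature index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .dataset_io import ExpressionDataset

__all__ = [
    "RankedFeatures",
    "rank_ttest",
    "rank_anova_fpr",
    "rank_wilcoxon",
    "rank_features",
    "export_ranking",
    "InsufficientSamplesError",
]

RANKING_METHODS = ("ttest", "anova_fpr", "wilcoxon")


class InsufficientSamplesError(ValueError):
    """A class has too few samples for the requested test."""


@dataclass(frozen=True)
class RankedFeatures:
    """Total order of feature indices by ascending p-value.

    ``order[r]`` is the 0-based original index of the feature at rank
    ``r + 1`` (rank 1 = most significant).  ``pvalues`` is aligned to
    original feature indices, not to ranks.
    """

    order: np.ndarray
    pvalues: np.ndarray
    method: str

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        pvalues = np.asarray(self.pvalues, dtype=float)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "pvalues", pvalues)
        n = order.size
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order is not a permutation of 0..n-1")
        if pvalues.shape != (n,):
            raise ValueError("pvalues misaligned with order")
        along = pvalues[order]
        if np.any(np.diff(along) < 0):
            raise ValueError("pvalues must be non-decreasing along the order")

    @property
    def n_features(self) -> int:
        return self.order.size

    def top(self, k: int) -> np.ndarray:
        """Original indices of the ``k`` most significant features."""
        return self.order[:k]

    def window(self, start_rank: int, length: int) -> np.ndarray:
        """Original indices of ranks ``start_rank .. start_rank+length-1`` (1-based)."""
        if not 1 <= start_rank <= self.n_features:
            raise IndexError(f"start_rank {start_rank} out of 1..{self.n_features}")
        return self.order[start_rank - 1 : start_rank - 1 + length]


def _split(ds: ExpressionDataset, min_per_class: int):
    if ds.P < min_per_class or ds.N < min_per_class:
        raise InsufficientSamplesError(
            f"need at least {min_per_class} samples per class (P={ds.P}, N={ds.N})"
        )
    return ds.matrix[:, ds.labels], ds.matrix[:, ~ds.labels]


def _order_from_pvalues(pvalues: np.ndarray, method: str) -> RankedFeatures:
    pvalues = np.where(np.isnan(pvalues), 1.0, pvalues)
    order = np.argsort(pvalues, kind="stable")
    return RankedFeatures(order=order, pvalues=pvalues, method=method)


def rank_ttest(ds: ExpressionDataset) -> RankedFeatures:
    """Rank by two-sided Student t-test with pooled variance.

    Features constant in both classes get p-value 1.0 and sink to the
    bottom of the ranking; the ordering is always total.
    """
    pos, neg = _split(ds, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(pos, neg, axis=1, equal_var=True)
    return _order_from_pvalues(res.pvalue, "ttest")


def rank_anova_fpr(ds: ExpressionDataset) -> RankedFeatures:
    """Rank by two-group one-way ANOVA F-test p-value.

    For two groups F = t**2, so the ordering coincides with
    :func:`rank_ttest` up to floating-point ties.
    """
    pos, neg = _split(ds, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(pos, neg, axis=1)
    return _order_from_pvalues(res.pvalue, "anova_fpr")


def rank_wilcoxon(ds: ExpressionDataset) -> RankedFeatures:
    """Rank by two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation otherwise (the host statistics library's
    ``method="auto"`` policy).
    """
    pos, neg = _split(ds, 1)
    pvalues = np.empty(ds.n_features)
    for i in range(ds.n_features):
        x, y = pos[i], neg[i]
        if np.ptp(x) == 0 and np.ptp(y) == 0 and (x.size == 0 or y.size == 0 or x[0] == y[0]):
            pvalues[i] = 1.0
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            pvalues[i] = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="auto"
            ).pvalue
    return _order_from_pvalues(pvalues, "wilcoxon")


_RANKERS = {
    "ttest": rank_ttest,
    "anova_fpr": rank_anova_fpr,
    "wilcoxon": rank_wilcoxon,
}


def rank_features(ds: ExpressionDataset, method: str = "ttest") -> RankedFeatures:
    """Dispatch to one of the ranking methods by name."""
    try:
        return _RANKERS[method](ds)
    except KeyError:
        raise ValueError(
            f"unknown ranking method {method!r}; choose from {RANKING_METHODS}"
        ) from None


def export_ranking(
    ranked: RankedFeatures, ds: ExpressionDataset, path: str | Path
) -> None:
    """Write the full ranking as TSV: feature_id, rank, p_value, method."""
    with open(path, "w") as fh:
        fh.write("feature_id\trank\tp_value\tmethod\n")
        for r, idx in enumerate(ranked.order, start=1):
            fh.write(
                f"{ds.feature_ids[idx]}\t{r}\t{ranked.pvalues[idx]:.6g}\t{ranked.method}\n"
            )
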