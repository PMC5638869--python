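"""Same-size filter baselines for head-to-head comparisons.

If the re-started search selects k features, each filter contributes its
top-k features under the identical evaluation protocol (same folds,
seeds and classifier set), so the rows differ only in the subset.
Filter names follow the usual shorthand: Trank (t-test), FPR (ANOVA-F
p-value) and Wrank (Wilcoxon rank-sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset_io import ExpressionDataset
from .evaluation import DEFAULT_CLASSIFIERS, evaluate_subset
from .ranking import rank_anova_fpr, rank_ttest, rank_wilcoxon
from .rifs_core import RIFSResult

__all__ = ["ComparisonRow", "compare_filters", "FILTER_METHODS",
           "wrapper_select"]

FILTER_METHODS = {
    "Trank": rank_ttest,
    "FPR": rank_anova_fpr,
    "Wrank": rank_wilcoxon,
}


@dataclass(frozen=True)
class ComparisonRow:
    method: str
    n_features: int
    mAcc: float
    Fscore: float
    feature_indices: tuple[int, ...]


def compare_filters(
    ds: ExpressionDataset,
    rifs_result: RIFSResult,
    methods: Sequence[str] = ("Trank", "FPR", "Wrank"),
    *,
    k: int = 10,
    seeds: Sequence[int] = tuple(range(20)),
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    scale: bool = False,
) -> list[ComparisonRow]:
    """Evaluate each filter's top-k against the selected subset.

    ``k`` here is the fold count; the subset size is taken from
    ``rifs_result``.  The first returned row is the search's own subset.
    """
    subset = rifs_result.selected_features
    if not subset:
        raise ValueError("rifs_result contains an empty subset")
    size = len(subset)

    def _row(name: str, indices: Sequence[int]) -> ComparisonRow:
        report = evaluate_subset(
            ds, indices, k=k, seeds=seeds, classifiers=classifiers, scale=scale
        )
        best = report.per_classifier[report.best_classifier]
        return ComparisonRow(
            method=name,
            n_features=len(tuple(indices)),
            mAcc=report.mAcc,
            Fscore=best["Fscore"],
            feature_indices=tuple(int(i) for i in indices),
        )

    rows = [_row("RIFS", subset)]
    for name in methods:
        try:
            ranker = FILTER_METHODS[name]
        except KeyError:
            raise ValueError(
                f"unknown filter {name!r}; choose from {sorted(FILTER_METHODS)}"
            ) from None
        rows.append(_row(name, ranker(ds).top(size)))
    return rows


def wrapper_select(
    ds: ExpressionDataset, method: str, *, seed: int = 0
) -> np.ndarray:
    """Optional adapters around off-the-shelf wrapper selectors.

    ``lasso`` (L1 linear model, alpha 0.1) returns features with
    non-zero coefficients; ``rf`` and ``ridge`` return features with
    above-mean importance/|coefficient|.  These exist for convenience
    only and are not part of the core comparison surface.
    """
    X, y = ds.matrix.T, ds.labels.astype(int)
    if method == "lasso":
        from sklearn.linear_model import Lasso

        coef = Lasso(alpha=0.1).fit(X, y).coef_
        return np.flatnonzero(coef != 0)
    if method == "ridge":
        from sklearn.linear_model import Ridge

        coef = np.abs(Ridge().fit(X, y).coef_)
        return np.flatnonzero(coef > coef.mean())
    if method == "rf":
        from sklearn.ensemble import RandomForestClassifier

        imp = RandomForestClassifier(random_state=seed).fit(X, y).feature_importances_
        return np.flatnonzero(imp > imp.mean())
    raise ValueError(f"unknown wrapper {method!r}")
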