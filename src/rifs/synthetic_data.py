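"""Synthetic large-p small-n expression-like matrices with planted signal.

Generates per-class Gaussian feature matrices with three ingredients:

* background features — identically distributed in both classes;
* strong features — a plain class-mean shift, which a univariate t-test
  ranks at the very top;
* synergy pairs — two features that are *individually* near-null under a
  univariate test yet *jointly* linearly separable.  Each pair is a 2-D
  configuration separated along one axis and rotated (default 45
  degrees) so the separation hides inside a high-variance shared
  component; per-class recentring plus a closed-form class shift then
  pin both members' realised pooled t-statistics to exactly the same
  target value, so the pair occupies adjacent ranks in the t-test
  ordering — the situation a re-started incremental search can exploit
  and a top-of-ranking search cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset_io import ExpressionDataset

__all__ = ["SyntheticSpec", "SynergyPairSpec", "GroundTruth", "generate",
           "CalibrationError"]


class CalibrationError(ValueError):
    """The requested marginal significance zone is unreachable."""


@dataclass(frozen=True)
class SynergyPairSpec:
    """One planted pair of marginally weak, jointly strong features.

    ``target_rank_zone`` is the p-value level (equivalently, the
    expected percentile within the uniform background p-value
    distribution) both members are calibrated to; ``pair_separation``
    is the between-class gap along the pair's joint discriminant
    direction, in units of the within-class spread along it.
    """

    target_rank_zone: float = 0.3
    pair_angle: float = 45.0  # degrees
    pair_separation: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.target_rank_zone < 1:
            raise ValueError("target_rank_zone must be in (0, 1)")
        if self.pair_separation <= 0:
            raise ValueError("pair_separation must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    n_features: int = 2000
    m_pos: int = 30
    m_neg: int = 30
    n_strong: int = 0
    strong_shift: float = 3.0
    synergy_pairs: tuple[SynergyPairSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.m_pos, self.m_neg) < 1:
            raise ValueError("all counts must be positive")
        if self.n_strong < 0 or self.noise_sd <= 0:
            raise ValueError("invalid n_strong or noise_sd")
        if self.n_strong + 2 * len(self.synergy_pairs) > self.n_features:
            raise ValueError("planted features exceed n_features")
        object.__setattr__(self, "synergy_pairs", tuple(self.synergy_pairs))


@dataclass(frozen=True)
class GroundTruth:
    """Original feature indices of the planted signal."""

    strong: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]


def _calibrated_pair(
    pair: SynergyPairSpec,
    labels: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one synergy pair as a (2, m) block."""
    m = labels.size
    p, n = int(labels.sum()), int(m - labels.sum())
    theta = np.deg2rad(pair.pair_angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    sep = pair.pair_separation
    sigma_u = 0.25 * noise_sd  # within-class spread along the discriminant

    # population-level nuisance variance needed for the marginal t target
    t_star = stats.t.isf(pair.target_rank_zone / 2.0, df=m - 2)
    se = np.sqrt(1.0 / p + 1.0 / n)
    s_target = sep * max(abs(cos_t), abs(sin_t)) / (t_star * se)
    if s_target**2 <= (sigma_u * cos_t) ** 2 or np.isclose(sin_t, 0.0):
        raise CalibrationError(
            f"target_rank_zone={pair.target_rank_zone} unreachable with "
            f"pair_separation={pair.pair_separation} at angle "
            f"{pair.pair_angle} deg"
        )
    sigma_v = np.sqrt(s_target**2 - (sigma_u * cos_t) ** 2) / abs(sin_t)

    sign = np.where(labels, 0.5, -0.5)
    u = sep * sign + rng.normal(0.0, sigma_u, m)
    v = rng.normal(0.0, sigma_v, m)
    # recentre per class so the realised discriminant gap is exactly sep
    # and the nuisance direction carries no realised class difference
    for cls in (True, False):
        idx = labels == cls
        u[idx] -= u[idx].mean() - sep * (0.5 if cls else -0.5)
        v[idx] -= v[idx].mean()
    block = np.vstack([cos_t * u - sin_t * v, sin_t * u + cos_t * v])

    # closed-form class shift pinning each member's realised pooled
    # t-statistic to exactly t_star (pooled sd is shift-invariant)
    for row in block:
        s_pooled = np.sqrt(
            (
                ((row[labels] - row[labels].mean()) ** 2).sum()
                + ((row[~labels] - row[~labels].mean()) ** 2).sum()
            )
            / (m - 2)
        )
        delta_now = row[labels].mean() - row[~labels].mean()
        delta_target = t_star * s_pooled * se
        shift = (delta_target - delta_now) / 2.0
        row[labels] += shift
        row[~labels] -= shift
    return block


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Deterministically generate a dataset and its planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    m = spec.m_pos + spec.m_neg
    labels = np.zeros(m, dtype=bool)
    labels[: spec.m_pos] = True

    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_features, m))

    n_planted = spec.n_strong + 2 * len(spec.synergy_pairs)
    planted = rng.choice(spec.n_features, size=n_planted, replace=False)
    strong_idx = tuple(int(i) for i in np.sort(planted[: spec.n_strong]))
    pair_idx = planted[spec.n_strong :]

    for i in strong_idx:
        X[i, labels] += spec.strong_shift

    pairs = []
    for j, pair in enumerate(spec.synergy_pairs):
        a, b = sorted(int(i) for i in pair_idx[2 * j : 2 * j + 2])
        X[[a, b], :] = _calibrated_pair(pair, labels, spec.noise_sd, rng)
        pairs.append((a, b))

    ds = ExpressionDataset(
        matrix=X,
        feature_ids=tuple(f"F{i:05d}" for i in range(spec.n_features)),
        labels=labels,
    )
    return ds, GroundTruth(strong=strong_idx, pairs=tuple(pairs))
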