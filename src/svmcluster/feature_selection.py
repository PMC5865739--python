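"""Frequency-based feature selection from the random SVM cluster.

Members whose individual validation accuracy exceeds a threshold (default
0.75) are kept; the occurrence count of every feature index across those
members' random feature subsets ranks the features. The most frequent
(default top 400) are the "important features". The optimal feature set is
then found by sweeping the pool size m: for each m, a fresh cluster draws
its d features per member only from the first m important features, and the
m with the best validation accuracy wins (smallest m on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    Dataset,
    MemberSvm,
    RandomSvmCluster,
    SplitSpec,
    SvmParams,
    build_cluster,
    cluster_accuracy,
)

__all__ = [
    "FeatureFrequencyTable",
    "ImportantFeatureSet",
    "FeaturePoolSweepResult",
    "high_accuracy_members",
    "feature_frequency",
    "important_features",
    "sweep_feature_pool",
]

ACCURACY_THRESHOLD = 0.75
TOP_FEATURES = 400


@dataclass
class FeatureFrequencyTable:
    """Occurrence count of each feature among the selected members.

    ``ranking`` sorts feature indices by count descending, ties broken by
    ascending feature index. The counts sum to (#members x d) exactly,
    because every member contributes each of its d features once.
    """

    counts: dict[int, int]
    n_members: int
    d: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_members * self.d:
            raise ValueError("counts must sum to n_members * d")

    @property
    def ranking(self) -> list[int]:
        return sorted(self.counts, key=lambda f: (-self.counts[f], f))

    def to_frame(self) -> pd.DataFrame:
        order = self.ranking
        return pd.DataFrame(
            {"feature_index": order, "count": [self.counts[f] for f in order]}
        )


@dataclass
class ImportantFeatureSet:
    """Top-ranked features, frequency high to low."""

    features: list[int]
    threshold: float
    size_limit: int

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("important features must be unique")
        if len(self.features) > self.size_limit:
            raise ValueError("more features than the size limit allows")


@dataclass
class FeaturePoolSweepResult:
    """Validation accuracy per pool size m, the best m and its feature set."""

    pool_sizes: list[int]
    accuracies: list[float]
    best_m: int
    optimal_features: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.pool_sizes, "accuracy": self.accuracies})


def high_accuracy_members(
    cluster: RandomSvmCluster, threshold: float = ACCURACY_THRESHOLD
) -> list[MemberSvm]:
    """Members with accuracy strictly above the threshold, best first.

    Requires member accuracies to have been computed (see
    :func:`svmcluster.ensemble.member_accuracies`). The sort is stable, so
    equally accurate members keep their build order.
    """
    if any(np.isnan(m.accuracy) for m in cluster.members):
        raise ValueError("member accuracies not computed; run member_accuracies first")
    selected = [m for m in cluster.members if m.accuracy > threshold]
    if not selected:
        best = max(m.accuracy for m in cluster.members)
        raise ValueError(
            f"no member exceeds accuracy threshold {threshold} (best is {best:.3f}); "
            "lower the threshold or enlarge the ensemble"
        )
    return sorted(selected, key=lambda m: -m.accuracy)


def feature_frequency(members: Sequence[MemberSvm]) -> FeatureFrequencyTable:
    """Count how often each feature index occurs across the members' subsets."""
    if not members:
        raise ValueError("need at least one member")
    d = len(members[0].feature_idx)
    all_feats = np.concatenate([m.feature_idx for m in members])
    idx, cnt = np.unique(all_feats, return_counts=True)
    return FeatureFrequencyTable(
        counts={int(i): int(c) for i, c in zip(idx, cnt)},
        n_members=len(members),
        d=d,
    )


def important_features(
    table: FeatureFrequencyTable,
    top: int = TOP_FEATURES,
    threshold: float = ACCURACY_THRESHOLD,
) -> ImportantFeatureSet:
    """The ``top`` most frequent features, high to low.

    If fewer than ``top`` distinct features occurred, all of them are
    returned with a warning. ``threshold`` is recorded for provenance only.
    """
    ranking = table.ranking
    if len(ranking) < top:
        warnings.warn(
            f"only {len(ranking)} distinct features occurred; returning all of them "
            f"(requested top {top})",
            stacklevel=2,
        )
    return ImportantFeatureSet(
        features=ranking[:top], threshold=threshold, size_limit=top
    )


def sweep_feature_pool(
    ds: Dataset,
    split: SplitSpec,
    important: ImportantFeatureSet,
    m_values: Sequence[int] | None = None,
    *,
    n: int,
    d: int,
    k: int,
    params: SvmParams | None = None,
    seed: int = 0,
) -> FeaturePoolSweepResult:
    """Find the optimal feature set by sweeping the sampling-pool size.

    For each m the cluster still draws d features per member, but only from
    the first m important features. Default grid: 70..400 step 10, clipped
    to the available ranking length. Ties for the best accuracy go to the
    smallest m; the optimal feature set is the first best_m important
    features.
    """
    if m_values is None:
        m_values = range(70, 401, 10)
    m_values = [int(m) for m in m_values]
    if not m_values:
        raise ValueError("m_values must be non-empty")
    for m in m_values:
        if m < d:
            raise ValueError(f"pool size m={m} is smaller than the subset size d={d}")
        if m > len(important.features):
            raise ValueError(
                f"pool size m={m} exceeds the {len(important.features)} ranked features"
            )
    child_seeds = np.random.default_rng(seed).integers(2**31, size=len(m_values))
    accuracies = []
    for m, child in zip(m_values, child_seeds):
        cluster = build_cluster(
            ds,
            split,
            n=n,
            d=d,
            k=k,
            params=params,
            seed=int(child),
            feature_pool=important.features[:m],
        )
        accuracies.append(cluster_accuracy(cluster, ds, split.validation_idx))
    best_pos = int(np.argmax(accuracies))  # argmax takes the first max: smallest m
    best_m = m_values[best_pos]
    return FeaturePoolSweepResult(
        pool_sizes=m_values,
        accuracies=accuracies,
        best_m=best_m,
        optimal_features=important.features[:best_m],
    )
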