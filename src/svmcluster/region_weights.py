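"""Per-region weights from a selected set of functional connections.

Each selected connection is an edge between two brain regions; a region's
weight is the number of selected connections incident to it (its degree in
the selected-connection graph). Regions touched by no selected connection
have weight 0. Summed over regions, the weights equal twice the number of
selected connections (every edge has two endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import default_region_labels, n_pairs, pair_of_index

__all__ = ["RegionWeightTable", "compute_region_weights", "top_regions", "edge_list"]


@dataclass
class RegionWeightTable:
    """Weight per region, with labels for human-readable reporting."""

    weights: dict[str, int]
    region_labels: list[str]
    n_selected: int

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.region_labels):
            raise ValueError("weights must cover every region exactly once")
        if sum(self.weights.values()) != 2 * self.n_selected:
            raise ValueError("region weights must sum to twice the connection count")

    def to_frame(self, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        """Rank-ordered table (weight desc, label asc), optionally joined to
        an atlas table with columns ``abbreviation`` / ``full_name``."""
        df = pd.DataFrame(
            {"region": self.region_labels, "weight": [self.weights[r] for r in self.region_labels]}
        )
        df = df.sort_values(["weight", "region"], ascending=[False, True]).reset_index(drop=True)
        if metadata is not None:
            df = df.merge(
                metadata[["abbreviation", "full_name"]],
                left_on="region",
                right_on="abbreviation",
                how="left",
            ).drop(columns="abbreviation")
        return df


def compute_region_weights(
    selected: Sequence[int],
    n_regions: int,
    region_labels: Sequence[str] | None = None,
) -> RegionWeightTable:
    """Degree of each region in the graph of selected connections.

    ``selected`` holds feature indices under the frozen pair-index
    convention; duplicates are counted with multiplicity.
    """
    labels = list(region_labels) if region_labels else default_region_labels(n_regions)
    if len(labels) != n_regions:
        raise ValueError(f"{len(labels)} labels for {n_regions} regions")
    total = n_pairs(n_regions)
    degree = np.zeros(n_regions, dtype=int)
    for idx in selected:
        if not 0 <= idx < total:
            raise ValueError(f"feature index {idx} out of range for R={n_regions}")
        i, j = pair_of_index(int(idx), n_regions)
        degree[i] += 1
        degree[j] += 1
    return RegionWeightTable(
        weights={lab: int(w) for lab, w in zip(labels, degree)},
        region_labels=labels,
        n_selected=len(selected),
    )


def top_regions(table: RegionWeightTable, min_weight: int = 1) -> list[str]:
    """Regions with weight >= min_weight, weight descending then label ascending."""
    keep = [(r, w) for r, w in table.weights.items() if w >= min_weight]
    keep.sort(key=lambda rw: (-rw[1], rw[0]))
    return [r for r, _ in keep]


def edge_list(
    selected: Sequence[int],
    n_regions: int,
    region_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Selected connections as a (region_a, region_b) edge table."""
    labels = list(region_labels) if region_labels else default_region_labels(n_regions)
    rows = []
    for idx in selected:
        i, j = pair_of_index(int(idx), n_regions)
        rows.append({"region_a": labels[i], "region_b": labels[j]})
    return pd.DataFrame(rows, columns=["region_a", "region_b"])
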