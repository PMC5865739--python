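"""Functional-connectivity features from regional time series.

Each subject is summarised by the Pearson correlation between every pair of
regional time courses. For the 90-region AAL parcellation this yields
90*89/2 = 4005 connectivity features per subject. The pair ordering is
frozen here (row-major upper triangle, 0-based) so that feature indices are
meaningful across the ensemble, the feature-selection ranking, output files
and the region-weight computation.

Also hosts the head-motion quality-control rule used to exclude subjects
whose maximum translation exceeds 2 mm or rotation exceeds 2 degrees.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityVector",
    "MotionSummary",
    "load_aal90_labels",
    "default_region_labels",
    "pearson_matrix",
    "vectorize_upper",
    "connectivity_vector",
    "pair_of_index",
    "index_of_pair",
    "n_pairs",
    "pair_labels",
    "motion_qc",
    "read_timeseries_csv",
    "write_feature_matrix",
    "read_feature_matrix",
]

_SYMMETRY_TOL = 1e-10


def load_aal90_labels() -> pd.DataFrame:
    """Load the packaged AAL-90 region table.

    Columns: ``index`` (1..90), ``abbreviation`` (e.g. ``ORBinf.L``),
    ``full_name``, ``hemisphere`` (``L``/``R``; odd indices are left).
    """
    ref = importlib.resources.files("svmcluster.data") / "aal90_labels.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def default_region_labels(n_regions: int = 90) -> list[str]:
    """AAL abbreviations for ``n_regions == 90``, generic ``R001..`` otherwise."""
    if n_regions == 90:
        return load_aal90_labels()["abbreviation"].tolist()
    return [f"R{i + 1:03d}" for i in range(n_regions)]


@dataclass
class RoiTimeSeries:
    """One subject's regional time series: a T x R signal matrix.

    ``data[t, r]`` is the signal of region ``r`` at time point ``t``; units
    are arbitrary because Pearson correlation is scale-free.
    """

    subject_id: str
    data: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x R) matrix")
        t, r = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if r < 3:
            raise ValueError(f"need at least 3 regions, got {r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")
        if not self.region_labels:
            self.region_labels = default_region_labels(r)
        if len(self.region_labels) != r:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {r} regions"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityVector:
    """Upper-triangle Pearson correlations in the frozen pair order.

    For R regions the vector has P = R(R-1)/2 entries ordered row-major over
    pairs (i, j) with 0-based i < j: (0,1), (0,2), ..., (0,R-1), (1,2), ...
    """

    values: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_pairs(self.n_regions)
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} entries for R={self.n_regions}, got {self.values.shape}"
            )
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation magnitudes exceed 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MotionSummary:
    """Maximum absolute head motion over a scan, from realignment parameters."""

    max_abs_translation_mm: float
    max_abs_rotation_deg: float

    def __post_init__(self) -> None:
        for name in ("max_abs_translation_mm", "max_abs_rotation_deg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def n_pairs(n_regions: int) -> int:
    """Number of distinct region pairs, R(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def pearson_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Sample Pearson correlation between every pair of regional time courses.

    Returns a symmetric R x R matrix with unit diagonal. A region whose
    signal is constant over time has no defined correlation and raises,
    naming the region.
    """
    sd = ts.data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.region_labels[i] for i in bad)
        raise ValueError(
            f"subject {ts.subject_id!r}: zero-variance time series in region(s) {names}"
        )
    mat = np.corrcoef(ts.data, rowvar=False)
    # guard rounding just outside [-1, 1]
    np.clip(mat, -1.0, 1.0, out=mat)
    np.fill_diagonal(mat, 1.0)
    return mat


def vectorize_upper(mat: np.ndarray) -> ConnectivityVector:
    """Flatten a symmetric correlation matrix into the frozen pair order."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(mat - mat.T)) > _SYMMETRY_TOL:
        raise ValueError("matrix is not symmetric within 1e-10")
    r = mat.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    return ConnectivityVector(values=mat[iu, ju], n_regions=r)


def connectivity_vector(ts: RoiTimeSeries) -> ConnectivityVector:
    """Convenience composition: ``vectorize_upper(pearson_matrix(ts))``."""
    return vectorize_upper(pearson_matrix(ts))


def index_of_pair(i: int, j: int, n_regions: int) -> int:
    """Feature index of region pair (i, j), 0-based, under the frozen order."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"need 0 <= i < j < R, got i={i}, j={j}, R={n_regions}")
    # pairs with first element < i come first: sum_{a<i} (R-1-a)
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


def pair_of_index(idx: int, n_regions: int) -> tuple[int, int]:
    """Inverse of :func:`index_of_pair`: region pair for a feature index."""
    total = n_pairs(n_regions)
    if not (0 <= idx < total):
        raise ValueError(f"feature index {idx} out of range for R={n_regions} (P={total})")
    i = 0
    remaining = idx
    row_len = n_regions - 1
    while remaining >= row_len:
        remaining -= row_len
        i += 1
        row_len -= 1
    return i, i + 1 + remaining


def pair_labels(region_labels: Sequence[str]) -> list[str]:
    """Feature names ``"<regA>__<regB>"`` in the frozen pair order."""
    r = len(region_labels)
    iu, ju = np.triu_indices(r, k=1)
    return [f"{region_labels[i]}__{region_labels[j]}" for i, j in zip(iu, ju)]


def motion_qc(
    m: MotionSummary, trans_limit: float = 2.0, rot_limit: float = 2.0
) -> bool:
    """Head-motion inclusion rule: True = keep the subject.

    A subject is excluded only when translation strictly exceeds
    ``trans_limit`` mm or rotation strictly exceeds ``rot_limit`` degrees;
    a scan exactly at the limit is kept.
    """
    return not (
        m.max_abs_translation_mm > trans_limit or m.max_abs_rotation_deg > rot_limit
    )


# ---------------------------------------------------------------------------
# Text I/O: per-subject time-series CSVs and subjects x features matrices
# ---------------------------------------------------------------------------

def read_timeseries_csv(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a T x R delimited table with a header row of region labels."""
    df = pd.read_csv(path)
    return RoiTimeSeries(
        subject_id=subject_id or Path(path).stem,
        data=df.to_numpy(dtype=float),
        region_labels=[str(c) for c in df.columns],
    )


def write_feature_matrix(
    path: str | Path,
    vectors: Iterable[ConnectivityVector],
    subject_ids: Sequence[str],
    region_labels: Sequence[str],
) -> pd.DataFrame:
    """Write a subjects x P feature matrix CSV with pair-named columns."""
    rows = [v.values for v in vectors]
    df = pd.DataFrame(rows, index=list(subject_ids), columns=pair_labels(region_labels))
    df.index.name = "subject_id"
    df.to_csv(path)
    return df


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    return pd.read_csv(path, index_col=0)
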