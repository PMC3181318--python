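"""Category matrices and Euclidean site-dissimilarity matrices.

Each measured category (resources RES, composition BCC, single-cell
characteristics SCC, physiological structure PS, metabolism BCM) is a
site-date × variable table. Before distances are taken the table is
normalized (optional per-variable log10 transform to tame skew) and
standardized (per-variable z-scores pooled over all site-dates, so that
dissimilarities are comparable across transitions), and then converted to a
Euclidean site-dissimilarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CategoryMatrix",
    "normalize_columns",
    "standardize_columns",
    "euclidean_distance_matrix",
]

_STAGES = ("raw", "normalized", "standardized")


@dataclass(frozen=True)
class CategoryMatrix:
    """A site-date × variable table for one measured category.

    ``stage`` tracks the processing state: ``raw`` → ``normalized`` (log
    transforms applied) → ``standardized`` (per-column z-scores).
    Rows with any missing variable are dropped (with a warning) before
    standardization, since Euclidean distances need complete rows.
    """

    category: str
    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")

    @property
    def site_date_ids(self) -> pd.Index:
        return self.data.index


def normalize_columns(
    matrix: CategoryMatrix,
    transform_map: dict[str, str] | None = None,
    shift: float = 0.0,
) -> CategoryMatrix:
    """Apply per-variable normalizing transforms.

    ``transform_map`` maps variable name → ``"identity"`` or ``"log10_shift"``
    (replace x by log10(x + shift)); unlisted variables are left unchanged.

    Raises
    ------
    ValueError
        If a log-flagged column has a non-positive minimum after the shift,
        naming the variable.
    """
    if matrix.stage != "raw":
        raise ValueError(f"normalize_columns expects a raw matrix, got {matrix.stage!r}")
    transform_map = transform_map or {}
    data = matrix.data.copy()
    for col, tf in transform_map.items():
        if col not in data.columns:
            raise KeyError(f"unknown variable {col!r} in transform map for {matrix.category}")
        if tf == "identity":
            continue
        if tf == "log10_shift":
            shifted = data[col] + shift
            if (shifted <= 0).any():
                raise ValueError(
                    f"variable {col!r} has non-positive values under log10 (shift={shift})"
                )
            data[col] = np.log10(shifted)
        else:
            raise ValueError(f"unknown transform {tf!r} for variable {col!r}")
    return replace(matrix, data=data, stage="normalized")


def standardize_columns(matrix: CategoryMatrix) -> CategoryMatrix:
    """Z-score every variable (sample SD, n−1) over all site-dates pooled.

    Missing rows are dropped first with a logged warning. Raises on
    zero-variance columns, naming the variable.
    """
    if matrix.stage == "standardized":
        raise ValueError("matrix is already standardized")
    data = matrix.data
    complete = data.dropna(axis=0, how="any")
    if len(complete) < len(data):
        dropped = data.index.difference(complete.index)
        log.warning(
            "%s: dropped %d incomplete row(s): %s",
            matrix.category, len(dropped), list(dropped),
        )
    sd = complete.std(ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()]
    if len(degenerate):
        raise ValueError(
            f"zero-variance column(s) in {matrix.category}: {list(degenerate)}"
        )
    z = (complete - complete.mean()) / sd
    return replace(matrix, data=z, stage="standardized")


def euclidean_distance_matrix(matrix: CategoryMatrix) -> DistanceMatrix:
    """Euclidean site-dissimilarity matrix of a standardized category table.

    Entry (i, j) = sqrt(Σ_k (x_ik − x_jk)²). Returned as a
    :class:`skbio.DistanceMatrix` keyed by site-date ids (which enforces
    symmetry and a zero diagonal).
    """
    if matrix.stage != "standardized":
        raise ValueError("distances are computed on standardized matrices")
    if matrix.data.empty:
        raise ValueError(f"empty matrix for category {matrix.category}")
    d = squareform(pdist(matrix.data.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in matrix.data.index])
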