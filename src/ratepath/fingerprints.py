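"""Composition metrics from band-intensity fingerprints.

A community fingerprint (e.g. a DGGE lane) is a vector of non-negative band
intensities, one per matched band position; a :class:`pandas.DataFrame` with
site-date row ids and band-id columns holds one study's worth of lanes.
Three quantities are computed from it:

* the relative contribution of each band to the total lane intensity,
* the Shannon diversity H' = −Σ p ln p of those relative intensities, and
* presence–absence band turnover between a transition's head site and a
  downstream site (bands gained or lost versus bands shared).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

__all__ = [
    "EmptyLaneError",
    "relative_intensities",
    "shannon_index",
    "band_turnover",
    "relative_intensity_table",
    "shannon_series",
]


class EmptyLaneError(ValueError):
    """Raised for a lane with no positive band intensity."""


def relative_intensities(row) -> np.ndarray:
    """Proportion of total lane intensity contributed by each band.

    Zeros are preserved; the output sums to 1.

    Raises
    ------
    EmptyLaneError
        If no band has positive intensity.
    ValueError
        If any intensity is negative.
    """
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise ValueError("band intensities must be non-negative")
    total = x.sum()
    if total <= 0:
        raise EmptyLaneError("lane has no positive band intensity")
    return x / total


def shannon_index(proportions, base: float = np.e) -> float:
    """Shannon diversity H' = −Σ p·log p over positive relative intensities.

    Parameters
    ----------
    proportions:
        Relative band intensities summing to 1 (0·log 0 is taken as 0).
    base:
        Logarithm base; natural log by default.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.6g})")
    # scipy's entropy renormalizes and handles 0·log 0 = 0
    return float(_entropy(p, base=base))


def band_turnover(head_row, site_row, presence_threshold: float = 0.0) -> tuple[int, int]:
    """Presence–absence band turnover between a head lane and a site lane.

    A band is *present* when its intensity exceeds ``presence_threshold``.

    Returns
    -------
    (n_shared, n_changed):
        ``n_shared`` bands present in both lanes; ``n_changed`` bands present
        in exactly one of the two (gained or lost relative to the head).

    Raises
    ------
    ValueError
        If the two lanes do not share the same band index space.
    """
    h = np.asarray(head_row, dtype=float)
    s = np.asarray(site_row, dtype=float)
    if isinstance(head_row, pd.Series) and isinstance(site_row, pd.Series):
        if not head_row.index.equals(site_row.index):
            raise ValueError("lanes are indexed by different band sets")
    if h.shape != s.shape:
        raise ValueError(f"lanes have different band counts ({h.size} vs {s.size})")
    ph = h > presence_threshold
    ps = s > presence_threshold
    n_shared = int((ph & ps).sum())
    n_changed = int((ph ^ ps).sum())
    return n_shared, n_changed


def relative_intensity_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Row-wise relative intensities for a whole band table."""
    out = bands.apply(lambda r: pd.Series(relative_intensities(r), index=bands.columns), axis=1)
    return out


def shannon_series(bands: pd.DataFrame, base: float = np.e) -> pd.Series:
    """Shannon H' per lane of a band table."""
    return bands.apply(lambda r: shannon_index(relative_intensities(r), base=base), axis=1)
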