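"""Rates of change along environmental transitions.

The core statistic: for one transition on one date, plot the dissimilarity
between the head (first) site and each successive site against the water
transit time (hours) and take the ordinary-least-squares slope as the rate
of change of that category, in dissimilarity·h⁻¹. Abundance uses the raw
difference to the head site instead of a dissimilarity; diversity (ΔH') and
band-pattern turnover rates are computed the same way but are kept out of
the path models.

`build_rate_table` assembles one row per transition × date with all rate
columns plus provenance (points per slope, r² per slope); `rate_regression`
reproduces the cross-rate log-log regressions between rate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .fingerprints import band_turnover, relative_intensity_table, shannon_series
from .matrices import (
    CategoryMatrix,
    euclidean_distance_matrix,
    normalize_columns,
    standardize_columns,
)

log = logging.getLogger(__name__)

__all__ = [
    "TransitionSeries",
    "RateTable",
    "RegressionResult",
    "head_dissimilarity_series",
    "rate_of_change",
    "fit_rate_series",
    "abundance_rate",
    "diversity_and_banding_rates",
    "build_rate_table",
    "rate_regression",
    "plot_rate_regression",
]

#: Rate columns that may enter path models.
SEM_COLUMNS = ("dRES", "dBCC", "dSCC", "dPS", "dBA", "dBCM")
#: Rate columns excluded from path models by design.
NON_SEM_COLUMNS = ("dH", "dBANDS")


@dataclass(frozen=True)
class TransitionSeries:
    """Ordered sites of one environmental transition on one sampling date.

    ``site_date_ids`` are row labels into the category matrices;
    ``transit_times`` are cumulative water transit times in hours, starting
    at 0 at the head site and strictly increasing downstream.
    """

    transition_id: str
    date: str
    site_date_ids: tuple[str, ...]
    transit_times: tuple[float, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.site_date_ids)
        tt = tuple(float(t) for t in self.transit_times)
        object.__setattr__(self, "site_date_ids", ids)
        object.__setattr__(self, "transit_times", tt)
        if len(ids) != len(tt):
            raise ValueError("site_date_ids and transit_times differ in length")
        if len(ids) < 2:
            raise ValueError(f"transition {self.transition_id!r} needs >=2 sites")
        if tt[0] != 0.0:
            raise ValueError("transit_times must start at 0 at the head site")
        if any(b <= a for a, b in zip(tt, tt[1:])):
            raise ValueError("transit_times must be strictly increasing")

    @property
    def head(self) -> str:
        return self.site_date_ids[0]


@dataclass
class RateTable:
    """One row per transition × date of per-category rates of change.

    ``table`` is indexed by (transition_id, date); ``provenance`` is a long
    table with, per slope, the supporting point count and r².
    """

    table: pd.DataFrame
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transition_id", "date", "column", "n", "r2"]
        )
    )

    def sem_data(self, columns=SEM_COLUMNS) -> pd.DataFrame:
        """The six rate columns that feed the path models."""
        missing = [c for c in columns if c not in self.table.columns]
        if missing:
            raise KeyError(f"rate table lacks column(s) {missing}")
        return self.table.loc[:, list(columns)]


def head_dissimilarity_series(
    d: DistanceMatrix, t: TransitionSeries
) -> list[tuple[float, float]]:
    """(transit time, dissimilarity-to-head) pairs along one transition.

    The first pair is (0, 0) by construction. Raises ``KeyError`` naming any
    site absent from the dissimilarity matrix.
    """
    known = set(d.ids)
    for sid in t.site_date_ids:
        if sid not in known:
            raise KeyError(
                f"site {sid!r} of transition {t.transition_id!r} not in dissimilarity matrix"
            )
    head = t.head
    return [(tt, float(d[head, sid])) for sid, tt in zip(t.site_date_ids, t.transit_times)]


def rate_of_change(
    series: list[tuple[float, float]], through_origin: bool = False
) -> tuple[float, float, int]:
    """OLS slope of value against transit time: the rate of change per hour.

    Returns ``(slope, r2, n)``. With ``through_origin`` the intercept is
    forced to 0 (slope = Σty/Σt²); by default the intercept is free.

    Raises
    ------
    ValueError
        With fewer than 2 points or all time values equal.
    """
    if len(series) < 2:
        raise ValueError("rate_of_change needs at least 2 points")
    t = np.asarray([p[0] for p in series], dtype=float)
    y = np.asarray([p[1] for p in series], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all transit times equal")
    if through_origin:
        slope = float(t @ y / (t @ t))
        fitted = slope * t
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return slope, r2, len(t)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else np.nan
    return float(res.slope), r2, len(t)


def fit_rate_series(
    series: list[tuple[float, float]],
    include_head: bool = False,
    through_origin: bool = False,
) -> tuple[float, float, int]:
    """Fit a difference-to-head series, handling the structural head anchor.

    Difference and dissimilarity series start at the structural point (0, 0).
    Anchoring the fit there biases the slope upward under pure noise (every
    downstream value sits a positive nugget above the head), so by default
    the head pair is dropped and the free intercept absorbs the nugget;
    2-point series keep the head (the fit is then the finite difference).
    ``include_head=True`` restores the anchored fit.
    """
    use = series if (include_head or len(series) <= 2) else series[1:]
    return rate_of_change(use, through_origin=through_origin)


def abundance_rate(
    abundances,
    t: TransitionSeries,
    include_head: bool = False,
    through_origin: bool = False,
) -> tuple[float, float, int]:
    """Rate of change of abundance: OLS slope of (Nᵢ − N_head) vs transit time."""
    a = np.asarray(abundances, dtype=float)
    if a.size != len(t.site_date_ids):
        raise ValueError("one abundance per site is required")
    diffs = a - a[0]
    series = list(zip(t.transit_times, diffs))
    return fit_rate_series(series, include_head=include_head,
                           through_origin=through_origin)


def diversity_and_banding_rates(
    bands: pd.DataFrame,
    t: TransitionSeries,
    presence_threshold: float = 0.0,
    include_head: bool = False,
    through_origin: bool = False,
) -> tuple[tuple[float, float, int], tuple[float, float, int]]:
    """Rates of change of Shannon diversity and of the banding pattern.

    ΔH': OLS slope of (H'ᵢ − H'_head) vs transit time. ΔBANDS: OLS slope of
    the count of bands present in exactly one of (head, site) vs transit
    time. Both are descriptive companions to dBCC and are excluded from the
    path models.
    """
    lanes = bands.loc[list(t.site_date_ids)]
    h = shannon_series(lanes).to_numpy()
    h_series = list(zip(t.transit_times, h - h[0]))
    head_lane = lanes.iloc[0]
    changed = [
        float(band_turnover(head_lane, lanes.iloc[i], presence_threshold)[1])
        for i in range(len(lanes))
    ]
    b_series = list(zip(t.transit_times, changed))
    return (
        fit_rate_series(h_series, include_head=include_head,
                        through_origin=through_origin),
        fit_rate_series(b_series, include_head=include_head,
                        through_origin=through_origin),
    )


def _single_column_matrix(category: CategoryMatrix, variable: str) -> CategoryMatrix:
    if variable not in category.data.columns:
        raise KeyError(f"variable {variable!r} not in category {category.category}")
    return CategoryMatrix(
        category=f"{category.category}:{variable}",
        data=category.data[[variable]],
        stage=category.stage,
    )


def build_rate_table(
    categories: dict[str, CategoryMatrix],
    bands: pd.DataFrame,
    transitions: list[TransitionSeries],
    transform_map: dict[str, dict[str, str]] | None = None,
    single_resource: str | None = None,
    presence_threshold: float = 0.0,
    include_head: bool = False,
    through_origin: bool = False,
) -> RateTable:
    """Assemble the full transition × date rate table.

    Parameters
    ----------
    categories:
        Raw :class:`CategoryMatrix` per category name. ``RES``, ``SCC``,
        ``PS`` and ``BCM`` go through normalize → standardize → Euclidean
        dissimilarity; ``BA`` must be a single-column raw abundance table.
    bands:
        Band-intensity table (site-date × band); its row-wise relative
        intensities, standardized, stand in for the BCC category.
    transform_map:
        Per-category variable → transform maps for :func:`normalize_columns`.
    single_resource:
        Optional resource variable name (e.g. ``"DOC"``): adds a
        ``d<NAME>`` column computed from that variable's one-column
        dissimilarity, for single-driver analyses.

    Returns
    -------
    RateTable
        One row per transition × date; columns dRES, dBCC, dSCC, dPS, dBA,
        dBCM, dH, dBANDS (+ the optional single-resource column), with
        per-slope provenance.
    """
    transform_map = transform_map or {}
    dissim: dict[str, DistanceMatrix] = {}
    normalized: dict[str, CategoryMatrix] = {}
    for name in ("RES", "SCC", "PS", "BCM"):
        if name not in categories:
            raise KeyError(f"missing category {name!r}")
        norm = normalize_columns(categories[name], transform_map.get(name))
        normalized[name] = norm
        dissim[name] = euclidean_distance_matrix(standardize_columns(norm))

    rel = relative_intensity_table(bands)
    informative = rel.columns[rel.std(ddof=1) > 0]
    if len(informative) < rel.shape[1]:
        log.info("BCC: dropping %d constant band column(s)",
                 rel.shape[1] - len(informative))
    rel = rel.loc[:, informative]
    bcc_matrix = CategoryMatrix("BCC", rel, stage="normalized")
    dissim["BCC"] = euclidean_distance_matrix(standardize_columns(bcc_matrix))

    if "BA" not in categories:
        raise KeyError("missing category 'BA'")
    ba = categories["BA"].data
    if ba.shape[1] != 1:
        raise ValueError("BA category must have exactly one abundance column")

    extra_col = None
    if single_resource is not None:
        single = _single_column_matrix(normalized["RES"], single_resource)
        dissim[single_resource] = euclidean_distance_matrix(standardize_columns(single))
        extra_col = f"d{single_resource}"

    rows: list[dict] = []
    prov: list[dict] = []
    for t in transitions:
        row: dict = {"transition_id": t.transition_id, "date": t.date}

        def _record(col: str, est: tuple[float, float, int]) -> None:
            slope, r2, n = est
            row[col] = slope
            prov.append(
                {"transition_id": t.transition_id, "date": t.date,
                 "column": col, "n": n, "r2": r2}
            )

        for name, col in (("RES", "dRES"), ("BCC", "dBCC"), ("SCC", "dSCC"),
                          ("PS", "dPS"), ("BCM", "dBCM")):
            series = head_dissimilarity_series(dissim[name], t)
            _record(col, fit_rate_series(series, include_head=include_head,
                                         through_origin=through_origin))
        missing_ba = [s for s in t.site_date_ids if s not in ba.index]
        if missing_ba:
            raise KeyError(f"site(s) {missing_ba} missing from BA table")
        _record("dBA", abundance_rate(
            ba.loc[list(t.site_date_ids)].iloc[:, 0].to_numpy(), t,
            include_head=include_head, through_origin=through_origin))
        if extra_col is not None:
            series = head_dissimilarity_series(dissim[single_resource], t)
            _record(extra_col, fit_rate_series(series, include_head=include_head,
                                               through_origin=through_origin))
        h_est, b_est = diversity_and_banding_rates(
            bands, t, presence_threshold=presence_threshold,
            include_head=include_head, through_origin=through_origin)
        _record("dH", h_est)
        _record("dBANDS", b_est)
        rows.append(row)

    table = pd.DataFrame(rows).set_index(["transition_id", "date"])
    order = [c for c in ("dRES", "dBCC", "dSCC", "dPS", "dBA", "dBCM") if c in table]
    rest = [c for c in table.columns if c not in order]
    return RateTable(table=table[order + rest], provenance=pd.DataFrame(prov))


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit between two rate columns (optionally log10-log10)."""

    x: str
    y: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_used: int
    n_excluded: int
    log10: bool


def rate_regression(
    rt: RateTable, x: str, y: str, log10: bool = True
) -> RegressionResult:
    """Cross-rate OLS regression of column ``y`` on column ``x``.

    Under ``log10`` both columns are log10-transformed and rows with a
    non-positive rate in either column are excluded (and counted), since
    negative OLS slopes on noisy dissimilarities have no logarithm.

    Raises
    ------
    ValueError
        With fewer than 3 usable rows.
    """
    data = rt.table[[x, y]].dropna()
    n_total = len(data)
    if log10:
        usable = data[(data[x] > 0) & (data[y] > 0)]
        xs, ys = np.log10(usable[x]), np.log10(usable[y])
    else:
        usable = data
        xs, ys = usable[x], usable[y]
    n_used = len(usable)
    if n_used < 3:
        raise ValueError(
            f"insufficient data for regression {y} ~ {x}: {n_used} usable rows"
        )
    res = stats.linregress(xs.to_numpy(), ys.to_numpy())
    return RegressionResult(
        x=x, y=y, slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p_value=float(res.pvalue),
        n_used=n_used, n_excluded=n_total - n_used, log10=log10,
    )


def plot_rate_regression(rt: RateTable, x: str, y: str, log10: bool = True, ax=None):
    """Scatter of rate column ``y`` against ``x`` with the OLS fit line."""
    import matplotlib.pyplot as plt

    reg = rate_regression(rt, x, y, log10=log10)
    data = rt.table[[x, y]].dropna()
    if log10:
        data = data[(data[x] > 0) & (data[y] > 0)]
        xs, ys = np.log10(data[x]), np.log10(data[y])
        xlab, ylab = f"log10 {x}", f"log10 {y}"
    else:
        xs, ys = data[x], data[y]
        xlab, ylab = x, y
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xs, ys, s=25, alpha=0.7, edgecolor="k", linewidth=0.3)
    grid = np.linspace(xs.min(), xs.max(), 50)
    ax.plot(grid, reg.intercept + reg.slope * grid, color="C3")
    ax.set_xlabel(f"{xlab} (h$^{{-1}}$)")
    ax.set_ylabel(f"{ylab} (h$^{{-1}}$)")
    ax.set_title(f"slope={reg.slope:.2f}, r$^2$={reg.r2:.2f}, n={reg.n_used}")
    return ax
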