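"""Reading and writing the pipeline's plain-text formats.

Everything is CSV/TSV + JSON/YAML: category tables (site_date_id × named
variables), a band table (site_date_id × band ids), a transitions metadata
table (transition_id, date, site_id, order, transit_time_h), the DAG
library JSON, and a run configuration (YAML or JSON).

``site_date_id`` is ``"<site_id>@<date>"`` throughout; readers cross-check
row ids between files and fail on orphans.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .matrices import CategoryMatrix
from .rates import RateTable, TransitionSeries
from .simulate import SimulatedDataset

__all__ = [
    "RunConfig",
    "read_category_tables",
    "write_dataset",
    "write_rate_table",
    "read_rate_table",
    "load_run_config",
    "config_hash",
]

CATEGORY_NAMES = ("RES", "SCC", "PS", "BCM", "BA")
TRANSITIONS_COLUMNS = ("transition_id", "date", "site_id", "order", "transit_time_h")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_category_tables(
    category_paths: dict[str, str | Path],
    bands_path: str | Path,
    transitions_path: str | Path,
) -> tuple[dict[str, CategoryMatrix], pd.DataFrame, list[TransitionSeries]]:
    """Load and cross-validate one study's input files.

    ``category_paths`` maps category name → CSV/TSV path; each table must
    have a ``site_date_id`` column. The transitions table must carry the
    columns ``transition_id, date, site_id, order, transit_time_h``; its
    implied ``site_id@date`` ids must all resolve in every category table
    and in the band table.

    Raises
    ------
    ValueError
        On schema mismatch or referential-integrity failure, naming the
        offending column or site-date id.
    """
    categories: dict[str, CategoryMatrix] = {}
    for name, path in category_paths.items():
        df = _read_table(path)
        if "site_date_id" not in df.columns:
            raise ValueError(f"{name} table {path} lacks a 'site_date_id' column")
        categories[name] = CategoryMatrix(name, df.set_index("site_date_id"), stage="raw")

    bands_df = _read_table(bands_path)
    if "site_date_id" not in bands_df.columns:
        raise ValueError(f"band table {bands_path} lacks a 'site_date_id' column")
    bands = bands_df.set_index("site_date_id")

    tdf = _read_table(transitions_path)
    missing_cols = [c for c in TRANSITIONS_COLUMNS if c not in tdf.columns]
    if missing_cols:
        raise ValueError(f"transitions table lacks column(s) {missing_cols}")

    transitions: list[TransitionSeries] = []
    for (tid, date), grp in tdf.groupby(["transition_id", "date"], sort=True):
        grp = grp.sort_values("order")
        ids = tuple(f"{sid}@{date}" for sid in grp["site_id"])
        transitions.append(
            TransitionSeries(str(tid), str(date), ids, tuple(grp["transit_time_h"]))
        )

    all_ids = {sid for t in transitions for sid in t.site_date_ids}
    for name, cm in categories.items():
        orphans = sorted(all_ids - set(cm.data.index.astype(str)))
        if orphans:
            raise ValueError(f"site-date id(s) {orphans[:5]} missing from {name} table")
    orphans = sorted(all_ids - set(bands.index.astype(str)))
    if orphans:
        raise ValueError(f"site-date id(s) {orphans[:5]} missing from band table")
    return categories, bands, transitions


def write_dataset(sim: SimulatedDataset, outdir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write a simulated dataset in the same formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    paths: dict[str, Path] = {}
    for name, cm in sim.categories.items():
        p = outdir / f"{name}{ext}"
        cm.data.rename_axis("site_date_id").to_csv(p, sep=sep)
        paths[name] = p
    p = outdir / f"bands{ext}"
    sim.bands.rename_axis("site_date_id").to_csv(p, sep=sep)
    paths["bands"] = p

    rows = []
    for t in sim.transitions:
        for order, (sid, tt) in enumerate(zip(t.site_date_ids, t.transit_times)):
            rows.append(
                {"transition_id": t.transition_id, "date": t.date,
                 "site_id": sid.split("@")[0], "order": order, "transit_time_h": tt}
            )
    p = outdir / "transitions.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["transitions"] = p
    return paths


def write_rate_table(rt: RateTable, csv_path: str | Path, provenance_path: str | Path | None = None) -> None:
    """Rate table as CSV plus a JSON provenance sidecar (per-slope n, r²)."""
    rt.table.to_csv(csv_path)
    if provenance_path is not None:
        records = rt.provenance.to_dict(orient="records")
        Path(provenance_path).write_text(json.dumps(records, indent=1, allow_nan=True))


def read_rate_table(csv_path: str | Path, provenance_path: str | Path | None = None) -> RateTable:
    table = pd.read_csv(csv_path).set_index(["transition_id", "date"])
    prov = pd.DataFrame(columns=["transition_id", "date", "column", "n", "r2"])
    if provenance_path is not None and Path(provenance_path).exists():
        prov = pd.DataFrame(json.loads(Path(provenance_path).read_text()))
    return RateTable(table=table, provenance=prov)


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    # input: either paths to measured tables, or a simulation section
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # category name -> path, plus bands/transitions
    transform_map: dict = field(default_factory=dict)
    single_resource: str | None = None
    presence_threshold: float = 0.0
    through_origin: bool = False
    alpha: float = 0.05
    library_path: str | None = None
    subset_modes: list = field(default_factory=list)
    min_subset_n: int = 10
    exog_free_cov: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 stamp of the resolved configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
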