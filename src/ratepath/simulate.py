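"""Synthetic data with known causal structure.

Two generators make every downstream stage testable without field data:

* :func:`sample_rate_sem` draws rate-table rows directly from a
  linear-Gaussian recursive system over the six rate variables — the
  ground-truth sampler for calibrating and power-testing the path-model
  engine.
* :func:`simulate_transition_dataset` emulates the study design itself:
  13 environmental transitions sampled on 3 dates, each an ordered series
  of sites with known water transit times, where resources drift along the
  transition with a per-transition gradient intensity and the downstream
  categories (composition, single-cell characteristics, physiological
  structure, abundance, metabolism) respond through a chosen causal DAG.
  Community composition is emitted as a band-intensity fingerprint whose
  behaviour realizes one of two scenarios: *adjustment* re-weights a fixed
  band set (relative intensities shift, identities do not), *replacement*
  progressively swaps the identities of the dominant bands along the
  transition.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``: one child stream per transition (band
structure) and one grandchild per transition × date (scores and noise), so
any fixed seed reproduces every table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dags import PathDAG, build_model_library, validate_dag
from .matrices import CategoryMatrix
from .rates import TransitionSeries

__all__ = [
    "SEMParameters",
    "CommunitySimConfig",
    "SimulatedDataset",
    "sample_rate_sem",
    "simulate_transition_dataset",
    "scenario_truth",
    "uniform_edge_coefficients",
]

#: Variable loadings used to materialize each multivariate category.
_CATEGORY_LOADINGS = {
    "RES": {"DOC": 1.0, "TP": 0.8, "TN": 0.6},
    "SCC": {"scc_fl1": 1.0, "scc_fl2": -0.8, "scc_ssc": 0.6},
    "PS": {"ps_hna": 1.0, "ps_ctc": 0.7, "ps_live": -0.5},
    "BCM": {"bcm_bp": 1.0, "bcm_bgr": 0.8, "bcm_resp": 0.6},
}

_NODE_OF_CATEGORY = {
    "RES": "dRES", "SCC": "dSCC", "PS": "dPS", "BCM": "dBCM",
    "BA": "dBA", "BCC": "dBCC",
}


def uniform_edge_coefficients(dag: PathDAG, value: float = 0.7) -> dict:
    """The same standardized coefficient on every edge of ``dag``."""
    return {e: float(value) for e in dag.edges}


@dataclass(frozen=True)
class SEMParameters:
    """Generating parameters of a linear-Gaussian recursive system.

    ``edge_coefficients`` maps (parent, child) edges to standardized path
    coefficients; ``residual_sd`` gives each *endogenous* node's error SD
    (exogenous nodes are drawn standard normal; their entries are accepted
    but unused).
    """

    dag: PathDAG
    edge_coefficients: dict
    residual_sd: dict
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        edges = set(self.dag.edges)
        for e in self.edge_coefficients:
            if tuple(e) not in edges:
                raise KeyError(f"coefficient for unknown edge {e!r} of {self.dag.name!r}")
        missing = [e for e in edges if tuple(e) not in
                   {tuple(k) for k in self.edge_coefficients}]
        if missing:
            raise KeyError(f"missing coefficient(s) for edge(s) {missing}")
        nodes = set(self.dag.nodes)
        for v, sd in self.residual_sd.items():
            if v not in nodes:
                raise KeyError(f"residual SD for unknown node {v!r}")
            if sd < 0:
                raise ValueError(f"negative residual SD for node {v!r}")
        for v in nodes:
            if self.dag.parents(v) and v not in self.residual_sd:
                raise KeyError(f"no residual SD for endogenous node {v!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def sample_rate_sem(params: SEMParameters) -> pd.DataFrame:
    """Draw rate-table rows from the linear-Gaussian system of ``params``.

    Nodes are generated in topological order: exogenous nodes as standard
    normals, endogenous nodes as the coefficient-weighted sum of their
    parents plus Gaussian noise with the node's residual SD. A fixed seed
    gives identical output.
    """
    order = validate_dag(params.dag, enforce_roles=False)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_samples
    coef = {tuple(k): v for k, v in params.edge_coefficients.items()}
    cols: dict[str, np.ndarray] = {}
    for v in order:
        parents = params.dag.parents(v)
        if not parents:
            cols[v] = rng.standard_normal(n)
        else:
            mean = np.zeros(n)
            for u in parents:
                mean += coef[(u, v)] * cols[u]
            cols[v] = mean + params.residual_sd[v] * rng.standard_normal(n)
    return pd.DataFrame({v: cols[v] for v in params.dag.nodes})


@dataclass
class CommunitySimConfig:
    """Configuration of the community-level transition simulator.

    Defaults mirror the emulated study design: 13 transitions × 3 sampling
    dates, 4 sites per transition with transit times up to 36 h, gradient
    intensities spanning roughly an order of magnitude across transitions,
    and seasonal (per-date) modulation of gradient strength.
    """

    n_transitions: int = 13
    sites_per_transition: int = 4
    transit_times: Sequence[float] = (0.0, 6.0, 18.0, 36.0)
    gradient_intensity: float | Sequence[float] | None = None
    scenario: str = "adjustment"
    generating_dag: PathDAG | None = None
    edge_coefficients: float | dict = 0.7
    n_bands_pool: int = 40
    n_active_bands: int = 12
    top_k_dominant: int = 5
    turnover_fraction: float = 0.6
    noise_sd: float = 0.3
    dates: Sequence[str] = ("jun", "jul", "aug")
    date_factors: Sequence[float] | None = (0.7, 1.0, 1.3)
    driver_resource: str | None = None
    ba_base: float = 1.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_transition < 2:
            raise ValueError("sites_per_transition must be >= 2")
        tt = tuple(float(t) for t in self.transit_times)
        if len(tt) != self.sites_per_transition:
            raise ValueError("transit_times must give one time per site")
        if tt[0] != 0.0 or any(b <= a for a, b in zip(tt, tt[1:])):
            raise ValueError("transit_times must start at 0 and strictly increase")
        self.transit_times = tt
        if self.scenario not in ("adjustment", "replacement"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.turnover_fraction <= 1.0:
            raise ValueError("turnover_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_bands_pool < self.n_active_bands + self.top_k_dominant:
            raise ValueError("band pool too small for active set plus turnover reserve")
        g = self.gradient_intensity
        if g is None:
            g = np.geomspace(0.25, 4.0, self.n_transitions)
        g = np.broadcast_to(np.asarray(g, dtype=float), (self.n_transitions,)).copy()
        if (g < 0).any():
            raise ValueError("gradient_intensity must be >= 0")
        self.gradient_intensity = g
        df = self.date_factors
        if df is None:
            df = np.ones(len(self.dates))
        df = np.broadcast_to(np.asarray(df, dtype=float), (len(self.dates),)).copy()
        self.date_factors = df

    def resolve_dag(self) -> PathDAG:
        if self.generating_dag is not None:
            return self.generating_dag
        wanted = "B-DAG4" if self.scenario == "adjustment" else "A-DAG4"
        return next(d for d in build_model_library() if d.name == wanted)

    def resolve_coefficients(self, dag: PathDAG) -> dict:
        if isinstance(self.edge_coefficients, dict):
            return {tuple(k): float(v) for k, v in self.edge_coefficients.items()}
        return uniform_edge_coefficients(dag, float(self.edge_coefficients))


def scenario_truth(config: CommunitySimConfig) -> PathDAG:
    """The generating DAG of a configuration (validated), for recovery tests."""
    dag = config.resolve_dag()
    validate_dag(dag)
    return dag


@dataclass
class SimulatedDataset:
    """Everything one simulated study emits."""

    transitions: list[TransitionSeries]
    categories: dict[str, CategoryMatrix]
    bands: pd.DataFrame
    config: CommunitySimConfig
    dag: PathDAG

    def default_transform_map(self) -> dict[str, dict[str, str]]:
        """Log10 transforms for the positively-skewed metabolism variables."""
        return {"BCM": {c: "log10_shift" for c in _CATEGORY_LOADINGS["BCM"]}}


def _node_scores(
    dag: PathDAG,
    coef: dict,
    drive: np.ndarray,
    tau: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Node scores along one transition: dRES carries the resource drive;
    endogenous nodes are the coefficient-weighted sums of their parents;
    exogenous non-RES nodes (e.g. composition in structures where it is
    independent of the gradient) drift with their own random slope, drawn
    per transition-date, uncorrelated with the resource drive."""
    order = validate_dag(dag, enforce_roles=False)
    scores: dict[str, np.ndarray] = {}
    for v in order:
        parents = dag.parents(v)
        if v == "dRES":
            scores[v] = drive
        elif not parents:
            scores[v] = float(rng.standard_normal()) * tau
        else:
            s = np.zeros_like(drive)
            for u in parents:
                s = s + coef[(u, v)] * scores[u]
            scores[v] = s
    return scores


def simulate_transition_dataset(config: CommunitySimConfig) -> SimulatedDataset:
    """Generate one full study: transitions, category tables and band table.

    Along each transition the resource score drifts linearly with transit
    time at a rate set by that transition's gradient intensity (modulated
    per date); downstream category scores propagate through the generating
    DAG; each measured variable is its category score times a fixed loading
    plus Gaussian noise. Abundance and the metabolism variables are
    exponentiated so they stay positive. The band table follows the
    configured scenario (see module docstring).
    """
    dag = scenario_truth(config)
    coef = config.resolve_coefficients(dag)
    ss = np.random.SeedSequence(config.seed)
    trans_seeds = ss.spawn(config.n_transitions)

    tt = np.asarray(config.transit_times)
    tau = tt / tt[-1]
    n_sites = config.sites_per_transition
    pool = [f"band_{i:03d}" for i in range(config.n_bands_pool)]

    transitions: list[TransitionSeries] = []
    cat_rows: dict[str, list[dict]] = {c: [] for c in ("RES", "SCC", "PS", "BCM", "BA")}
    band_rows: list[dict] = []
    index: list[str] = []

    for t_idx in range(config.n_transitions):
        tid = f"T{t_idx + 1:02d}"
        t_ss = trans_seeds[t_idx]
        band_rng = np.random.default_rng(t_ss)
        active = list(band_rng.choice(config.n_bands_pool, config.n_active_bands,
                                      replace=False))
        remaining = [i for i in range(config.n_bands_pool) if i not in active]
        reserve = list(band_rng.choice(remaining, config.top_k_dominant, replace=False))
        base_logits = band_rng.normal(0.0, 1.0, config.n_active_bands)
        drift = band_rng.normal(0.0, 1.0, config.n_active_bands)
        date_seeds = t_ss.spawn(len(config.dates))

        for d_idx, date in enumerate(config.dates):
            rng = np.random.default_rng(date_seeds[d_idx])
            g = config.gradient_intensity[t_idx] * config.date_factors[d_idx]
            drive = g * tau
            scores = _node_scores(dag, coef, drive, tau, rng)

            site_ids = [f"{tid}S{s + 1}@{date}" for s in range(n_sites)]
            transitions.append(TransitionSeries(tid, str(date), tuple(site_ids), tuple(tt)))
            index.extend(site_ids)

            for cat, loadings in _CATEGORY_LOADINGS.items():
                sc = scores[_NODE_OF_CATEGORY[cat]]
                for s in range(n_sites):
                    row: dict = {"site_date_id": site_ids[s]}
                    for var, load in loadings.items():
                        signal = load * sc[s]
                        if cat == "RES" and config.driver_resource is not None:
                            signal = load * sc[s] if var == config.driver_resource else 0.0
                        raw = signal + config.noise_sd * rng.standard_normal()
                        row[var] = float(np.exp(raw)) if cat == "BCM" else float(raw)
                    cat_rows[cat].append(row)
            ba_sc = scores["dBA"]
            for s in range(n_sites):
                raw = 0.4 * ba_sc[s] + config.noise_sd * rng.standard_normal()
                cat_rows["BA"].append(
                    {"site_date_id": site_ids[s], "abundance": float(config.ba_base * np.exp(raw))}
                )

            # band table for this transition-date
            bcc_sc = scores["dBCC"]
            logits = (base_logits[None, :] + bcc_sc[:, None] * drift[None, :]
                      + config.noise_sd * rng.standard_normal((n_sites, config.n_active_bands)))
            expl = np.exp(logits - logits.max(axis=1, keepdims=True))
            intens = 100.0 * expl / expl.sum(axis=1, keepdims=True)
            # dominant bands at the head, most intense first
            dom_order = np.argsort(intens[0])[::-1][: config.top_k_dominant]
            for s in range(n_sites):
                lane = {pool[b]: 0.0 for b in range(config.n_bands_pool)}
                values = intens[s].copy()
                targets = {}
                if config.scenario == "replacement":
                    n_swap = int(round(config.turnover_fraction
                                       * config.top_k_dominant * tau[s]))
                    for j in range(n_swap):
                        targets[dom_order[j]] = reserve[j]
                for j, b in enumerate(active):
                    if j in targets:
                        lane[pool[targets[j]]] = float(values[j])
                    else:
                        lane[pool[b]] = float(values[j])
                lane["site_date_id"] = site_ids[s]
                band_rows.append(lane)

    categories = {
        cat: CategoryMatrix(cat, pd.DataFrame(rows).set_index("site_date_id"), stage="raw")
        for cat, rows in cat_rows.items()
    }
    bands = pd.DataFrame(band_rows).set_index("site_date_id").loc[index]
    bands = bands[pool]
    return SimulatedDataset(
        transitions=transitions, categories=categories, bands=bands,
        config=config, dag=dag,
    )
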