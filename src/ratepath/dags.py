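"""Candidate causal structures over the six rate-of-change variables.

A community response to a resource gradient is modelled as a directed acyclic
graph (DAG) over six rate variables: resources (dRES, the exogenous driver),
community composition (dBCC), single-cell characteristics (dSCC),
physiological structure (dPS), abundance (dBA), and community metabolism
(dBCM, the terminal response). Two broad families of candidate structures are
distinguished by which structural variable responds to resources first:

* **replacement** ("Scenario A") — resources act first on community
  composition (dRES → dBCC): the identity of the dominant phylotypes turns
  over, and the new phylotypes carry different single-cell properties.
* **adjustment** ("Scenario B") — resources act first on single-cell
  characteristics of the standing phylotypes (dRES → dSCC): the community
  re-tunes its activity without replacing its members.

The built-in library of nine candidate DAGs ships as JSON data
(``data/model_library.json``) so that edge sets can be curated without code
changes; :func:`build_model_library` loads it, and any file with the same
schema can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _resources
from pathlib import Path

import networkx as nx

__all__ = [
    "RATE_NODES",
    "PathDAG",
    "CyclicGraphError",
    "validate_dag",
    "model_df",
    "build_model_library",
]

#: Canonical order of the six rate-of-change variables.
RATE_NODES: tuple[str, ...] = ("dRES", "dBCC", "dSCC", "dPS", "dBA", "dBCM")

#: The exogenous driver: resources never have parents.
ROOT_NODE = "dRES"
#: The terminal response: community metabolism never has children.
SINK_NODE = "dBCM"


class CyclicGraphError(ValueError):
    """Raised when a candidate structure contains a directed cycle."""


@dataclass(frozen=True)
class PathDAG:
    """A candidate causal ordering of the six rate variables.

    Parameters
    ----------
    name:
        Library identifier (``A-DAG1`` .. ``B-DAG5``) or a custom label.
    edges:
        Ordered (parent, child) pairs.
    nodes:
        Variable names; defaults to the six rate variables.
    scenario:
        ``"replacement"``, ``"adjustment"`` or ``None`` for custom models.
    """

    name: str
    edges: tuple[tuple[str, str], ...]
    nodes: tuple[str, ...] = RATE_NODES
    scenario: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((str(u), str(v)) for u, v in self.edges))
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in self.edges if v == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for u, v in self.edges if u == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PathDAG({self.name!r}, {self.n_edges} edges)"


def validate_dag(dag: PathDAG, enforce_roles: bool = True) -> list[str]:
    """Validate a candidate structure and return a topological node order.

    Checks: edges reference declared nodes, no self-loops, no duplicate
    edges, acyclicity; and (when ``enforce_roles`` and the node set is the
    standard six) that resources have no parents and metabolism no children.

    Raises
    ------
    CyclicGraphError
        If a directed cycle exists; the message lists the cycle.
    ValueError
        For self-loops, duplicate edges, unknown nodes or role violations.
    """
    known = set(dag.nodes)
    for u, v in dag.edges:
        if u not in known or v not in known:
            raise ValueError(f"edge ({u!r}, {v!r}) references an undeclared node")
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
    if len(set(dag.edges)) != len(dag.edges):
        raise ValueError(f"duplicate edges in {dag.name!r}")

    g = dag.to_networkx()
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise CyclicGraphError(f"cycle detected in {dag.name!r}: {cycle}") from None

    if enforce_roles and set(dag.nodes) == set(RATE_NODES):
        if dag.parents(ROOT_NODE):
            raise ValueError(f"{ROOT_NODE} must be exogenous (has parents in {dag.name!r})")
        if dag.children(SINK_NODE):
            raise ValueError(f"{SINK_NODE} must be terminal (has children in {dag.name!r})")
    return order


def model_df(dag: PathDAG) -> int:
    """Degrees of freedom of the covariance-structure test for ``dag``.

    With ``p`` observed variables there are ``p(p+1)/2`` distinct sample
    moments. The model spends one variance parameter per node (exogenous
    variances plus residual variances) and one path coefficient per edge;
    exogenous variables are assumed mutually uncorrelated, so no covariance
    parameters are spent on them:

        df = p(p+1)/2 − (p + E)

    A six-node model with seven edges therefore has df = 21 − 13 = 8.

    Raises
    ------
    ValueError
        If the model has more parameters than moments (df < 0).
    """
    p = len(dag.nodes)
    df = p * (p + 1) // 2 - (p + dag.n_edges)
    if df < 0:
        raise ValueError(
            f"model {dag.name!r} is over-parameterized: "
            f"{p + dag.n_edges} parameters for {p * (p + 1) // 2} moments"
        )
    return df


def _load_library_json(text: str) -> list[PathDAG]:
    raw = json.loads(text)
    dags = []
    for entry in raw:
        dag = PathDAG(
            name=entry["name"],
            edges=tuple(tuple(e) for e in entry["edges"]),
            scenario=entry.get("scenario"),
        )
        validate_dag(dag)
        dags.append(dag)
    return dags


def build_model_library(path: str | Path | None = None) -> list[PathDAG]:
    """Load the candidate-model library (nine DAGs by default).

    Parameters
    ----------
    path:
        Optional JSON file overriding the built-in library. Schema: a list
        of ``{"name": str, "scenario": str, "edges": [[parent, child], ...]}``.

    Returns
    -------
    list of PathDAG, each validated (acyclic, dRES root, dBCM sink).
    """
    if path is None:
        text = _resources.files("ratepath.data").joinpath("model_library.json").read_text()
    else:
        text = Path(path).read_text()
    return _load_library_json(text)
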