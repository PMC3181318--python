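"""Recursive path-model (structural equation) engine for rate tables.

A candidate :class:`~ratepath.dags.PathDAG` over the six rate-of-change
variables is fitted to a rate table as a linear-Gaussian recursive system:
every endogenous node is a linear function of its parents plus an
independent Gaussian error. Variables are standardized inside the engine,
so the estimated edge weights are *standardized path coefficients* (the SD
change in a child per SD change in a parent).

For recursive models with uncorrelated errors the maximum-likelihood
estimates are the equation-wise OLS estimates computed from the sample
correlation matrix ``S`` (the Gaussian likelihood factorizes over nodes).
The fitted model implies a covariance matrix

    Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ

with ``B`` the path-coefficient matrix and ``Ψ`` the diagonal matrix of
exogenous and residual variances. Goodness of fit uses the ML discrepancy

    F_ml = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p,

scaled to the chi-square statistic ``T = (n − 1)·F_ml`` with
``df = p(p+1)/2 − (p + E)`` — a model is *retained* ("significant" in the
path-analysis sense) when T does **not** exceed the chi-square critical
value, i.e. when the implied covariance structure is consistent with the
data. A numerical ML optimizer (:meth:`PathModel.fit_ml_numeric`) is kept
as an internal cross-check of the closed-form estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dags import PathDAG, model_df, validate_dag

log = logging.getLogger(__name__)

__all__ = [
    "PathModel",
    "PathModelResults",
    "ModelComparison",
    "fit_equations",
    "implied_covariance",
    "ml_discrepancy",
    "compare_models",
    "subset_analysis",
]


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Maximum-likelihood discrepancy between sample and implied covariances.

    ``F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p``; non-negative, zero iff S = Σ.

    Raises
    ------
    ValueError
        If either matrix is not symmetric positive definite, or the
        dimensions differ.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square matrices of equal size")
    p = S.shape[0]
    for name, m in (("S", S), ("Sigma", Sigma)):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError(f"{name} is not symmetric")
        try:
            np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            raise ValueError(f"{name} is not positive definite") from None
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    tr = float(np.trace(np.linalg.solve(Sigma, S)))
    f = logdet_m + tr - logdet_s - p
    # clamp tiny negative round-off at the optimum
    return float(max(f, 0.0))


def _coef_matrix(dag: PathDAG, coefficients: dict, order: list[str]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(order)}
    B = np.zeros((len(order), len(order)))
    for (u, v), beta in coefficients.items():
        if (u, v) not in set(dag.edges):
            raise KeyError(f"coefficient given for edge ({u}, {v}) not in {dag.name!r}")
        B[idx[v], idx[u]] = beta
    return B


def implied_covariance(
    dag: PathDAG,
    coefficients: dict,
    residual_variances: dict,
    exog_covariances: dict | None = None,
) -> pd.DataFrame:
    """Model-implied covariance matrix Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ.

    ``residual_variances`` must cover every node (exogenous nodes contribute
    their own variance to the diagonal of Ψ). ``exog_covariances`` optionally
    supplies covariances between exogenous node pairs (off-diagonal Ψ).
    """
    order = list(dag.nodes)
    missing = [v for v in order if v not in residual_variances]
    if missing:
        raise KeyError(f"residual variance missing for node(s) {missing}")
    B = _coef_matrix(dag, coefficients, order)
    Psi = np.diag([float(residual_variances[v]) for v in order])
    if exog_covariances:
        idx = {v: i for i, v in enumerate(order)}
        for (u, v), c in exog_covariances.items():
            Psi[idx[u], idx[v]] = Psi[idx[v], idx[u]] = float(c)
    I = np.eye(len(order))
    A = np.linalg.solve(I - B, I)  # (I−B)⁻¹; always invertible for acyclic B
    Sigma = A @ Psi @ A.T
    Sigma = (Sigma + Sigma.T) / 2.0
    return pd.DataFrame(Sigma, index=order, columns=order)


def fit_equations(
    dag: PathDAG, S: pd.DataFrame, n: int | None = None
) -> tuple[dict, dict, pd.DataFrame]:
    """Equation-wise OLS on the correlation matrix: the ML estimates.

    Each endogenous node is regressed on its parents using the blocks of
    ``S``; the standardized coefficients are β = S_PP⁻¹ S_Pv and the
    residual variance is the Schur complement ψ = S_vv − S_vP β (so, on the
    standardized scale, ψ = 1 − R²). Parentless nodes get ψ = S_vv and no
    coefficients.

    Returns ``(coefficients, residual_variances, coef_table)``; the table
    carries per-coefficient SE, t and p when ``n`` is given.

    Raises
    ------
    np.linalg.LinAlgError
        For a singular parent block (collinear parents), naming the node.
    """
    order = validate_dag(dag, enforce_roles=False)
    coefficients: dict = {}
    residual_variances: dict = {}
    rows = []
    for v in order:
        parents = list(dag.parents(v))
        s_vv = float(S.loc[v, v])
        if not parents:
            residual_variances[v] = s_vv
            continue
        S_pp = S.loc[parents, parents].to_numpy()
        S_pv = S.loc[parents, v].to_numpy()
        try:
            beta = np.linalg.solve(S_pp, S_pv)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular design for node {v!r}: collinear parents {parents}"
            ) from None
        psi = s_vv - float(S_pv @ beta)
        residual_variances[v] = psi
        k = len(parents)
        if n is not None and n - k - 1 > 0:
            sigma2 = psi * (n - 1) / (n - k - 1)
            cov_beta = sigma2 * np.linalg.inv(S_pp) / (n - 1)
            se = np.sqrt(np.diag(cov_beta))
        else:
            se = np.full(k, np.nan)
        for j, u in enumerate(parents):
            coefficients[(u, v)] = float(beta[j])
            t = beta[j] / se[j] if np.isfinite(se[j]) and se[j] > 0 else np.nan
            pv = (
                2 * stats.t.sf(abs(t), df=n - k - 1)
                if n is not None and np.isfinite(t)
                else np.nan
            )
            rows.append(
                {"edge": f"{u} -> {v}", "parent": u, "child": v,
                 "coef": float(beta[j]), "se": float(se[j]), "t": float(t) if np.isfinite(t) else np.nan,
                 "p": float(pv) if np.isfinite(pv) else np.nan}
            )
    table = pd.DataFrame(rows, columns=["edge", "parent", "child", "coef", "se", "t", "p"])
    return coefficients, residual_variances, table


class PathModel:
    """A candidate path model bound to rate data, statsmodels-style.

    Parameters
    ----------
    dag:
        The candidate causal structure.
    data:
        DataFrame with one column per DAG node (any superset of columns is
        accepted; rows with missing values in the model columns are
        dropped). Columns are standardized internally, so input scaling is
        irrelevant to the fit.
    exog_free_cov:
        If True, covariances between exogenous nodes are free parameters
        (estimated at their sample values) instead of fixed to zero; df
        shrinks accordingly.
    """

    def __init__(self, dag: PathDAG, data: pd.DataFrame, exog_free_cov: bool = False):
        validate_dag(dag, enforce_roles=False)
        missing = [c for c in dag.nodes if c not in data.columns]
        if missing:
            raise KeyError(f"data lacks model column(s) {missing}")
        sub = data.loc[:, list(dag.nodes)].dropna()
        self.dag = dag
        self.data = sub
        self.exog_free_cov = bool(exog_free_cov)
        self.nobs = len(sub)
        max_parents = max((len(dag.parents(v)) for v in dag.nodes), default=0)
        if self.nobs <= max_parents + 1:
            raise ValueError(
                f"n={self.nobs} too small for a model with {max_parents} parents"
            )
        sd = sub.std(ddof=1)
        degenerate = sd.index[(sd == 0) | sd.isna()]
        if len(degenerate):
            raise ValueError(f"zero-variance column(s): {list(degenerate)}")
        self.S = sub.corr()

    @classmethod
    def from_rate_table(cls, dag: PathDAG, rate_table, **kwargs) -> "PathModel":
        """Build from a :class:`~ratepath.rates.RateTable`."""
        return cls(dag, rate_table.table, **kwargs)

    @property
    def exog_nodes(self) -> list[str]:
        return [v for v in self.dag.nodes if not self.dag.parents(v)]

    def model_df(self) -> int:
        df = model_df(self.dag)
        if self.exog_free_cov:
            k = len(self.exog_nodes)
            df -= k * (k - 1) // 2
        if df < 0:
            raise ValueError("over-parameterized model")
        return df

    def fit(self, alpha: float = 0.05) -> "PathModelResults":
        """ML fit via equation-wise OLS; chi-square test of the structure."""
        coef, psi, table = fit_equations(self.dag, self.S, n=self.nobs)
        exog_cov = None
        if self.exog_free_cov:
            exog = self.exog_nodes
            exog_cov = {
                (u, v): float(self.S.loc[u, v])
                for i, u in enumerate(exog)
                for v in exog[i + 1:]
            }
        sigma = implied_covariance(self.dag, coef, psi, exog_covariances=exog_cov)
        fml = ml_discrepancy(self.S.to_numpy(), sigma.loc[self.S.index, self.S.columns].to_numpy())
        df = self.model_df()
        T = (self.nobs - 1) * fml
        p_value = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
        r2 = {
            v: 1.0 - psi[v] for v in self.dag.nodes if self.dag.parents(v)
        }
        return PathModelResults(
            model=self,
            coefficients=coef,
            residual_variances=psi,
            coef_table=table,
            implied_cov=sigma,
            fml=fml,
            statistic=T,
            df=df,
            p_value=p_value,
            alpha=alpha,
            rejected=bool(p_value < alpha) if df > 0 else False,
            r2=r2,
        )

    # ---- numerical ML (internal cross-check of the closed form) ----

    def _unpack(self, theta: np.ndarray) -> tuple[dict, dict]:
        edges = list(self.dag.edges)
        coef = {e: float(b) for e, b in zip(edges, theta[: len(edges)])}
        psi = {
            v: float(np.exp(t))
            for v, t in zip(self.dag.nodes, theta[len(edges):])
        }
        return coef, psi

    def _fml_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        order = list(self.dag.nodes)
        idx = {v: i for i, v in enumerate(order)}
        edges = list(self.dag.edges)
        coef, psi = self._unpack(theta)
        B = _coef_matrix(self.dag, coef, order)
        psi_vec = np.array([psi[v] for v in order])
        I = np.eye(len(order))
        A = np.linalg.solve(I - B, I)
        Sigma = (A * psi_vec) @ A.T
        S = self.S.loc[order, order].to_numpy()
        Sigma_inv = np.linalg.inv(Sigma)
        sign, logdet_m = np.linalg.slogdet(Sigma)
        _, logdet_s = np.linalg.slogdet(S)
        f = logdet_m + float(np.trace(S @ Sigma_inv)) - logdet_s - len(order)
        G = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        SGA = Sigma @ G @ A
        AGA = A.T @ G @ A
        grad = np.empty_like(theta)
        for k, (u, v) in enumerate(edges):
            grad[k] = 2.0 * SGA[idx[u], idx[v]]
        for k, v in enumerate(order):
            grad[len(edges) + k] = AGA[idx[v], idx[v]] * psi_vec[idx[v]]
        return f, grad

    def fit_ml_numeric(
        self,
        start: np.ndarray | None = None,
        jitter: float = 0.2,
        rng: np.random.Generator | None = None,
        gtol: float = 1e-12,
    ) -> tuple[dict, dict, float]:
        """Minimize F_ml numerically from a (perturbed) start.

        Exists to verify that the closed-form equation-wise estimates are
        the ML optimum; returns ``(coefficients, residual_variances, fml)``.
        """
        edges = list(self.dag.edges)
        coef0, psi0, _ = fit_equations(self.dag, self.S, n=self.nobs)
        theta0 = np.concatenate(
            [
                np.array([coef0[e] for e in edges]),
                np.log(np.array([max(psi0[v], 1e-8) for v in self.dag.nodes])),
            ]
        )
        if start is not None:
            theta0 = np.asarray(start, dtype=float)
        elif jitter:
            rng = rng or np.random.default_rng(0)
            theta0 = theta0 + rng.normal(0.0, jitter, size=theta0.size)
        res = optimize.minimize(
            self._fml_and_grad,
            theta0,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 2000},
        )
        coef, psi = self._unpack(res.x)
        return coef, psi, float(res.fun)


@dataclass
class PathModelResults:
    """Fitted path model: estimates, fit statistics and diagnostics."""

    model: PathModel
    coefficients: dict
    residual_variances: dict
    coef_table: pd.DataFrame
    implied_cov: pd.DataFrame
    fml: float
    statistic: float
    df: int
    p_value: float
    alpha: float
    rejected: bool
    r2: dict = field(default_factory=dict)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def retained(self) -> bool:
        """True when the structure is consistent with the data at level α."""
        return not self.rejected

    def to_dict(self) -> dict:
        return {
            "model": self.model.dag.name,
            "scenario": self.model.dag.scenario,
            "n": self.nobs,
            "T": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "alpha": self.alpha,
            "rejected": self.rejected,
            "coefficients": {f"{u} -> {v}": b for (u, v), b in self.coefficients.items()},
            "residual_variances": dict(self.residual_variances),
            "r2": dict(self.r2),
        }

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-flavoured."""
        d = self.model.dag
        lines = [
            f"Path model {d.name}" + (f" ({d.scenario} scenario)" if d.scenario else ""),
            "=" * 58,
            f"n = {self.nobs}    chi2 = {self.statistic:.3f}    df = {self.df}"
            f"    p = {self.p_value:.4f}",
            f"model {'REJECTED' if self.rejected else 'retained'} at alpha = {self.alpha}",
            "-" * 58,
            f"{'edge':<18}{'coef':>9}{'se':>9}{'t':>8}{'p':>9}",
        ]
        for _, row in self.coef_table.iterrows():
            lines.append(
                f"{row['edge']:<18}{row['coef']:>9.3f}{row['se']:>9.3f}"
                f"{row['t']:>8.2f}{row['p']:>9.4f}"
            )
        lines.append("-" * 58)
        lines.append("variance explained (r2):")
        for v, r in self.r2.items():
            lines.append(f"  {v:<8}{r:>7.3f}")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """Chi-square screening of a model library against one dataset."""

    results: dict[str, PathModelResults]
    table: pd.DataFrame
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[~self.table["rejected"], "model"])

    @property
    def best(self) -> str | None:
        """Best-fitting retained model, or None if all are rejected."""
        kept = self.retained
        return kept[0] if kept else None

    def to_dict(self) -> dict:
        return {name: res.to_dict() for name, res in self.results.items()}


def compare_models(
    library: list[PathDAG],
    data: pd.DataFrame,
    alpha: float = 0.05,
    exog_free_cov: bool = False,
) -> ModelComparison:
    """Fit every library model to ``data`` and rank them.

    Models are partitioned into retained / rejected at level ``alpha``;
    retained models come first, ranked by descending p-value, ties broken by
    fewer edges then by library order.
    """
    results: dict[str, PathModelResults] = {}
    rows = []
    for lib_idx, dag in enumerate(library):
        res = PathModel(dag, data, exog_free_cov=exog_free_cov).fit(alpha=alpha)
        results[dag.name] = res
        rows.append(
            {"model": dag.name, "scenario": dag.scenario, "n_edges": dag.n_edges,
             "T": res.statistic, "df": res.df, "p": res.p_value,
             "rejected": res.rejected, "_lib": lib_idx}
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["rejected", "p", "n_edges", "_lib"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_lib").reset_index(drop=True)
    return ModelComparison(results=results, table=table, alpha=alpha)


def subset_analysis(
    rate_table,
    mode: str,
    library: list[PathDAG],
    alpha: float = 0.05,
    min_n: int = 10,
    single_resource: str | None = None,
    exog_free_cov: bool = False,
) -> dict[str, ModelComparison]:
    """Library screening on subsets of the rate table.

    Modes
    -----
    ``by_date``:
        One screening per sampling-date label.
    ``by_intensity_median_split``:
        Transitions split into equal-sized low / high groups by the median
        of dRES (with odd n the extra row goes to the high group).
    ``single_resource``:
        dRES replaced by the single-resource rate column ``d<NAME>`` (e.g.
        dDOC) and the library re-screened on the full table.

    Subsets smaller than ``min_n`` rows are skipped with a logged warning.
    """
    table = rate_table.table
    subsets: dict[str, pd.DataFrame] = {}
    if mode == "by_date":
        for date, sub in table.groupby(level="date", sort=True):
            subsets[str(date)] = sub
    elif mode == "by_intensity_median_split":
        order = table["dRES"].rank(method="first").to_numpy()
        n_low = len(table) // 2
        low_mask = order <= n_low
        subsets["low"] = table.loc[low_mask]
        subsets["high"] = table.loc[~low_mask]
    elif mode == "single_resource":
        if not single_resource:
            raise ValueError("single_resource mode needs a resource name")
        col = f"d{single_resource}"
        if col not in table.columns:
            raise KeyError(f"rate table lacks column {col!r}")
        sub = table.drop(columns="dRES").rename(columns={col: "dRES"})
        subsets[single_resource] = sub
    else:
        raise ValueError(f"unknown subset mode {mode!r}")

    reports: dict[str, ModelComparison] = {}
    for label, sub in subsets.items():
        if len(sub) < min_n:
            log.warning(
                "subset %r skipped: n=%d below minimum %d", label, len(sub), min_n
            )
            continue
        reports[label] = compare_models(
            library, sub, alpha=alpha, exog_free_cov=exog_free_cov
        )
    return reports
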