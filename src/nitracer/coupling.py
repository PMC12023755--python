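"""Connectivity–nitrogen–microbiome coupling statistics.

* :func:`correlate` — Pearson / Spearman correlation with two-tailed
  p-value (the t transform of r).
* :func:`fit_path_model` — piecewise structural equation model: one
  ordinary-least-squares submodel per endogenous variable, fitted on
  z-standardized variables, reporting standardized path coefficients with
  slope t-test p-values and per-endpoint R².  No global covariance fit, no
  latent variables — matching how path diagrams with per-path coefficients
  and per-endpoint R² are produced in practice.
* :func:`indirect_effect` — product of coefficients along a directed path.
* :func:`nse` / :func:`r_squared` — Nash–Sutcliffe efficiency and squared
  Pearson correlation for model-evaluation use.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConditioningError, DomainError, GraphCycleError, SchemaError
from .io import WatershedTable

__all__ = [
    "correlate",
    "PathEdge",
    "PathModel",
    "fit_path_model",
    "indirect_effect",
    "nse",
    "r_squared",
]


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-tailed p-value.

    Pearson by default; Spearman ranks both vectors first.  Raises on
    zero-variance input (the coefficient is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("x and y must be equal-length 1-D vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PathEdge:
    source: str
    target: str
    coefficient: float
    p_value: float


@dataclass
class PathModel:
    """Fitted piecewise SEM: standardized edges plus per-endpoint R²."""

    edges: list[PathEdge]
    r_squared: dict[str, float]

    def coefficient(self, source: str, target: str) -> float:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.coefficient
        raise DomainError(f"no edge {source!r} -> {target!r} in the model")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "coefficient": e.coefficient,
                    "p_value": e.p_value,
                }
                for e in self.edges
            ]
        )


def fit_path_model(
    data: WatershedTable | pd.DataFrame,
    edges: list[tuple[str, str]],
) -> PathModel:
    """Fit one standardized OLS submodel per endogenous variable.

    ``edges`` is a directed (source, target) list; it must be acyclic and
    every named variable must be a column of ``data``.  All variables are
    z-standardized before fitting, so single-parent coefficients equal the
    Pearson correlation of the pair and every coefficient is invariant to
    affine rescaling of any variable.
    """
    df = data.data if isinstance(data, WatershedTable) else data
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise GraphCycleError("path model edges contain a cycle")
    missing = [v for v in g.nodes if v not in df.columns]
    if missing:
        raise SchemaError(f"variables not in data: {missing}")

    z = {}
    for v in g.nodes:
        col = df[v].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise DomainError(f"variable {v!r} has zero variance")
        z[v] = (col - col.mean()) / sd

    fitted_edges: list[PathEdge] = []
    r2: dict[str, float] = {}
    for target in g.nodes:
        parents = list(g.predecessors(target))
        if not parents:
            continue
        X = np.column_stack([z[p] for p in parents])
        if np.linalg.cond(X.T @ X) > 1e8:
            raise ConditioningError(
                f"collinear parents for {target!r}: {parents}"
            )
        model = sm.OLS(z[target], sm.add_constant(X)).fit()
        for i, p in enumerate(parents):
            fitted_edges.append(
                PathEdge(
                    source=p,
                    target=target,
                    coefficient=float(model.params[i + 1]),
                    p_value=float(model.pvalues[i + 1]),
                )
            )
        r2[target] = float(model.rsquared)
    return PathModel(edges=fitted_edges, r_squared=r2)


def indirect_effect(model: PathModel, path: list[str]) -> float:
    """Product of standardized coefficients along consecutive path edges."""
    if len(path) < 2:
        raise DomainError("path must name at least two variables")
    effect = 1.0
    for a, b in zip(path[:-1], path[1:]):
        effect *= model.coefficient(a, b)
    return effect


def _check_eval_inputs(observed, simulated) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1 or len(obs) < 2:
        raise DomainError("observed and simulated must be equal-length vectors, n >= 2")
    if np.var(obs) == 0:
        raise DomainError("metric undefined: observed series has zero variance")
    return obs, sim


def nse(observed, simulated) -> float:
    """Nash–Sutcliffe efficiency 1 − Σ(obs−sim)² / Σ(obs−mean(obs))²."""
    obs, sim = _check_eval_inputs(observed, simulated)
    return float(1.0 - ((obs - sim) ** 2).sum() / ((obs - obs.mean()) ** 2).sum())


def r_squared(observed, simulated) -> float:
    """Squared Pearson correlation between observed and simulated series."""
    obs, sim = _check_eval_inputs(observed, simulated)
    if np.var(sim) == 0:
        raise DomainError("metric undefined: simulated series has zero variance")
    r, _ = stats.pearsonr(obs, sim)
    return float(r**2)
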