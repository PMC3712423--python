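"""Deterministic path-model core.

Fit standardized path coefficients to a single correlation matrix, compute
the model-implied correlation matrix of a recursive system, and form
compound (indirect) path coefficients as products along a chain of edges.

For a fully recursive model on standardized variables the fit is exact and
non-iterative: for each endogenous variable ``y`` with parent set ``P`` the
coefficients are the solution of the normal equations on the correlation
scale, ``beta = R[P,P]^-1 R[P,y]`` — the standardized partial regression
coefficients of ``y`` on its parents. The residual variance is
``psi_y = 1 - R[y,P] beta`` and ``R^2 = 1 - psi_y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagrams import PathDiagram

__all__ = ["PathFitError", "PathFit", "fit_paths", "implied_matrix", "compound_coefficient"]


class PathFitError(ValueError):
    """Raised for ill-posed fits (singular blocks, mismatched variables)."""


@dataclass(frozen=True)
class PathFit:
    """Standardized coefficients of one path model fitted to one matrix."""

    diagram: PathDiagram
    coefficients: dict[str, float]          # edge label -> beta
    exog_correlations: dict[tuple[str, str], float]
    residual_variances: dict[str, float]    # endogenous variable -> psi
    r_squared: dict[str, float]


def _as_matrix(R, diagram: PathDiagram) -> np.ndarray:
    if isinstance(R, pd.DataFrame):
        missing = [v for v in diagram.variables if v not in R.columns]
        if missing:
            raise PathFitError(f"matrix lacks diagram variables {missing}")
        R = R.loc[list(diagram.variables), list(diagram.variables)].to_numpy()
    R = np.asarray(R, dtype=float)
    p = len(diagram.variables)
    if R.shape != (p, p):
        raise PathFitError(f"matrix shape {R.shape} does not match {p} variables")
    return R


def fit_paths(R, diagram: PathDiagram) -> PathFit:
    """Fit standardized path coefficients to a correlation matrix.

    Parameters
    ----------
    R
        Correlation matrix, either a square array in ``diagram.variables``
        order or a labelled DataFrame (reordered as needed). Must be
        symmetric with unit diagonal.
    diagram
        The recursive model to fit.
    """
    R = _as_matrix(R, diagram)
    idx = {v: i for i, v in enumerate(diagram.variables)}

    coefficients: dict[str, float] = {}
    residual: dict[str, float] = {}
    r2: dict[str, float] = {}
    for y in diagram.endogenous:
        parent_edges = [e for e in diagram.edges if e.target == y]
        P = [idx[e.source] for e in parent_edges]
        Rpp = R[np.ix_(P, P)]
        rpy = R[P, idx[y]]
        try:
            beta = np.linalg.solve(Rpp, rpy)
        except np.linalg.LinAlgError as err:
            raise PathFitError(f"singular parent block for {y!r}") from err
        if not np.all(np.isfinite(beta)):
            raise PathFitError(f"singular parent block for {y!r}")
        for e, b in zip(parent_edges, beta):
            coefficients[e.label] = float(b)
        explained = float(rpy @ beta)
        residual[y] = 1.0 - explained
        r2[y] = explained

    exog_corr = {
        (a, b): float(R[idx[a], idx[b]]) for a, b in diagram.correlations
    }
    return PathFit(diagram, coefficients, exog_corr, residual, r2)


def implied_matrix(diagram: PathDiagram, fit: PathFit) -> np.ndarray:
    """Model-implied correlation matrix ``(I - B)^-1 Psi (I - B)^-T``.

    ``B[child, parent] = beta`` collects the directed coefficients; ``Psi``
    holds the declared exogenous correlations (unit diagonal on exogenous
    variables) and the residual variances of endogenous variables. For a
    correctly standardized fit the result has unit diagonal.
    """
    p = len(diagram.variables)
    idx = {v: i for i, v in enumerate(diagram.variables)}
    B = np.zeros((p, p))
    for e in diagram.edges:
        B[idx[e.target], idx[e.source]] = fit.coefficients[e.label]
    psi = np.zeros((p, p))
    for v in diagram.exogenous:
        psi[idx[v], idx[v]] = 1.0
    for v, value in fit.residual_variances.items():
        psi[idx[v], idx[v]] = value
    for (a, b), r in fit.exog_correlations.items():
        psi[idx[a], idx[b]] = r
        psi[idx[b], idx[a]] = r

    ident = np.eye(p)
    try:
        T = np.linalg.solve(ident - B, ident)
    except np.linalg.LinAlgError as err:  # impossible for a DAG; corrupt input
        raise PathFitError("(I - B) is singular") from err
    S = T @ psi @ T.T
    return (S + S.T) / 2.0


def _is_trek(edges) -> bool:
    """True if the ordered edges form an admissible compound path: a walk
    that may first move against arrows (up to a common cause) and then
    with arrows, never through a collider. Head-to-tail chains are the
    all-forward special case."""
    for start in (edges[0].source, edges[0].target):
        pos = start
        descending = False
        ok = True
        for e in edges:
            if pos == e.source:        # forward traversal
                pos = e.target
                descending = True
            elif pos == e.target and not descending:   # backward traversal
                pos = e.source
            else:
                ok = False
                break
        if ok and pos != start:
            return True
    return False


def compound_coefficient(fit: PathFit, edge_labels) -> float:
    """Product of coefficients along an ordered compound path.

    The edges must connect into an admissible path: consecutive edges
    share a variable and the walk changes direction at most once, from
    against-arrows to with-arrows (so indirect effects through a common
    cause are allowed, colliders are not).
    """
    edge_labels = [str(lbl) for lbl in edge_labels]
    if not edge_labels:
        raise PathFitError("empty compound path")
    edges = [fit.diagram.edge_by_label(lbl) for lbl in edge_labels]
    if not _is_trek(edges):
        chain = " x ".join(edge_labels)
        raise PathFitError(f"compound path {chain!r} does not form a connected path")
    out = 1.0
    for e in edges:
        out *= fit.coefficients[e.label]
    return out
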