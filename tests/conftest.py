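"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's computational routes:
the tracing oracle computes model-implied correlations by exhaustive
enumeration of directed paths (never matrix inversion), the regression
oracle fits standardized least squares directly on raw data, and the
variance-components oracle uses one-way ANOVA method-of-moments.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

import bayespath as bp
from bayespath.diagrams import PathDiagram
from bayespath.pathmodel import PathFit
from bayespath.simulate import _implied_correlation


# ---------------------------------------------------------------- oracles

def directed_path_sums(diagram: PathDiagram, coefficients: dict[str, float]):
    """T[a][i] = sum over all directed paths a -> i of the product of
    edge coefficients (the empty path contributes 1 to T[a][a]),
    computed by exhaustive recursive enumeration."""
    children = defaultdict(list)
    for e in diagram.edges:
        children[e.source].append((e.target, coefficients[e.label]))

    T: dict[str, dict[str, float]] = {}

    def walk(start: str, node: str, product: float) -> None:
        T[start][node] += product
        for child, beta in children[node]:
            walk(start, child, product * beta)

    for a in diagram.variables:
        T[a] = defaultdict(float)
        walk(a, a, 1.0)
    return T


def traced_implied_matrix(diagram: PathDiagram, fit: PathFit) -> np.ndarray:
    """Model-implied correlation matrix via the tracing enumeration:
    Sigma_ij = sum_{a,b} T[a][i] Psi_ab T[b][j]."""
    T = directed_path_sums(diagram, fit.coefficients)
    variables = diagram.variables
    psi = {}
    for v in diagram.exogenous:
        psi[(v, v)] = 1.0
    for v, value in fit.residual_variances.items():
        psi[(v, v)] = value
    for (a, b), r in fit.exog_correlations.items():
        psi[(a, b)] = r
        psi[(b, a)] = r

    p = len(variables)
    out = np.zeros((p, p))
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            total = 0.0
            for (a, b), w in psi.items():
                total += T[a].get(vi, 0.0) * w * T[b].get(vj, 0.0)
            out[i, j] = total
    return out


def standardized_ols(data: pd.DataFrame, diagram: PathDiagram) -> dict[str, float]:
    """Standardized partial regression coefficients by least squares on
    the z-scored raw data, one regression per endogenous variable."""
    z = (data - data.mean()) / data.std(ddof=1)
    coefs: dict[str, float] = {}
    for y in diagram.endogenous:
        parent_edges = [e for e in diagram.edges if e.target == y]
        X = z[[e.source for e in parent_edges]].to_numpy()
        beta, *_ = np.linalg.lstsq(X, z[y].to_numpy(), rcond=None)
        for e, b in zip(parent_edges, beta):
            coefs[e.label] = float(b)
    return coefs


def anova_variance_components(y: np.ndarray, individual: np.ndarray):
    """Method-of-moments estimators for the balanced one-way random
    effects model (k measures per individual)."""
    ids, idx = np.unique(individual, return_inverse=True)
    k = y.size // ids.size
    group_means = np.bincount(idx, weights=y) / k
    grand = y.mean()
    msb = k * np.sum((group_means - grand) ** 2) / (ids.size - 1)
    msw = np.sum((y - group_means[idx]) ** 2) / (ids.size * (k - 1))
    return (msb - msw) / k, msw


def random_recursive_model(rng: np.random.Generator, n_vars: int = 5,
                           edge_prob: float = 0.6, max_beta: float = 0.6):
    """A random DAG diagram plus coefficients guaranteed to leave positive
    residual variance (rejection-sampled)."""
    names = [f"v{i}" for i in range(n_vars)]
    for _ in range(200):
        lines = []
        label = 0
        for j in range(1, n_vars):
            for i in range(j):
                if rng.random() < edge_prob:
                    label += 1
                    lines.append(f"{label}: {names[i]} -> {names[j]}")
        if not lines:
            continue
        diagram = bp.parse_diagram("\n".join(lines))
        coefs = {
            e.label: float(rng.uniform(-max_beta, max_beta)) for e in diagram.edges
        }
        config_coefs = {
            (e.source, e.target): coefs[e.label] for e in diagram.edges
        }
        try:
            cfg = bp.GeneratorConfig(n_pairs=1, coefficients=config_coefs, seed=0)
            _implied_correlation(cfg)
        except bp.InvalidCoefficientError:
            continue
        return diagram, coefs
    raise RuntimeError("could not build a valid random model")


def make_fit(diagram: PathDiagram, coefficients: dict[str, float],
             exog_correlations: dict[tuple[str, str], float] | None = None) -> PathFit:
    """Assemble a PathFit with residual variances completing unit
    variances (via the generator's forward recursion, independent of
    implied_matrix)."""
    exog_correlations = exog_correlations or {}
    cfg = bp.GeneratorConfig(
        n_pairs=1,
        coefficients={(e.source, e.target): coefficients[e.label] for e in diagram.edges},
        exog_correlations=exog_correlations,
        seed=0,
    )
    _, resid = _implied_correlation(cfg)
    r2 = {v: 1.0 - psi for v, psi in resid.items()}
    return PathFit(diagram, dict(coefficients), dict(exog_correlations), resid, r2)


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def male_diagram() -> PathDiagram:
    return bp.presets.male_diagram()


@pytest.fixture(scope="session")
def female_diagram() -> PathDiagram:
    return bp.presets.female_diagram()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130807)
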