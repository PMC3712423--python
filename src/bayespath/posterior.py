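"""Posterior propagation of covariance uncertainty through path models.

The path model is refitted once per posterior covariance draw, so every
path coefficient — and every compound (indirect) path, computed as the
within-draw product of its component coefficients — has a full posterior
sample. Each sample is summarized by its kernel-density mode ("most
likely" value), posterior mean, 95% equal-tailed credible interval and a
two-sided tail probability p = 2 * min(fraction > 0, fraction < 0),
floored at 1/n_draws (the one-sided positive fraction is reported
alongside). Support is classified as in the source analyses: *strong* if
the credible interval excludes zero, *some* if it overlaps zero but
p < 0.05, *none* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._summaries import equal_tailed_interval, kde_mode
from .covariance import CovarianceDraws
from .diagrams import PathDiagram
from .pathmodel import compound_coefficient, fit_paths

__all__ = [
    "PropagationError",
    "EdgeSummary",
    "propagate",
    "summarize",
    "summarize_all",
    "classify_support",
    "report",
    "report_dot",
]

logger = logging.getLogger(__name__)

_REJECT_EIG = -1e-4     # draws more indefinite than this are discarded
_CLIP_EIG = 1e-8        # smaller eigenvalues are clipped during repair
_MAX_REJECT_FRACTION = 0.05


class PropagationError(RuntimeError):
    """Raised when too many covariance draws cannot be repaired."""


@dataclass(frozen=True)
class EdgeSummary:
    """Posterior summary of one (compound) path coefficient."""

    label: str
    link: str
    point: float        # kernel-density mode
    mean: float
    lower95: float
    upper95: float
    p: float            # two-sided tail probability, floored at 1/n_draws
    p_positive: float   # one-sided fraction of positive draws
    support: str        # strong | some | none
    n: int | None = None


def _repair_correlation(matrix: np.ndarray) -> np.ndarray | None:
    """Convert one covariance draw to a PD correlation matrix.

    Eigenvalues below the clip threshold are raised to it and the result
    re-normalized to unit diagonal; draws that are decidedly indefinite
    (min eigenvalue < -1e-4 on the correlation scale) are rejected.
    """
    d = np.diag(matrix)
    if np.any(d <= 0):
        return None
    scale = 1.0 / np.sqrt(d)
    corr = matrix * np.outer(scale, scale)
    w, V = np.linalg.eigh(corr)
    if w.min() < _REJECT_EIG:
        return None
    if w.min() < _CLIP_EIG:
        w = np.clip(w, _CLIP_EIG, None)
        corr = (V * w) @ V.T
        s = 1.0 / np.sqrt(np.diag(corr))
        corr = corr * np.outer(s, s)
    return (corr + corr.T) / 2.0


def propagate(
    draws: CovarianceDraws,
    diagram: PathDiagram,
    compounds: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, np.ndarray]:
    """Fit the path model to every covariance draw.

    Returns one coefficient vector per directed-edge label, per declared
    exogenous-correlation edge (keyed ``"a<->b"``) and per compound label
    (within-draw products). Draws whose correlation conversion is
    irreparably indefinite are rejected and logged; more than 5%
    rejections is an error.
    """
    compounds = compounds or {}
    order = [draws.variables.index(v) for v in diagram.variables]
    missing = [v for v in diagram.variables if v not in draws.variables]
    if missing:
        raise ValueError(f"draws lack diagram variables {missing}")

    labels = [e.label for e in diagram.edges]
    corr_labels = [f"{a}<->{b}" for a, b in diagram.correlations]
    values: dict[str, list[float]] = {
        lbl: [] for lbl in labels + corr_labels + list(compounds)
    }

    n_rejected = 0
    for i in range(len(draws)):
        sub = draws.matrices[i][np.ix_(order, order)]
        corr = _repair_correlation(sub)
        if corr is None:
            n_rejected += 1
            logger.warning("rejected indefinite covariance draw %d", i)
            continue
        fit = fit_paths(corr, diagram)
        for lbl in labels:
            values[lbl].append(fit.coefficients[lbl])
        for (a, b), lbl in zip(diagram.correlations, corr_labels):
            values[lbl].append(fit.exog_correlations[(a, b)])
        for lbl, chain in compounds.items():
            values[lbl].append(compound_coefficient(fit, chain))

    if n_rejected > _MAX_REJECT_FRACTION * len(draws):
        raise PropagationError(
            f"{n_rejected}/{len(draws)} covariance draws rejected as indefinite"
        )
    return {lbl: np.asarray(v) for lbl, v in values.items()}


def summarize(
    values: np.ndarray,
    n_pair: int | None = None,
    label: str = "",
    link: str = "",
) -> EdgeSummary:
    """Summarize one coefficient draw vector (>= 100 draws)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty coefficient draw vector")
    if values.size < 100:
        raise ValueError("need at least 100 draws to summarize")
    lo, hi = equal_tailed_interval(values)
    frac_pos = float(np.mean(values > 0))
    frac_neg = float(np.mean(values < 0))
    p = 2.0 * min(frac_pos, frac_neg)
    p = min(1.0, max(p, 1.0 / values.size))
    support = classify_support(lo, hi, p)
    return EdgeSummary(
        label=label,
        link=link,
        point=kde_mode(values),
        mean=float(values.mean()),
        lower95=lo,
        upper95=hi,
        p=p,
        p_positive=frac_pos,
        support=support,
        n=n_pair,
    )


def classify_support(lower95: float, upper95: float, p: float) -> str:
    """Strong if the 95% interval excludes zero; some if it overlaps zero
    but p < 0.05; none otherwise."""
    if lower95 > 0.0 or upper95 < 0.0:
        return "strong"
    if p < 0.05:
        return "some"
    return "none"


def summarize_all(
    coefficient_draws: dict[str, np.ndarray],
    diagram: PathDiagram,
    compounds: dict[str, tuple[str, ...]] | None = None,
    pairwise_n: pd.DataFrame | None = None,
) -> list[EdgeSummary]:
    """Summarize every propagated label in diagram order.

    ``pairwise_n`` (from :class:`CovarianceDraws`) supplies each edge's
    joint sample size; compound paths take the smallest n along the chain.
    """
    compounds = compounds or {}

    def n_of(a: str, b: str) -> int | None:
        if pairwise_n is None:
            return None
        return int(pairwise_n.loc[a, b])

    out: list[EdgeSummary] = []
    for e in diagram.edges:
        out.append(
            summarize(
                coefficient_draws[e.label],
                n_pair=n_of(e.source, e.target),
                label=e.label,
                link=f"{e.source} -> {e.target}",
            )
        )
    for a, b in diagram.correlations:
        lbl = f"{a}<->{b}"
        out.append(
            summarize(coefficient_draws[lbl], n_pair=n_of(a, b), label=lbl,
                      link=f"{a} <-> {b}")
        )
    for lbl, chain in compounds.items():
        edges = [diagram.edge_by_label(c) for c in chain]
        ns = [n_of(e.source, e.target) for e in edges]
        n = min((x for x in ns if x is not None), default=None)
        link = " x ".join(chain)
        out.append(summarize(coefficient_draws[lbl], n_pair=n, label=lbl, link=link))
    return out


def report(summaries: list[EdgeSummary], csv_path=None) -> pd.DataFrame:
    """Result table in the published layout: one row per (compound) path
    with its n, coefficient, credible interval, p and support class."""
    frame = pd.DataFrame(
        {
            "path": [s.label for s in summaries],
            "link": [s.link for s in summaries],
            "n": [s.n for s in summaries],
            "path_coef": [s.point for s in summaries],
            "mean": [s.mean for s in summaries],
            "lower95": [s.lower95 for s in summaries],
            "upper95": [s.upper95 for s in summaries],
            "p": [s.p for s in summaries],
            "p_positive": [s.p_positive for s in summaries],
            "support": [s.support for s in summaries],
        }
    )
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame


def report_dot(summaries: list[EdgeSummary], diagram: PathDiagram) -> str:
    """DOT rendering of the supported paths only: solid edges for strong
    support, dashed for some; unsupported paths are omitted."""
    by_label = {s.label: s for s in summaries}
    lines = ["digraph supported_paths {", "  rankdir=LR;"]
    for v in diagram.variables:
        lines.append(f'  "{v}";')
    for e in diagram.edges:
        s = by_label.get(e.label)
        if s is None or s.support == "none":
            continue
        style = "solid" if s.support == "strong" else "dashed"
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[label="{e.label}: {s.point:.2f}", style={style}];'
        )
    lines.append("}")
    return "\n".join(lines)
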