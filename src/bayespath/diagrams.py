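"""Path-diagram parsing and validation.

A path diagram is a recursive (acyclic) structural model over named
variables: one-headed arrows are hypothesized causal links carrying a
standardized partial regression coefficient, and two-headed curved arrows
are free correlations between exogenous variables.

Diagrams are written in a small plain-text DSL, one edge per line::

    # male provisioning model (excerpt)
    1: aggression -> exploration
    2: aggression -> own_feed_rate
    aggression <-> some_other_exogenous_trait

Directed edges take an optional label (used to address paths in compound
products and result tables); unlabeled edges are auto-labelled
``"source->target"``. Correlation edges are unlabeled and may only join
exogenous variables (variables with no incoming directed edge).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["DiagramError", "DirectedEdge", "PathDiagram", "parse_diagram", "to_dot"]


class DiagramError(ValueError):
    """Raised for structurally invalid path diagrams."""


@dataclass(frozen=True)
class DirectedEdge:
    source: str
    target: str
    label: str


_EDGE_RE = re.compile(
    r"^(?:(?P<label>[\w.\-]+)\s*:\s*)?(?P<a>[\w.\-]+)\s*(?P<op><->|->)\s*(?P<b>[\w.\-]+)$"
)


@dataclass(frozen=True)
class PathDiagram:
    """A validated recursive path model.

    Parameters
    ----------
    variables
        Variable names in first-appearance order.
    edges
        Directed (causal) edges with unique labels.
    correlations
        Unordered pairs of exogenous variables with a free correlation.
    """

    variables: tuple[str, ...]
    edges: tuple[DirectedEdge, ...]
    correlations: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        known = set(self.variables)
        seen_pairs: set[tuple[str, str]] = set()
        labels: set[str] = set()
        for e in self.edges:
            if e.source == e.target:
                raise DiagramError(f"self-edge on {e.source!r}")
            if e.source not in known or e.target not in known:
                raise DiagramError(f"edge {e.source}->{e.target} uses unknown variable")
            if (e.source, e.target) in seen_pairs:
                raise DiagramError(f"duplicate edge {e.source} -> {e.target}")
            seen_pairs.add((e.source, e.target))
            if e.label in labels:
                raise DiagramError(f"duplicate edge label {e.label!r}")
            labels.add(e.label)

        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(u for u, _ in nx.find_cycle(g)) or "?"
            raise DiagramError(f"directed edges contain a cycle: {cycle}")

        exog = set(self.exogenous)
        seen_corr: set[frozenset[str]] = set()
        for a, b in self.correlations:
            if a == b:
                raise DiagramError(f"self-correlation on {a!r}")
            if a not in known or b not in known:
                raise DiagramError(f"correlation {a} <-> {b} uses unknown variable")
            if a not in exog or b not in exog:
                raise DiagramError(
                    f"correlation edge {a} <-> {b} touches an endogenous variable"
                )
            key = frozenset((a, b))
            if key in seen_corr:
                raise DiagramError(f"duplicate correlation edge {a} <-> {b}")
            seen_corr.add(key)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    @property
    def exogenous(self) -> tuple[str, ...]:
        has_in = {e.target for e in self.edges}
        return tuple(v for v in self.variables if v not in has_in)

    @property
    def endogenous(self) -> tuple[str, ...]:
        has_in = {e.target for e in self.edges}
        return tuple(v for v in self.variables if v in has_in)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(e.source for e in self.edges if e.target == v)

    def edge_by_label(self, label: str) -> DirectedEdge:
        for e in self.edges:
            if e.label == label:
                return e
        raise KeyError(f"no edge labelled {label!r}")

    def topological_order(self) -> list[str]:
        # deterministic: break ties by declaration order
        index = {v: i for i, v in enumerate(self.variables)}
        return list(nx.lexicographical_topological_sort(self.graph(), key=index.get))

    def index(self, v: str) -> int:
        return self.variables.index(v)


def parse_diagram(text: str) -> PathDiagram:
    """Parse the diagram DSL into a validated :class:`PathDiagram`.

    Lines are ``label: A -> B``, ``A -> B`` or ``A <-> B``; ``#`` starts a
    comment. Variables are collected in first-appearance order.
    """
    variables: list[str] = []
    edges: list[DirectedEdge] = []
    correlations: list[tuple[str, str]] = []

    def note(v: str) -> None:
        if v not in variables:
            variables.append(v)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _EDGE_RE.match(line)
        if m is None:
            raise DiagramError(f"line {lineno}: cannot parse {raw.strip()!r}")
        label, a, op, b = m.group("label"), m.group("a"), m.group("op"), m.group("b")
        note(a)
        note(b)
        if op == "->":
            edges.append(DirectedEdge(a, b, label if label is not None else f"{a}->{b}"))
        else:
            if label is not None:
                raise DiagramError(f"line {lineno}: correlation edges take no label")
            correlations.append((a, b))

    return PathDiagram(tuple(variables), tuple(edges), tuple(correlations))


def to_dot(diagram: PathDiagram) -> str:
    """Render the bare diagram as Graphviz DOT text."""
    lines = ["digraph paths {", "  rankdir=LR;"]
    for v in diagram.variables:
        lines.append(f'  "{v}";')
    for e in diagram.edges:
        lines.append(f'  "{e.source}" -> "{e.target}" [label="{e.label}"];')
    for a, b in diagram.correlations:
        lines.append(f'  "{a}" -> "{b}" [dir=both, style=curved, constraint=false];')
    lines.append("}")
    return "\n".join(lines)
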