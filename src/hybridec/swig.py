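"""Selection single-world intervention graphs (SWIGs) for assessing
mean exchangeability of external controls.

A causal DAG over the outcome's direct causes is augmented with selection
nodes S_Z -> Z for each covariate whose conditional law is declared to
differ between the trial and external-control populations (and S_Y -> Y
if the outcome mechanism itself differs).  The treatment node is split
into a random half (keeps incoming edges) and a fixed half set to the
control level (keeps outgoing edges), making the control potential
outcome Y^0 explicit.  Mean exchangeability across sources given an
adjustment set X holds whenever Y^0 is d-separated from every S node
given X on this selection SWIG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = [
    "CausalGraph",
    "SelectionSWIG",
    "GraphError",
    "load_graph",
    "parse_graph",
    "build_selection_swig",
    "d_separated",
    "check_a4",
    "minimal_adjustment_sets",
    "to_dot",
]

ROLES = ("covariate", "treatment", "outcome", "unmeasured")


class GraphError(ValueError):
    """Raised for malformed graphs or invalid graph queries."""


@dataclass
class CausalGraph:
    """A causal DAG with node roles.

    Roles: ``covariate`` (measured), ``unmeasured`` (latent; participates
    in paths but cannot be conditioned on), ``treatment``, ``outcome``.
    """

    graph: nx.DiGraph
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise GraphError(f"graph contains a cycle: {cycle}")
        for node in self.graph.nodes:
            self.roles.setdefault(node, "covariate")
        bad = {r for r in self.roles.values()} - set(ROLES)
        if bad:
            raise GraphError(f"unknown role(s): {sorted(bad)}")
        outcomes = [v for v, r in self.roles.items() if r == "outcome"]
        if len(outcomes) != 1:
            raise GraphError(f"exactly one outcome node required; found {outcomes}")

    @property
    def outcome(self) -> str:
        return next(v for v, r in self.roles.items() if r == "outcome")

    @property
    def treatment(self) -> str | None:
        return next((v for v, r in self.roles.items() if r == "treatment"), None)

    def covariates(self, measured_only: bool = True) -> set:
        keep = ("covariate",) if measured_only else ("covariate", "unmeasured")
        return {v for v, r in self.roles.items() if r in keep}


def parse_graph(text: str) -> CausalGraph:
    """Parse an edge-list description.

    One edge per line, ``parent -> child``; role annotations as
    ``role: node`` lines with role in {treatment, outcome, latent,
    covariate}; ``#`` starts a comment.
    """
    g = nx.DiGraph()
    roles: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            parts = [p.strip() for p in line.split("->")]
            if len(parts) != 2 or not all(parts):
                raise GraphError(f"line {lineno}: cannot parse edge {raw!r}")
            g.add_edge(*parts)
        elif ":" in line:
            role, node = (p.strip() for p in line.split(":", 1))
            role = {"latent": "unmeasured"}.get(role, role)
            if role not in ROLES:
                raise GraphError(f"line {lineno}: unknown role {role!r}")
            g.add_node(node)
            roles[node] = role
        else:
            raise GraphError(f"line {lineno}: cannot parse {raw!r}")
    return CausalGraph(graph=g, roles=roles)


def load_graph(path) -> CausalGraph:
    with open(path) as fh:
        return parse_graph(fh.read())


@dataclass
class SelectionSWIG:
    """A selection SWIG: split treatment, explicit Y^0, selection nodes."""

    base: CausalGraph
    graph: nx.DiGraph
    s_nodes: list
    outcome: str  # the Y^0 node in the split graph
    random_node: str
    fixed_node: str

    def measured(self) -> set:
        return self.base.covariates(measured_only=True)

    def latent(self) -> set:
        return self.base.covariates(measured_only=False) - self.base.covariates()


def build_selection_swig(
    g: CausalGraph,
    differing_covariates=(),
    outcome_mechanism_differs: bool = False,
    treatment: str | None = None,
    a: int = 0,
) -> SelectionSWIG:
    """Construct the selection SWIG from a causal DAG and user declarations.

    Declarations (which covariate conditionals and whether the outcome
    mechanism differ across populations) are supplied by the analyst; the
    conservative default in applications declares every covariate.  The
    treatment node is split into a random half (inherits in-edges) and a
    fixed half at the control level (inherits out-edges); the original
    outcome node, now a descendant of the fixed half, is Y^0.
    """
    treatment = treatment or g.treatment
    if treatment is None or treatment not in g.graph:
        raise GraphError("a treatment node is required to build the SWIG")
    outcome = g.outcome
    differing = set(differing_covariates)
    known = g.covariates(measured_only=False)
    unknown = differing - known
    if unknown:
        raise GraphError(f"declared covariates not in graph (or not covariates): {sorted(unknown)}")

    split = nx.DiGraph()
    fixed = f"{treatment}={a}"
    for node in g.graph.nodes:
        split.add_node(node if node != treatment else treatment)
    split.add_node(fixed)
    for u, v in g.graph.edges:
        if v == treatment:
            split.add_edge(u, treatment)      # random half keeps in-edges
        elif u == treatment:
            split.add_edge(fixed, v)          # fixed half keeps out-edges
        else:
            split.add_edge(u, v)

    s_nodes = []
    for z in sorted(differing):
        s = f"S_{z}"
        split.add_edge(s, z)
        s_nodes.append(s)
    if outcome_mechanism_differs:
        s = f"S_{outcome}"
        split.add_edge(s, outcome)
        s_nodes.append(s)
    if not nx.is_directed_acyclic_graph(split):  # pragma: no cover - defensive
        raise GraphError("node splitting produced a cycle (malformed input graph)")
    return SelectionSWIG(
        base=g, graph=split, s_nodes=s_nodes, outcome=outcome,
        random_node=treatment, fixed_node=fixed,
    )


# ---------------------------------------------------------------------------
# d-separation


def d_separated(g, src, dst, cond=()) -> bool:
    """Standard d-separation on a DAG.

    ``g`` may be a DiGraph, CausalGraph or SelectionSWIG.  Chains and
    forks are blocked by conditioning; a collider is open iff it or one
    of its descendants is conditioned on.
    """
    G = _as_digraph(g)
    src, dst, cond = {*_iter(src)}, {*_iter(dst)}, {*_iter(cond)}
    for s in (src | dst | cond):
        if s not in G:
            raise GraphError(f"unknown node {s!r}")
    if (src & dst) or (src & cond) or (dst & cond):
        raise GraphError("src, dst and cond must be disjoint")
    return nx.is_d_separator(G, src, dst, cond)


def _as_digraph(g) -> nx.DiGraph:
    if isinstance(g, SelectionSWIG):
        return g.graph
    if isinstance(g, CausalGraph):
        return g.graph
    return g


def _iter(x):
    if isinstance(x, str):
        return [x]
    return list(x)


def _open_path(G: nx.DiGraph, src: str, dst: str, cond: set) -> list | None:
    """Return one d-connecting path from src to dst given cond, else None.

    Exhaustive walk over simple paths of the skeleton; adequate for the
    small graphs used in adjustment-set reasoning.
    """
    desc = {v: nx.descendants(G, v) | {v} for v in G.nodes}

    def path_open(path: list) -> bool:
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            collider = G.has_edge(prev, node) and G.has_edge(nxt, node)
            if collider:
                if not (desc[node] & cond):
                    return False
            else:
                if node in cond:
                    return False
        return True

    skeleton = G.to_undirected(as_view=True)
    for path in nx.all_simple_paths(skeleton, src, dst):
        if path_open(path):
            return path
    return None


@dataclass
class A4Verdict:
    """Graphical verdict on mean exchangeability across sources."""

    holds: bool
    adjustment_set: set
    witness_paths: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.holds


def check_a4(swig: SelectionSWIG, adjustment_set=()) -> A4Verdict:
    """Check mean exchangeability graphically on the selection SWIG.

    Holds iff Y^0 is d-separated from every selection node given the
    adjustment set.  On failure, one open path per offending S node is
    returned as a witness.  The adjustment set must consist of measured
    covariates.
    """
    X = set(_iter(adjustment_set))
    latent = swig.latent()
    if X & latent:
        raise GraphError(f"adjustment set contains latent node(s): {sorted(X & latent)}")
    unknown = X - swig.measured()
    if unknown:
        raise GraphError(f"adjustment set not among measured covariates: {sorted(unknown)}")
    witnesses = {}
    for s in swig.s_nodes:
        if not d_separated(swig.graph, {s}, {swig.outcome}, X):
            witnesses[s] = _open_path(swig.graph, s, swig.outcome, X)
    return A4Verdict(holds=not witnesses, adjustment_set=X, witness_paths=witnesses)


def minimal_adjustment_sets(swig: SelectionSWIG, candidates=None, max_size: int | None = None):
    """All inclusion-minimal adjustment sets among ``candidates`` for which
    the exchangeability check holds, ordered by size (exhaustive search)."""
    cands = sorted(set(_iter(candidates)) if candidates is not None else swig.measured())
    if len(cands) > 20:
        raise GraphError("candidate set too large for exhaustive enumeration (max 20)")
    max_size = len(cands) if max_size is None else min(max_size, len(cands))
    found: list[set] = []
    for k in range(0, max_size + 1):
        for combo in combinations(cands, k):
            X = set(combo)
            if any(prev <= X for prev in found):
                continue
            if check_a4(swig, X).holds:
                found.append(X)
    return found


def to_dot(g) -> str:
    """Render a graph as DOT text (selection nodes boxed, latent dashed)."""
    G = _as_digraph(g)
    latent = g.latent() if isinstance(g, SelectionSWIG) else set()
    s_nodes = set(g.s_nodes) if isinstance(g, SelectionSWIG) else set()
    lines = ["digraph G {"]
    for v in G.nodes:
        attrs = []
        if v in s_nodes:
            attrs.append("shape=box")
        if v in latent:
            attrs.append("style=dashed")
        lines.append(f'  "{v}"' + (f" [{', '.join(attrs)}]" if attrs else "") + ";")
    for u, v in G.edges:
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
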