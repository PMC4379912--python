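"""Median-joining haplotype networks with mutation-labeled edges.

Haplotypes are state vectors over a fixed site panel.  The network combines
epsilon-relaxed minimum-spanning connectivity with inferred median (Steiner)
vectors generated from triplets of linked nodes, iterated to a fixpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx

from .variants import VariantProfile

State = tuple[Hashable, ...]


@dataclass
class Haplotype:
    """A collapsed haplotype: one state vector with its sample multiplicity."""

    label: str
    states: State
    frequency: int = 1
    populations: set[str] = field(default_factory=set)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")


@dataclass
class NetworkGraph:
    """A haplotype network; wraps an undirected networkx graph.

    Node attributes: ``states``, ``frequency``, ``observed``.  Edge attribute
    ``tokens`` lists the panel site labels at which the endpoints differ
    (edge length = token count).
    """

    graph: nx.Graph
    panel: list[str]
    epsilon: int = 0

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]


def condense_haplotypes(
    profiles: Sequence[VariantProfile],
    panel: Sequence[tuple[int, int, str]] | Sequence[str],
    populations: dict[str, str] | None = None,
) -> list[Haplotype]:
    """Collapse identical profiles over a site panel into haplotypes.

    The panel is a list of mutation keys ``(position, insertion_index,
    derived)`` (or formatted tokens, resolved against profile tokens); the
    state vector is presence/absence of each panel mutation.  Every profile
    must cover every panel position.
    """
    keys: list[tuple[int, int, str]] = []
    for entry in panel:
        if isinstance(entry, tuple):
            keys.append(entry)
        else:
            raise TypeError("panel entries must be (position, insertion_index, derived) keys")
    by_state: dict[State, Haplotype] = {}
    for p in profiles:
        for pos, _, _ in keys:
            if not p.covers(pos):
                raise ValueError(f"profile {p.sample_id} does not cover panel position {pos}")
        pk = p.keys
        state = tuple(1 if k in pk else 0 for k in keys)
        if state not in by_state:
            by_state[state] = Haplotype(
                label=f"H{len(by_state) + 1}", states=state, frequency=0
            )
        h = by_state[state]
        h.frequency += 1
        h.samples.append(p.sample_id)
        if populations and p.sample_id in populations:
            h.populations.add(populations[p.sample_id])
    return list(by_state.values())


def _distance(a: State, b: State, weights: Sequence[float]) -> float:
    return sum(w for x, y, w in zip(a, b, weights) if x != y)


def _msn_edges(
    vectors: list[State], weights: Sequence[float], epsilon: float
) -> list[tuple[int, int]]:
    """Epsilon-relaxed minimum spanning network over state vectors.

    A pair (u, v) is linked iff d(u, v) <= sigma(u, v) + epsilon, where
    sigma is the minimax (bottleneck) path cost over the complete graph,
    i.e. the connection cost at which u and v first join in single-linkage
    clustering.  epsilon = 0 gives the classic minimum spanning network.
    """
    n = len(vectors)
    dist = [[0.0] * n for _ in range(n)]
    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        d = _distance(vectors[i], vectors[j], weights)
        dist[i][j] = dist[j][i] = d
        pairs.append((d, i, j))
    pairs.sort()
    # single-linkage: record sigma(u, v) via union-find merge levels
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sigma = [[0.0] * n for _ in range(n)]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for d, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            for a in members[ri]:
                for b in members[rj]:
                    sigma[a][b] = sigma[b][a] = d
            parent[rj] = ri
            members[ri].extend(members[rj])
            del members[rj]
    return [
        (i, j)
        for d, i, j in pairs
        if d <= sigma[i][j] + epsilon
    ]


def _median(u: State, v: State, w: State) -> State | None:
    """Coordinatewise majority vector; None where no site has a majority tie issue.

    For multistate sites with three distinct states the first vector's state
    is kept (quasi-median simplification; exact for binary data).
    """
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)
    return tuple(out)


def median_joining_network(
    haplotypes: Sequence[Haplotype],
    epsilon: int = 0,
    weights: Sequence[float] | None = None,
) -> NetworkGraph:
    """Build the median-joining network of a set of haplotypes.

    Iterates: epsilon-relaxed minimum-spanning connectivity, median vector
    generation from linked triplets (added when their connection cost is
    within epsilon of the optimum), and deletion of obsolete medians
    (unobserved vectors of degree <= 2), until no change.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    n_sites = len(haplotypes[0].states)
    if any(len(h.states) != n_sites for h in haplotypes):
        raise ValueError("haplotypes must share one site panel")
    if weights is None:
        weights = [1.0] * n_sites
    sampled: dict[State, Haplotype] = {}
    for h in haplotypes:
        if h.states in sampled:
            raise ValueError("duplicate haplotype state vectors; condense first")
        sampled[h.states] = h

    vectors: list[State] = [h.states for h in haplotypes]
    if len(vectors) == 1:
        g = nx.Graph()
        h = haplotypes[0]
        g.add_node(h.label, states=h.states, frequency=h.frequency, observed=True)
        return NetworkGraph(g, panel=[str(i) for i in range(n_sites)], epsilon=epsilon)

    for _ in range(200):  # fixpoint iteration bound
        edges = _msn_edges(vectors, weights, epsilon)
        linked = {tuple(sorted(e)) for e in edges}

        def is_linked(i: int, j: int) -> bool:
            return tuple(sorted((i, j))) in linked

        existing = set(vectors)
        candidates: dict[State, float] = {}
        for i, j, k in itertools.combinations(range(len(vectors)), 3):
            n_links = is_linked(i, j) + is_linked(i, k) + is_linked(j, k)
            if n_links < 2:
                continue
            m = _median(vectors[i], vectors[j], vectors[k])
            if m in existing:
                continue
            cost = (
                _distance(vectors[i], m, weights)
                + _distance(vectors[j], m, weights)
                + _distance(vectors[k], m, weights)
            )
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        added = False
        if candidates:
            lam = min(candidates.values())
            for m, cost in sorted(candidates.items(), key=lambda kv: (kv[1], kv[0])):
                if cost <= lam + epsilon:
                    vectors.append(m)
                    added = True
        # obsolete-median deletion on the refreshed connectivity
        while True:
            edges = _msn_edges(vectors, weights, epsilon)
            degree: dict[int, int] = {i: 0 for i in range(len(vectors))}
            for i, j in edges:
                degree[i] += 1
                degree[j] += 1
            drop = [
                i
                for i in range(len(vectors))
                if vectors[i] not in sampled and degree[i] <= 2
            ]
            if not drop:
                break
            vectors = [v for i, v in enumerate(vectors) if i not in set(drop)]
        if not added:
            break

    # build the final graph
    edges = _msn_edges(vectors, weights, epsilon)
    g = nx.Graph()
    median_count = 0
    labels: dict[State, str] = {}
    for v in sorted(vectors, key=lambda s: (s not in sampled, sampled[s].label if s in sampled else s)):
        if v in sampled:
            h = sampled[v]
            labels[v] = h.label
            g.add_node(
                h.label,
                states=v,
                frequency=h.frequency,
                observed=True,
                populations=sorted(h.populations),
            )
        else:
            median_count += 1
            labels[v] = f"mv{median_count}"
            g.add_node(labels[v], states=v, frequency=0, observed=False, populations=[])
    for i, j in edges:
        u, v = vectors[i], vectors[j]
        tokens = [str(s) for s in range(n_sites) if u[s] != v[s]]
        g.add_edge(labels[u], labels[v], tokens=tokens, length=len(tokens))
    return NetworkGraph(g, panel=[str(i) for i in range(n_sites)], epsilon=epsilon)


def total_edge_length(net: NetworkGraph) -> int:
    return sum(d["length"] for _, _, d in net.graph.edges(data=True))


def export_network(net: NetworkGraph, path: str, fmt: str = "GML") -> None:
    """Write the network as GML or DOT with deterministic node ordering."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    fmt = fmt.upper()
    if fmt == "GML":
        g = nx.Graph()
        for n in sorted(net.graph.nodes):
            d = net.graph.nodes[n]
            g.add_node(
                n,
                size=d["frequency"],
                observed=int(d["observed"]),
                states="".join(str(s) for s in d["states"]),
            )
        for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
            d = net.graph.edges[u, v]
            g.add_edge(u, v, label=" ".join(d["tokens"]), length=d["length"])
        nx.write_gml(g, path)
    elif fmt == "DOT":
        lines = ["graph haplotype_network {"]
        for n in sorted(net.graph.nodes):
            d = net.graph.nodes[n]
            shape = "circle" if d["observed"] else "point"
            lines.append(
                f'  "{n}" [width={max(d["frequency"], 1)}, shape={shape}];'
            )
        for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
            d = net.graph.edges[u, v]
            label = " ".join(d["tokens"])
            lines.append(f'  "{u}" -- "{v}" [label="{label}"];')
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_gml(path: str) -> NetworkGraph:
    g = nx.read_gml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(
            n,
            states=tuple(int(c) for c in d["states"]),
            frequency=int(d["size"]),
            observed=bool(d["observed"]),
        )
    for u, v, d in g.edges(data=True):
        tokens = d["label"].split() if d.get("label") else []
        out.add_edge(u, v, tokens=tokens, length=int(d["length"]))
    n_sites = len(next(iter(out.nodes(data=True)))[1]["states"]) if out.nodes else 0
    return NetworkGraph(out, panel=[str(i) for i in range(n_sites)])
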