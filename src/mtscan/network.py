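"""Statistical-parsimony haplotype network estimation and branch contrasts.

Observed haplotypes are joined through single-mutation edges, inserting
unobserved intermediate nodes where the closest pair of two components
differs at more than one site.  Components are connected at increasing
Hamming distance (the Kruskal order), which makes the total number of edges
minimal over all connection topologies.

Two kinds of ambiguity are tracked:

* **connection loops** — a pair of haplotypes becomes connectable at the same
  distance through which the components were already joined in the same
  round; the alternative connection is materialized, creating a cycle, and
  recorded as an :class:`AmbiguityLoop`.  This is what a homoplasy (a site
  mutating twice) produces.
* **path-order loops** — a multi-step connection admits several orders of the
  intermediate mutations.  The ascending-rCRS order is materialized and the
  ambiguity is recorded as metadata only, because every ordering induces the
  same bipartitions of observed haplotypes and is therefore statistically
  inert.

Connection loops are resolved by two criteria applied in order: descend from
the "older" candidate parent (higher ancestry score: a blend of haplotype
frequency and closeness centrality), then from the higher-frequency parent;
double ties stay unresolved and are carried into scanning as alternative
resolutions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .genotype_io import Haplotype, VariantDef

__all__ = [
    "hamming",
    "build_network",
    "score_ancestry",
    "resolve_ambiguities",
    "enumerate_contrasts",
    "HaplotypeNetwork",
    "AmbiguityLoop",
    "Contrast",
    "write_graphml",
    "write_dot",
    "write_contrast_table",
]


def hamming(alleles_a: Sequence[int], alleles_b: Sequence[int]) -> int:
    """Number of sites at which two allele vectors differ."""
    a = np.asarray(alleles_a)
    b = np.asarray(alleles_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int((a != b).sum())


@dataclass
class AmbiguityLoop:
    """One ambiguity: alternative equally parsimonious connections."""

    loop_id: str
    kind: str  # "connection" | "path_order"
    child: str  # node whose parent edge is ambiguous (connection loops)
    candidate_edges: list[tuple[str, str]]  # (child, candidate_parent)
    resolution: str = "unresolved"  # resolved_by_age | resolved_by_frequency | unresolved
    chosen_edge: tuple[str, str] | None = None
    # path_order loops: the sites of the multi-step connection
    sites: tuple[int, ...] = ()
    n_alternative_orders: int = 0


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: alleles, observed, count; edge attr: site
    ambiguity_loops: list[AmbiguityLoop] = field(default_factory=list)
    root_id: str | None = None
    ancestry_scores: dict[str, float] = field(default_factory=dict)
    connected: bool = True

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def unresolved_loops(self, kind: str = "connection") -> list[AmbiguityLoop]:
        return [
            l
            for l in self.ambiguity_loops
            if l.kind == kind and l.resolution == "unresolved"
        ]

    #: total single-mutation steps of the chosen connections (excludes
    #: materialized alternative connections); for a fully resolved network
    #: this equals |edges| = |nodes| - 1
    parsimony_edge_count: int = 0

    @property
    def tree_edge_count(self) -> int:
        return self.parsimony_edge_count


@dataclass
class Contrast:
    """A branch cut: bipartition of observed haplotypes into two alleles.

    ``side_a`` is the clade side (fewer individuals); ``side_b`` the rest of
    the network.
    """

    contrast_id: str
    branch_ids: list[int]
    resolution_id: str
    side_a: frozenset[str]  # haplotype ids
    side_b: frozenset[str]
    individuals_a: frozenset[str]
    individuals_b: frozenset[str]
    sites: tuple[int, ...] = ()  # site indices of the contributing branches


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _intermediate_path(
    alleles_a: tuple[int, ...],
    alleles_b: tuple[int, ...],
    variants: Sequence[VariantDef] | None,
) -> list[tuple[tuple[int, ...], int]]:
    """Single-site steps from a to b, flipping sites in ascending rCRS order.

    Returns a list of (next_vector, site_index) pairs ending at ``alleles_b``.
    """
    diff = [i for i, (x, y) in enumerate(zip(alleles_a, alleles_b)) if x != y]
    if variants is not None:
        diff.sort(key=lambda i: variants[i].rcrs_position)
    steps = []
    cur = list(alleles_a)
    for site in diff:
        cur[site] = 1 - cur[site]
        steps.append((tuple(cur), site))
    return steps


def build_network(
    haplotypes: Sequence[Haplotype],
    max_connection_steps: int = 10,
    variants: Sequence[VariantDef] | None = None,
) -> HaplotypeNetwork:
    """Estimate the parsimony network over observed haplotypes.

    Components are joined at increasing connection distance d = 1, 2, ...,
    ``max_connection_steps``; a d-step join inserts d-1 inferred intermediate
    nodes (sites flipped in ascending rCRS order).  Equally short alternative
    connections found in the same round are materialized and recorded as
    ambiguity loops.  If the network is still disconnected at the limit the
    partitioned graph is returned with ``connected=False``.
    """
    if not haplotypes:
        raise ValueError("no haplotypes to connect")
    if max_connection_steps < 1:
        raise ValueError("max_connection_steps must be >= 1")

    G = nx.Graph()
    vec_to_node: dict[tuple[int, ...], str] = {}
    for h in haplotypes:
        G.add_node(h.haplotype_id, alleles=h.alleles, observed=True, count=h.count)
        if h.alleles in vec_to_node:
            raise ValueError("duplicate allele vectors across haplotypes")
        vec_to_node[h.alleles] = h.haplotype_id

    ids = [h.haplotype_id for h in haplotypes]
    vecs = np.array([h.alleles for h in haplotypes], dtype=np.int8)
    D = (vecs[:, None, :] != vecs[None, :, :]).sum(axis=2)

    loops: list[AmbiguityLoop] = []
    inferred_counter = itertools.count(1)

    def add_connection(node_a: str, node_b: str) -> tuple[str, str]:
        """Materialize a path of single-site edges; return the edge at node_b."""
        va = G.nodes[node_a]["alleles"]
        vb = G.nodes[node_b]["alleles"]
        steps = _intermediate_path(va, vb, variants)
        prev = node_a
        last_edge = (node_a, node_b)
        for vec, site in steps:
            if vec == vb:
                nxt = node_b
            elif vec in vec_to_node:
                nxt = vec_to_node[vec]
            else:
                nxt = f"I{next(inferred_counter):03d}"
                G.add_node(nxt, alleles=vec, observed=False, count=0)
                vec_to_node[vec] = nxt
            if not G.has_edge(prev, nxt):
                G.add_edge(prev, nxt, site=site)
            last_edge = (prev, nxt)
            prev = nxt
        if len(steps) > 1:
            loops.append(
                AmbiguityLoop(
                    loop_id=f"L{len(loops) + 1:03d}",
                    kind="path_order",
                    child=node_b,
                    candidate_edges=[],
                    sites=tuple(s for _, s in steps),
                    n_alternative_orders=(
                        math.factorial(len(steps)) - 1 if len(steps) <= 10 else -1
                    ),
                )
            )
        return last_edge

    uf = _UnionFind(ids)
    # deterministic candidate order: distance, then allele vectors
    order = sorted(
        ((int(D[i, j]), i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))),
        key=lambda t: (t[0], tuple(vecs[t[1]]), tuple(vecs[t[2]])),
    )
    by_d: dict[int, list[tuple[int, int]]] = {}
    for d, i, j in order:
        by_d.setdefault(d, []).append((i, j))

    mst_weight = 0
    for d in range(1, max_connection_steps + 1):
        if d not in by_d:
            continue
        start_comp = {x: uf.find(x) for x in ids}
        for i, j in by_d[d]:
            a, b = ids[i], ids[j]
            if uf.find(a) != uf.find(b):
                add_connection(a, b)
                uf.union(a, b)
                mst_weight += d
            elif start_comp[a] != start_comp[b]:
                # joined earlier in THIS round: an equally short alternative
                child, parent = (a, b) if tuple(vecs[i]) > tuple(vecs[j]) else (b, a)
                try:
                    old_path = nx.shortest_path(G, child, parent)
                except nx.NetworkXNoPath:  # pragma: no cover - defensive
                    continue
                old_edge = (child, old_path[1])
                new_edge = add_connection(parent, child)
                new_edge = (child, new_edge[0] if new_edge[1] == child else new_edge[1])
                if {old_edge[1]} == {new_edge[1]}:
                    continue  # same edge; nothing ambiguous
                loops.append(
                    AmbiguityLoop(
                        loop_id=f"L{len(loops) + 1:03d}",
                        kind="connection",
                        child=child,
                        candidate_edges=[old_edge, new_edge],
                    )
                )
            # same component since before this round: a longer connection
            # already exists; not equally parsimonious, skip silently
        if len({uf.find(x) for x in ids}) == 1:
            break

    n_comp = len({uf.find(x) for x in ids})
    net = HaplotypeNetwork(
        graph=G,
        ambiguity_loops=loops,
        connected=n_comp == 1,
        parsimony_edge_count=mst_weight,
    )
    if n_comp > 1:
        import logging

        logging.getLogger("mtscan").warning(
            "network disconnected at max_connection_steps=%d: %d components",
            max_connection_steps,
            n_comp,
        )
    return net


# ---------------------------------------------------------------------------
# ancestry scoring and ambiguity resolution
# ---------------------------------------------------------------------------

def score_ancestry(net: HaplotypeNetwork, w: float = 0.5) -> dict[str, float]:
    """Score each node's plausibility as an ancestral haplotype.

    score = w * (count / total count) + (1-w) * closeness centrality
    rescaled to [0, 1].  The root is the argmax, ties broken by lexicographic
    allele vector.  Higher scores mean "older" under the interior/frequency
    heuristics used to orient the network.
    """
    G = net.graph
    total = sum(nx.get_node_attributes(G, "count").values()) or 1
    closeness = nx.closeness_centrality(G)
    cmax = max(closeness.values()) or 1.0
    scores = {
        n: w * (G.nodes[n]["count"] / total) + (1 - w) * (closeness[n] / cmax)
        for n in G.nodes
    }
    net.ancestry_scores = scores
    net.root_id = min(
        G.nodes, key=lambda n: (-scores[n], tuple(G.nodes[n]["alleles"]))
    )
    return scores


def resolve_ambiguities(net: HaplotypeNetwork) -> HaplotypeNetwork:
    """Resolve connection loops by the age then frequency criteria.

    For each loop the child keeps the edge to the candidate parent with the
    higher ancestry score; on a tie, the higher-count parent; on a double tie
    the loop stays unresolved (and is later enumerated as alternative
    resolutions).  The rejected connection's edges are removed, along with
    any inferred nodes left dangling (degree <= 1) by the removal.
    """
    if not net.ancestry_scores:
        score_ancestry(net)
    G = net.graph
    scores = net.ancestry_scores
    for loop in net.ambiguity_loops:
        if loop.kind != "connection" or loop.resolution != "unresolved":
            continue
        parents = [e[1] for e in loop.candidate_edges]
        sc = [scores[p] for p in parents]
        cnt = [G.nodes[p]["count"] for p in parents]
        best_sc = max(sc)
        tied = [k for k, s in enumerate(sc) if abs(s - best_sc) < 1e-12]
        if len(tied) == 1:
            winner = tied[0]
            loop.resolution = "resolved_by_age"
        else:
            best_cnt = max(cnt[k] for k in tied)
            tied2 = [k for k in tied if cnt[k] == best_cnt]
            if len(tied2) == 1:
                winner = tied2[0]
                loop.resolution = "resolved_by_frequency"
            else:
                continue  # unresolved: carried into scanning
        loop.chosen_edge = loop.candidate_edges[winner]
        for k, edge in enumerate(loop.candidate_edges):
            if k != winner:
                _remove_connection(G, edge)
    return net


def _remove_connection(G: nx.Graph, edge: tuple[str, str]) -> None:
    if G.has_edge(*edge):
        G.remove_edge(*edge)
    # prune inferred nodes orphaned by the removal
    changed = True
    while changed:
        changed = False
        for n in list(G.nodes):
            if not G.nodes[n]["observed"] and G.degree(n) <= 1:
                G.remove_node(n)
                changed = True


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def _resolution_graphs(net: HaplotypeNetwork) -> list[tuple[str, nx.Graph]]:
    """One tree per alternative resolution of remaining unresolved loops."""
    unresolved = net.unresolved_loops("connection")
    if not unresolved:
        return [("R0", net.graph)]
    graphs = []
    choices = [range(len(l.candidate_edges)) for l in unresolved]
    for r, combo in enumerate(itertools.product(*choices)):
        H = net.graph.copy()
        for loop, keep in zip(unresolved, combo):
            for k, edge in enumerate(loop.candidate_edges):
                if k != keep:
                    _remove_connection(H, edge)
        graphs.append((f"R{r}", H))
    return graphs


def enumerate_contrasts(
    net: HaplotypeNetwork, haplotypes: Sequence[Haplotype]
) -> list[Contrast]:
    """Enumerate branch cuts as bipartitions of observed haplotypes.

    Every edge of the (resolved) tree is cut; cuts inducing the same
    bipartition of observed haplotypes (hence of individuals) are merged into
    one contrast that retains all contributing branch ids.  Unresolved loops
    are handled by enumerating each alternative resolution separately and
    tagging the contrasts with the resolution id.
    """
    members = {h.haplotype_id: h.members for h in haplotypes}
    observed_ids = set(members)
    contrasts: list[Contrast] = []
    for res_id, G in _resolution_graphs(net):
        edges = sorted(
            G.edges(data=True),
            key=lambda e: (e[2]["site"], min(e[0], e[1]), max(e[0], e[1])),
        )
        bridge_set = {frozenset(e) for e in nx.bridges(G)}
        seen: dict[frozenset[frozenset[str]], int] = {}
        per_res: list[dict] = []
        for branch_id, (u, v, data) in enumerate(edges, start=1):
            if frozenset((u, v)) not in bridge_set:
                continue  # cycle edge under an unresolved loop kept verbatim
            H = G.copy()
            H.remove_edge(u, v)
            comp_u = nx.node_connected_component(H, u)
            side_u = frozenset(n for n in comp_u if n in observed_ids)
            side_v = frozenset(observed_ids - side_u)
            if not side_u or not side_v:
                continue  # cutting a pendant inferred branch: no split
            key = frozenset((side_u, side_v))
            if key in seen:
                per_res[seen[key]]["branch_ids"].append(branch_id)
                per_res[seen[key]]["sites"].append(data["site"])
                continue
            seen[key] = len(per_res)
            per_res.append(
                {
                    "branch_ids": [branch_id],
                    "sites": [data["site"]],
                    "sides": (side_u, side_v),
                }
            )
        for entry in per_res:
            side_u, side_v = entry["sides"]
            ind_u = frozenset().union(*(members[h] for h in side_u))
            ind_v = frozenset().union(*(members[h] for h in side_v))
            if (len(ind_u), sorted(side_u)) <= (len(ind_v), sorted(side_v)):
                a, b, ia, ib = side_u, side_v, ind_u, ind_v
            else:
                a, b, ia, ib = side_v, side_u, ind_v, ind_u
            contrasts.append(
                Contrast(
                    contrast_id="",
                    branch_ids=sorted(entry["branch_ids"]),
                    resolution_id=res_id,
                    side_a=a,
                    side_b=b,
                    individuals_a=ia,
                    individuals_b=ib,
                    sites=tuple(sorted(set(entry["sites"]))),
                )
            )
    contrasts.sort(key=lambda c: (c.resolution_id, c.branch_ids[0]))
    width = max(3, len(str(len(contrasts))))
    for k, c in enumerate(contrasts, start=1):
        c.contrast_id = f"C{k:0{width}d}"
    return contrasts


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _edge_label(data: dict, variants: Sequence[VariantDef] | None) -> str:
    site = data["site"]
    if variants is not None:
        return variants[site].label
    return f"site{site}"


def write_graphml(
    net: HaplotypeNetwork,
    path: str | Path,
    variants: Sequence[VariantDef] | None = None,
) -> None:
    G = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        G.add_node(
            n,
            observed=bool(d["observed"]),
            count=int(d["count"]),
            alleles="".join(str(int(a)) for a in d["alleles"]),
        )
    for u, v, d in net.graph.edges(data=True):
        G.add_edge(u, v, site=int(d["site"]), label=_edge_label(d, variants))
    nx.write_graphml(G, str(path))


def write_dot(
    net: HaplotypeNetwork,
    path: str | Path,
    variants: Sequence[VariantDef] | None = None,
) -> None:
    """Minimal Graphviz DOT export (observed nodes as labelled ovals)."""
    lines = ["graph haplotype_network {"]
    for n, d in sorted(net.graph.nodes(data=True)):
        if d["observed"]:
            lines.append(f'  "{n}" [label="{n} (n={d["count"]})"];')
        else:
            lines.append(f'  "{n}" [label="", shape=point];')
    for u, v, d in sorted(net.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{_edge_label(d, variants)}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_contrast_table(contrasts: Sequence[Contrast], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "contrast_id": c.contrast_id,
            "resolution_id": c.resolution_id,
            "branch_ids": ";".join(map(str, c.branch_ids)),
            "n_a": len(c.individuals_a),
            "n_b": len(c.individuals_b),
            "side_a_haplotypes": ";".join(sorted(c.side_a)),
            "side_b_haplotypes": ";".join(sorted(c.side_b)),
        }
        for c in contrasts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
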