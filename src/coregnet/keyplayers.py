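"""Key-player extraction: hub-degree nodes, MDS and MCDS.

Domination is directed: a node u dominates v iff u == v or the edge u->v
exists ("control via outgoing regulation"); any node with in-degree 0 must
therefore belong to every dominating set. Connectivity (for the MCDS and the
largest connected component) is evaluated on the underlying undirected graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from coregnet.netbuild import RegulatoryNetwork

__all__ = [
    "KeyPlayerReport",
    "hub_nodes",
    "minimum_dominating_set",
    "largest_connected_component",
    "minimum_connected_dominating_set",
    "key_player_report",
]


@dataclass
class KeyPlayerReport:
    """Hub, MDS and MCDS node sets of one network."""

    network_id: str
    hubs: set[str]
    mds: set[str]
    mcds: set[str]
    lcc_size: int
    optimality: dict[str, str]  # per feature: "proven" | "heuristic"

    def feature(self, name: str) -> set[str]:
        return {"hubs": self.hubs, "mds": self.mds, "mcds": self.mcds}[name]


def hub_nodes(net: RegulatoryNetwork, fraction: float = 0.10) -> set[str]:
    """Top ``ceil(fraction * n)`` nodes by total (in + out) degree.

    Ties at the cut are resolved by higher degree first, then lexicographic
    node id.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("hub selection on an empty network")
    k = math.ceil(fraction * g.number_of_nodes())
    ranked = sorted(g.nodes, key=lambda v: (-(g.in_degree(v) + g.out_degree(v)), v))
    return set(ranked[:k])


# ---------------------------------------------------------------------------
# minimum dominating set (exact branch-and-bound, greedy fallback)
# ---------------------------------------------------------------------------

def _covers(g: nx.DiGraph) -> dict[str, frozenset[str]]:
    """node -> set of nodes it dominates (itself plus out-neighbours)."""
    return {v: frozenset({v}) | frozenset(g.successors(v)) for v in g.nodes}


def _greedy_mds(nodes: list[str], covers: dict[str, frozenset[str]], uncovered: set[str], chosen: set[str]) -> set[str]:
    chosen = set(chosen)
    uncovered = set(uncovered)
    while uncovered:
        best = min(
            (v for v in nodes if covers[v] & uncovered),
            key=lambda v: (-len(covers[v] & uncovered), v),
        )
        chosen.add(best)
        uncovered -= covers[best]
    return chosen


def minimum_dominating_set(
    net: RegulatoryNetwork,
    exact: bool = True,
    node_budget: int = 5_000_000,
) -> tuple[set[str], bool]:
    """Smallest set S with every node in S or out-reachable in one step from S.

    Solved by branch-and-bound on the equivalent set-cover instance (each
    node covers itself and its out-neighbours); nodes with in-degree 0 are
    forced members. Returns ``(set, proven)`` where ``proven`` is False when
    ``exact`` is off or the search budget was exhausted (greedy answer).
    The search order is deterministic, branching on the hardest-to-cover
    node and trying candidate coverers in (coverage, id) order.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("MDS of an empty network")
    covers = _covers(g)
    nodes = sorted(g.nodes)
    forced = {v for v in nodes if g.in_degree(v) == 0}
    uncovered = set(nodes)
    for v in forced:
        uncovered -= covers[v]

    greedy = _greedy_mds(nodes, covers, uncovered, forced)
    if not exact:
        return greedy, False

    best = [set(greedy)]
    budget = [node_budget]
    coverers: dict[str, list[str]] = {
        v: sorted(
            (u for u in nodes if v in covers[u]),
            key=lambda u: (-len(covers[u]), u),
        )
        for v in nodes
    }
    max_cover = max((len(c) for c in covers.values()), default=1)

    def search(chosen: set[str], uncov: frozenset[str]) -> None:
        if budget[0] <= 0:
            return
        budget[0] -= 1
        if not uncov:
            if len(chosen) < len(best[0]):
                best[0] = set(chosen)
            return
        if len(chosen) + math.ceil(len(uncov) / max_cover) >= len(best[0]):
            return
        # branch on the uncovered node with fewest coverers (most constrained)
        v = min(uncov, key=lambda x: (len(coverers[x]), x))
        for u in coverers[v]:
            search(chosen | {u}, uncov - covers[u])

    search(set(forced), frozenset(uncovered))
    proven = budget[0] > 0
    return best[0], proven


def largest_connected_component(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Induced subgraph on the largest weakly connected component.

    Ties between equal-sized components go to the one containing the
    lexicographically smallest node id.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("LCC of an empty network")
    comps = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), min(c)))
    sub = g.subgraph(comps[0]).copy()
    return RegulatoryNetwork(graph=sub, provenance=net.provenance, disease_name=net.disease_name)


def minimum_connected_dominating_set(net: RegulatoryNetwork) -> set[str]:
    """Connected dominating set of the LCC by deterministic greedy + pruning.

    Growth starts from the maximum-degree LCC node and repeatedly adds the
    undirected neighbour of the current set that dominates the most not-yet
    dominated nodes (ties: higher total degree, then lexicographic id). When
    no frontier node gains coverage, the next node on a shortest undirected
    path toward an undominated node is added, which guarantees progress.
    Afterwards members are pruned in reverse insertion order when removal
    preserves connectivity and domination. Feasible always; minimal not
    guaranteed.
    """
    lcc = largest_connected_component(net)
    g = lcc.graph
    nodes = set(g.nodes)
    if len(nodes) == 1:
        return set(nodes)
    und = g.to_undirected(as_view=False)
    covers = _covers(g)

    def deg(v: str) -> int:
        return g.in_degree(v) + g.out_degree(v)

    start = min(nodes, key=lambda v: (-deg(v), v))
    chosen: list[str] = [start]
    chosen_set = {start}
    dominated = set(covers[start])

    while dominated != nodes:
        frontier = sorted(
            {n for c in chosen_set for n in und.neighbors(c)} - chosen_set
        )
        gains = {v: len(covers[v] - dominated) for v in frontier}
        best_gain = max(gains.values(), default=0)
        if best_gain > 0:
            nxt = min(
                (v for v in frontier if gains[v] == best_gain),
                key=lambda v: (-deg(v), v),
            )
        else:
            nxt = _step_toward_undominated(und, chosen_set, nodes - dominated)
        chosen.append(nxt)
        chosen_set.add(nxt)
        dominated |= covers[nxt]

    # prune redundant members, newest first
    for v in reversed(chosen):
        if len(chosen_set) == 1:
            break
        trial = chosen_set - {v}
        still_dominated = set().union(*(covers[u] for u in trial)) == nodes
        if still_dominated and nx.is_connected(und.subgraph(trial)):
            chosen_set = trial
    return chosen_set


def _step_toward_undominated(und: nx.Graph, chosen: set[str], undominated: set[str]) -> str:
    """First node after the chosen set on a shortest path to an undominated node."""
    import collections

    q = collections.deque(sorted(chosen))
    parent: dict[str, str | None] = {v: None for v in chosen}
    target = None
    while q:
        v = q.popleft()
        if v in undominated and v not in chosen:
            target = v
            break
        for w in sorted(und.neighbors(v)):
            if w not in parent:
                parent[w] = v
                q.append(w)
    if target is None:  # unreachable: LCC is connected, cannot happen
        raise RuntimeError("no path to an undominated node inside the LCC")
    # walk back to the node adjacent to the chosen set
    node = target
    while parent[node] is not None and parent[node] not in chosen:
        node = parent[node]
    return node if node not in chosen else target


def key_player_report(
    net: RegulatoryNetwork,
    network_id: str,
    hub_fraction: float = 0.10,
    mds_exact: bool = True,
) -> KeyPlayerReport:
    """Compute hubs, MDS and MCDS of one network in a single report."""
    hubs = hub_nodes(net, hub_fraction)
    mds, proven = minimum_dominating_set(net, exact=mds_exact)
    lcc = largest_connected_component(net)
    mcds = minimum_connected_dominating_set(net)
    return KeyPlayerReport(
        network_id=network_id,
        hubs=hubs,
        mds=mds,
        mcds=mcds,
        lcc_size=lcc.n_nodes,
        optimality={"mds": "proven" if proven else "heuristic", "mcds": "heuristic"},
    )
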