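"""Non-serial dynamic programming over graph decomposition.

Rather than solving one large orientation ILP, the scaffolding graph is
decomposed along vertex cuts: connected components are independent;
articulation points (1-cuts) split them into biconnected pieces; vertex
pairs whose removal disconnects a piece (separation pairs, 2-cuts) split
those further, down to triconnected components.  Each piece is solved
bottom-up — twice for a 2-cut boundary (boundary vertices in the same and
in opposite orientation) — and the two values sol00/sol01 enter the parent
ILP as the term sol00 + (sol01 - sol00) * S_ij on the boundary pair.  A
top-down pass then picks, for every child, the stored sub-solution
matching the parent's realized boundary parity, flipping the whole child
solution when the boundary vertex orientations disagree.

Because the ILP (including the 3-cycle constraints) depends on the flip
bits only through edge parities, a child's optimum is a function of the
boundary parity alone, which makes the two-solve scheme exact.  To keep it
exact, a separation pair {u, v} is only used when all common neighbours of
u and v fall on a single side of the cut (so no triangle is torn apart);
the (u, v) edge itself travels to that side.

The decomposition is specified by contract (split at vertex cuts until no
valid cut remains); the quadratic separation-pair search below is adequate
at the component sizes the thinning heuristic guarantees, with SPQR-style
linear-time decomposition as a possible optimization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .graph import ScaffoldEdge, ScaffoldGraph, rebundle
from .orient import OrientationSolution, recompute_objective, solve_orientation

log = logging.getLogger("mlscaffold")

DEFAULT_MAX_COMPONENT_NODES = 500


@dataclass
class DecompositionNode:
    """One piece of the decomposition: an edge-disjoint induced component
    plus its 0-, 1- or 2-vertex boundary toward the parent."""

    nodes: frozenset[str]
    edges: list[ScaffoldEdge]
    boundary: tuple[str, ...]
    children: list["DecompositionNode"] = field(default_factory=list)
    #: per boundary case (None for 0/1-cut, 0/1 parity for 2-cut):
    #: the component-local solution and the value including descendants
    sol_cases: dict = field(default_factory=dict)
    case_values: dict = field(default_factory=dict)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class DecompositionTree:
    roots: list[DecompositionNode]

    def all_nodes(self) -> list[DecompositionNode]:
        return [n for r in self.roots for n in r.walk()]

    def max_component_size(self) -> int:
        sizes = [len(n.nodes) for n in self.all_nodes()]
        return max(sizes) if sizes else 0

    def report_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("component\tnodes\tedges\tboundary\tdepth\n")

            def rec(node, depth, idx):
                fh.write(
                    f"{idx}\t{len(node.nodes)}\t{len(node.edges)}\t"
                    f"{','.join(node.boundary) or '-'}\t{depth}\n"
                )
                j = idx + 1
                for c in node.children:
                    j = rec(c, depth + 1, j)
                return j

            i = 0
            for r in self.roots:
                i = rec(r, 0, i)


def _nx_graph(nodes: frozenset[str], edges: Sequence[ScaffoldEdge]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_edges_from(e.key for e in edges)
    return g


def _partition_edges(
    edges: Sequence[ScaffoldEdge],
    cut: tuple[str, ...],
    comp_of: dict[str, int],
    uv_edge_comp: int | None,
) -> dict[int, list[ScaffoldEdge]]:
    """Assign each edge to the component of its non-cut endpoint(s);
    ``uv_edge_comp`` receives the cut-pair edge itself (-1 = home)."""
    out: dict[int, list[ScaffoldEdge]] = {}
    cutset = set(cut)
    for e in edges:
        ends = [n for n in e.key if n not in cutset]
        if not ends:
            out.setdefault(uv_edge_comp if uv_edge_comp is not None else -1,
                           []).append(e)
        else:
            out.setdefault(comp_of[ends[0]], []).append(e)
    return out


def _try_split(node: DecompositionNode):
    """Find a valid 1- or 2-vertex cut of ``node``'s component.

    Pinned vertices (the node's own boundary plus the boundaries of
    already-attached children) must stay together on the home side.
    Returns (home_nodes, home_edges, [(child_nodes, child_edges, cut)])
    or None when no valid cut exists.
    """
    if len(node.nodes) <= 2:
        return None
    g = _nx_graph(node.nodes, node.edges)
    pinned = set(node.boundary)
    for c in node.children:
        pinned |= set(c.boundary)

    def finish(cut, comps, uv_comp):
        comp_of = {v: i for i, comp in enumerate(comps) for v in comp}
        pin_comps = {comp_of[v] for v in pinned if v not in cut}
        if len(pin_comps) > 1:
            return None
        if pin_comps:
            home = pin_comps.pop()
        else:
            home = max(range(len(comps)), key=lambda i: (len(comps[i]),
                                                         -i))
        edge_parts = _partition_edges(
            node.edges, cut, comp_of, uv_comp if uv_comp is not None else home
        )
        home_nodes = frozenset(comps[home]) | set(cut)
        home_edges = edge_parts.get(home, [])
        kids = []
        for i, comp in enumerate(comps):
            if i == home:
                continue
            kids.append((frozenset(comp) | set(cut), edge_parts.get(i, []),
                         cut))
        if not kids:
            return None
        return home_nodes, home_edges, kids

    # 1-cuts first: articulation points
    for c in sorted(nx.articulation_points(g)):
        h = g.copy()
        h.remove_node(c)
        comps = sorted(nx.connected_components(h), key=lambda s: sorted(s)[0])
        res = finish((c,), comps, None)
        if res is not None:
            return res
    # 2-cuts: separation pairs, triangle-safe
    vs = sorted(node.nodes)
    if len(vs) < 4:
        return None
    adj = {v: set(g.neighbors(v)) for v in vs}
    for i, u in enumerate(vs):
        for v in vs[i + 1:]:
            h = g.copy()
            h.remove_nodes_from((u, v))
            if nx.is_connected(h):
                continue
            comps = sorted(nx.connected_components(h),
                           key=lambda s: sorted(s)[0])
            comp_of = {x: k for k, comp in enumerate(comps) for x in comp}
            common = (adj[u] & adj[v]) - {u, v}
            uv_comp = None
            if g.has_edge(u, v):
                owner = {comp_of[w] for w in common}
                if len(owner) > 1:
                    continue  # a cut here would tear a triangle apart
                uv_comp = owner.pop() if owner else None
            res = finish((u, v), comps, uv_comp)
            if res is not None:
                return res
    return None


def decompose(
    graph: ScaffoldGraph | tuple[Sequence[str], Sequence[ScaffoldEdge]],
    max_component_nodes: int = DEFAULT_MAX_COMPONENT_NODES,
) -> DecompositionTree:
    """Decompose the scaffolding graph into a forest of 2-/3-connected
    pieces.  ``max_component_nodes`` is not enforced here; callers use
    :func:`thin` when a piece stays above the threshold."""
    if isinstance(graph, ScaffoldGraph):
        all_nodes = graph.nodes
        all_edges = graph.edge_list()
    else:
        all_nodes, all_edges = sorted(graph[0]), sorted(
            graph[1], key=lambda e: e.key
        )
    g = nx.Graph()
    g.add_nodes_from(all_nodes)
    g.add_edges_from(e.key for e in all_edges)
    edges_by_key = {e.key: e for e in all_edges}

    roots = []
    for comp in sorted(nx.connected_components(g), key=lambda s: sorted(s)[0]):
        comp = frozenset(comp)
        comp_edges = [edges_by_key[k] for k in sorted(edges_by_key)
                      if k[0] in comp]
        root = DecompositionNode(nodes=comp, edges=comp_edges, boundary=())
        stack = [root]
        while stack:
            node = stack.pop()
            res = _try_split(node)
            if res is None:
                continue
            home_nodes, home_edges, kids = res
            node.nodes = home_nodes
            node.edges = home_edges
            for kid_nodes, kid_edges, cut in kids:
                child = DecompositionNode(
                    nodes=kid_nodes, edges=kid_edges, boundary=tuple(cut)
                )
                node.children.append(child)
                stack.append(child)
            stack.append(node)  # the home piece may split further
        roots.append(root)
    return DecompositionTree(roots=roots)


def nsdp_solve(
    tree: DecompositionTree,
    all_edges: Sequence[ScaffoldEdge] | None = None,
    forbid_triangles: bool = True,
) -> OrientationSolution:
    """Bottom-up two-solve dynamic program over the decomposition tree,
    followed by the top-down pass merging child solutions into one globally
    consistent orientation."""
    # bottom-up: post-order over each root
    for root in tree.roots:
        order: list[DecompositionNode] = []
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(n.children)
        for node in reversed(order):
            bonuses: dict[tuple[str, str], list[float]] = {}
            const = 0.0
            for child in node.children:
                if len(child.boundary) == 2:
                    key = tuple(sorted(child.boundary))
                    b = bonuses.setdefault(key, [0.0, 0.0])
                    b[0] += child.case_values[0]
                    b[1] += child.case_values[1]
                else:
                    const += child.case_values[None]
            pb = {k: (v[0], v[1]) for k, v in bonuses.items()}
            if len(node.boundary) == 2:
                i, j = sorted(node.boundary)
                for parity in (0, 1):
                    sol = solve_orientation(
                        node.nodes, node.edges, boundary={i: 0, j: parity},
                        pair_bonuses=pb, forbid_triangles=forbid_triangles,
                    )
                    node.sol_cases[parity] = sol
                    node.case_values[parity] = sol.total_value + const
            else:
                fixed = {}
                if len(node.boundary) == 1:
                    fixed = {node.boundary[0]: 0}
                elif node.nodes:
                    fixed = {min(node.nodes): 0}  # break the global flip tie
                sol = solve_orientation(
                    node.nodes, node.edges, boundary=fixed,
                    pair_bonuses=pb, forbid_triangles=forbid_triangles,
                )
                node.sol_cases[None] = sol
                node.case_values[None] = sol.total_value + const

    # top-down: select and orient child solutions
    flips: dict[str, int] = {}
    parity: dict[tuple[str, str], int] = {}
    selected: dict[tuple[str, str], object] = {}
    for root in tree.roots:
        stack = [(root, None, 0)]
        while stack:
            node, case, invert = stack.pop()
            sol = node.sol_cases[case]
            for v, f in sol.flips.items():
                flips[v] = f ^ invert
            for k, s in sol.selected_state.items():
                selected[k] = s
                parity[k] = flips[k[0]] ^ flips[k[1]]
            for child in node.children:
                if len(child.boundary) == 2:
                    i, j = sorted(child.boundary)
                    p = flips[i] ^ flips[j]
                    stack.append((child, p, flips[i]))
                else:
                    (c,) = child.boundary
                    stack.append((child, None, flips[c]))

    edges = all_edges
    if edges is None:
        edges = [e for t in tree.all_nodes() for e in t.edges]
    merged = OrientationSolution(flips, parity, selected, 0.0, 0.0)
    merged.objective = recompute_objective(merged, edges)
    merged.total_value = merged.objective
    expected = sum(r.case_values[None] for r in tree.roots)
    if abs(merged.objective - expected) > 1e-6 * max(1.0, abs(expected)):
        raise RuntimeError(
            "NSDP merge inconsistency: merged objective "
            f"{merged.objective:.9g} != combined component value {expected:.9g}"
        )
    return merged


def thin(
    graph: ScaffoldGraph,
    max_component_nodes: int = DEFAULT_MAX_COMPONENT_NODES,
) -> tuple[ScaffoldGraph, int, DecompositionTree]:
    """Raise the bundle-size threshold until no decomposition piece exceeds
    ``max_component_nodes``; returns the thinned graph, the threshold
    actually used, and the final decomposition."""
    g = graph
    bundle = graph.min_bundle
    rounds = 0
    while True:
        tree = decompose(g, max_component_nodes)
        if tree.max_component_size() <= max_component_nodes:
            if rounds:
                log.info("thinning: %d rounds, final min_bundle=%d, "
                         "%d edges kept", rounds, bundle, len(g.edges))
            return g, bundle, tree
        bundle += 1
        rounds += 1
        g = rebundle(g, bundle)
        if not g.edges:
            log.warning("thinning emptied the graph at min_bundle=%d", bundle)
            return g, bundle, decompose(g, max_component_nodes)
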