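"""Maximum-likelihood contig orientation as an integer linear program.

For one connected component of the scaffolding graph, the ILP chooses a
flip bit S_i per contig and at most one state per bundled edge so that the
sum of selected state log-odds weights is maximal, subject to:

- parity agreement: an auxiliary S_ij = S_i XOR S_j per edge; same-
  orientation states (A, D) are selectable only when S_ij = 0, opposite-
  orientation states (B, C) only when S_ij = 1;
- 3-cycle exclusion over the precedence convention (A, B assert
  contig_a -> contig_b; C, D the reverse) for every triangle; 2-cycles are
  impossible because an edge carries at most one selected state.

Longer directed cycles are broken heuristically after solving.  The ILP is
solved exactly with HiGHS through :func:`scipy.optimize.milp`.  A
brute-force enumerator over all flip assignments serves as an independent
test oracle for small components.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import (
    ALL_STATES,
    STATE_PARITY,
    STATES_A_AHEAD,
    EdgeState,
    ScaffoldEdge,
)

log = logging.getLogger("mlscaffold")

INTEGRALITY_TOL = 1e-6


@dataclass
class BoundaryCondition:
    """Flip bits forced on 0, 1, or 2 cut vertices during a component solve."""

    fixed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fixed) > 2:
            raise ValueError("at most 2 boundary nodes per component solve")
        if any(v not in (0, 1) for v in self.fixed.values()):
            raise ValueError("boundary values must be 0 or 1")


@dataclass
class OrientationSolution:
    """Per-contig flips, per-edge parity and selected state, and the
    log-odds objective (sum of selected state weights)."""

    flips: dict[str, int]
    edge_parity: dict[tuple[str, str], int]
    selected_state: dict[tuple[str, str], EdgeState | None]
    objective: float
    #: objective plus any dynamic-programming bonus terms realized in this
    #: solve (equals ``objective`` for a plain solve)
    total_value: float = 0.0

    def copy(self) -> "OrientationSolution":
        return OrientationSolution(
            dict(self.flips), dict(self.edge_parity),
            dict(self.selected_state), self.objective, self.total_value,
        )


def conv_direction(
    key: tuple[str, str], state: EdgeState
) -> tuple[str, str]:
    """Precedence convention: A and B assert contig_a -> contig_b, C and D
    assert contig_b -> contig_a."""
    a, b = key
    return (a, b) if state in STATES_A_AHEAD else (b, a)


def physical_direction(
    key: tuple[str, str], state: EdgeState, flip_a: int
) -> tuple[str, str]:
    """Physically realized precedence of a selected state given the flip of
    the lexicographically smaller endpoint.

    With flip_a = 0 the final strand of the a-side mate equals its observed
    strand, so states whose a-strand is '+' (A, B) place contig_a first;
    flipping contig_a mirrors that.
    """
    a, b = key
    ahead = (state in STATES_A_AHEAD) == (flip_a == 0)
    return (a, b) if ahead else (b, a)


# ---------------------------------------------------------------------------
# Triangle (3-cycle) constraints
# ---------------------------------------------------------------------------

def find_triangles(edges: Sequence[ScaffoldEdge]) -> list[tuple[str, str, str]]:
    adj: dict[str, set[str]] = {}
    for e in edges:
        adj.setdefault(e.contig_a, set()).add(e.contig_b)
        adj.setdefault(e.contig_b, set()).add(e.contig_a)
    tris = []
    for e in edges:
        u, v = e.contig_a, e.contig_b
        for w in sorted(adj[u] & adj[v]):
            if w > v:
                tris.append((u, v, w))
    return sorted(tris)


def precedence_cycle_constraints(
    edges: Sequence[ScaffoldEdge],
) -> list[list[tuple[tuple[str, str], tuple[str, str]]]]:
    """For each triangle, the two rotation constraints forbidding a directed
    3-cycle of selected precedences.

    Each constraint is a list of three (edge_key, asserted_direction) terms
    whose indicator sum must be <= 2; the indicator of (key, (x, y)) is
    A_xy + B_xy when x is the smaller endpoint, C + D otherwise.
    """
    by_pair = {e.key: e for e in edges}
    out = []
    for (u, v, w) in find_triangles(edges):
        def term(x, y):
            key = (x, y) if x < y else (y, x)
            assert key in by_pair
            return (key, (x, y))

        out.append([term(u, v), term(v, w), term(w, u)])
        out.append([term(v, u), term(w, v), term(u, w)])
    return out


# ---------------------------------------------------------------------------
# ILP model
# ---------------------------------------------------------------------------

@dataclass
class IlpModel:
    nodes: list[str]
    edges: list[ScaffoldEdge]
    node_var: dict[str, int]
    parity_var: dict[tuple[str, str], int]
    state_var: dict[tuple[tuple[str, str], EdgeState], int]
    c: np.ndarray  # maximization objective coefficients
    constraints: LinearConstraint | None
    lb: np.ndarray
    ub: np.ndarray
    constant: float  # bonus constant added to the objective value
    n_agreement_constraints: int
    n_cycle_constraints: int

    @property
    def n_vars(self) -> int:
        return len(self.c)

    def dump_lp(self, path) -> None:
        """Debug dump in a minimal LP-ish text format."""
        names = [""] * self.n_vars
        for n, i in self.node_var.items():
            names[i] = f"S_{n}"
        for k, i in self.parity_var.items():
            names[i] = f"S_{k[0]}_{k[1]}"
        for (k, s), i in self.state_var.items():
            names[i] = f"{s.value}_{k[0]}_{k[1]}"
        with open(path, "w") as fh:
            fh.write("Maximize\n obj: " + " + ".join(
                f"{self.c[i]:.6g} {names[i]}"
                for i in range(self.n_vars) if self.c[i]
            ) + f" + {self.constant:.6g}\n")
            fh.write("Binaries\n " + " ".join(names) + "\n")


def build_ilp(
    nodes: Iterable[str],
    edges: Sequence[ScaffoldEdge],
    boundary: BoundaryCondition | dict[str, int] | None = None,
    pair_bonuses: dict[tuple[str, str], tuple[float, float]] | None = None,
    forbid_triangles: bool = True,
) -> IlpModel:
    """Assemble the orientation ILP for one component.

    ``pair_bonuses`` maps a node pair (i, j) to (bonus_same,
    bonus_opposite): the value added to the objective when S_i XOR S_j is
    0, respectively 1.  This realizes the dynamic-programming weight update
    (bonus_same on the same-orientation states A/D, bonus_opposite on B/C),
    implemented equivalently as bonus_same + (bonus_opposite - bonus_same)
    * S_ij so the bonus also applies when no state is selected on the pair.
    A pair without a real edge gets a zero-weight virtual parity variable.
    """
    if boundary is None:
        boundary = BoundaryCondition()
    elif isinstance(boundary, dict):
        boundary = BoundaryCondition(fixed=dict(boundary))
    pair_bonuses = pair_bonuses or {}
    nodes = sorted(nodes)
    node_set = set(nodes)
    for n in boundary.fixed:
        if n not in node_set:
            raise ValueError(f"boundary node {n!r} not in component")
    edges = sorted(edges, key=lambda e: e.key)

    parity_keys = sorted({e.key for e in edges} | set(pair_bonuses))
    for (i, j) in parity_keys:
        if i not in node_set or j not in node_set:
            raise ValueError(f"edge/bonus pair ({i},{j}) not in component")

    node_var = {n: i for i, n in enumerate(nodes)}
    off = len(nodes)
    parity_var = {k: off + i for i, k in enumerate(parity_keys)}
    off += len(parity_keys)
    state_var: dict[tuple[tuple[str, str], EdgeState], int] = {}
    for e in edges:
        for s in ALL_STATES:
            state_var[(e.key, s)] = off
            off += 1
    n_vars = off

    c = np.zeros(n_vars)
    for e in edges:
        for s in ALL_STATES:
            c[state_var[(e.key, s)]] = e.weight_by_state[s]
    constant = 0.0
    for k, (b_same, b_opp) in pair_bonuses.items():
        c[parity_var[k]] += b_opp - b_same
        constant += b_same

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    ub_rows: list[float] = []

    def add_row(terms: list[tuple[int, float]], bound: float) -> None:
        r = len(ub_rows)
        for col, v in terms:
            rows.append(r)
            cols.append(col)
            vals.append(v)
        ub_rows.append(bound)

    # agreement constraints tying S_ij to S_i XOR S_j
    for (i, j) in parity_keys:
        si, sj, sij = node_var[i], node_var[j], parity_var[(i, j)]
        add_row([(sij, 1), (si, -1), (sj, -1)], 0)   # S_ij <= S_i + S_j
        add_row([(sij, 1), (si, 1), (sj, 1)], 2)     # S_ij <= 2 - S_i - S_j
        add_row([(sij, -1), (sj, 1), (si, -1)], 0)   # S_ij >= S_j - S_i
        add_row([(sij, -1), (si, 1), (sj, -1)], 0)   # S_ij >= S_i - S_j
    # state admissibility per edge
    for e in edges:
        sij = parity_var[e.key]
        add_row([(state_var[(e.key, EdgeState.A)], 1),
                 (state_var[(e.key, EdgeState.D)], 1), (sij, 1)], 1)
        add_row([(state_var[(e.key, EdgeState.B)], 1),
                 (state_var[(e.key, EdgeState.C)], 1), (sij, -1)], 0)
    n_agreement = len(ub_rows)

    n_cycle = 0
    if forbid_triangles:
        for constraint in precedence_cycle_constraints(edges):
            terms = []
            for key, (x, _y) in constraint:
                if x == key[0]:
                    pair = (EdgeState.A, EdgeState.B)
                else:
                    pair = (EdgeState.C, EdgeState.D)
                terms += [(state_var[(key, s)], 1.0) for s in pair]
            add_row(terms, 2)
            n_cycle += 1

    lb = np.zeros(n_vars)
    ub = np.ones(n_vars)
    for n, v in boundary.fixed.items():
        lb[node_var[n]] = ub[node_var[n]] = v

    constraints = None
    if ub_rows:
        A = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(ub_rows), n_vars)
        ).tocsr()
        constraints = LinearConstraint(
            A, -np.inf * np.ones(len(ub_rows)), np.array(ub_rows)
        )

    return IlpModel(
        nodes=nodes, edges=edges, node_var=node_var, parity_var=parity_var,
        state_var=state_var, c=c, constraints=constraints, lb=lb, ub=ub,
        constant=constant, n_agreement_constraints=n_agreement - 0,
        n_cycle_constraints=n_cycle,
    )


def solve_ilp(model: IlpModel) -> OrientationSolution:
    """Solve a built model to proven optimality and extract the solution.

    Selected states with non-positive weight are normalized to "no state":
    they contribute nothing to the likelihood, and dropping them makes the
    selection deterministic across solver tie-breaks.
    """
    if not model.edges and not any(model.c):
        # degenerate component: no selectable evidence
        flips = {n: 0 for n in model.nodes}
        for i, n in enumerate(model.nodes):
            if model.lb[model.node_var[n]] == model.ub[model.node_var[n]]:
                flips[n] = int(model.lb[model.node_var[n]])
        parity = {k: flips[k[0]] ^ flips[k[1]] for k in model.parity_var}
        return OrientationSolution(flips, parity, {}, 0.0, model.constant)
    res = milp(
        c=-model.c,
        constraints=model.constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(model.lb, model.ub),
    )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP solve failed: {res.message}")
    x = res.x
    flips = {n: int(round(x[i])) for n, i in model.node_var.items()}
    parity = {k: int(round(x[i])) for k, i in model.parity_var.items()}
    selected: dict[tuple[str, str], EdgeState | None] = {}
    objective = 0.0
    for e in model.edges:
        chosen: EdgeState | None = None
        for s in ALL_STATES:
            if x[model.state_var[(e.key, s)]] > 0.5:
                chosen = s
                break
        if chosen is not None and e.weight_by_state[chosen] <= 0:
            chosen = None
        selected[e.key] = chosen
        if chosen is not None:
            objective += e.weight_by_state[chosen]
    bonus_value = -res.fun - sum(
        e.weight_by_state[s]
        for e in model.edges
        for s in ALL_STATES
        if x[model.state_var[(e.key, s)]] > 0.5
    )
    total = objective + bonus_value + model.constant
    return OrientationSolution(flips, parity, selected, objective, total)


def solve_orientation(
    nodes: Iterable[str],
    edges: Sequence[ScaffoldEdge],
    boundary: BoundaryCondition | dict[str, int] | None = None,
    pair_bonuses: dict[tuple[str, str], tuple[float, float]] | None = None,
    forbid_triangles: bool = True,
) -> OrientationSolution:
    """Build and solve the orientation ILP for one component."""
    model = build_ilp(nodes, edges, boundary, pair_bonuses, forbid_triangles)
    return solve_ilp(model)


# ---------------------------------------------------------------------------
# Heuristic breaking of cycles longer than 3
# ---------------------------------------------------------------------------

def break_long_cycles(
    solution: OrientationSolution, edges: Sequence[ScaffoldEdge]
) -> OrientationSolution:
    """Deselect the minimum-weight edge of every remaining directed cycle in
    the selected-precedence graph; returns a new solution with the
    objective recomputed."""
    by_key = {e.key: e for e in edges}
    sol = solution.copy()
    dg = nx.DiGraph()
    for key, state in sol.selected_state.items():
        if state is None:
            continue
        u, v = conv_direction(key, state)
        dg.add_edge(u, v, key=key, weight=by_key[key].weight_by_state[state])
    removed = 0
    while True:
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            break
        worst = min(cycle, key=lambda uv: dg.edges[uv[0], uv[1]]["weight"])
        key = dg.edges[worst[0], worst[1]]["key"]
        sol.selected_state[key] = None
        dg.remove_edge(*worst[:2])
        removed += 1
    if removed:
        log.info("cycle breaking deselected %d edges", removed)
        sol.objective = recompute_objective(sol, edges)
        sol.total_value = sol.objective
    return sol


def recompute_objective(
    solution: OrientationSolution, edges: Sequence[ScaffoldEdge]
) -> float:
    by_key = {e.key: e for e in edges}
    return sum(
        by_key[k].weight_by_state[s]
        for k, s in solution.selected_state.items()
        if s is not None
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_orientation(
    nodes: Iterable[str],
    edges: Sequence[ScaffoldEdge],
    forbid_triangles: bool = True,
    max_nodes: int = 15,
) -> OrientationSolution:
    """Exhaustive optimum over all 2^|V| flip assignments.

    For each assignment, every edge independently takes the best
    non-negative admissible state (same-parity forward or backward
    precedence), except that edges participating in triangles are searched
    exactly so that no directed 3-cycle of selected precedences remains.
    Independent of the ILP path; used as the correctness oracle.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    if n > max_nodes:
        raise ValueError(f"component too large for brute force ({n} nodes)")
    edges = sorted(edges, key=lambda e: e.key)
    m = len(edges)
    idx = {v: i for i, v in enumerate(nodes)}
    if m == 0:
        return OrientationSolution({v: 0 for v in nodes}, {}, {}, 0.0, 0.0)

    ia = np.array([idx[e.contig_a] for e in edges])
    ib = np.array([idx[e.contig_b] for e in edges])
    wA = np.array([e.weight_by_state[EdgeState.A] for e in edges])
    wB = np.array([e.weight_by_state[EdgeState.B] for e in edges])
    wC = np.array([e.weight_by_state[EdgeState.C] for e in edges])
    wD = np.array([e.weight_by_state[EdgeState.D] for e in edges])

    n_assign = 1 << n
    bits = (np.arange(n_assign)[:, None] >> np.arange(n)[None, :]) & 1
    par = bits[:, ia] ^ bits[:, ib]  # (n_assign, m)
    w_fwd = np.where(par == 0, wA, wB)  # conv a -> b
    w_bwd = np.where(par == 0, wD, wC)  # conv b -> a
    greedy = np.maximum(0.0, np.maximum(w_fwd, w_bwd))

    triangles: list[tuple[int, int, int]] = []
    if forbid_triangles:
        key_idx = {e.key: i for i, e in enumerate(edges)}
        for (u, v, w) in find_triangles(edges):
            triangles.append((
                key_idx[tuple(sorted((u, v)))],
                key_idx[tuple(sorted((v, w)))],
                key_idx[tuple(sorted((u, w)))],
            ))
    tri_edges = sorted({e for t in triangles for e in t})
    free_mask = np.ones(m, bool)
    free_mask[tri_edges] = False

    def directed_pair(e_i: int, d: int) -> tuple[str, str]:
        a, b = edges[e_i].contig_a, edges[e_i].contig_b
        return (a, b) if d > 0 else (b, a)

    def is_cycle(dirs: dict[int, int], tri: tuple[int, int, int]) -> bool:
        pairs = []
        for e_i in tri:
            d = dirs.get(e_i, 0)
            if d == 0:
                return False
            pairs.append(directed_pair(e_i, d))
        heads = {p[1] for p in pairs}
        return len(heads) == 3

    # triangles completed once all their edges are decided, indexed by the
    # position (in tri_edges) of their last-decided edge
    pos_of = {e_i: p for p, e_i in enumerate(tri_edges)}
    done_at: list[list[tuple[int, int, int]]] = [[] for _ in tri_edges]
    for t in triangles:
        done_at[max(pos_of[e] for e in t)].append(t)

    def exact_value(k: int) -> tuple[float, dict[int, int]]:
        base = float(greedy[k, free_mask].sum())
        wf, wb = w_fwd[k], w_bwd[k]
        suffix = np.zeros(len(tri_edges) + 1)
        for p in range(len(tri_edges) - 1, -1, -1):
            suffix[p] = suffix[p + 1] + greedy[k, tri_edges[p]]
        best_v = -math.inf
        best_choice: dict[int, int] = {}
        dirs: dict[int, int] = {}

        def dfs(p: int, acc: float) -> None:
            nonlocal best_v, best_choice
            if acc + suffix[p] <= best_v + 1e-12:
                return
            if p == len(tri_edges):
                if acc > best_v:
                    best_v = acc
                    best_choice = dict(dirs)
                return
            e_i = tri_edges[p]
            options = sorted(
                [(float(wf[e_i]), 1), (float(wb[e_i]), -1), (0.0, 0)],
                key=lambda t: -t[0],
            )
            for gain, d in options:
                if d != 0 and gain <= 0:
                    continue
                dirs[e_i] = d
                if d == 0 or all(
                    not is_cycle(dirs, t) for t in done_at[p]
                ):
                    dfs(p + 1, acc + (gain if d else 0.0))
                del dirs[e_i]

        dfs(0, 0.0)
        return base + best_v, best_choice

    if not triangles:
        best_k = int(np.argmax(greedy.sum(1)))
        best_val = float(greedy[best_k].sum())
        best_choice: dict[int, int] = {}
    else:
        bound = greedy.sum(1)
        order = np.argsort(-bound, kind="stable")
        best_val = -math.inf
        best_k = 0
        best_choice = {}
        for k in order:
            if bound[k] <= best_val + 1e-12:
                break
            val, choice = exact_value(int(k))
            if val > best_val + 1e-12:
                best_val, best_k, best_choice = val, int(k), choice

    flips = {v: int(bits[best_k, idx[v]]) for v in nodes}
    parity = {}
    selected: dict[tuple[str, str], EdgeState | None] = {}
    for e_i, e in enumerate(edges):
        p = int(par[best_k, e_i])
        parity[e.key] = p
        if e_i in pos_of:
            d = best_choice.get(e_i, 0)
        else:
            wf, wb = float(w_fwd[best_k, e_i]), float(w_bwd[best_k, e_i])
            if max(wf, wb) <= 0:
                d = 0
            else:
                d = 1 if wf >= wb else -1
        if d == 0:
            selected[e.key] = None
        elif d > 0:
            selected[e.key] = EdgeState.A if p == 0 else EdgeState.B
        else:
            selected[e.key] = EdgeState.D if p == 0 else EdgeState.C
    return OrientationSolution(flips, parity, selected, best_val, best_val)


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

def validate_solution(
    solution: OrientationSolution,
    edges: Sequence[ScaffoldEdge],
    require_acyclic: bool = False,
    tol: float = 1e-6,
) -> None:
    """Assert the structural invariants of an orientation solution:
    XOR-consistent parities, parity-admissible selected states, objective
    equal to the selected-weight sum, and no directed 2-/3-cycles among
    selected precedences (no cycles at all with ``require_acyclic``)."""
    by_key = {e.key: e for e in edges}
    for (i, j), p in solution.edge_parity.items():
        if p != (solution.flips[i] ^ solution.flips[j]):
            raise AssertionError(f"parity of ({i},{j}) is not S_i XOR S_j")
    dg = nx.DiGraph()
    for key, state in solution.selected_state.items():
        if state is None:
            continue
        if key in solution.edge_parity:
            if STATE_PARITY[state] != solution.edge_parity[key]:
                raise AssertionError(f"state {state} inadmissible on {key}")
        dg.add_edge(*conv_direction(key, state))
    obj = recompute_objective(solution, [by_key[k] for k in solution.selected_state])
    if abs(obj - solution.objective) > tol:
        raise AssertionError("objective does not match selected weights")
    if require_acyclic:
        if not nx.is_directed_acyclic_graph(dg):
            raise AssertionError("selected precedences contain a directed cycle")
    else:
        for cyc in nx.simple_cycles(dg, length_bound=3):
            raise AssertionError(f"short directed cycle {cyc} survived the ILP")
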