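"""Scaffold chain extraction and maximum-likelihood gap estimation.

The orientation solution selects at most one state per edge; the
physically realized precedence of each selected edge (which contig comes
first, given the flips) defines a directed graph that is linearized by
maximum-weight bipartite matching between successor slots and predecessor
slots.  Matched edges form vertex-disjoint simple paths — the scaffold
chains.  Gap lengths are then estimated per chain by minimizing the
squared standardized deviation of every spanning pair's implied insert
from the library mean, a bound-constrained linear least-squares problem.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import lsq_linear

from .alignment_io import ContigRecord, InsertModel, ReadPairLink
from .graph import ScaffoldEdge, ScaffoldGraph
from .orient import OrientationSolution, physical_direction

log = logging.getLogger("mlscaffold")

#: default lower bound on gap estimates: small negative values represent
#: contig overlaps the assembler failed to merge
DEFAULT_G_MIN = -150.0
DEFAULT_GAP = 100.0


@dataclass
class ScaffoldChain:
    """Ordered, oriented contigs with estimated gaps between neighbours."""

    contigs: list[tuple[str, str]]  # (contig id, '+' or '-')
    gaps: list[float] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contigs)

    def ids(self) -> list[str]:
        return [c for c, _ in self.contigs]

    def span(self, contigs: dict[str, ContigRecord]) -> float:
        total = sum(contigs[c].length for c, _ in self.contigs)
        return total + sum(self.gaps)


@dataclass
class GapEstimate:
    value: float
    support: int
    residual: float  # RMS deviation of implied inserts from mu


# ---------------------------------------------------------------------------
# Linearization by bipartite matching
# ---------------------------------------------------------------------------

def selected_directed_edges(
    solution: OrientationSolution, graph: ScaffoldGraph
) -> list[tuple[str, str, float, tuple[str, str]]]:
    """(u, v, weight, key) for every selected edge, with u preceding v in
    the physically realized layout."""
    out = []
    for key in sorted(solution.selected_state):
        state = solution.selected_state[key]
        if state is None:
            continue
        u, v = physical_direction(key, state, solution.flips[key[0]])
        w = graph.edges[key].weight_by_state[state]
        out.append((u, v, w, key))
    return out


def linearize(
    solution: OrientationSolution, graph: ScaffoldGraph
) -> list[ScaffoldChain]:
    """Extract vertex-disjoint chains from the selected precedences.

    A bipartite graph pairs each contig's successor slot with candidate
    predecessor slots; maximum-weight matching keeps the best-supported
    successor per contig.  Any residual successor cycle (impossible after
    cycle breaking, but tolerated defensively) is opened at its
    minimum-weight matched edge.  Contigs without a matched neighbour
    become singleton chains.

    Selected edges that are transitively implied (u -> w alongside a
    selected two-step path u -> v -> w) are long-range links spanning a
    short intervening contig; they support the same layout rather than an
    alternative one, so they are excluded from the adjacency matching
    (their pairs still inform gap estimation).
    """
    directed = selected_directed_edges(solution, graph)
    out_nbrs: dict[str, set[str]] = {}
    for u, v, _w, _k in directed:
        out_nbrs.setdefault(u, set()).add(v)
    skip = {
        (u, v)
        for u, v, _w, _k in directed
        if any(v in out_nbrs.get(x, ()) for x in out_nbrs.get(u, ()))
    }
    if skip:
        log.info("matching: %d transitively implied long-range edges "
                 "set aside", len(skip))
    bg = nx.Graph()
    for u, v, w, key in directed:
        if (u, v) in skip:
            continue
        # small constant keeps zero-weight selected edges in the matching
        bg.add_edge(("out", u), ("in", v), weight=w + 1e-6, key=key, w=w)
    matching = nx.max_weight_matching(bg)

    succ: dict[str, str] = {}
    meta: dict[str, tuple[float, tuple[str, str]]] = {}
    for x, y in matching:
        if x[0] == "in":
            x, y = y, x
        u, v = x[1], y[1]
        data = bg.edges[x, y]
        succ[u] = v
        meta[u] = (data["w"], data["key"])

    # open residual successor cycles at the weakest matched edge
    pred = {v: u for u, v in succ.items()}
    visited: set[str] = set()
    for start in sorted(succ):
        if start in visited:
            continue
        path = []
        seen_local = {}
        cur = start
        while cur in succ and cur not in seen_local:
            seen_local[cur] = len(path)
            path.append(cur)
            cur = succ[cur]
        visited.update(path)
        if cur in seen_local:  # found a cycle
            cyc = path[seen_local[cur]:]
            weakest = min(cyc, key=lambda u: (meta[u][0], u))
            del pred[succ[weakest]]
            del succ[weakest]
            log.warning("opened a residual %d-cycle in the matching", len(cyc))

    flips = solution.flips
    chains: list[ScaffoldChain] = []
    placed: set[str] = set()
    for cid in sorted(graph.contigs):
        if cid in placed or cid in pred:
            continue
        members = [cid]
        edge_keys = []
        cur = cid
        while cur in succ:
            edge_keys.append(meta[cur][1])
            cur = succ[cur]
            members.append(cur)
        placed.update(members)
        chains.append(ScaffoldChain(
            contigs=[(m, "-" if flips.get(m, 0) else "+") for m in members],
            edges=edge_keys,
        ))
    return chains


# ---------------------------------------------------------------------------
# Gap estimation
# ---------------------------------------------------------------------------

def _final_strand(observed: str, orientation: str) -> str:
    if orientation == "+":
        return observed
    return "-" if observed == "+" else "+"


def _spanning_conditional_mean(
    mu: float,
    sigma: float,
    T: np.ndarray,
    len_left: np.ndarray,
    len_right: np.ndarray,
    read_len: float,
    max_offset_sum: float | None = None,
    grid_points: int = 201,
) -> np.ndarray:
    """Expected insert among pairs observed to span a gap region.

    A fragment of insert i spans a region of total length T (gaps plus
    interior contigs) only when both mates land fully on the flanking
    contigs, which allows
    ``min(L_left, i - T - rlen) - max(rlen, i - T - L_right) + 1``
    placements of the left mate; conditional on being observed, the insert
    density is the Gaussian tilted by that placement count (zero beyond the
    discordant-pair cutoff ``max_offset_sum`` on i - T).  The conditional
    mean has no closed form once the flank lengths bind, so it is computed
    on a grid over mu +/- 5 sigma.
    """
    i = np.linspace(mu - 5 * sigma, mu + 5 * sigma, grid_points)[None, :]
    f = np.exp(-0.5 * ((i - mu) / sigma) ** 2)
    o = i - T[:, None]  # offset sum implied by insert i
    w = (
        np.minimum(len_left[:, None], o - read_len)
        - np.maximum(read_len, o - len_right[:, None])
        + 1.0
    )
    w = np.clip(w, 0.0, None)
    if max_offset_sum is not None:
        w = np.where(o <= max_offset_sum, w, 0.0)
    fw = f * w
    norm_ = fw.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (fw * i).sum(axis=1) / norm_
    return np.where(norm_ > 1e-12, m, mu)


def estimate_gaps(
    chain: ScaffoldChain,
    spanning_links: Sequence[ReadPairLink],
    contigs: dict[str, ContigRecord],
    insert_model: InsertModel,
    g_min: float = DEFAULT_G_MIN,
    default_gap: float = DEFAULT_GAP,
    read_len: float | None = None,
    max_offset_sum: float | None = None,
) -> list[GapEstimate]:
    """Maximum-likelihood gap lengths for one chain.

    Every link whose two mates land on chain contigs at positions u < v and
    point toward each other in the final orientations implies
    insert = offset_u + sum(g_t + [t > u] * len_t for t in u..v-1) + offset_v,
    linear in the gap vector.  The Gaussian insert likelihood is maximized
    by bound-constrained least squares (g >= g_min, allowing small
    overlaps).  Adjacencies with no spanning link fall back to
    ``default_gap``.  Updates ``chain.gaps`` in place.

    When ``read_len`` is given, the conditional-likelihood correction for
    spanning-pair length bias is applied: pairs observed to span a gap are
    biased toward long inserts (long fragments have more placements that
    straddle the gap), so each link's target is the tilted-Gaussian mean
    from :func:`_spanning_tilted_mean` instead of mu, re-fit once from the
    uncorrected solution.
    """
    k = len(chain) - 1
    if k <= 0:
        chain.gaps = []
        return []
    pos = {c: i for i, (c, _) in enumerate(chain.contigs)}
    orient = dict(chain.contigs)
    lengths = [contigs[c].length for c, _ in chain.contigs]

    rows: list[tuple[int, int]] = []  # gap index range [u, v)
    rhs: list[float] = []
    for link in spanning_links:
        if link.contig_a not in pos or link.contig_b not in pos:
            continue
        ia, ib = pos[link.contig_a], pos[link.contig_b]
        if ia == ib:
            continue
        if ia < ib:
            u, v = ia, ib
            s_u = _final_strand(link.strand_a, orient[link.contig_a])
            s_v = _final_strand(link.strand_b, orient[link.contig_b])
            off_u, off_v = link.offset_a, link.offset_b
        else:
            u, v = ib, ia
            s_u = _final_strand(link.strand_b, orient[link.contig_b])
            s_v = _final_strand(link.strand_a, orient[link.contig_a])
            off_u, off_v = link.offset_b, link.offset_a
        if s_u != "+" or s_v != "-":
            continue  # not concordant with the chain layout
        interior = sum(lengths[u + 1:v])
        rows.append((u, v))
        rhs.append(insert_model.mu - off_u - off_v - interior)

    estimates = [GapEstimate(default_gap, 0, 0.0) for _ in range(k)]
    if rows:
        covered = sorted({t for (u, v) in rows for t in range(u, v)})
        col = {t: i for i, t in enumerate(covered)}
        A = np.zeros((len(rows), len(covered)))
        for r, (u, v) in enumerate(rows):
            for t in range(u, v):
                A[r, col[t]] = 1.0
        b = np.asarray(rhs)
        res = lsq_linear(
            A, b, bounds=(g_min, np.inf), tol=1e-12, max_iter=500
        )
        g = res.x
        if read_len is not None:
            # length-bias correction: re-target each link at the
            # conditional mean implied by the current gap-region estimate
            mu, sigma = insert_model.mu, insert_model.sigma
            interior_arr = np.array(
                [sum(lengths[u + 1:v]) for (u, v) in rows], dtype=float
            )
            T = interior_arr + A @ g
            l_left = np.array([lengths[u] for (u, _v) in rows], dtype=float)
            l_right = np.array([lengths[v] for (_u, v) in rows], dtype=float)
            mu_eff = _spanning_conditional_mean(
                mu, sigma, T, l_left, l_right, read_len,
                max_offset_sum=max_offset_sum,
            )
            res = lsq_linear(
                A, b + (mu_eff - mu), bounds=(g_min, np.inf),
                tol=1e-12, max_iter=500,
            )
            g = res.x
        fitted = A @ g - b  # implied insert minus mu, per link
        for t in covered:
            i = col[t]
            touching = [r for r, (u, v) in enumerate(rows) if u <= t < v]
            rms = float(math.sqrt(np.mean(fitted[touching] ** 2)))
            estimates[t] = GapEstimate(float(g[i]), len(touching), rms)
    chain.gaps = [e.value for e in estimates]
    return estimates


def links_by_chain(
    chains: Sequence[ScaffoldChain], links: Sequence[ReadPairLink]
) -> dict[int, list[ReadPairLink]]:
    """Group links by the chain on which both of their contigs lie."""
    chain_of: dict[str, int] = {}
    for i, ch in enumerate(chains):
        for c, _ in ch.contigs:
            chain_of[c] = i
    out: dict[int, list[ReadPairLink]] = {i: [] for i in range(len(chains))}
    for link in links:
        ia = chain_of.get(link.contig_a)
        ib = chain_of.get(link.contig_b)
        if ia is not None and ia == ib:
            out[ia].append(link)
    return out


# ---------------------------------------------------------------------------
# AGP / FASTA emission
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _gap_run(gap: float) -> int:
    return max(1, int(round(gap)))


def name_chains(
    chains: Sequence[ScaffoldChain],
    contigs: dict[str, ContigRecord],
    prefix: str = "scaffold",
) -> list[tuple[str, ScaffoldChain]]:
    """Deterministic scaffold names, numbered by decreasing span."""
    order = sorted(
        range(len(chains)),
        key=lambda i: (-chains[i].span(contigs), chains[i].ids()[0]),
    )
    return [(f"{prefix}_{r + 1}", chains[i]) for r, i in enumerate(order)]


def write_agp(
    named: Sequence[tuple[str, ScaffoldChain]],
    contigs: dict[str, ContigRecord],
    path,
) -> None:
    """AGP v2.1: one W line per contig, one N line per gap (gap_type
    scaffold, linkage yes, evidence paired-ends).  The raw (possibly
    negative) gap estimate is preserved in gap-estimate comment lines;
    the N-line length is the estimate rounded and floored at 1."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for name, chain in named:
            for t, g in enumerate(chain.gaps):
                fh.write(f"# gap-estimate\t{name}\t{t + 1}\t{g:.2f}\n")
        for name, chain in named:
            pos = 1
            part = 1
            for i, (cid, orient) in enumerate(chain.contigs):
                clen = contigs[cid].length
                fh.write("\t".join([
                    name, str(pos), str(pos + clen - 1), str(part), "W",
                    cid, "1", str(clen), orient,
                ]) + "\n")
                pos += clen
                part += 1
                if i < len(chain.gaps):
                    run = _gap_run(chain.gaps[i])
                    fh.write("\t".join([
                        name, str(pos), str(pos + run - 1), str(part), "N",
                        str(run), "scaffold", "yes", "paired-ends",
                    ]) + "\n")
                    pos += run
                    part += 1


def parse_agp(path) -> list[tuple[str, ScaffoldChain]]:
    """Re-parse an AGP file written by :func:`write_agp` (round-trip)."""
    chains: dict[str, ScaffoldChain] = {}
    order: list[str] = []
    est: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# gap-estimate"):
                _, name, t, g = ln.split("\t")
                est[(name, int(t))] = float(g)
                continue
            if ln.startswith("#"):
                continue
            parts = ln.split("\t")
            name = parts[0]
            if name not in chains:
                chains[name] = ScaffoldChain(contigs=[], gaps=[])
                order.append(name)
            if parts[4] == "W":
                chains[name].contigs.append((parts[5], parts[8]))
            elif parts[4] == "N":
                t = len(chains[name].gaps) + 1
                chains[name].gaps.append(
                    est.get((name, t), float(parts[5]))
                )
    return [(n, chains[n]) for n in order]


def write_scaffold_fasta(
    named: Sequence[tuple[str, ScaffoldChain]],
    contigs: dict[str, ContigRecord],
    path,
    width: int = 60,
) -> None:
    """Scaffold sequences: oriented contigs joined by N runs (>= 1 N even
    for non-positive gap estimates)."""
    with open(path, "w") as fh:
        for name, chain in named:
            parts = []
            for i, (cid, orient) in enumerate(chain.contigs):
                seq = contigs[cid].sequence
                if seq is None:
                    raise ValueError(f"contig {cid} has no sequence")
                parts.append(seq if orient == "+" else revcomp(seq))
                if i < len(chain.gaps):
                    parts.append("N" * _gap_run(chain.gaps[i]))
            seq = "".join(parts)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_chains_tsv(
    named: Sequence[tuple[str, ScaffoldChain]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\tcontig\torientation\tgap_after\n")
        for name, chain in named:
            for i, (cid, orient) in enumerate(chain.contigs):
                gap = f"{chain.gaps[i]:.2f}" if i < len(chain.gaps) else "."
                fh.write(f"{name}\t{i + 1}\t{cid}\t{orient}\t{gap}\n")


def read_chains_tsv(path) -> list[tuple[str, ScaffoldChain]]:
    chains: dict[str, ScaffoldChain] = {}
    order: list[str] = []
    with open(path) as fh:
        next(fh)
        for ln in fh:
            name, _pos, cid, orient, gap = ln.rstrip("\n").split("\t")
            if name not in chains:
                chains[name] = ScaffoldChain(contigs=[], gaps=[])
                order.append(name)
            chains[name].contigs.append((cid, orient))
            if gap != ".":
                chains[name].gaps.append(float(gap))
    return [(n, chains[n]) for n in order]


def validate_chains(
    chains: Sequence[ScaffoldChain], contigs: dict[str, ContigRecord]
) -> None:
    """Chains are vertex-disjoint and cover every contig exactly once."""
    seen: list[str] = [c for ch in chains for c in ch.ids()]
    if len(seen) != len(set(seen)):
        raise AssertionError("a contig appears in more than one chain")
    if set(seen) != set(contigs):
        raise AssertionError("chains do not cover the contig set exactly")
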