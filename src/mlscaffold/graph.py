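"""Scaffolding graph construction.

Contigs are nodes; all read pairs bridging one pair of contigs are bundled
into a single bidirected edge.  The four strand configurations of a pair
(A, B, C, D) encode the relative orientation and precedence of the two
contigs: A and D require the contigs in the *same* relative orientation,
B and C in *opposite* orientation.  Each state accumulates the log-odds
weight sum of its supporting pairs, which is what the orientation ILP
maximizes over.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .alignment_io import (
    DEFAULT_EPSILON,
    ContigRecord,
    InsertModel,
    ReadPairLink,
    clamp,
    log_odds,
)

log = logging.getLogger("mlscaffold")


class EdgeState(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


#: (strand_a, strand_b) -> state, for links canonicalized with contig_a < contig_b
STATE_OF_STRANDS = {
    ("+", "-"): EdgeState.A,
    ("-", "+"): EdgeState.D,
    ("+", "+"): EdgeState.B,
    ("-", "-"): EdgeState.C,
}

#: orientation parity class: 0 = same relative orientation, 1 = opposite
STATE_PARITY = {EdgeState.A: 0, EdgeState.D: 0, EdgeState.B: 1, EdgeState.C: 1}

#: precedence convention: these states assert contig_a -> contig_b, the
#: other two assert contig_b -> contig_a (representative flip S_a = 0)
STATES_A_AHEAD = frozenset({EdgeState.A, EdgeState.B})

ALL_STATES = (EdgeState.A, EdgeState.B, EdgeState.C, EdgeState.D)

PROBABILITY_MODELS = ("uniform", "repeat", "coverage", "product")


def classify_state(link: ReadPairLink) -> EdgeState:
    """State of a canonical link from its observed strand pair."""
    return STATE_OF_STRANDS[(link.strand_a, link.strand_b)]


def coverage_similarity(cov_a: float, cov_b: float) -> float:
    """1 - |cov_a - cov_b| / (cov_a + cov_b); defined as 1 when both are 0
    (no evidence of dissimilarity)."""
    total = cov_a + cov_b
    if total <= 0:
        return 1.0
    return 1.0 - abs(cov_a - cov_b) / total


def mapping_probability(
    link: ReadPairLink,
    model: str,
    coverages: dict[str, float] | None = None,
    p0: float = 0.9,
    eps: float = DEFAULT_EPSILON,
) -> float:
    """Annotate a link with its mapping probability p_r under one of the
    four models (uniform constant p0, repeat-based, coverage-based, or
    their product).  Updates ``link.p_cov``/``link.p_r`` and returns p_r."""
    if model not in PROBABILITY_MODELS:
        raise ValueError(f"unknown probability model {model!r}")
    if model in ("coverage", "product"):
        if coverages is None:
            raise ValueError(f"model {model!r} requires contig coverages")
        p_cov = coverage_similarity(
            coverages[link.contig_a], coverages[link.contig_b]
        )
        link.p_cov = clamp(p_cov, eps)
    if model == "uniform":
        p = p0
    elif model == "repeat":
        p = link.p_rep
    elif model == "coverage":
        p = link.p_cov
    else:
        p = link.p_rep * link.p_cov
    link.p_r = clamp(p, eps)
    return link.p_r


def filter_discordant(
    links: Iterable[ReadPairLink],
    insert_model: InsertModel,
    k_sigma: float = 3.0,
) -> list[ReadPairLink]:
    """Drop links whose insert-length lower bound (offset_a + offset_b,
    i.e. the implied insert at gap 0) exceeds mu + k_sigma * sigma."""
    limit = insert_model.mu + k_sigma * insert_model.sigma
    return [l for l in links if l.offset_a + l.offset_b <= limit]


@dataclass
class ScaffoldEdge:
    """Bundled bidirected edge between two contigs (contig_a < contig_b)."""

    contig_a: str
    contig_b: str
    pairs_by_state: dict[EdgeState, list[ReadPairLink]] = field(
        default_factory=lambda: {s: [] for s in ALL_STATES}
    )
    weight_by_state: dict[EdgeState, float] = field(
        default_factory=lambda: {s: 0.0 for s in ALL_STATES}
    )

    @property
    def key(self) -> tuple[str, str]:
        return (self.contig_a, self.contig_b)

    @property
    def total_pairs(self) -> int:
        return sum(len(v) for v in self.pairs_by_state.values())

    def weight(self, state: EdgeState) -> float:
        return self.weight_by_state[state]

    def all_pairs(self) -> list[ReadPairLink]:
        return [p for s in ALL_STATES for p in self.pairs_by_state[s]]

    @classmethod
    def from_weights(
        cls, a: str, b: str, wA: float = 0.0, wB: float = 0.0,
        wC: float = 0.0, wD: float = 0.0,
    ) -> "ScaffoldEdge":
        """Synthetic edge carrying bare state weights (test instances and
        randomly weighted benchmark graphs)."""
        e = cls(contig_a=a, contig_b=b)
        e.weight_by_state = {
            EdgeState.A: wA, EdgeState.B: wB, EdgeState.C: wC, EdgeState.D: wD,
        }
        return e


@dataclass
class ScaffoldGraph:
    """Simple graph: at most one bundled edge per contig pair; every edge
    carries at least ``min_bundle`` read pairs (synthetic edges exempt)."""

    contigs: dict[str, ContigRecord]
    edges: dict[tuple[str, str], ScaffoldEdge]
    min_bundle: int = 2

    @property
    def nodes(self) -> list[str]:
        return sorted(self.contigs)

    def edge_list(self) -> list[ScaffoldEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def degree_nodes(self) -> set[str]:
        return {n for k in self.edges for n in k}


def build_graph(
    links: Sequence[ReadPairLink],
    contigs: dict[str, ContigRecord],
    min_bundle: int = 2,
) -> ScaffoldGraph:
    """Bundle probability-annotated links into a scaffolding graph,
    dropping contig pairs supported by fewer than ``min_bundle`` pairs."""
    bundles: dict[tuple[str, str], list[ReadPairLink]] = {}
    for link in links:
        bundles.setdefault((link.contig_a, link.contig_b), []).append(link)
    edges: dict[tuple[str, str], ScaffoldEdge] = {}
    for key in sorted(bundles):
        pairs = bundles[key]
        if len(pairs) < min_bundle:
            continue
        edge = ScaffoldEdge(contig_a=key[0], contig_b=key[1])
        for p in pairs:
            s = classify_state(p)
            edge.pairs_by_state[s].append(p)
            edge.weight_by_state[s] += p.log_odds
        edges[key] = edge
    log.info(
        "scaffold graph: %d contigs, %d bundled edges (min_bundle=%d, "
        "%d links in, %d on kept edges)",
        len(contigs), len(edges), min_bundle, len(links),
        sum(e.total_pairs for e in edges.values()),
    )
    return ScaffoldGraph(contigs=contigs, edges=edges, min_bundle=min_bundle)


def rebundle(graph: ScaffoldGraph, min_bundle: int) -> ScaffoldGraph:
    """Return a copy of the graph keeping only edges with at least
    ``min_bundle`` pairs (used by the thinning heuristic)."""
    edges = {
        k: e for k, e in graph.edges.items() if e.total_pairs >= min_bundle
    }
    return ScaffoldGraph(contigs=graph.contigs, edges=edges, min_bundle=min_bundle)


def write_edges_tsv(graph: ScaffoldGraph, path) -> None:
    """Debug serialization: per-state pair counts and weights per edge."""
    with open(path, "w") as fh:
        cols = ["contig_a", "contig_b"]
        cols += [f"n_{s.value}" for s in ALL_STATES]
        cols += [f"w_{s.value}" for s in ALL_STATES]
        fh.write("\t".join(cols) + "\n")
        for e in graph.edge_list():
            row = [e.contig_a, e.contig_b]
            row += [str(len(e.pairs_by_state[s])) for s in ALL_STATES]
            row += [f"{e.weight_by_state[s]:.6f}" for s in ALL_STATES]
            fh.write("\t".join(row) + "\n")


def read_edge_pairs(path) -> set[frozenset[str]]:
    """Contig-pair universe from an edges TSV (for evaluation)."""
    out: set[frozenset[str]] = set()
    with open(path) as fh:
        next(fh)
        for ln in fh:
            a, b = ln.split("\t")[:2]
            out.add(frozenset((a, b)))
    return out
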