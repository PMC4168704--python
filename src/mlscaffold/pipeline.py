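"""End-to-end scaffolding pipeline and the benchmark protocol.

Order of operations: parse alignments -> reconstruct pairs -> estimate the
insert model -> annotate mapping probabilities -> drop discordant pairs ->
bundle into the scaffolding graph -> decompose (with thinning) -> solve
the orientation ILP by non-serial dynamic programming -> break residual
cycles -> linearize into chains by matching -> estimate gaps -> emit
AGP/FASTA and reports.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

import importlib

from . import alignment_io as aio
from . import graph as sg
from . import nsdp
from . import orient
from . import synth

# `linearize` is both a submodule and a package-level function; resolve the
# submodule explicitly so the alias is stable regardless of import order
lin = importlib.import_module(".linearize", __package__)

log = logging.getLogger("mlscaffold")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure with a distinct exit code."""

    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunConfig:
    contigs_fasta: str | None = None
    alignments: str | None = None
    repeats_bed: str | None = None
    model: str = "product"
    min_bundle: int = 2
    k_sigma: float = 3.0
    insert_mu: float | None = None
    insert_sigma: float | None = None
    max_component_nodes: int = nsdp.DEFAULT_MAX_COMPONENT_NODES
    g_min: float | None = None
    default_gap: float = lin.DEFAULT_GAP
    p0: float = 0.9
    epsilon: float = aio.DEFAULT_EPSILON
    seed: int = 0
    out_prefix: str = "scaffolds"

    def validate_paths(self) -> None:
        for label, p in (("contigs FASTA", self.contigs_fasta),
                         ("alignments", self.alignments)):
            if p is None:
                raise PipelineError(f"missing {label} path", exit_code=2)
            if not Path(p).exists():
                raise PipelineError(f"{label} not found: {p}", exit_code=2)
        if self.repeats_bed and not Path(self.repeats_bed).exists():
            raise PipelineError(
                f"repeats BED not found: {self.repeats_bed}", exit_code=2
            )
        if self.model not in sg.PROBABILITY_MODELS:
            raise PipelineError(f"unknown model {self.model!r}", exit_code=2)
        if self.min_bundle < 1 or self.k_sigma <= 0:
            raise PipelineError("numeric parameters out of range", exit_code=2)


@dataclass
class PipelineResult:
    chains: list[lin.ScaffoldChain]
    named: list[tuple[str, lin.ScaffoldChain]]
    gap_estimates: dict[int, list[lin.GapEstimate]]
    solution: orient.OrientationSolution
    graph: sg.ScaffoldGraph
    insert_model: aio.InsertModel
    links: list[aio.ReadPairLink]
    final_min_bundle: int
    stats: dict = field(default_factory=dict)


def _stage(stats: dict, name: str, n_in: int, n_out: int, t0: float) -> None:
    stats[name] = {"in": n_in, "out": n_out, "seconds": round(time.time() - t0, 3)}
    log.info("stage %-16s in=%-8d out=%-8d %.2fs",
             name, n_in, n_out, time.time() - t0)


def scaffold_pipeline(
    contigs: dict[str, aio.ContigRecord],
    alignments: Sequence[aio.ReadAlignment],
    cfg: RunConfig,
) -> PipelineResult:
    """Run the full method on in-memory contigs and alignments."""
    stats: dict = {}
    t0 = time.time()
    links, inserts = aio.extract_pairs(alignments, contigs, eps=cfg.epsilon)
    if not links:
        raise PipelineError("no valid inter-contig read pairs", exit_code=3)
    _stage(stats, "extract_pairs", len(alignments), len(links), t0)

    t0 = time.time()
    coverages = aio.compute_coverage(alignments, contigs)
    fallback = None
    if cfg.insert_mu is not None and cfg.insert_sigma is not None:
        fallback = aio.InsertModel(mu=cfg.insert_mu, sigma=cfg.insert_sigma)
    insert_model = aio.estimate_insert_model(
        inserts, fallback=fallback,
        contig_lengths=[c.length for c in contigs.values()],
    )
    for link in links:
        sg.mapping_probability(
            link, cfg.model, coverages=coverages, p0=cfg.p0, eps=cfg.epsilon
        )
    filtered = sg.filter_discordant(links, insert_model, k_sigma=cfg.k_sigma)
    _stage(stats, "filter_pairs", len(links), len(filtered), t0)

    t0 = time.time()
    graph = sg.build_graph(filtered, contigs, min_bundle=cfg.min_bundle)
    graph, final_bundle, tree = nsdp.thin(graph, cfg.max_component_nodes)
    _stage(stats, "graph", len(filtered),
           sum(e.total_pairs for e in graph.edges.values()), t0)

    t0 = time.time()
    solution = nsdp.nsdp_solve(tree, graph.edge_list())
    orient.validate_solution(solution, graph.edge_list())
    solution = orient.break_long_cycles(solution, graph.edge_list())
    orient.validate_solution(solution, graph.edge_list(), require_acyclic=True)
    _stage(stats, "orientation", len(graph.edges),
           sum(1 for s in solution.selected_state.values() if s), t0)

    t0 = time.time()
    chains = lin.linearize(solution, graph)
    lin.validate_chains(chains, contigs)
    read_len = (float(np.mean([a.aligned_length for a in alignments[:1000]]))
                if alignments else 100.0)
    g_min = cfg.g_min if cfg.g_min is not None else -read_len
    by_chain = lin.links_by_chain(chains, filtered)
    gap_estimates = {}
    for i, ch in enumerate(chains):
        gap_estimates[i] = lin.estimate_gaps(
            ch, by_chain.get(i, []), contigs, insert_model,
            g_min=g_min, default_gap=cfg.default_gap, read_len=read_len,
            max_offset_sum=insert_model.mu + cfg.k_sigma * insert_model.sigma,
        )
    named = lin.name_chains(chains, contigs)
    _stage(stats, "linearize", len(graph.contigs), len(chains), t0)

    stats["insert_model"] = {"mu": insert_model.mu, "sigma": insert_model.sigma}
    stats["final_min_bundle"] = final_bundle
    return PipelineResult(
        chains=chains, named=named, gap_estimates=gap_estimates,
        solution=solution, graph=graph, insert_model=insert_model,
        links=filtered, final_min_bundle=final_bundle, stats=stats,
    )


def run_scaffold(cfg: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs, run, write all outputs."""
    cfg.validate_paths()
    contigs = aio.read_fasta(cfg.contigs_fasta)
    if cfg.repeats_bed:
        repeats = aio.read_bed(cfg.repeats_bed)
        for cid, ivs in repeats.items():
            if cid in contigs:
                contigs[cid].repeat_intervals = aio.merge_intervals(ivs)
    alignments = aio.parse_alignments(cfg.alignments)
    result = scaffold_pipeline(contigs, alignments, cfg)

    prefix = cfg.out_prefix
    lin.write_agp(result.named, contigs, f"{prefix}.agp")
    if all(c.sequence is not None for c in contigs.values()):
        lin.write_scaffold_fasta(result.named, contigs, f"{prefix}.fasta")
    lin.write_chains_tsv(result.named, f"{prefix}.chains.tsv")
    with open(f"{prefix}.gaps.tsv", "w") as fh:
        fh.write("scaffold\tgap_index\testimate\tsupport\tresidual_rms\n")
        for name, ch in result.named:
            i = next(j for j, c in enumerate(result.chains) if c is ch)
            for t, e in enumerate(result.gap_estimates[i]):
                fh.write(f"{name}\t{t + 1}\t{e.value:.2f}\t{e.support}\t"
                         f"{e.residual:.2f}\n")
    sg.write_edges_tsv(result.graph, f"{prefix}.edges.tsv")
    with open(f"{prefix}.stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, sort_keys=True)
    return result


def run_simulate(
    out_prefix: str,
    genome_length: int = 1_000_000,
    coverage: float = 5.0,
    insert_mu: float = 3000.0,
    insert_sigma: float = 300.0,
    read_len: int = 100,
    chimera_rate: float = 0.0,
    seed: int = 0,
    contig_sizes: Sequence[int] = synth.DEFAULT_CONTIG_SIZES,
    gap_sizes: Sequence[int] = synth.DEFAULT_GAP_SIZES,
) -> tuple[synth.TruthAssembly, dict]:
    """Simulate a draft assembly plus read pairs; write contig FASTA,
    truth table and SAM."""
    truth, contigs = synth.simulate_assembly(
        genome_length, contig_sizes, gap_sizes, seed=seed
    )
    model = aio.InsertModel(mu=insert_mu, sigma=insert_sigma)
    alignments = synth.simulate_read_pairs(
        truth, model, coverage=coverage, read_len=read_len,
        chimera_rate=chimera_rate, seed=seed + 1,
    )
    aio.write_fasta(
        {c.id: c.sequence for c in contigs.values()}, f"{out_prefix}.contigs.fasta"
    )
    synth.write_truth_tsv(truth, f"{out_prefix}.truth.tsv")
    synth.write_sam(alignments, contigs, f"{out_prefix}.sam")
    return truth, contigs


def run_evaluate(
    chains_tsv: str,
    truth_tsv: str,
    edges_tsv: str | None = None,
    out_json: str | None = None,
) -> dict:
    """Score chains against the simulation truth (MCC, N50, TPN50,
    orientation accuracy)."""
    named = lin.read_chains_tsv(chains_tsv)
    chains = [ch for _, ch in named]
    truth = synth.read_truth_tsv(truth_tsv)
    chain_ids = {c for ch in chains for c in ch.ids()}
    if not chain_ids <= set(truth.rank):
        raise PipelineError(
            "chains reference contigs absent from the truth table", exit_code=4
        )
    contigs = {
        c.id: aio.ContigRecord(id=c.id, length=c.length)
        for c in truth.contigs
    }
    if edges_tsv:
        universe = sg.read_edge_pairs(edges_tsv)
    else:
        universe = set(synth.chain_adjacencies(chains)) | {
            frozenset((a.id, b.id))
            for a, b in zip(truth.contigs, truth.contigs[1:])
        }
    conf = synth.adjacency_confusion(chains, truth, universe)
    metrics = {
        "mcc": synth.mcc(conf),
        "TP": conf.TP, "FP": conf.FP, "FN": conf.FN, "TN": conf.TN,
        "n50": synth.n50(synth.chain_spans(chains, contigs)),
        "tpn50": synth.tpn50(chains, truth, contigs),
        "orientation_accuracy": synth.orientation_accuracy(chains, truth),
        "n_scaffolds": len(chains),
    }
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
    return metrics


# ---------------------------------------------------------------------------
# Benchmark protocol (simulate -> scaffold -> score, all in memory)
# ---------------------------------------------------------------------------

def run_benchmark(
    seed: int,
    genome_length: int = 1_000_000,
    coverage: float = 5.0,
    insert_mu: float = 3000.0,
    insert_sigma: float = 300.0,
    read_len: int = 100,
    chimera_rate: float = 0.0,
    min_bundle: int = 2,
    model: str = "product",
) -> dict:
    """One replicate of the simulated-contig protocol: fragment a random
    linear genome, simulate innie pairs, scaffold, and score against the
    known layout.  Returns the metric dict (plus gap-error summaries)."""
    truth, contigs = synth.simulate_assembly(
        genome_length, seed=seed, with_sequence=False
    )
    alignments = synth.simulate_read_pairs(
        truth, aio.InsertModel(insert_mu, insert_sigma),
        coverage=coverage, read_len=read_len,
        chimera_rate=chimera_rate, seed=seed + 1,
    )
    cfg = RunConfig(
        model=model, min_bundle=min_bundle,
        insert_mu=insert_mu, insert_sigma=insert_sigma, seed=seed,
    )
    result = scaffold_pipeline(contigs, alignments, cfg)
    universe = {frozenset(k) for k in result.graph.edges}
    conf = synth.adjacency_confusion(result.chains, truth, universe)

    # per-adjacency gap errors for true-positive joins
    gap_errors: list[float] = []
    supports: list[int] = []
    for i, ch in enumerate(result.chains):
        ests = result.gap_estimates[i]
        for t, ((u, ou), (v, ov)) in enumerate(
            zip(ch.contigs, ch.contigs[1:])
        ):
            if (u, ou, v, ov) not in truth.adjacency_realizations(u, v):
                continue
            first = min(u, v, key=lambda c: truth.rank[c])
            true_gap = truth.by_id(first).gap_after
            if ests[t].support > 0:
                gap_errors.append(ests[t].value - true_gap)
                supports.append(ests[t].support)

    return {
        "mcc": synth.mcc(conf),
        "confusion": conf,
        "orientation_accuracy": synth.orientation_accuracy(
            result.chains, truth
        ),
        "n50": synth.n50(synth.chain_spans(result.chains, contigs)),
        "tpn50": synth.tpn50(result.chains, truth, contigs),
        "n_contigs": len(contigs),
        "n_pairs": len(alignments) // 2,
        "gap_errors": gap_errors,
        "gap_supports": supports,
        "result": result,
        "truth": truth,
    }
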