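"""Synthetic assemblies with known ground truth, and scaffold accuracy
metrics.

The generator emulates the benchmark protocol used to evaluate
scaffolders on simulated draft assemblies: contig and gap sizes are drawn
alternately (with replacement) from empirical size lists until a linear
genome is exhausted, each contig is emitted in a random orientation, and
innie read pairs with Gaussian insert lengths are placed uniformly over
the genome.  Pairs whose mates land on different contigs become the
linkage evidence; a controllable fraction of pairs is made chimeric by
relocating the second mate uniformly, emulating library artifacts.

Accuracy is scored as a binary classification over the scaffolding
graph's bundled edges (Matthews correlation coefficient), plus N50 and
its truth-corrected variant TPN50 obtained by breaking scaffolds at
incorrect joins.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment_io import ContigRecord, InsertModel, ReadAlignment
from .linearize import ScaffoldChain

log = logging.getLogger("mlscaffold")

#: contig sizes (bp) emulating a short-read draft assembly: spanning
#: 2-20 kb, skewed toward short contigs as empirical contig size lists are
DEFAULT_CONTIG_SIZES = (
    2000, 2000, 2000, 2000, 3000, 3000, 3000, 4000, 4000,
    5000, 6000, 8000, 12000, 20000,
)
#: gap sizes (bp) between adjacent contigs
DEFAULT_GAP_SIZES = (50, 100, 150, 200, 300, 400, 500)


@dataclass
class TruthContig:
    id: str
    start: int  # genomic start, 0-based
    length: int
    flipped: bool  # emitted as the reverse complement of the genome slice
    gap_after: int  # bp to the next contig (0 for the last)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def orientation(self) -> str:
        """Orientation that places the emitted sequence back on the genome."""
        return "-" if self.flipped else "+"


@dataclass
class TruthAssembly:
    genome_length: int
    contigs: list[TruthContig]
    seed: int
    genome: str | None = None
    rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rank = {c.id: i for i, c in enumerate(self.contigs)}
        for a, b in zip(self.contigs, self.contigs[1:]):
            if b.start < a.end:
                raise ValueError("truth contigs must not overlap")

    def by_id(self, cid: str) -> TruthContig:
        return self.contigs[self.rank[cid]]

    def adjacent(self, u: str, v: str) -> bool:
        return abs(self.rank[u] - self.rank[v]) == 1

    def adjacency_realizations(self, u: str, v: str) -> set[tuple]:
        """The two oriented (first, o_first, second, o_second) layouts that
        correctly realize a true adjacency (a chain read in either
        direction is the same scaffold)."""
        if not self.adjacent(u, v):
            return set()
        a, b = sorted((u, v), key=lambda c: self.rank[c])
        oa, ob = self.by_id(a).orientation, self.by_id(b).orientation
        flip = {"+": "-", "-": "+"}
        return {(a, oa, b, ob), (b, flip[ob], a, flip[oa])}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def simulate_assembly(
    genome: int | str,
    contig_sizes: Sequence[int] = DEFAULT_CONTIG_SIZES,
    gap_sizes: Sequence[int] = DEFAULT_GAP_SIZES,
    seed: int = 0,
    flip_prob: float = 0.5,
    with_sequence: bool = True,
) -> tuple[TruthAssembly, dict[str, ContigRecord]]:
    """Fragment a (possibly random) linear genome into contigs and gaps by
    alternate sampling from the size lists; contigs are emitted in a
    random orientation with the true layout recorded."""
    if not contig_sizes or not gap_sizes:
        raise ValueError("size lists must be non-empty")
    rng = np.random.default_rng(seed)
    if isinstance(genome, str):
        seq: str | None = genome
        glen = len(genome)
    else:
        glen = int(genome)
        # separate stream so the layout is identical with or without
        # sequence generation
        seq_rng = np.random.default_rng([seed, 1])
        seq = _random_genome(glen, seq_rng) if with_sequence else None

    truth: list[TruthContig] = []
    pos = 0
    i = 0
    while pos < glen:
        clen = min(int(rng.choice(contig_sizes)), glen - pos)
        flipped = bool(rng.random() < flip_prob)
        gap = int(rng.choice(gap_sizes))
        if pos + clen + gap >= glen:
            gap = 0
        truth.append(TruthContig(
            id=f"ctg{i:05d}", start=pos, length=clen,
            flipped=flipped, gap_after=gap,
        ))
        pos += clen + gap
        if gap == 0:
            break
        i += 1

    contigs: dict[str, ContigRecord] = {}
    for tc in truth:
        cseq = None
        if seq is not None:
            piece = seq[tc.start:tc.end]
            if tc.flipped:
                from .linearize import revcomp

                piece = revcomp(piece)
            cseq = piece
        contigs[tc.id] = ContigRecord(id=tc.id, length=tc.length, sequence=cseq)
    assembly = TruthAssembly(
        genome_length=glen, contigs=truth, seed=seed, genome=seq
    )
    return assembly, contigs


def write_truth_tsv(truth: TruthAssembly, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tlength\torientation\tgap_after\n")
        for c in truth.contigs:
            fh.write(f"{c.id}\t{c.start}\t{c.length}\t{c.orientation}\t"
                     f"{c.gap_after}\n")


def read_truth_tsv(path) -> TruthAssembly:
    contigs = []
    with open(path) as fh:
        next(fh)
        for ln in fh:
            cid, start, length, orientation, gap = ln.split("\t")
            contigs.append(TruthContig(
                id=cid, start=int(start), length=int(length),
                flipped=orientation == "-", gap_after=int(gap),
            ))
    glen = contigs[-1].end if contigs else 0
    return TruthAssembly(genome_length=glen, contigs=contigs, seed=-1)


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------

def simulate_read_pairs(
    truth: TruthAssembly,
    insert_model: InsertModel,
    n_pairs: int | None = None,
    coverage: float | None = None,
    read_len: int = 100,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadAlignment]:
    """Simulate innie read pairs and report them as per-mate alignments in
    contig coordinates (what an aligner mapping mates independently would
    produce on this assembly).

    Fragment starts are uniform over the genome; inserts are Gaussian,
    truncated at 2 * read_len.  A mate overlapping a gap is unmapped and
    omitted.  With probability ``chimera_rate`` the second mate of a pair
    is relocated uniformly, producing wrong-link noise.
    """
    if n_pairs is None:
        if coverage is None:
            raise ValueError("need n_pairs or coverage")
        n_pairs = int(math.ceil(coverage * truth.genome_length
                                / (2 * read_len)))
    rng = np.random.default_rng(seed)
    glen = truth.genome_length
    inserts = np.maximum(
        np.round(rng.normal(insert_model.mu, insert_model.sigma, n_pairs)),
        2 * read_len,
    ).astype(np.int64)
    inserts = np.minimum(inserts, glen)
    starts = rng.integers(0, np.maximum(glen - inserts, 1))
    # mate 1: forward at the fragment's left end; mate 2: reverse at right
    m1_start = starts
    m2_start = starts + inserts - read_len
    m2_strand_fwd = np.zeros(n_pairs, dtype=bool)
    if chimera_rate > 0:
        chim = rng.random(n_pairs) < chimera_rate
        m2_start = np.where(
            chim, rng.integers(0, glen - read_len, n_pairs), m2_start
        )
        m2_strand_fwd = chim & (rng.random(n_pairs) < 0.5)

    c_starts = np.array([c.start for c in truth.contigs])
    c_ends = np.array([c.end for c in truth.contigs])

    def place(gstart: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(c_starts, gstart, side="right") - 1
        idx = np.clip(idx, 0, len(c_starts) - 1)
        ok = (gstart >= c_starts[idx]) & (gstart + read_len <= c_ends[idx])
        return idx, ok

    i1, ok1 = place(m1_start)
    i2, ok2 = place(m2_start)

    out: list[ReadAlignment] = []
    for k in range(n_pairs):
        name = f"sim{k:07d}"
        for mate, (gs, ci, ok, fwd) in enumerate([
            (m1_start[k], i1[k], ok1[k], True),
            (m2_start[k], i2[k], ok2[k], bool(m2_strand_fwd[k])),
        ], start=1):
            if not ok:
                continue
            tc = truth.contigs[ci]
            rel = int(gs) - tc.start
            strand = "+" if fwd else "-"
            if tc.flipped:
                rel = tc.length - rel - read_len
                strand = "-" if strand == "+" else "+"
            out.append(ReadAlignment(
                read_id=name, mate_index=mate, contig_id=tc.id,
                start=rel, aligned_length=read_len, strand=strand,
            ))
    return out


def write_sam(
    alignments: Sequence[ReadAlignment],
    contigs: dict[str, ContigRecord],
    path,
) -> None:
    """Minimal SAM serialization of simulated per-mate alignments."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid in sorted(contigs):
            fh.write(f"@SQ\tSN:{cid}\tLN:{contigs[cid].length}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            fh.write("\t".join([
                f"{a.read_id}/{a.mate_index}", str(flag), a.contig_id,
                str(a.start + 1), "60", f"{a.aligned_length}M",
                "*", "0", "0", "*", "*", "AS:i:0",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Accuracy metrics
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyConfusion:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def chain_adjacencies(
    chains: Sequence[ScaffoldChain],
) -> dict[frozenset[str], tuple]:
    """Realized oriented adjacency per unordered contig pair."""
    out: dict[frozenset[str], tuple] = {}
    for ch in chains:
        for (u, ou), (v, ov) in zip(ch.contigs, ch.contigs[1:]):
            out[frozenset((u, v))] = (u, ou, v, ov)
    return out


def adjacency_confusion(
    chains: Sequence[ScaffoldChain],
    truth: TruthAssembly,
    universe: set[frozenset[str]],
) -> AdjacencyConfusion:
    """Confusion counts over the candidate universe (the bundled edges of
    the scaffolding graph).

    An edge is predicted-positive when realized as a chain adjacency; it
    counts as a true positive only when the contigs are genomically
    adjacent *and* the realized order/orientation matches the truth (up to
    reading the chain backwards).  A realized but wrong adjacency is a
    false positive; an unrealized true adjacency a false negative.
    """
    realized = chain_adjacencies(chains)
    conf = AdjacencyConfusion()
    for pair in universe:
        u, v = sorted(pair)
        truth_adj = truth.adjacent(u, v)
        if pair in realized:
            if truth_adj and realized[pair] in truth.adjacency_realizations(u, v):
                conf.TP += 1
            else:
                conf.FP += 1
        else:
            if truth_adj:
                conf.FN += 1
            else:
                conf.TN += 1
    return conf


def mcc(conf: AdjacencyConfusion) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0,
    NaN (with a warning) on an empty universe."""
    if conf.total == 0:
        log.warning("MCC undefined on an empty candidate universe")
        return float("nan")
    tp, fp, fn, tn = conf.TP, conf.FP, conf.FN, conf.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def adjacency_mcc(
    chains: Sequence[ScaffoldChain],
    truth: TruthAssembly,
    universe: set[frozenset[str]],
) -> float:
    return mcc(adjacency_confusion(chains, truth, universe))


def n50(lengths: Sequence[float]) -> float:
    """Largest L such that pieces of length >= L sum to at least half the
    total span."""
    ls = sorted((l for l in lengths if l > 0), reverse=True)
    if not ls:
        return 0.0
    half = sum(ls) / 2.0
    acc = 0.0
    for l in ls:
        acc += l
        if acc >= half:
            return float(l)
    return float(ls[-1])


def chain_spans(
    chains: Sequence[ScaffoldChain], contigs: dict[str, ContigRecord],
    include_gaps: bool = True,
) -> list[float]:
    spans = []
    for ch in chains:
        s = float(sum(contigs[c].length for c, _ in ch.contigs))
        if include_gaps:
            s += float(sum(ch.gaps))
        spans.append(s)
    return spans


def split_at_errors(
    chains: Sequence[ScaffoldChain], truth: TruthAssembly
) -> list[ScaffoldChain]:
    """Break every chain at adjacencies that are not truth-correct."""
    out: list[ScaffoldChain] = []
    for ch in chains:
        cur = [ch.contigs[0]]
        gaps: list[float] = []
        for i, ((u, ou), (v, ov)) in enumerate(
            zip(ch.contigs, ch.contigs[1:])
        ):
            ok = (u, ou, v, ov) in truth.adjacency_realizations(u, v)
            if ok:
                cur.append((v, ov))
                gaps.append(ch.gaps[i] if i < len(ch.gaps) else 0.0)
            else:
                out.append(ScaffoldChain(contigs=cur, gaps=gaps))
                cur = [(v, ov)]
                gaps = []
        out.append(ScaffoldChain(contigs=cur, gaps=gaps))
    return out


def tpn50(
    chains: Sequence[ScaffoldChain],
    truth: TruthAssembly,
    contigs: dict[str, ContigRecord],
    include_gaps: bool = True,
) -> float:
    """N50 after splitting scaffolds at incorrect joins (<= plain N50,
    with equality iff every adjacency is correct)."""
    pieces = split_at_errors(chains, truth)
    return n50(chain_spans(pieces, contigs, include_gaps))


def orientation_accuracy(
    chains: Sequence[ScaffoldChain], truth: TruthAssembly
) -> float:
    """Fraction of contigs (in multi-contig chains) whose predicted
    orientation matches the truth, allowing each chain one global flip;
    1.0 when there are no multi-contig chains."""
    match = 0
    total = 0
    for ch in chains:
        if len(ch) < 2:
            continue
        m = sum(
            1 for c, o in ch.contigs if truth.by_id(c).orientation == o
        )
        match += max(m, len(ch) - m)
        total += len(ch)
    return match / total if total else 1.0
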