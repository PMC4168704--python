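"""Alignment parsing and read-pair evidence extraction.

Scaffolding consumes alignments of *both* mates mapped independently of
their pairing (e.g. bowtie2 run on the two mate files separately).  This
module turns a SAM/BAM stream into :class:`ReadAlignment` records,
reconstructs mate pairs by read name, routes same-contig pairs to insert
size estimation, and builds the inter-contig :class:`ReadPairLink` records
that carry the per-pair mapping probabilities used by the likelihood model.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted on parse.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

log = logging.getLogger("mlscaffold")

#: probability clamp keeping log-odds ln(p/(1-p)) finite
DEFAULT_EPSILON = 1e-3

#: minimum number of same-contig unique pairs before the insert model is
#: estimated from data rather than taken from configuration
MIN_INSERT_PAIRS = 100


def clamp(p: float, eps: float = DEFAULT_EPSILON) -> float:
    """Clamp a probability into [eps, 1 - eps]."""
    return min(max(p, eps), 1.0 - eps)


def log_odds(p: float, eps: float = DEFAULT_EPSILON) -> float:
    p = clamp(p, eps)
    return math.log(p / (1.0 - p))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a sorted, non-overlapping list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class ContigRecord:
    """A contig: node unit of the scaffolding graph.

    ``repeat_intervals`` are half-open intervals on the contig marking
    annotated repeat families; they are stored merged and clipped to the
    contig.  ``coverage`` is the mean read depth, filled in by
    :func:`compute_coverage`.
    """

    id: str
    length: int
    sequence: str | None = None
    coverage: float = 0.0
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: length must be > 0")
        if self.coverage < 0:
            raise ValueError(f"contig {self.id}: coverage must be >= 0")
        clipped = [
            (max(0, s), min(self.length, e)) for s, e in self.repeat_intervals
        ]
        self.repeat_intervals = merge_intervals(clipped)


@dataclass
class ReadAlignment:
    """One primary alignment of a single mate onto a contig."""

    read_id: str
    mate_index: int  # 1 or 2
    contig_id: str
    start: int  # 0-based
    aligned_length: int
    strand: str  # '+' or '-'
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.mate_index not in (1, 2):
            raise ValueError("mate_index must be 1 or 2")
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be > 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        return self.start + self.aligned_length


@dataclass
class ReadPairLink:
    """A read pair bridging two distinct contigs.

    ``contig_a < contig_b`` lexicographically.  ``offset_a``/``offset_b``
    measure, for each mate, the distance from its 5' alignment start to the
    contig end the read points toward (strand '+': the right end, strand
    '-': the left end).  This convention is invariant under flipping the
    contig, and for a concordant innie pair spanning a gap g the implied
    insert length is exactly ``offset_a + g + offset_b``.
    """

    pair_id: str
    contig_a: str
    contig_b: str
    strand_a: str
    strand_b: str
    offset_a: int
    offset_b: int
    p_rep: float = 1.0 - DEFAULT_EPSILON
    p_cov: float = 1.0 - DEFAULT_EPSILON
    p_r: float = 1.0 - DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError("link must bridge distinct contigs")
        if self.contig_a > self.contig_b:
            raise ValueError("link must be canonical (contig_a < contig_b)")

    @property
    def log_odds(self) -> float:
        return log_odds(self.p_r)


@dataclass
class InsertModel:
    """Gaussian insert-length model (fragment end-to-end length)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("insert mean must be > 0")
        if self.sigma <= 0:
            raise ValueError("insert standard deviation must be > 0")


# ---------------------------------------------------------------------------
# SAM parsing
# ---------------------------------------------------------------------------

def _mate_index(rec: pysam.AlignedSegment) -> tuple[str, int]:
    """Return (pair id, mate index) for a SAM record.

    Mates mapped without pairing information are identified either by SAM
    flags (0x40/0x80 when the aligner kept them) or by a ``/1``/``/2`` name
    suffix; otherwise the read is treated as mate 1 of its own pair.
    """
    name = rec.query_name
    if rec.is_paired:
        return name, (2 if rec.is_read2 else 1)
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2], int(name[-1])
    return name, 1


def parse_alignments(
    sam_source,
    unique_policy: str = "best_score",
) -> list[ReadAlignment]:
    """Parse a SAM/BAM source into one :class:`ReadAlignment` per primary
    alignment of a mapped read.

    ``unique_policy`` decides when a read counts as uniquely mapped:

    - ``"best_score"`` (default): unique iff exactly one alignment achieves
      the best alignment score (AS tag; falls back to record count when the
      aligner reports no scores).
    - ``"single"``: unique iff the read has exactly one reported alignment.

    Unmapped reads are omitted.  A record referencing a contig absent from
    the @SQ header, or a truncated stream, raises a format error (pysam).
    """
    if unique_policy not in ("best_score", "single"):
        raise ValueError(f"unknown unique_policy {unique_policy!r}")
    if isinstance(sam_source, pysam.AlignmentFile):
        af = sam_source
        close = False
    else:
        af = pysam.AlignmentFile(str(sam_source))
        close = True

    # group alignments per mate so secondary hits can veto uniqueness
    groups: dict[tuple[str, int], list[tuple[bool, float | None, ReadAlignment]]] = {}
    try:
        for rec in af:
            if rec.is_unmapped:
                # htslib downgrades records whose RNAME is absent from the
                # @SQ header to unmapped but keeps their CIGAR/position
                if rec.cigarstring is not None or rec.reference_start >= 0:
                    raise ValueError(
                        f"alignment {rec.query_name} references a contig "
                        "absent from the @SQ header"
                    )
                continue
            if rec.is_supplementary:
                continue
            pair_id, mate = _mate_index(rec)
            aln = ReadAlignment(
                read_id=pair_id,
                mate_index=mate,
                contig_id=rec.reference_name,
                start=rec.reference_start,
                aligned_length=rec.reference_length or rec.query_length,
                strand="-" if rec.is_reverse else "+",
            )
            score = rec.get_tag("AS") if rec.has_tag("AS") else None
            groups.setdefault((pair_id, mate), []).append(
                (not rec.is_secondary, score, aln)
            )
    finally:
        if close:
            af.close()

    out: list[ReadAlignment] = []
    for hits in groups.values():
        primaries = [h for h in hits if h[0]]
        if not primaries:
            continue
        if unique_policy == "single":
            unique = len(hits) == 1
        else:
            scores = [s for _, s, _ in hits]
            if any(s is None for s in scores):
                unique = len(hits) == 1
            else:
                best = max(scores)
                unique = scores.count(best) == 1
        for _, _, aln in primaries:
            aln.is_unique = unique
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------

def gap_facing_offset(aln: ReadAlignment, contig_length: int) -> int:
    """Distance from the read's 5' alignment start to the contig end it
    points toward ('+': right end, '-': left end)."""
    if aln.strand == "+":
        return contig_length - aln.start
    return aln.start + aln.aligned_length


def extract_pairs(
    alignments: Sequence[ReadAlignment],
    contigs: dict[str, ContigRecord],
    eps: float = DEFAULT_EPSILON,
) -> tuple[list[ReadPairLink], list[float]]:
    """Reconstruct mate pairs and split them into scaffolding links and
    same-contig insert observations.

    Only pairs with both mates uniquely aligned are used; pairs on distinct
    contigs become :class:`ReadPairLink` records (with ``p_rep`` computed
    from repeat annotation), unique same-contig innie pairs contribute their
    observed insert length to the returned list, everything else is dropped.
    """
    by_pair: dict[str, dict[int, list[ReadAlignment]]] = {}
    for aln in alignments:
        by_pair.setdefault(aln.read_id, {}).setdefault(aln.mate_index, []).append(aln)

    links: list[ReadPairLink] = []
    inserts: list[float] = []
    dropped_multi = 0
    for pair_id in sorted(by_pair):
        mates = by_pair[pair_id]
        if sum(len(v) for v in mates.values()) > 2:
            dropped_multi += 1
            continue
        if set(mates) != {1, 2}:
            continue
        (a,), (b,) = mates[1], mates[2]
        if not (a.is_unique and b.is_unique):
            continue
        if a.contig_id == b.contig_id:
            # innie orientation on one contig yields an insert observation
            if {a.strand, b.strand} == {"+", "-"}:
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                ins = minus.end - plus.start
                if ins > 0:
                    inserts.append(float(ins))
            continue
        if a.contig_id > b.contig_id:
            a, b = b, a
        if a.contig_id not in contigs or b.contig_id not in contigs:
            raise KeyError(f"pair {pair_id} references unknown contig")
        p_rep = repeat_probability(
            (a, b),
            {c: contigs[c].repeat_intervals for c in (a.contig_id, b.contig_id)},
            eps=eps,
        )
        links.append(
            ReadPairLink(
                pair_id=pair_id,
                contig_a=a.contig_id,
                contig_b=b.contig_id,
                strand_a=a.strand,
                strand_b=b.strand,
                offset_a=gap_facing_offset(a, contigs[a.contig_id].length),
                offset_b=gap_facing_offset(b, contigs[b.contig_id].length),
                p_rep=p_rep,
            )
        )
    if dropped_multi:
        log.warning("dropped %d pairs with >2 alignments", dropped_multi)
    return links, inserts


def compute_coverage(
    alignments: Sequence[ReadAlignment],
    contigs: dict[str, ContigRecord],
) -> dict[str, float]:
    """Mean depth per contig from *all* alignments (non-unique reads are
    expected to be pre-resolved to a single location upstream, e.g. the
    aligner's randomly allocated primary hit).

    coverage = (sum of aligned bases on the contig) / contig length.
    Updates each :class:`ContigRecord` in place and returns the mapping.
    """
    bases: dict[str, int] = {cid: 0 for cid in contigs}
    for aln in alignments:
        if aln.contig_id not in bases:
            raise KeyError(f"alignment references unknown contig {aln.contig_id}")
        bases[aln.contig_id] += aln.aligned_length
    cov = {cid: bases[cid] / contigs[cid].length for cid in contigs}
    for cid, c in cov.items():
        contigs[cid].coverage = c
    return cov


def _overlap_bases(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in intervals:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


def repeat_probability(
    alignment_pair: tuple[ReadAlignment, ReadAlignment],
    repeat_intervals: dict[str, list[tuple[int, int]]],
    eps: float = DEFAULT_EPSILON,
) -> float:
    """Repeat-based mapping probability of a pair: the fraction of the two
    mates' aligned bases falling outside annotated repeats, clamped."""
    total = 0
    overlap = 0
    for aln in alignment_pair:
        total += aln.aligned_length
        ivs = repeat_intervals.get(aln.contig_id, [])
        overlap += _overlap_bases(aln.start, aln.end, ivs)
    if total == 0:
        return clamp(1.0, eps)
    return clamp((total - overlap) / total, eps)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def estimate_insert_model(
    inserts: Sequence[float],
    fallback: InsertModel | None = None,
    min_pairs: int = MIN_INSERT_PAIRS,
    contig_lengths: Sequence[int] | None = None,
) -> InsertModel:
    """Robust (median/MAD) insert model from same-contig pairs, or the
    configured fallback when fewer than ``min_pairs`` observations exist.

    A fragment is only observed on a single contig when it fits inside it,
    so same-contig inserts are length-biased toward short fragments: an
    insert i can be placed in sum_c max(L_c - i + 1, 0) positions.  When
    ``contig_lengths`` is provided, observations are reweighted by the
    inverse of that placement count, removing the bias.
    """
    if len(inserts) >= min_pairs:
        x = np.asarray(inserts, dtype=float)
        if contig_lengths is not None:
            ls = np.sort(np.asarray(contig_lengths, dtype=float))
            suffix = np.concatenate([np.cumsum(ls[::-1])[::-1], [0.0]])
            idx = np.searchsorted(ls, x, side="left")
            # W(i) = sum over contigs with L >= i of (L - i + 1)
            placements = suffix[idx] - (len(ls) - idx) * (x - 1.0)
            w = 1.0 / np.maximum(placements, 1.0)
        else:
            w = np.ones_like(x)
        mu = _weighted_median(x, w)
        mad = _weighted_median(np.abs(x - mu), w)
        sigma = 1.4826 * mad
        if sigma > 0 and mu > 0:
            return InsertModel(mu=mu, sigma=sigma)
    if fallback is None:
        raise ValueError(
            "too few same-contig pairs to estimate the insert model and no "
            "configured fallback (insert_mu/insert_sigma)"
        )
    return fallback


# ---------------------------------------------------------------------------
# File readers / writers for standard formats
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, ContigRecord]:
    """Load contigs from FASTA via pyfaidx."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    contigs: dict[str, ContigRecord] = {}
    for name in fa.keys():
        seq = str(fa[name][:])
        contigs[name] = ContigRecord(id=name, length=len(seq), sequence=seq)
    return contigs


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 repeat annotation (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {ln!r}")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {k: merge_intervals(v) for k, v in out.items()}


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
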