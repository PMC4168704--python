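import math
import random

import numpy as np
import pytest

from mlscaffold.alignment_io import (
    ContigRecord,
    InsertModel,
    ReadAlignment,
    clamp,
    compute_coverage,
    estimate_insert_model,
    extract_pairs,
    merge_intervals,
    parse_alignments,
    repeat_probability,
)
from mlscaffold.graph import filter_discordant

from conftest import make_link


def contig(cid, length, repeats=()):
    return ContigRecord(id=cid, length=length,
                        repeat_intervals=list(repeats))


def aln(read_id, mate, cid, start, alen, strand, unique=True):
    return ReadAlignment(read_id=read_id, mate_index=mate, contig_id=cid,
                         start=start, aligned_length=alen, strand=strand,
                         is_unique=unique)


class TestParseAlignments:
    def test_header_only_sam_is_empty(self, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n")
        assert parse_alignments(p) == []

    def test_reverse_strand_and_zero_based_start(self, tiny_sam):
        recs = parse_alignments(tiny_sam)
        r2 = [r for r in recs if r.read_id == "r2" and r.mate_index == 1][0]
        assert (r2.contig_id, r2.start, r2.strand) == ("c1", 10, "-")
        assert r2.aligned_length == 40

    def test_equal_score_secondary_marks_non_unique(self, tiny_sam):
        recs = parse_alignments(tiny_sam)
        r3 = [r for r in recs if r.read_id == "r3" and r.mate_index == 1]
        assert len(r3) == 1  # only the primary record is emitted
        assert not r3[0].is_unique
        # its mate has a single alignment and stays unique
        assert [r.is_unique for r in recs
                if r.read_id == "r3" and r.mate_index == 2] == [True]

    def test_missing_sq_is_fatal(self, tmp_path):
        p = tmp_path / "bad.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n"
                     "r1/1\t0\tcX\t1\t60\t50M\t*\t0\t0\t*\t*\n")
        with pytest.raises(Exception):
            parse_alignments(p)


class TestExtractPairs:
    contigs = {"c1": contig("c1", 100), "c2": contig("c2", 200)}

    def test_distinct_contig_pair_becomes_link(self):
        links, inserts = extract_pairs(
            [aln("p", 1, "c1", 0, 50, "+"), aln("p", 2, "c2", 50, 50, "-")],
            self.contigs,
        )
        assert len(links) == 1 and not inserts
        l = links[0]
        assert (l.contig_a, l.contig_b) == ("c1", "c2")
        # '+' mate: distance to right end; '-' mate: distance to left end
        assert (l.offset_a, l.offset_b) == (100, 100)

    def test_same_contig_pair_feeds_insert_model_only(self):
        links, inserts = extract_pairs(
            [aln("p", 1, "c1", 0, 50, "+"), aln("p", 2, "c1", 50, 50, "-")],
            self.contigs,
        )
        assert not links
        assert inserts == [100.0]

    def test_non_unique_mate_drops_pair(self):
        links, inserts = extract_pairs(
            [aln("p", 1, "c1", 0, 50, "+", unique=False),
             aln("p", 2, "c2", 50, 50, "-")],
            self.contigs,
        )
        assert not links and not inserts

    def test_order_independent(self, rng):
        base = []
        for k in range(30):
            base.append(aln(f"p{k}", 1, "c1", k, 10, "+"))
            base.append(aln(f"p{k}", 2, "c2", k, 10, "-"))
        links1, _ = extract_pairs(base, self.contigs)
        shuffled = list(base)
        random.Random(1).shuffle(shuffled)
        links2, _ = extract_pairs(shuffled, self.contigs)
        assert [l.pair_id for l in links1] == [l.pair_id for l in links2]


class TestCoverage:
    def test_mean_depth(self):
        contigs = {"c1": contig("c1", 100), "c2": contig("c2", 50)}
        cov = compute_coverage(
            [aln("a", 1, "c1", 0, 100, "+"),
             aln("b", 1, "c1", 0, 50, "+"), aln("b", 2, "c1", 50, 50, "-")],
            contigs,
        )
        assert cov["c1"] == pytest.approx(2.0)
        assert cov["c2"] == 0.0

    def test_conservation(self, rng):
        contigs = {f"c{i}": contig(f"c{i}", int(rng.integers(50, 500)))
                   for i in range(10)}
        alns = []
        for k in range(200):
            cid = f"c{int(rng.integers(10))}"
            L = contigs[cid].length
            alns.append(aln(f"r{k}", 1, cid, 0, int(rng.integers(1, L)), "+"))
        cov = compute_coverage(alns, contigs)
        total = sum(cov[c] * contigs[c].length for c in contigs)
        assert total == pytest.approx(sum(a.aligned_length for a in alns))


class TestRepeatProbability:
    def test_values_and_clamping(self):
        a = aln("p", 1, "c1", 0, 100, "+")
        b = aln("p", 2, "c2", 0, 100, "-")
        no_rep = {"c1": [], "c2": []}
        assert repeat_probability((a, b), no_rep) == pytest.approx(1 - 1e-3)
        full = {"c1": [(0, 100)], "c2": [(0, 100)]}
        assert repeat_probability((a, b), full) == pytest.approx(1e-3)
        half = {"c1": [(50, 100)], "c2": []}
        assert repeat_probability((a, b), half) == pytest.approx(150 / 200)

    @pytest.mark.parametrize("extra", [0, 10, 25, 40])
    def test_monotone_in_repeat_overlap(self, extra):
        a = aln("p", 1, "c1", 0, 100, "+")
        b = aln("p", 2, "c2", 0, 100, "-")
        p1 = repeat_probability((a, b), {"c1": [(0, 10 + extra)], "c2": []})
        p2 = repeat_probability((a, b), {"c1": [(0, 10)], "c2": []})
        assert p1 <= p2

    def test_merge_intervals(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30), (8, 12)]) == \
            [(0, 12), (20, 30)]


class TestInsertModel:
    def test_discordance_filter_threshold(self):
        model = InsertModel(mu=500, sigma=50)
        keep = make_link("a", "b", offset_a=300, offset_b=300)   # mu + 2s
        drop = make_link("a", "b", offset_a=350, offset_b=350)   # mu + 4s
        assert filter_discordant([keep, drop], model, k_sigma=3) == [keep]
        assert filter_discordant([], model) == []

    def test_estimation_recovers_mu_sigma(self, rng):
        xs = rng.normal(500, 50, 5000)
        m = estimate_insert_model(xs)
        assert m.mu == pytest.approx(500, abs=5)
        assert m.sigma == pytest.approx(50, abs=5)

    def test_length_bias_reweighting(self, rng):
        # fragments observed on an L=700 contig are size-biased by (L-i+1)
        L = 700.0
        xs = rng.normal(500, 50, 200_000)
        w = np.clip(L - xs + 1, 0, None)
        keep = rng.random(len(xs)) < w / w.max()
        biased = xs[keep]
        naive = estimate_insert_model(biased)
        fixed = estimate_insert_model(biased, contig_lengths=[700] * 10)
        assert abs(fixed.mu - 500) < abs(naive.mu - 500)
        assert fixed.mu == pytest.approx(500, abs=5)

    def test_fallback_required_when_too_few(self):
        with pytest.raises(ValueError):
            estimate_insert_model([500.0] * 10)
        m = estimate_insert_model([500.0] * 10,
                                  fallback=InsertModel(400, 40))
        assert (m.mu, m.sigma) == (400, 40)


def test_clamp_keeps_log_odds_finite():
    assert clamp(0.0) == 1e-3 and clamp(1.0) == 1 - 1e-3
    assert math.isfinite(math.log(clamp(1.0) / (1 - clamp(1.0))))
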