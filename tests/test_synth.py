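import numpy as np
import pytest

from mlscaffold.alignment_io import ContigRecord, InsertModel
from mlscaffold.graph import classify_state
from mlscaffold.linearize import ScaffoldChain
from mlscaffold.synth import (
    AdjacencyConfusion,
    adjacency_confusion,
    mcc,
    n50,
    orientation_accuracy,
    simulate_assembly,
    simulate_read_pairs,
    split_at_errors,
    tpn50,
    chain_spans,
)
from mlscaffold import alignment_io as aio


class TestSimulateAssembly:
    def test_deterministic_given_seed(self):
        t1, c1 = simulate_assembly(50_000, seed=3)
        t2, c2 = simulate_assembly(50_000, seed=3)
        assert [(c.id, c.start, c.length, c.flipped, c.gap_after)
                for c in t1.contigs] == \
            [(c.id, c.start, c.length, c.flipped, c.gap_after)
             for c in t2.contigs]
        assert all(c1[k].sequence == c2[k].sequence for k in c1)

    def test_alternating_layout_arithmetic(self):
        truth, contigs = simulate_assembly(
            10_000, contig_sizes=[1000], gap_sizes=[100], seed=0
        )
        lens = [c.length for c in truth.contigs]
        assert lens == [1000] * 9 + [100]  # trailing truncation
        gaps = [c.gap_after for c in truth.contigs]
        assert gaps == [100] * 9 + [0]
        starts = [c.start for c in truth.contigs]
        assert starts == [1100 * i for i in range(10)]

    def test_orientation_flip_fraction(self):
        truth, _ = simulate_assembly(
            2_000_000, contig_sizes=[1000], gap_sizes=[1000], seed=1,
            with_sequence=False,
        )
        assert len(truth.contigs) == 1000
        frac = np.mean([c.flipped for c in truth.contigs])
        assert 0.45 <= frac <= 0.55

    def test_contig_sequence_is_oriented_genome_slice(self):
        truth, contigs = simulate_assembly(20_000, seed=5)
        from mlscaffold.linearize import revcomp

        for tc in truth.contigs:
            piece = truth.genome[tc.start:tc.end]
            expect = revcomp(piece) if tc.flipped else piece
            assert contigs[tc.id].sequence == expect


class TestSimulateReadPairs:
    model = InsertModel(mu=500, sigma=50)

    def _links(self, truth, contigs, alignments):
        links, _ = aio.extract_pairs(alignments, contigs)
        return links

    def test_insert_sample_mean(self):
        truth, contigs = simulate_assembly(
            100_000, contig_sizes=[5000], gap_sizes=[50], seed=2,
            with_sequence=False,
        )
        alns = simulate_read_pairs(truth, self.model, n_pairs=4000,
                                   read_len=50, seed=3)
        _, inserts = aio.extract_pairs(alns, contigs)
        n = len(inserts)
        assert n > 500
        # CLT bound (generous: same-contig inserts are mildly length-biased)
        assert abs(np.mean(inserts) - 500) < 4 * 50 / np.sqrt(n) + 5

    def test_error_free_links_are_concordant_with_truth(self):
        truth, contigs = simulate_assembly(
            60_000, contig_sizes=[2000], gap_sizes=[100], seed=4,
            with_sequence=False,
        )
        alns = simulate_read_pairs(truth, self.model, n_pairs=3000,
                                   read_len=50, chimera_rate=0.0, seed=5)
        links = self._links(truth, contigs, alns)
        assert links
        for link in links:
            assert truth.adjacent(link.contig_a, link.contig_b)
            # the observed state must be admissible for the true flips
            a, b = truth.by_id(link.contig_a), truth.by_id(link.contig_b)
            from mlscaffold.graph import STATE_PARITY

            assert STATE_PARITY[classify_state(link)] == \
                (a.flipped ^ b.flipped)

    def test_full_chimerism_breaks_adjacency(self):
        truth, contigs = simulate_assembly(
            60_000, contig_sizes=[2000], gap_sizes=[100], seed=4,
            with_sequence=False,
        )
        alns = simulate_read_pairs(truth, self.model, n_pairs=3000,
                                   read_len=50, chimera_rate=1.0, seed=5)
        links = self._links(truth, contigs, alns)
        non_adjacent = sum(
            not truth.adjacent(l.contig_a, l.contig_b) for l in links
        )
        assert non_adjacent > len(links) * 0.5


class TestMetrics:
    def test_mcc_formula(self):
        assert mcc(AdjacencyConfusion(TP=8, FP=2, FN=2, TN=8)) == \
            pytest.approx(0.6)
        assert mcc(AdjacencyConfusion(TP=5, FP=0, FN=0, TN=5)) == 1.0
        assert mcc(AdjacencyConfusion(TP=0, FP=0, FN=5, TN=5)) == 0.0
        assert np.isnan(mcc(AdjacencyConfusion()))

    def test_perfect_recovery_scores_one(self):
        truth, contigs = simulate_assembly(
            20_000, contig_sizes=[1000], gap_sizes=[100], seed=7,
            with_sequence=False,
        )
        chain = ScaffoldChain(
            contigs=[(c.id, c.orientation) for c in truth.contigs],
            gaps=[float(c.gap_after) for c in truth.contigs[:-1]],
        )
        ids = [c.id for c in truth.contigs]
        universe = {frozenset((a.id, b.id))
                    for a, b in zip(truth.contigs, truth.contigs[1:])}
        # plus skip pairs, as a real scaffolding graph would contain
        universe |= {frozenset((u, v)) for u, v in zip(ids, ids[2:])}
        conf = adjacency_confusion([chain], truth, universe)
        assert conf.FP == conf.FN == 0
        assert mcc(conf) == 1.0
        assert orientation_accuracy([chain], truth) == 1.0
        assert tpn50([chain], truth, contigs) == \
            n50(chain_spans([chain], contigs))

    def test_reversed_chain_is_still_correct(self):
        truth, contigs = simulate_assembly(
            10_000, contig_sizes=[1000], gap_sizes=[100], seed=8,
            with_sequence=False,
        )
        flip = {"+": "-", "-": "+"}
        chain = ScaffoldChain(
            contigs=[(c.id, flip[c.orientation])
                     for c in reversed(truth.contigs)],
            gaps=[float(c.gap_after)
                  for c in reversed(truth.contigs[:-1])],
        )
        universe = {frozenset((a.id, b.id))
                    for a, b in zip(truth.contigs, truth.contigs[1:])}
        conf = adjacency_confusion([chain], truth, universe)
        assert conf.FP == conf.FN == 0
        assert orientation_accuracy([chain], truth) == 1.0

    def test_label_permutation_gives_near_zero_mcc(self, rng):
        truth, contigs = simulate_assembly(
            60_000, contig_sizes=[1000], gap_sizes=[100], seed=9,
            with_sequence=False,
        )
        ids = [c.id for c in truth.contigs]
        # fixed universe: all contig pairs, so predictions independent of
        # the truth average out to MCC ~ 0
        universe = {frozenset(p) for p in
                    __import__("itertools").combinations(ids, 2)}
        vals = []
        for rep in range(20):
            perm = list(rng.permutation(ids))
            chain = ScaffoldChain(
                contigs=[(c, "+") for c in perm],
                gaps=[0.0] * (len(perm) - 1),
            )
            vals.append(mcc(adjacency_confusion([chain], truth, universe)))
        assert abs(np.mean(vals)) < 0.1

    def test_n50_cumulative_definition(self):
        assert n50([10, 10, 40, 40]) == 40
        assert n50([]) == 0.0
        assert n50([7]) == 7

    def test_split_then_n50(self):
        truth, contigs = simulate_assembly(
            100_000, contig_sizes=[1000], gap_sizes=[100], seed=10,
            with_sequence=False,
        )
        good = [(c.id, c.orientation) for c in truth.contigs]
        # corrupt one middle adjacency by flipping a contig's orientation
        mid = len(good) // 2
        flip = {"+": "-", "-": "+"}
        bad = list(good)
        bad[mid] = (bad[mid][0], flip[bad[mid][1]])
        chain = ScaffoldChain(contigs=bad,
                              gaps=[0.0] * (len(bad) - 1))
        pieces = split_at_errors([chain], truth)
        assert len(pieces) == 3  # both adjacencies of the flipped contig
        t = tpn50([chain], truth, contigs)
        n = n50(chain_spans([chain], contigs))
        assert t < n
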