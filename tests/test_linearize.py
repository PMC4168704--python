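import itertools

import numpy as np
import pytest

from mlscaffold.alignment_io import ContigRecord, InsertModel
from mlscaffold.graph import EdgeState, ScaffoldEdge, ScaffoldGraph
from mlscaffold.linearize import (
    ScaffoldChain,
    estimate_gaps,
    linearize,
    name_chains,
    parse_agp,
    revcomp,
    validate_chains,
    write_agp,
    write_scaffold_fasta,
)
from mlscaffold.orient import OrientationSolution

from conftest import make_link


def contigs_of(*lengths):
    return {
        f"c{i}": ContigRecord(id=f"c{i}", length=l, sequence="ACGT" * (l // 4))
        for i, l in enumerate(lengths)
    }


def graph_of(contigs, *weighted_edges):
    edges = {}
    for a, b, state, w in weighted_edges:
        e = ScaffoldEdge.from_weights(a, b)
        e.weight_by_state[state] = w
        edges[(a, b)] = e
    return ScaffoldGraph(contigs=contigs, edges=edges, min_bundle=1)


def solution_of(graph, flips, selected):
    return OrientationSolution(
        flips=flips,
        edge_parity={k: flips[k[0]] ^ flips[k[1]] for k in selected},
        selected_state=dict(selected),
        objective=0.0,
    )


class TestLinearize:
    def test_simple_path(self):
        contigs = contigs_of(100, 100, 100)
        g = graph_of(contigs, ("c0", "c1", EdgeState.A, 5.0),
                     ("c1", "c2", EdgeState.A, 4.0))
        sol = solution_of(g, {"c0": 0, "c1": 0, "c2": 0},
                          {("c0", "c1"): EdgeState.A,
                           ("c1", "c2"): EdgeState.A})
        chains = linearize(sol, g)
        assert len(chains) == 1
        assert chains[0].contigs == [("c0", "+"), ("c1", "+"), ("c2", "+")]

    def test_matching_keeps_heavier_successor(self):
        contigs = contigs_of(100, 100, 100)
        g = graph_of(contigs, ("c0", "c1", EdgeState.A, 5.0),
                     ("c0", "c2", EdgeState.A, 3.0))
        sol = solution_of(g, {"c0": 0, "c1": 0, "c2": 0},
                          {("c0", "c1"): EdgeState.A,
                           ("c0", "c2"): EdgeState.A})
        chains = sorted(linearize(sol, g), key=len, reverse=True)
        assert chains[0].ids() == ["c0", "c1"]
        assert chains[1].ids() == ["c2"]

    def test_flipped_pair_physical_direction(self):
        # state A with both contigs flipped is physically c1 -> c0
        contigs = contigs_of(100, 100)
        g = graph_of(contigs, ("c0", "c1", EdgeState.A, 5.0))
        sol = solution_of(g, {"c0": 1, "c1": 1},
                          {("c0", "c1"): EdgeState.A})
        chains = linearize(sol, g)
        assert chains[0].contigs == [("c1", "-"), ("c0", "-")]

    def test_residual_cycle_broken_at_weakest_edge(self):
        # a successor cycle constructed by bypassing the acyclicity pass
        contigs = contigs_of(100, 100, 100)
        g = graph_of(contigs, ("c0", "c1", EdgeState.A, 5.0),
                     ("c1", "c2", EdgeState.A, 4.0),
                     ("c0", "c2", EdgeState.D, 2.0))
        sol = solution_of(g, {"c0": 0, "c1": 0, "c2": 0},
                          {("c0", "c1"): EdgeState.A,
                           ("c1", "c2"): EdgeState.A,
                           ("c0", "c2"): EdgeState.D})
        chains = linearize(sol, g)
        assert len(chains) == 1
        assert chains[0].ids() == ["c0", "c1", "c2"]

    def test_chains_are_vertex_disjoint_and_cover(self, rng):
        contigs = contigs_of(*[100] * 8)
        names = sorted(contigs)
        edges = {}
        selected = {}
        for _ in range(10):
            a, b = sorted(rng.choice(names, 2, replace=False))
            if (a, b) in edges:
                continue
            e = ScaffoldEdge.from_weights(a, b)
            e.weight_by_state[EdgeState.A] = float(rng.uniform(1, 5))
            edges[(a, b)] = e
            selected[(a, b)] = EdgeState.A
        g = ScaffoldGraph(contigs=contigs, edges=edges, min_bundle=1)
        sol = solution_of(g, {n: 0 for n in names}, selected)
        chains = linearize(sol, g)
        validate_chains(chains, contigs)


class TestEstimateGaps:
    model = InsertModel(mu=500, sigma=50)

    def _chain(self, *lengths):
        contigs = contigs_of(*lengths)
        chain = ScaffoldChain(
            contigs=[(f"c{i}", "+") for i in range(len(lengths))]
        )
        return contigs, chain

    def test_single_gap_closed_form(self):
        contigs, chain = self._chain(1000, 1000)
        links = [
            make_link("c0", "c1", "+", "-", pair_id="a",
                      offset_a=200, offset_b=200),
            make_link("c0", "c1", "+", "-", pair_id="b",
                      offset_a=200, offset_b=220),
        ]
        est = estimate_gaps(chain, links, contigs, self.model, g_min=-150)
        assert est[0].value == pytest.approx(90.0, abs=1e-6)
        assert est[0].support == 2

    def test_lower_bound_projection(self):
        contigs, chain = self._chain(1000, 1000)
        links = [
            make_link("c0", "c1", "+", "-", pair_id="a",
                      offset_a=200, offset_b=200),
            make_link("c0", "c1", "+", "-", pair_id="b",
                      offset_a=200, offset_b=220),
        ]
        est = estimate_gaps(chain, links, contigs, self.model, g_min=100)
        assert est[0].value == pytest.approx(100.0, abs=1e-6)

    def test_discordant_link_excluded(self):
        contigs, chain = self._chain(1000, 1000)
        links = [
            make_link("c0", "c1", "+", "-", pair_id="a",
                      offset_a=200, offset_b=200),
            # '-' on the first contig points away from the junction
            make_link("c0", "c1", "-", "-", pair_id="bad",
                      offset_a=990, offset_b=200),
        ]
        est = estimate_gaps(chain, links, contigs, self.model)
        assert est[0].support == 1
        assert est[0].value == pytest.approx(100.0, abs=1e-6)

    def test_coupled_gaps_match_grid_search(self, rng):
        # 2 gaps, direct links on each plus one long-range link over both
        for trial in range(5):
            contigs, chain = self._chain(300, 150, 300)
            mu = float(self.model.mu)
            g_true = rng.uniform(20, 120, 2)
            links = []
            for k, (u, v, span) in enumerate(
                [(0, 1, g_true[0]), (1, 2, g_true[1]),
                 (0, 2, g_true[0] + 150 + g_true[1])]
            ):
                noise = float(rng.normal(0, 20))
                off_a = 100.0
                off_b = mu - span - off_a + noise
                links.append(make_link(
                    f"c{u}", f"c{v}", "+", "-", pair_id=f"l{k}",
                    offset_a=int(off_a), offset_b=int(round(off_b)),
                ))
            est = estimate_gaps(chain, links, contigs, self.model,
                                g_min=-150)
            got = np.array([e.value for e in est])

            def objective(g):
                tot = 0.0
                for (u, v), link in zip([(0, 1), (1, 2), (0, 2)], links):
                    span = sum(g[u:v]) + (150 if v - u == 2 else 0)
                    tot += (link.offset_a + span + link.offset_b - mu) ** 2
                return tot

            grid = range(-150, 301)
            best = min(itertools.product(grid, grid), key=objective)
            assert np.all(np.abs(got - np.array(best)) <= 1.0)

    def test_singleton_chain_has_no_gaps(self):
        contigs, chain = self._chain(1000)
        assert estimate_gaps(chain, [], contigs, self.model) == []

    def test_unsupported_adjacency_falls_back_to_default(self):
        contigs, chain = self._chain(1000, 1000)
        est = estimate_gaps(chain, [], contigs, self.model, default_gap=42.0)
        assert est[0].value == 42.0 and est[0].support == 0


class TestEmission:
    def _named(self):
        contigs = contigs_of(120, 80)
        chain = ScaffoldChain(contigs=[("c0", "+"), ("c1", "-")],
                              gaps=[90.0])
        single = ScaffoldChain(contigs=[("c1", "+")])
        named = name_chains([chain], contigs)
        return contigs, named

    def test_agp_round_trip_is_byte_exact(self, tmp_path):
        contigs, named = self._named()
        p1, p2 = tmp_path / "a.agp", tmp_path / "b.agp"
        write_agp(named, contigs, p1)
        reparsed = parse_agp(p1)
        assert [(n, ch.contigs, ch.gaps) for n, ch in reparsed] == \
            [(n, ch.contigs, ch.gaps) for n, ch in named]
        write_agp(reparsed, contigs, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fasta_layout(self, tmp_path):
        contigs, named = self._named()
        path = tmp_path / "s.fasta"
        write_scaffold_fasta(named, contigs, path)
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True)
        seq = str(fa["scaffold_1"][:])
        assert len(seq) == 120 + 90 + 80
        assert seq[:120] == contigs["c0"].sequence
        assert seq[120:210] == "N" * 90
        assert seq[210:] == revcomp(contigs["c1"].sequence)

    def test_negative_gap_uses_single_n_spacer(self, tmp_path):
        contigs = contigs_of(120, 80)
        chain = ScaffoldChain(contigs=[("c0", "+"), ("c1", "+")],
                              gaps=[-30.0])
        named = name_chains([chain], contigs)
        agp = tmp_path / "n.agp"
        write_agp(named, contigs, agp)
        lines = [l for l in agp.read_text().splitlines()
                 if "\tN\t" in l]
        assert lines[0].split("\t")[5] == "1"
        # raw estimate preserved in metadata
        assert any("-30.00" in l for l in agp.read_text().splitlines())
        reparsed = parse_agp(agp)
        assert reparsed[0][1].gaps == [-30.0]

    def test_singleton_chain_is_one_w_line(self, tmp_path):
        contigs = contigs_of(120)
        named = name_chains([ScaffoldChain(contigs=[("c0", "+")])], contigs)
        agp = tmp_path / "s.agp"
        write_agp(named, contigs, agp)
        body = [l for l in agp.read_text().splitlines()
                if not l.startswith("#")]
        assert len(body) == 1  # a single W line, no gap line
        assert body[0].split("\t")[4] == "W"
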