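import numpy as np
import pytest

from mlscaffold.alignment_io import ReadPairLink
from mlscaffold.graph import ScaffoldEdge


def random_weighted_graph(rng, max_nodes=12, max_edges=20, low=-3.0, high=5.0):
    """Random connected-ish graph with uniform per-state weights."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    m_target = int(rng.integers(1, max_edges + 1))
    edges = {}
    for _ in range(10 * m_target):
        if len(edges) >= m_target:
            break
        i, j = sorted(map(int, rng.choice(n, 2, replace=False)))
        key = (nodes[i], nodes[j])
        if key in edges:
            continue
        edges[key] = ScaffoldEdge.from_weights(*key, *rng.uniform(low, high, 4))
    return nodes, list(edges.values())


def glued_graph(rng, n_blobs=4, low=-3.0, high=5.0):
    """Random graph built by gluing small random blobs at 1 or 2 shared
    vertices, guaranteeing articulation points and separation pairs."""
    nodes, edges = [], {}
    counter = [0]

    def new_node():
        v = f"n{counter[0]:03d}"
        counter[0] += 1
        nodes.append(v)
        return v

    prev = [new_node()]
    for _ in range(n_blobs):
        share = 1 if rng.random() < 0.5 or len(prev) < 2 else 2
        base = list(rng.choice(prev, share, replace=False))
        size = int(rng.integers(3, 7))
        blob = base + [new_node() for _ in range(size - share)]
        for i in range(1, len(blob)):
            j = int(rng.integers(0, i))
            key = tuple(sorted((blob[i], blob[j])))
            if key not in edges:
                edges[key] = ScaffoldEdge.from_weights(
                    *key, *rng.uniform(low, high, 4)
                )
        for _ in range(int(rng.integers(0, size))):
            i, j = rng.choice(len(blob), 2, replace=False)
            key = tuple(sorted((blob[int(i)], blob[int(j)])))
            if key[0] != key[1] and key not in edges:
                edges[key] = ScaffoldEdge.from_weights(
                    *key, *rng.uniform(low, high, 4)
                )
        prev = blob
    return nodes, list(edges.values())


def make_link(a, b, strand_a="+", strand_b="-", p=0.9, pair_id="p0",
              offset_a=0, offset_b=0):
    return ReadPairLink(
        pair_id=pair_id, contig_a=a, contig_b=b,
        strand_a=strand_a, strand_b=strand_b,
        offset_a=offset_a, offset_b=offset_b, p_r=p,
    )


TINY_SAM = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:c1\tLN:100
@SQ\tSN:c2\tLN:200
r1/1\t0\tc1\t1\t60\t50M\t*\t0\t0\t*\t*\tAS:i:0
r1/2\t16\tc2\t51\t60\t50M\t*\t0\t0\t*\t*\tAS:i:0
r2/1\t16\tc1\t11\t60\t40M\t*\t0\t0\t*\t*\tAS:i:0
r2/2\t0\tc1\t1\t60\t40M\t*\t0\t0\t*\t*\tAS:i:0
r3/1\t0\tc1\t1\t60\t50M\t*\t0\t0\t*\t*\tAS:i:10
r3/1\t256\tc2\t1\t60\t50M\t*\t0\t0\t*\t*\tAS:i:10
r3/2\t16\tc2\t100\t60\t50M\t*\t0\t0\t*\t*\tAS:i:10
"""


@pytest.fixture
def tiny_sam(tmp_path):
    p = tmp_path / "tiny.sam"
    p.write_text(TINY_SAM)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(0)
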