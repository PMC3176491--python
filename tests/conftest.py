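from __future__ import annotations

import numpy as np
import pytest

from emap_motifs.emap_io import ScoreMatrix, canonical_pair
from emap_motifs.network_build import SignedEdge, SignedNetwork


def make_network(edge_spec, extra_nodes=()) -> SignedNetwork:
    """Build a SignedNetwork from (a, b, sign, score) tuples."""
    edges = {}
    nodes = set(extra_nodes)
    for a, b, sign, score in edge_spec:
        pair = canonical_pair(a, b)
        edges[pair] = SignedEdge(pair, sign, float(score))
        nodes.update(pair)
    return SignedNetwork(nodes=nodes, edges=edges)


def random_signed_network(rng: np.random.Generator, n_nodes: int, p_edge: float) -> SignedNetwork:
    """Random signed graph with scores consistent with edge signs."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    spec = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                if rng.random() < 0.5:
                    spec.append((names[i], names[j], "N", -rng.uniform(1, 10)))
                else:
                    spec.append((names[i], names[j], "P", rng.uniform(1, 10)))
    return make_network(spec, extra_nodes=names)


def matrix_from_pairs(pairs: dict) -> ScoreMatrix:
    """ScoreMatrix from a {(a, b): score} dict."""
    scores = {canonical_pair(a, b): float(s) for (a, b), s in pairs.items()}
    genes = sorted({g for p in scores for g in p})
    return ScoreMatrix(genes=genes, scores=scores)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
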