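"""Signed network construction from an S-score matrix.

Interactions are classified as positive (P), negative (N) or neutral by
symmetric percentile cutoffs: the most negative X percent and the most
positive X percent of all stored scores become edges, everything in
between is dropped. Genes with fewer than a minimum number of
supra-threshold edges are then removed, which suppresses noise-only
genes that could never take part in a closed triplet.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Iterator

import pandas as pd

from emap_motifs.emap_io import Pair, ScoreMatrix, canonical_pair

logger = logging.getLogger(__name__)

NEGATIVE = "N"
POSITIVE = "P"
SIGNS = (NEGATIVE, POSITIVE)


@dataclass
class ThresholdConfig:
    """Parameters of the sign classification.

    Parameters
    ----------
    percentile_x
        Tail mass per side, in percent. The realized cutoffs are the
        ``k``-th smallest and ``k``-th largest stored score with
        ``k = ceil(percentile_x / 100 * n_pairs)`` (nearest-rank,
        symmetric by construction).
    min_signed_degree
        Minimum total number of supra-threshold edges (N-degree plus
        P-degree) a gene must carry to be retained; default 2.
    iterate_filter
        If True, re-apply the degree filter until a fixpoint instead of
        the default single pass.
    """

    percentile_x: float = 1.0
    min_signed_degree: int = 2
    iterate_filter: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.percentile_x <= 50:
            raise ValueError("percentile_x must be in (0, 50]")
        if self.min_signed_degree < 0:
            raise ValueError("min_signed_degree must be >= 0")


@dataclass(frozen=True)
class SignedEdge:
    """One supra-threshold interaction: unordered pair, sign, S-score."""

    pair: Pair
    sign: str
    s_score: float

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")


@dataclass
class SignedNetwork:
    """Genes plus signed, scored edges and the realized cutoffs.

    ``edges`` maps each canonical pair to its :class:`SignedEdge`; a pair
    holds at most one edge. ``cutoffs`` is the realized
    (negative, positive) threshold pair.
    """

    nodes: set[str]
    edges: dict[Pair, SignedEdge]
    cutoffs: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        for pair, e in self.edges.items():
            if e.pair != pair:
                raise ValueError(f"edge key {pair} does not match edge pair {e.pair}")
            if pair[0] not in self.nodes or pair[1] not in self.nodes:
                raise ValueError(f"edge {pair} endpoint missing from node set")

    def signed_degrees(self) -> dict[str, dict[str, int]]:
        """Per-node N and P degree counts."""
        deg = {g: {NEGATIVE: 0, POSITIVE: 0} for g in self.nodes}
        for (a, b), e in self.edges.items():
            deg[a][e.sign] += 1
            deg[b][e.sign] += 1
        return deg

    def edges_of_sign(self, sign: str) -> list[SignedEdge]:
        return [e for e in self.edges.values() if e.sign == sign]

    def neighbours(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_networkx(self):
        """Export as a networkx Graph with sign/s_score edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, sign=e.sign, s_score=e.s_score)
        return g


def nearest_rank_cutoffs(scores: list[float], percentile_x: float) -> tuple[float, float]:
    """Symmetric nearest-rank tail cutoffs.

    Returns the ``k``-th smallest and ``k``-th largest score, with
    ``k = ceil(percentile_x / 100 * n)``. Both tails hold exactly ``k``
    scores up to ties at the cutoff.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("no scores")
    k = max(1, ceil(percentile_x / 100.0 * n))
    ordered = sorted(scores)
    return ordered[k - 1], ordered[n - k]


def threshold_scores(matrix: ScoreMatrix, config: ThresholdConfig) -> SignedNetwork:
    """Classify stored pairs into N / P edges by symmetric percentile cutoffs.

    Pairs with score <= the negative cutoff become N edges, pairs with
    score >= the positive cutoff become P edges; comparisons are
    inclusive, so ties at a cutoff are admitted. In the degenerate case
    where a score satisfies both cutoffs (possible only when the two
    cutoffs coincide) the edge is classified N.
    """
    if matrix.n_pairs < 1:
        raise ValueError("matrix has no stored pairs")
    lo, hi = nearest_rank_cutoffs(list(matrix.scores.values()), config.percentile_x)
    edges: dict[Pair, SignedEdge] = {}
    n_neg = n_pos = 0
    for pair, s in matrix.scores.items():
        if s <= lo:
            edges[pair] = SignedEdge(pair, NEGATIVE, s)
            n_neg += 1
        elif s >= hi:
            edges[pair] = SignedEdge(pair, POSITIVE, s)
            n_pos += 1
    if n_neg == 0 or n_pos == 0:
        warnings.warn(
            f"percentile {config.percentile_x} leaves an empty side "
            f"(N={n_neg}, P={n_pos})",
            stacklevel=2,
        )
    return SignedNetwork(nodes=set(matrix.genes), edges=edges, cutoffs=(lo, hi))


def filter_low_degree(network: SignedNetwork, config: ThresholdConfig) -> SignedNetwork:
    """Remove genes with total signed degree below the minimum.

    By default this is a single pass computed on the input network:
    surviving genes are not re-examined after edge removal, so a gene
    can end up below the minimum in the output. With
    ``config.iterate_filter`` the pass is repeated to a fixpoint.
    """
    nodes = set(network.nodes)
    edges = dict(network.edges)
    while True:
        deg: dict[str, int] = {g: 0 for g in nodes}
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        drop = {g for g in nodes if deg[g] < config.min_signed_degree}
        if not drop:
            break
        nodes -= drop
        edges = {p: e for p, e in edges.items() if p[0] in nodes and p[1] in nodes}
        if not config.iterate_filter:
            break
    return SignedNetwork(nodes=nodes, edges=edges, cutoffs=network.cutoffs)


def build_network(matrix: ScoreMatrix, config: ThresholdConfig) -> SignedNetwork:
    """threshold_scores followed by filter_low_degree."""
    net = threshold_scores(matrix, config)
    net = filter_low_degree(net, config)
    logger.info(
        "network: %d genes, %d N edges, %d P edges (cutoffs %.4g / %.4g)",
        len(net.nodes),
        len(net.edges_of_sign(NEGATIVE)),
        len(net.edges_of_sign(POSITIVE)),
        *net.cutoffs,
    )
    return net


def read_signed_edges(path) -> SignedNetwork:
    """Read a long-form signed edge TSV back into a SignedNetwork."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    edges: dict[Pair, SignedEdge] = {}
    nodes: set[str] = set()
    for row in df.itertuples(index=False):
        pair = canonical_pair(row.gene_a, row.gene_b)
        edges[pair] = SignedEdge(pair, str(row.sign), float(row.s_score))
        nodes.update(pair)
    return SignedNetwork(nodes=nodes, edges=edges)


def write_signed_edges(network: SignedNetwork, path) -> None:
    """Write the long-form signed edge TSV ``gene_a gene_b sign s_score``."""
    rows = [
        {"gene_a": a, "gene_b": b, "sign": e.sign, "s_score": e.s_score}
        for (a, b), e in sorted(network.edges.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign", "s_score"]).to_csv(
        path, sep="\t", index=False
    )
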