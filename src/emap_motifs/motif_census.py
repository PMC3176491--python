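"""Closed-triplet enumeration, classification and participation statistics.

A triplet motif is a set of three genes whose three pairs all carry
supra-threshold epistatic interactions. Triplets are classified by the
multiset of their edge signs — NNN, NNP, NPP or PPP — and the three
edges are ordered by ascending S-score into positions i (most negative),
ii, iii (most positive); position codes built downstream refer to this
ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy.stats import binomtest

from emap_motifs.emap_io import Pair
from emap_motifs.network_build import NEGATIVE, POSITIVE, SignedEdge, SignedNetwork

MOTIF_CLASSES = ("NNN", "NNP", "NPP", "PPP")


@dataclass(frozen=True)
class Triplet:
    """Three mutually interacting genes with score-ordered edges."""

    genes: tuple[str, str, str]
    edges: tuple[SignedEdge, SignedEdge, SignedEdge]
    motif_class: str

    @property
    def positions(self) -> tuple[Pair, Pair, Pair]:
        """The gene pairs at positions i, ii, iii."""
        return tuple(e.pair for e in self.edges)  # type: ignore[return-value]

    def shared_node(self, sign: str) -> str:
        """The gene incident to both edges of *sign* in a mixed triplet.

        For NPP this is the "positive node" (sign='P'); for NNP the
        "spanned node" (sign='N'). Raises for classes without exactly
        two edges of the sign.
        """
        same = [e for e in self.edges if e.sign == sign]
        if len(same) != 2:
            raise ValueError(
                f"class {self.motif_class} has no unique node shared by two "
                f"{sign} edges"
            )
        (a, b), (c, d) = same[0].pair, same[1].pair
        shared = {a, b} & {c, d}
        if len(shared) != 1:
            raise ValueError("degenerate triplet: edges do not share one node")
        return next(iter(shared))


@dataclass
class TripletCensus:
    """All closed triplets of a network plus per-class and per-edge counts."""

    triplets: list[Triplet]
    counts: dict[str, int]
    edge_participation: dict[Pair, int]

    @property
    def n_triplets(self) -> int:
        return len(self.triplets)

    def of_class(self, motif_class: str) -> list[Triplet]:
        return [t for t in self.triplets if t.motif_class == motif_class]


def classify_edges(edges: Iterable[SignedEdge]) -> tuple[tuple[SignedEdge, ...], str]:
    """Order edges ascending by (S-score, pair) and derive the class label.

    Ties on the S-score are broken lexicographically by the canonical
    pair labels so position codes are deterministic.
    """
    ordered = tuple(sorted(edges, key=lambda e: (e.s_score, e.pair)))
    n_neg = sum(1 for e in ordered if e.sign == NEGATIVE)
    label = NEGATIVE * n_neg + POSITIVE * (len(ordered) - n_neg)
    return ordered, label


def enumerate_triplets(network: SignedNetwork) -> TripletCensus:
    """Enumerate every closed gene triple exactly once.

    Uses the standard edge-iterator triangle listing: for each edge
    (u, v) with u < v, each common neighbour w > v closes one triangle.
    """
    if len(network.nodes) < 3:
        raise ValueError("network has fewer than 3 nodes")
    adj = network.neighbours()
    edges = network.edges
    triplets: list[Triplet] = []
    counts = {c: 0 for c in MOTIF_CLASSES}
    participation: dict[Pair, int] = {}
    for (u, v) in sorted(edges):
        for w in sorted(adj[u] & adj[v]):
            if w <= v:
                continue
            trio = (
                edges[(u, v)],
                edges[(u, w) if u < w else (w, u)],
                edges[(v, w) if v < w else (w, v)],
            )
            ordered, label = classify_edges(trio)
            t = Triplet(genes=(u, v, w), edges=ordered, motif_class=label)
            triplets.append(t)
            counts[label] += 1
            for e in ordered:
                participation[e.pair] = participation.get(e.pair, 0) + 1
    return TripletCensus(triplets=triplets, counts=counts, edge_participation=participation)


def participation_summary(census: TripletCensus) -> dict:
    """Per-sign participation statistics over edges in at least one triplet.

    Returns the fraction of participating edges that are negative and
    the mean number of triplets per participating N edge and P edge.
    An empty census yields a flagged-undefined summary.
    """
    if census.n_triplets == 0:
        return {
            "defined": False,
            "n_participating_edges": 0,
            "fraction_negative": float("nan"),
            "mean_triplets_per_N_edge": float("nan"),
            "mean_triplets_per_P_edge": float("nan"),
        }
    sign_by_pair: dict[Pair, str] = {}
    for t in census.triplets:
        for e in t.edges:
            sign_by_pair[e.pair] = e.sign
    by_sign: dict[str, list[int]] = {NEGATIVE: [], POSITIVE: []}
    for pair, k in census.edge_participation.items():
        by_sign[sign_by_pair[pair]].append(k)
    n_edges = len(census.edge_participation)

    def _mean(xs: list[int]) -> float:
        return sum(xs) / len(xs) if xs else float("nan")

    return {
        "defined": True,
        "n_participating_edges": n_edges,
        "fraction_negative": len(by_sign[NEGATIVE]) / n_edges,
        "mean_triplets_per_N_edge": _mean(by_sign[NEGATIVE]),
        "mean_triplets_per_P_edge": _mean(by_sign[POSITIVE]),
    }


def gene_sign_polarity(network: SignedNetwork) -> pd.DataFrame:
    """Per-gene sign skew with an exact binomial test.

    For every gene with at least one edge: N-degree, P-degree, fraction
    of its edges that are negative, a two-sided exact binomial p-value
    against an even 0.5 split, and the Bonferroni-corrected p across the
    tested genes.
    """
    deg = network.signed_degrees()
    rows = []
    for g in sorted(network.nodes):
        n, p = deg[g][NEGATIVE], deg[g][POSITIVE]
        total = n + p
        if total == 0:
            continue
        pval = binomtest(n, total, 0.5, alternative="two-sided").pvalue
        rows.append(
            {"gene": g, "n_degree": n, "p_degree": p,
             "fraction_negative": n / total, "p_raw": pval}
        )
    df = pd.DataFrame(
        rows, columns=["gene", "n_degree", "p_degree", "fraction_negative", "p_raw"]
    )
    if len(df):
        df["p_bonferroni"] = (df["p_raw"] * len(df)).clip(upper=1.0)
    else:
        df["p_bonferroni"] = pd.Series(dtype=float)
    return df


def write_triplets(census: TripletCensus, path) -> None:
    """Write the triplet TSV: genes, class, and the three ordered scores."""
    rows = []
    for t in census.triplets:
        rows.append(
            {
                "gene_a": t.genes[0],
                "gene_b": t.genes[1],
                "gene_c": t.genes[2],
                "class": t.motif_class,
                "score_i": t.edges[0].s_score,
                "score_ii": t.edges[1].s_score,
                "score_iii": t.edges[2].s_score,
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "gene_c", "class",
                 "score_i", "score_ii", "score_iii"],
    ).to_csv(path, sep="\t", index=False)


def write_census_json(census: TripletCensus, path) -> None:
    summary = participation_summary(census)
    with open(path, "w") as fh:
        json.dump({"counts": census.counts, "participation": summary}, fh, indent=2)
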