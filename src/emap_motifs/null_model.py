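"""Signed-degree-preserving randomization and motif enrichment z-scores.

The null model rewires the network by repeated double-edge switches
applied independently within the negative edge set and within the
positive edge set, so every node keeps its exact N-degree and P-degree.
Proposed switches that would create a self-loop or place a second edge
on an occupied pair (of either sign) are rejected, keeping the graph
simple. With a symmetric proposal and rejection counted as a self-loop
of the chain, the stationary distribution is uniform over the reachable
configurations with the original signed degree sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emap_motifs.emap_io import Pair, canonical_pair
from emap_motifs.motif_census import MOTIF_CLASSES, enumerate_triplets
from emap_motifs.network_build import NEGATIVE, POSITIVE, SignedEdge, SignedNetwork


@dataclass
class NullSummary:
    """Observed vs null-ensemble triplet counts per motif class.

    ``z`` is (observed − mean) / SD with the ensemble SD using the n−1
    denominator; it is NaN (flagged in ``z_defined``) when the SD is 0.
    """

    observed: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    z: dict[str, float]
    z_defined: dict[str, bool]
    n_random: int
    q: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(MOTIF_CLASSES),
                "observed": [self.observed[c] for c in MOTIF_CLASSES],
                "mean": [self.mean[c] for c in MOTIF_CLASSES],
                "sd": [self.sd[c] for c in MOTIF_CLASSES],
                "z": [self.z[c] for c in MOTIF_CLASSES],
            }
        )


def randomize_network(
    network: SignedNetwork, q: int, seed: int | np.random.Generator
) -> SignedNetwork:
    """One degree-preserving random rewiring of the network.

    Attempts ``q`` double-edge switches per edge, independently within
    each sign class. Each attempt draws two distinct edges of the class
    and one of the two reconnection orientations uniformly; the switch
    is applied only if it creates no self-loop and no duplicate pair
    (across both signs). Edge S-scores travel with their edge slot, so
    the per-sign score multiset is preserved.

    Parameters
    ----------
    q
        Attempted switches per edge (must be positive).
    seed
        Integer seed or a ``numpy.random.Generator`` to draw from.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    n_by_sign = {s: len(network.edges_of_sign(s)) for s in (NEGATIVE, POSITIVE)}
    if max(n_by_sign.values()) < 2:
        raise ValueError("network needs at least 2 edges of one sign")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # edge lists as mutable [gene, gene, score] slots per sign
    slots: dict[str, list[list]] = {NEGATIVE: [], POSITIVE: []}
    for e in network.edges.values():
        slots[e.sign].append([e.pair[0], e.pair[1], e.s_score])
    occupied: set[Pair] = set(network.edges)

    # q * m attempts per sign class, interleaved in a random schedule:
    # each attempt's kernel is symmetric (doubly stochastic), so any
    # interleaving keeps the uniform distribution over reachable
    # configurations invariant; a fixed per-sign phase order would not
    # sample the coupled N/P space uniformly.
    schedule = np.repeat(
        [NEGATIVE, POSITIVE],
        [q * len(slots[NEGATIVE]) if len(slots[NEGATIVE]) >= 2 else 0,
         q * len(slots[POSITIVE]) if len(slots[POSITIVE]) >= 2 else 0],
    )
    rng.shuffle(schedule)
    n_attempts = len(schedule)
    raw = rng.random(size=(n_attempts, 2))
    orient = rng.integers(0, 2, size=n_attempts)
    for step, sign in enumerate(schedule):
        edges = slots[sign]
        m = len(edges)
        i, j = int(raw[step, 0] * m), int(raw[step, 1] * m)
        if i == j:
            continue
        a, b, sa = edges[i]
        c, d, sc = edges[j]
        if orient[step]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = canonical_pair(a, d)
        new2 = canonical_pair(c, b)
        if new1 == new2 or new1 in occupied or new2 in occupied:
            continue
        occupied.discard(canonical_pair(a, b))
        occupied.discard(canonical_pair(c, d))
        occupied.add(new1)
        occupied.add(new2)
        edges[i] = [a, d, sa]
        edges[j] = [c, b, sc]

    new_edges: dict[Pair, SignedEdge] = {}
    for sign in (NEGATIVE, POSITIVE):
        for a, b, s in slots[sign]:
            pair = canonical_pair(a, b)
            new_edges[pair] = SignedEdge(pair, sign, s)
    return SignedNetwork(nodes=set(network.nodes), edges=new_edges, cutoffs=network.cutoffs)


def motif_enrichment(
    network: SignedNetwork,
    n_random: int = 1000,
    q: int = 100,
    seed: int = 0,
) -> NullSummary:
    """Observed triplet-class counts vs a randomized ensemble.

    Each ensemble member is an independent rewiring of the input
    network, drawn from a per-draw stream derived from ``seed`` by a
    counter-based scheme, so runs are reproducible and draw-order
    independent.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2 for an SD to exist")
    observed = enumerate_triplets(network).counts
    ensemble = np.zeros((n_random, len(MOTIF_CLASSES)), dtype=float)
    for r in range(n_random):
        rng = np.random.default_rng([seed, r])
        random_net = randomize_network(network, q=q, seed=rng)
        counts = enumerate_triplets(random_net).counts
        ensemble[r] = [counts[c] for c in MOTIF_CLASSES]
    mean = ensemble.mean(axis=0)
    sd = ensemble.std(axis=0, ddof=1)
    z: dict[str, float] = {}
    z_defined: dict[str, bool] = {}
    for k, c in enumerate(MOTIF_CLASSES):
        if sd[k] > 0:
            z[c] = (observed[c] - mean[k]) / sd[k]
            z_defined[c] = True
        else:
            z[c] = float("nan")
            z_defined[c] = False
    return NullSummary(
        observed=dict(observed),
        mean={c: float(mean[k]) for k, c in enumerate(MOTIF_CLASSES)},
        sd={c: float(sd[k]) for k, c in enumerate(MOTIF_CLASSES)},
        z=z,
        z_defined=z_defined,
        n_random=n_random,
        q=q,
        seed=seed if isinstance(seed, int) else -1,
    )


def write_null_summary(summary: NullSummary, tsv_path, json_path=None) -> None:
    summary.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "n_random": summary.n_random,
                    "q": summary.q,
                    "seed": summary.seed,
                    "observed": summary.observed,
                    "mean": summary.mean,
                    "sd": summary.sd,
                    "z": {c: (None if math.isnan(v) else v) for c, v in summary.z.items()},
                },
                fh,
                indent=2,
            )
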