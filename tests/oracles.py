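"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive: exhaustive loops, exact
enumeration, direct combinatorial arithmetic. None of it shares code
with the package paths it verifies.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

from emap_motifs.network_build import SignedNetwork


def brute_force_triplets(network: SignedNetwork):
    """All closed triples by exhaustive triple loop.

    Returns a set of (genes, ordered pairs, class) tuples with edges
    sorted ascending by (score, pair) — the same canonical form the
    census uses, derived independently.
    """
    result = set()
    edges = network.edges
    for a, b, c in combinations(sorted(network.nodes), 3):
        trio_pairs = [(a, b), (a, c), (b, c)]
        if not all(p in edges for p in trio_pairs):
            continue
        trio = sorted(
            ((edges[p].s_score, p, edges[p].sign) for p in trio_pairs),
        )
        label = "".join(sorted(sign for _, _, sign in trio))
        ordered_pairs = tuple(p for _, p, _ in trio)
        result.add(((a, b, c), ordered_pairs, label))
    return result


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the point probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (with a tiny relative tolerance for float round-off).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x: int) -> float:
        # P(X = x) for X hypergeometric: x successes in r1 draws,
        # c1 successes in population n
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = point_prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = point_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def hypergeom_over_p(k: int, M: int, K: int, n: int) -> float:
    """One-sided over-representation P(X >= k) by direct summation."""
    return sum(
        comb(K, x) * comb(M - K, n - x) / comb(M, n)
        for x in range(k, min(K, n) + 1)
    )


def _state(network_edges):
    n = frozenset(p for p, e in network_edges.items() if e.sign == "N")
    p = frozenset(p for p, e in network_edges.items() if e.sign == "P")
    return n, p


def reachable_states(network: SignedNetwork):
    """BFS over all double-edge-switch moves from the input network.

    A move picks two distinct edges of one sign and one of the two
    reconnection orientations; it is legal if it creates no self-loop
    and no duplicate pair across both signs. Returns the set of
    (N-pair frozenset, P-pair frozenset) states reachable from the
    input — the support of the switching chain's stationary
    distribution, which is uniform on this set because the proposal is
    symmetric.
    """
    start = _state(network.edges)
    seen = {start}
    queue = deque([start])
    while queue:
        n_set, p_set = queue.popleft()
        occupied = n_set | p_set
        for sign_set, other in ((n_set, p_set), (p_set, n_set)):
            edges = sorted(sign_set)
            for (e1, e2) in combinations(edges, 2):
                (a, b), (c, d) = e1, e2
                for (x1, y1), (x2, y2) in (((a, d), (c, b)), ((a, c), (b, d))):
                    if x1 == y1 or x2 == y2:
                        continue
                    new1 = (x1, y1) if x1 < y1 else (y1, x1)
                    new2 = (x2, y2) if x2 < y2 else (y2, x2)
                    if new1 == new2:
                        continue
                    if (new1 in occupied and new1 not in (e1, e2)) or (
                        new2 in occupied and new2 not in (e1, e2)
                    ):
                        continue
                    new_set = frozenset(sign_set - {e1, e2} | {new1, new2})
                    if sign_set is n_set:
                        state = (new_set, p_set)
                    else:
                        state = (n_set, new_set)
                    if state not in seen:
                        seen.add(state)
                        queue.append(state)
    return seen


def exact_class_expectation(network: SignedNetwork):
    """Exact per-class mean triplet count over the reachable states."""
    states = reachable_states(network)
    totals = {"NNN": 0.0, "NNP": 0.0, "NPP": 0.0, "PPP": 0.0}
    for n_set, p_set in states:
        sign_of = {p: "N" for p in n_set}
        sign_of.update({p: "P" for p in p_set})
        nodes = sorted({g for p in sign_of for g in p})
        for a, b, c in combinations(nodes, 3):
            trio = [(a, b), (a, c), (b, c)]
            if all(p in sign_of for p in trio):
                label = "".join(sorted(sign_of[p] for p in trio))
                totals[label] += 1
    k = len(states)
    return {c: t / k for c, t in totals.items()}, states
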