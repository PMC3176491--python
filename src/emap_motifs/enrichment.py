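"""Statistical association of triplet motifs with annotation channels.

Four analyses are provided:

* position-coded Fisher enrichment — each triplet gets a 3-bit code per
  channel recording, for its edges ordered from most negative to most
  positive S-score (positions i, ii, iii), whether the gene pair shares
  the feature; codes are cross-tabulated against motif classes with
  two-sided Fisher exact tests;
* edge-context fold changes — for each edge sign, the fraction of edges
  sharing a feature in each triplet context, relative to same-sign
  edges outside any triplet;
* within-triplet profile correlation — Spearman correlation of the two
  genes' S-score vectors over common partners, summarized per edge-sign
  role within a motif class;
* positional gene-set enrichment — hypergeometric over-representation
  of terms among the genes occupying a given node role (e.g. the
  positive node of NPP triplets, the gene incident to both P edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, spearmanr

from emap_motifs.annotations import AnnotationSet, pair_shares
from emap_motifs.emap_io import ScoreMatrix
from emap_motifs.motif_census import MOTIF_CLASSES, TripletCensus
from emap_motifs.network_build import NEGATIVE, POSITIVE, SignedNetwork

logger = logging.getLogger(__name__)

ALL_PATTERNS = ("000", "100", "010", "001", "110", "101", "011", "111")
#: Named position aggregates: a bit set at the given position, rest free.
POSITION_AGGREGATES = {"any-bit-at-i": 0, "any-bit-at-ii": 1, "any-bit-at-iii": 2}

#: Node roles per motif class: the gene incident to both edges of the sign.
NODE_ROLES = {
    ("NPP", "positive_node"): POSITIVE,
    ("NNP", "spanned_node"): NEGATIVE,
}


def code_features(
    census: TripletCensus,
    annotation: AnnotationSet,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One 3-bit feature code per (triplet, channel).

    Bit k of the code is '1' iff the gene pair of the edge at position k
    (i = most negative, iii = most positive) shares the channel's
    feature. Genes missing from the annotation simply contribute 0 bits.
    Returns a frame with columns ``triplet, motif_class, channel, code``.
    """
    channels = list(channels) if channels is not None else annotation.channels()
    rows = []
    for idx, t in enumerate(census.triplets):
        for channel in channels:
            bits = "".join(
                "1" if pair_shares(annotation, channel, e.pair) else "0"
                for e in t.edges
            )
            rows.append(
                {"triplet": idx, "motif_class": t.motif_class,
                 "channel": channel, "code": bits}
            )
    return pd.DataFrame(rows, columns=["triplet", "motif_class", "channel", "code"])


def multi_bit_diagnostic(codes: pd.DataFrame) -> pd.DataFrame:
    """Observed frequency of the two-bit codes {110, 101, 011} per channel.

    For channels whose sharing relation is transitive (e.g. membership
    of one complex), any two shared edges force the third, so two-bit
    codes indicate non-transitive sharing; their frequency is emitted as
    a diagnostic.
    """
    two_bit = codes[codes["code"].isin(("110", "101", "011"))]
    out = (
        two_bit.groupby(["channel", "code"]).size().rename("count").reset_index()
    )
    return out


def code_matches(code: str, pattern: str, collapse: bool = False) -> bool:
    """Whether a 3-bit code matches a pattern or named position aggregate.

    With ``collapse``, any code with two or more set bits is mapped to
    '111' before matching.
    """
    if collapse and code.count("1") >= 2:
        code = "111"
    if pattern in POSITION_AGGREGATES:
        return code[POSITION_AGGREGATES[pattern]] == "1"
    if len(pattern) == 3 and set(pattern) <= {"0", "1"}:
        return code == pattern
    raise ValueError(f"unknown pattern {pattern!r}")


@dataclass
class EnrichmentRecord:
    """One Fisher cross-tabulation of a code pattern against a motif class."""

    channel: str
    pattern: str
    motif_class: str
    a: int  #: in class, code matches
    b: int  #: in class, no match
    c: int  #: other classes, code matches
    d: int  #: other classes, no match
    odds_ratio: float
    p_raw: float
    p_bonferroni: float = float("nan")
    testable: bool = True


def _haldane_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_cross_tab(
    codes: pd.DataFrame,
    census: TripletCensus,
    channel: str,
    pattern: str,
    motif_class: str,
    collapse: bool = False,
) -> EnrichmentRecord:
    """Two-sided Fisher exact test of a code pattern vs a motif class.

    Rows of the 2x2 table are {triplet in class, not}; columns are
    {code matches pattern, not}. The odds ratio applies the Haldane 0.5
    correction when any cell is zero. A class with zero triplets yields
    an untestable record.
    """
    sub = codes[codes["channel"] == channel]
    if len(sub) != census.n_triplets:
        raise ValueError("code table does not cover every triplet for the channel")
    in_class = sub["motif_class"] == motif_class
    matches = sub["code"].map(lambda c: code_matches(c, pattern, collapse=collapse))
    a = int((in_class & matches).sum())
    b = int((in_class & ~matches).sum())
    c = int((~in_class & matches).sum())
    d = int((~in_class & ~matches).sum())
    if a + b == 0:
        return EnrichmentRecord(channel, pattern, motif_class, a, b, c, d,
                                float("nan"), float("nan"), testable=False)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentRecord(
        channel, pattern, motif_class, a, b, c, d,
        _haldane_odds_ratio(a, b, c, d), float(p),
    )


def enrichment_scan(
    codes: pd.DataFrame,
    census: TripletCensus,
    channels: Sequence[str] | None = None,
    patterns: Sequence[str] = ("100", "010", "001", "111"),
    classes: Sequence[str] = MOTIF_CLASSES,
    collapse: bool = False,
) -> pd.DataFrame:
    """All (channel x pattern x class) Fisher tests with Bonferroni.

    The Bonferroni family is the set of testable records emitted by this
    run. Returns a frame with the contingency cells, odds ratio, raw and
    corrected p per test.
    """
    channels = list(channels) if channels is not None else sorted(codes["channel"].unique())
    records: list[EnrichmentRecord] = []
    for channel in channels:
        for pattern in patterns:
            for mclass in classes:
                records.append(
                    fisher_cross_tab(codes, census, channel, pattern, mclass,
                                     collapse=collapse)
                )
    family = sum(1 for r in records if r.testable)
    for r in records:
        if r.testable:
            r.p_bonferroni = min(1.0, r.p_raw * family)
    return pd.DataFrame(
        [
            {"channel": r.channel, "pattern": r.pattern, "class": r.motif_class,
             "a": r.a, "b": r.b, "c": r.c, "d": r.d,
             "odds_ratio": r.odds_ratio, "p": r.p_raw, "p_bonf": r.p_bonferroni,
             "testable": r.testable}
            for r in records
        ]
    )


def edge_context_foldchange(
    network: SignedNetwork,
    census: TripletCensus,
    annotation: AnnotationSet,
    sign: str,
    channels: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Feature-sharing fold change of in-triplet edges over lone edges.

    For every channel and every edge category of the given sign
    (not-in-triplet baseline; in any triplet; in NPP; in NNP; in the
    same-sign homogeneous class), the fraction of edges whose pair
    shares the feature, the fold change over the baseline, and a
    two-sided Fisher p vs the baseline with Bonferroni correction
    across all emitted comparisons; significance at corrected p < alpha.
    """
    if sign not in (NEGATIVE, POSITIVE):
        raise ValueError(f"sign must be N or P, got {sign!r}")
    channels = list(channels) if channels is not None else annotation.channels()
    sign_edges = [e.pair for e in network.edges.values() if e.sign == sign]
    classes_of_pair: dict = {}
    for t in census.triplets:
        for e in t.edges:
            classes_of_pair.setdefault(e.pair, set()).add(t.motif_class)
    homogeneous = "NNN" if sign == NEGATIVE else "PPP"
    categories = {
        "not_in_triplet": [p for p in sign_edges if p not in classes_of_pair],
        "in_any_triplet": [p for p in sign_edges if p in classes_of_pair],
        "in_NPP": [p for p in sign_edges if "NPP" in classes_of_pair.get(p, ())],
        "in_NNP": [p for p in sign_edges if "NNP" in classes_of_pair.get(p, ())],
        f"in_{homogeneous}": [
            p for p in sign_edges if homogeneous in classes_of_pair.get(p, ())
        ],
    }
    baseline = categories["not_in_triplet"]
    rows = []
    for channel in channels:
        base_shared = sum(pair_shares(annotation, channel, p) for p in baseline)
        base_frac = base_shared / len(baseline) if baseline else float("nan")
        for cat, pairs in categories.items():
            if cat == "not_in_triplet":
                continue
            shared = sum(pair_shares(annotation, channel, p) for p in pairs)
            frac = shared / len(pairs) if pairs else float("nan")
            if baseline and pairs and base_frac > 0:
                fold = frac / base_frac
            else:
                fold = float("nan")
            if baseline and pairs:
                _, p_raw = fisher_exact(
                    [[shared, len(pairs) - shared],
                     [base_shared, len(baseline) - base_shared]],
                    alternative="two-sided",
                )
            else:
                p_raw = float("nan")
            rows.append(
                {"sign": sign, "channel": channel, "category": cat,
                 "n_edges": len(pairs), "n_shared": shared, "fraction": frac,
                 "baseline_fraction": base_frac, "fold_change": fold,
                 "p": p_raw}
            )
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    family = int(tested.sum())
    df["p_bonf"] = (df["p"] * family).clip(upper=1.0)
    df["significant"] = tested & (df["p_bonf"] < alpha)
    return df


def profile_correlation(
    matrix: ScoreMatrix,
    census: TripletCensus,
    motif_class: str,
    min_common: int = 10,
) -> pd.DataFrame:
    """Spearman similarity of interaction profiles within a motif class.

    For each triplet of the class and each of its edges, the Spearman
    rank correlation of the two genes' S-score vectors over the partners
    scored for both (the two triplet-mates themselves excluded). Edges
    with fewer than ``min_common`` common partners are skipped. The
    summary reports, per edge-sign role within the class, the mean, SD
    and standard error of the correlations.
    """
    partner_cache: dict[str, dict[str, float]] = {}

    def _partners(g: str) -> dict[str, float]:
        if g not in partner_cache:
            partner_cache[g] = matrix.partners(g)
        return partner_cache[g]

    per_edge: dict[str, list[float]] = {NEGATIVE: [], POSITIVE: []}
    for t in census.of_class(motif_class):
        for e in t.edges:
            a, b = e.pair
            pa, pb = _partners(a), _partners(b)
            common = sorted((set(pa) & set(pb)) - {a, b})
            if len(common) < min_common:
                continue
            va = [pa[g] for g in common]
            vb = [pb[g] for g in common]
            rho = spearmanr(va, vb).statistic
            per_edge[e.sign].append(float(rho))
    rows = []
    for sign in (NEGATIVE, POSITIVE):
        vals = np.asarray(per_edge[sign], dtype=float)
        n = len(vals)
        rows.append(
            {
                "motif_class": motif_class,
                "edge_sign": sign,
                "n_edges": n,
                "mean_rho": float(vals.mean()) if n else float("nan"),
                "sd_rho": float(vals.std(ddof=1)) if n > 1 else float("nan"),
                "se_rho": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def position_gene_enrichment(
    census: TripletCensus,
    annotation: AnnotationSet,
    motif_class: str,
    role: str,
    channel: str,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Term over-representation among genes occupying a triplet node role.

    The gene set is the distinct genes occupying ``role`` across all
    triplets of ``motif_class`` (e.g. the NPP 'positive_node', incident
    to both P edges). For each term of the channel annotating at least
    one universe gene: the percentage of the set annotated, a one-sided
    hypergeometric p against the universe, Bonferroni correction across
    terms, and fold enrichment (set fraction over universe fraction).
    Results are sorted by corrected p, then descending fold.
    """
    try:
        role_sign = NODE_ROLES[(motif_class, role)]
    except KeyError:
        raise ValueError(f"unknown role {role!r} for class {motif_class!r}") from None
    if channel not in annotation.gene_terms:
        raise KeyError(f"{channel!r} is not a term channel")
    universe = set(universe)
    role_genes = sorted(
        {t.shared_node(role_sign) for t in census.of_class(motif_class)} & universe
    )
    n = len(role_genes)
    M = len(universe)
    terms = annotation.gene_terms[channel]
    genes_by_term: dict[str, set[str]] = {}
    for gene in universe:
        for term in terms.get(gene, ()):  # frequency over the universe only
            genes_by_term.setdefault(term, set()).add(gene)
    rows = []
    for term, annotated in sorted(genes_by_term.items()):
        K = len(annotated)
        k = len(annotated & set(role_genes))
        p = float(hypergeom.sf(k - 1, M, K, n)) if n else float("nan")
        fold = (k / n) / (K / M) if n and K else 0.0
        rows.append(
            {"term": term, "n_set": k, "n_universe": K,
             "percent_of_set": 100.0 * k / n if n else float("nan"),
             "p": p, "fold_enrichment": fold}
        )
    df = pd.DataFrame(
        rows, columns=["term", "n_set", "n_universe", "percent_of_set",
                       "p", "fold_enrichment"]
    )
    df["p_bonf"] = (df["p"] * len(df)).clip(upper=1.0)
    return df.sort_values(
        ["p_bonf", "p", "fold_enrichment"], ascending=[True, True, False]
    ).reset_index(drop=True)
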