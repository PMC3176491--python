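"""E-MAP-like synthetic score matrices with planted biological structure.

The generator emulates the gross statistics of a pooled epistasis map —
a sparse (~78% missing) symmetric S-score matrix — and plants the four
arrangements the motif analysis is designed to detect:

* protein complexes: small cliques of strongly positive scores (PPP);
* between-complex bridges: strongly negative edges between the liaison
  genes of two complexes. Bridged complex pairs are taken in a fixed
  order that makes the first three complexes mutually bridged, so the
  liaison genes of that triangle of complexes form all-negative
  triplets (NNN) while each single bridge plants NNP triplets
  (a liaison pair's positive intra-complex edge spanned by two
  negatives from the partner complex);
* redundant pathway pairs: strongly negative within-pathway edges;
* regulators: genes positively linked to every member of their target
  pathways (by default each regulator acts on two pathways), planting
  NPP triplets whose positive node is the regulator.

Ground-truth labels are emitted as an annotation set in the channels the
enrichment analyses consume, so planted structure is recoverable
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from emap_motifs.annotations import AnnotationSet
from emap_motifs.emap_io import Pair, ScoreMatrix, canonical_pair
from emap_motifs.network_build import ThresholdConfig, build_network
from emap_motifs.motif_census import enumerate_triplets
from emap_motifs.null_model import motif_enrichment
from emap_motifs.enrichment import position_gene_enrichment

#: GO-like term marking planted regulators in the go_function channel.
REGULATOR_TERM = "regulatory_activity"
PATHWAY_ENZYME_TERM = "pathway_enzyme_activity"
COMPLEX_SUBUNIT_TERM = "complex_subunit_activity"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic E-MAP generator.

    Score distributions are Gaussian: structural pairs draw from
    N(mean, noise_sd) with |mean| large against the N(0, background_sd)
    background, so permissive tail cutoffs capture the planted edges.
    """

    n_genes: int = 100
    n_complexes: int = 5
    complex_size: tuple[int, int] = (4, 4)
    n_pathways: int = 5
    pathway_size: tuple[int, int] = (2, 2)
    n_regulators: int = 5
    pathways_per_regulator: int = 2
    n_bridges: int = 3
    bridge_liaisons: int = 2
    intra_complex_mean: float = 6.0
    pathway_pair_mean: float = -6.0
    bridge_mean: float = -6.0
    regulator_mean: float = 6.0
    background_mean: float = 0.0
    background_sd: float = 1.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.78
    keep_planted: bool = True
    block_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        for lo, hi in (self.complex_size, self.pathway_size):
            if lo < 2 or hi < lo:
                raise ValueError("size ranges must satisfy 2 <= lo <= hi")


@dataclass
class SyntheticTruth:
    """Planted roles and the motif-generating configurations."""

    roles: dict[str, str]
    complexes: list[list[str]]
    pathways: list[list[str]]
    regulators: dict[str, list[int]]  #: regulator gene -> target pathway indices
    bridged_complexes: list[tuple[int, int]]
    planted_structures: list[dict] = field(default_factory=list)


def _complex_pair_order(n_complexes: int) -> list[tuple[int, int]]:
    """Complex pairs in colexicographic order: (0,1), (0,2), (1,2), ...

    The first three entries bridge complexes 0, 1 and 2 mutually.
    """
    out = []
    for j in range(1, n_complexes):
        for i in range(j):
            out.append((i, j))
    return out


def generate_emap(config: SyntheticConfig) -> tuple[ScoreMatrix, SyntheticTruth, AnnotationSet]:
    """Draw one synthetic score matrix with ground truth and annotations.

    The missing mask is uniform over non-planted pairs (planted pairs
    are exempt unless ``keep_planted`` is off), with the per-pair
    missing probability scaled so the expected overall missingness
    equals ``missing_fraction``. With ``block_size`` set, pairs spanning
    different gene blocks are additionally missing, emulating the
    fragmented coverage of pooled screens.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    # --- assign roles from the front of the gene list
    cursor = 0
    roles: dict[str, str] = {}
    complexes: list[list[str]] = []
    for i in range(config.n_complexes):
        size = int(rng.integers(config.complex_size[0], config.complex_size[1] + 1))
        members = genes[cursor:cursor + size]
        cursor += size
        if cursor > config.n_genes:
            raise ValueError("planted structure exceeds the number of genes")
        complexes.append(members)
        for g in members:
            roles[g] = f"complex:{i}"
    pathways: list[list[str]] = []
    for i in range(config.n_pathways):
        size = int(rng.integers(config.pathway_size[0], config.pathway_size[1] + 1))
        members = genes[cursor:cursor + size]
        cursor += size
        if cursor > config.n_genes:
            raise ValueError("planted structure exceeds the number of genes")
        pathways.append(members)
        for g in members:
            roles[g] = f"pathway:{i}"
    regulators: dict[str, list[int]] = {}
    for i in range(config.n_regulators):
        if cursor >= config.n_genes:
            raise ValueError("planted structure exceeds the number of genes")
        g = genes[cursor]
        cursor += 1
        n_pw = max(1, config.n_pathways)
        targets = sorted({(i + k) % n_pw for k in range(config.pathways_per_regulator)})
        regulators[g] = targets
        roles[g] = "regulator:" + ",".join(map(str, targets))
    if cursor > config.n_genes:
        raise ValueError("planted structure exceeds the number of genes")

    # --- planted structural pairs with their score means
    planted: dict[Pair, float] = {}
    structures: list[dict] = []

    def _plant(a: str, b: str, mean: float) -> None:
        planted[canonical_pair(a, b)] = mean

    for i, members in enumerate(complexes):
        for a, b in combinations(members, 2):
            _plant(a, b, config.intra_complex_mean)
        structures.append({"kind": "complex", "genes": members, "expected_class": "PPP"})
    bridged = _complex_pair_order(config.n_complexes)[: config.n_bridges]
    for i, j in bridged:
        la = complexes[i][: config.bridge_liaisons]
        lb = complexes[j][: config.bridge_liaisons]
        for a in la:
            for b in lb:
                _plant(a, b, config.bridge_mean)
        structures.append(
            {"kind": "bridge", "complexes": [i, j], "genes": la + lb,
             "expected_class": "NNP"}
        )
    mutually_bridged = [
        (i, j, k)
        for i, j, k in combinations(range(config.n_complexes), 3)
        if {(i, j), (i, k), (j, k)} <= set(bridged)
    ]
    for i, j, k in mutually_bridged:
        structures.append(
            {"kind": "bridge_triangle", "complexes": [i, j, k],
             "expected_class": "NNN"}
        )
    for i, members in enumerate(pathways):
        for a, b in combinations(members, 2):
            _plant(a, b, config.pathway_pair_mean)
        structures.append({"kind": "pathway", "genes": members, "expected_class": None})
    for reg, targets in regulators.items():
        for pw in targets:
            for m in pathways[pw]:
                _plant(reg, m, config.regulator_mean)
            structures.append(
                {"kind": "regulator", "genes": [reg] + pathways[pw],
                 "regulator": reg, "expected_class": "NPP"}
            )
    total_pairs = comb(config.n_genes, 2)
    if len(planted) > total_pairs:
        raise ValueError("planted structure exceeds available gene pairs")

    # --- scores with a uniform missing mask over non-planted pairs
    n_nonplanted = total_pairs - (len(planted) if config.keep_planted else 0)
    target_missing = config.missing_fraction * total_pairs
    p_missing = min(1.0, target_missing / n_nonplanted) if n_nonplanted else 0.0
    block_of = (
        {g: idx // config.block_size for idx, g in enumerate(genes)}
        if config.block_size
        else None
    )
    scores: dict[Pair, float] = {}
    for a, b in combinations(genes, 2):
        pair = (a, b)
        is_planted = pair in planted
        if is_planted and config.keep_planted:
            scores[pair] = planted[pair] + rng.normal(0.0, config.noise_sd)
            continue
        if block_of is not None and block_of[a] != block_of[b]:
            continue
        if rng.random() < p_missing:
            continue
        if is_planted:
            scores[pair] = planted[pair] + rng.normal(0.0, config.noise_sd)
        else:
            scores[pair] = rng.normal(config.background_mean, config.background_sd)

    matrix = ScoreMatrix(genes=genes, scores=scores, n_sources={p: 1 for p in scores})
    truth = SyntheticTruth(
        roles=roles,
        complexes=complexes,
        pathways=pathways,
        regulators=regulators,
        bridged_complexes=bridged,
        planted_structures=structures,
    )
    annotation = _truth_annotations(truth)
    return matrix, truth, annotation


def _truth_annotations(truth: SyntheticTruth) -> AnnotationSet:
    """Annotation channels exposing the planted labels."""
    complex_terms: dict[str, set[str]] = {}
    go_function: dict[str, set[str]] = {}
    physical: set[Pair] = set()
    for i, members in enumerate(truth.complexes):
        for g in members:
            complex_terms.setdefault(g, set()).add(f"CPX{i}")
            go_function.setdefault(g, set()).add(COMPLEX_SUBUNIT_TERM)
        for a, b in combinations(members, 2):
            physical.add(canonical_pair(a, b))
    pathway_terms: dict[str, set[str]] = {}
    genetic: set[Pair] = set()
    for i, members in enumerate(truth.pathways):
        for g in members:
            pathway_terms.setdefault(g, set()).add(f"PWY{i}")
            go_function.setdefault(g, set()).add(PATHWAY_ENZYME_TERM)
        for a, b in combinations(members, 2):
            genetic.add(canonical_pair(a, b))
    for g in truth.regulators:
        go_function.setdefault(g, set()).add(REGULATOR_TERM)
    return AnnotationSet(
        gene_terms={
            "complex": complex_terms,
            "pathway": pathway_terms,
            "go_function": go_function,
        },
        pair_relations={
            "physical_interaction": physical,
            "genetic_interaction": genetic,
        },
    )


#: Recovery threshold: tails sized so the planted structure (~4.6% of
#: measured pairs at the default scale) falls inside them.
DEFAULT_RECOVERY_THRESHOLD = ThresholdConfig(percentile_x=5.0, min_signed_degree=2)


def unstructured_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Default-sized config with every planted structure removed."""
    fields = dict(n_complexes=0, n_pathways=0, n_regulators=0, n_bridges=0, seed=seed)
    fields.update(overrides)
    return SyntheticConfig(**fields)


def null_calibration(
    n_replicates: int = 100,
    threshold_config: ThresholdConfig | None = None,
    n_random: int = 200,
    q: int = 50,
    seed: int = 0,
    z_bound: float = 3.0,
) -> dict:
    """False-alarm rate of the motif z-scores on unstructured matrices.

    Each replicate generates a background-only matrix, builds the signed
    network at the same threshold the recovery experiment uses, and asks
    whether every class z lies within ``z_bound``. A class whose null SD
    is zero counts as within bounds iff its observed count equals the
    null mean; a network too small or too sparse to randomize carries no
    triplet structure and counts as within bounds for all classes.
    """
    threshold_config = threshold_config or DEFAULT_RECOVERY_THRESHOLD
    import warnings

    within = 0
    violations: list[dict] = []
    for r in range(n_replicates):
        rep_seed = (seed * 100003 + r) % (2**31 - 1)
        matrix, _, _ = generate_emap(unstructured_config(seed=rep_seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            network = build_network(matrix, threshold_config)
        degenerate = len(network.nodes) < 3 or max(
            len(network.edges_of_sign(s)) for s in "NP"
        ) < 2
        if degenerate:
            within += 1
            continue
        summary = motif_enrichment(network, n_random=n_random, q=q, seed=rep_seed)
        ok = all(
            (summary.z_defined[c] and abs(summary.z[c]) <= z_bound)
            or (not summary.z_defined[c] and summary.observed[c] == summary.mean[c])
            for c in summary.z
        )
        within += ok
        if not ok:
            violations.append(
                {"replicate": r, "observed": dict(summary.observed),
                 "z": dict(summary.z)}
            )
    return {
        "n_replicates": n_replicates,
        "n_within": within,
        "fraction_within": within / n_replicates,
        "z_bound": z_bound,
        "violations": violations,
    }


def recovery_experiment(
    config: SyntheticConfig | None = None,
    threshold_config: ThresholdConfig | None = None,
    n_random: int = 500,
    q: int = 50,
    seed: int = 0,
) -> dict:
    """Full-pipeline recovery of planted structure.

    Generates a matrix, builds the signed network, enumerates triplets,
    computes null-model z-scores per motif class, and checks that the
    planted regulators are recovered at the NPP positive node and that
    the planted regulator term tops the positional enrichment.
    """
    config = config or SyntheticConfig(seed=seed)
    threshold_config = threshold_config or DEFAULT_RECOVERY_THRESHOLD
    matrix, truth, annotation = generate_emap(config)
    network = build_network(matrix, threshold_config)
    census = enumerate_triplets(network)
    summary = motif_enrichment(network, n_random=n_random, q=q, seed=seed)

    npp_nodes = {t.shared_node("P") for t in census.of_class("NPP")}
    planted_regs = set(truth.regulators)
    recovered = (
        len(npp_nodes & planted_regs) / len(planted_regs) if planted_regs else float("nan")
    )
    table = position_gene_enrichment(
        census, annotation, "NPP", "positive_node", "go_function", network.nodes
    )
    if len(table) and REGULATOR_TERM in set(table["term"]):
        reg_rank = int(table.index[table["term"] == REGULATOR_TERM][0]) + 1
    else:
        reg_rank = 0  # term absent from the enrichment table
    return {
        "config": config,
        "network_genes": len(network.nodes),
        "network_edges": len(network.edges),
        "census_counts": dict(census.counts),
        "null_summary": summary,
        "z_scores": dict(summary.z),
        "regulator_recovery_fraction": recovered,
        "regulator_term_rank": reg_rank,
        "enrichment_table": table,
    }
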