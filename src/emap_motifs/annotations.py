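"""Functional annotation channels and pair-sharing predicates.

Nine annotation channels are supported, split into two families:

* term channels (gene → term set): protein complex membership, pathway
  membership, knockout phenotype, GO function, GO process, GO location;
* pair channels (sets of unordered gene pairs): physical interaction,
  curated genetic interaction, sequence homology.

Two genes "share" a term channel when their term sets intersect, and a
pair channel when the pair is in the relation. Channel-specific filters
mirror common curation practice: genetic interactions are restricted to
manually curated synthetic-lethal / synthetic-growth-defect entries, GO
annotations are propagated to ancestor terms and then restricted to
terms of intermediate frequency (2-40 genes of the analysis universe),
and the uninformative phenotype 'viable' is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from emap_motifs.emap_io import Pair, canonical_pair

logger = logging.getLogger(__name__)

TERM_CHANNELS = ("complex", "pathway", "phenotype", "go_function", "go_process", "go_location")
PAIR_CHANNELS = ("physical_interaction", "genetic_interaction", "homology")
ALL_CHANNELS = TERM_CHANNELS + PAIR_CHANNELS

#: Default curation filter for genetic-interaction tables.
DEFAULT_CURATION = frozenset({"Manual curation"})
#: Default interaction-type filter.
DEFAULT_GI_TYPES = frozenset({"Synthetic Lethality", "Synthetic growth defect"})

GO_MIN_FREQ = 2
GO_MAX_FREQ = 40


@dataclass
class AnnotationSet:
    """All loaded annotation channels for one analysis."""

    gene_terms: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    pair_relations: dict[str, set[Pair]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for channel, mapping in self.gene_terms.items():
            for gene, terms in mapping.items():
                if "" in terms:
                    raise ValueError(f"empty term for gene {gene!r} in {channel}")
        for channel, pairs in self.pair_relations.items():
            for a, b in pairs:
                if a == b:
                    raise ValueError(f"self-pair in {channel}: {a!r}")

    def channels(self) -> list[str]:
        return list(self.gene_terms) + list(self.pair_relations)


def load_gene_terms(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """Load a two-column ``gene<TAB>term`` file into a gene → term-set map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            gene, term = parts[0].strip(), parts[1].strip()
            if not term:
                continue
            out.setdefault(gene, set()).add(term)
    return out


def load_pair_list(path: str | Path, sep: str = "\t") -> set[Pair]:
    """Load a two-column gene-pair file as a set of canonical pairs."""
    pairs: set[Pair] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                continue
            pairs.add(canonical_pair(a, b))
    return pairs


def load_genetic_interactions(
    path: str | Path,
    curation_filter: Iterable[str] = DEFAULT_CURATION,
    type_filter: Iterable[str] = DEFAULT_GI_TYPES,
) -> set[Pair]:
    """Load a curated genetic-interaction table as a deduplicated pair set.

    The TSV must carry columns ``gene_a, gene_b, curation,
    interaction_type``; only rows whose curation and type both pass the
    filters are kept, as unordered pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "curation", "interaction_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genetic-interaction file missing columns: {sorted(missing)}")
    curation_filter = set(curation_filter)
    type_filter = set(type_filter)
    keep = df["curation"].isin(curation_filter) & df["interaction_type"].isin(type_filter)
    pairs: set[Pair] = set()
    for row in df[keep].itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        pairs.add(canonical_pair(str(row.gene_a), str(row.gene_b)))
    return pairs


def load_parent_map(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """Load a ``child<TAB>parent`` edge list of the term DAG."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            child, parent = parts[0].strip(), parts[1].strip()
            parents.setdefault(child, set()).add(parent)
    return parents


def parent_map_from_obo(path: str | Path) -> dict[str, set[str]]:
    """Extract an is_a child → parents map from an OBO ontology file."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return parents


def _ancestors(term: str, parent_map: Mapping[str, set[str]],
               cache: dict[str, set[str]], stack: list[str]) -> set[str]:
    if term in cache:
        return cache[term]
    if term in stack:
        cycle = stack[stack.index(term):] + [term]
        raise ValueError(f"cycle in parent map involving {term!r}: {' -> '.join(cycle)}")
    stack.append(term)
    anc: set[str] = set()
    for parent in parent_map.get(term, ()):  # roots have no entry
        anc.add(parent)
        anc |= _ancestors(parent, parent_map, cache, stack)
    stack.pop()
    cache[term] = anc
    return anc


def go_ancestor_closure(
    gene_terms: Mapping[str, set[str]],
    parent_map: Mapping[str, set[str]],
    universe: Iterable[str],
    min_freq: int = GO_MIN_FREQ,
    max_freq: int = GO_MAX_FREQ,
) -> dict[str, set[str]]:
    """Propagate terms to ancestors, then frequency-filter.

    Each gene's term set is replaced by its closure under the parent
    relation; afterwards any term annotating fewer than ``min_freq`` or
    more than ``max_freq`` genes of ``universe`` (bounds inclusive) is
    removed from every gene. Applying the operation twice gives the same
    result as applying it once.
    """
    cache: dict[str, set[str]] = {}
    closed: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        full: set[str] = set()
        for t in terms:
            full.add(t)
            full |= _ancestors(t, parent_map, cache, [])
        closed[gene] = full

    universe = set(universe)
    freq: dict[str, int] = {}
    for gene in universe:
        for t in closed.get(gene, ()):  # only universe genes count
            freq[t] = freq.get(t, 0) + 1
    keep = {t for t, k in freq.items() if min_freq <= k <= max_freq}
    return {gene: terms & keep for gene, terms in closed.items()}


def clean_phenotypes(gene_terms: Mapping[str, set[str]], drop: str = "viable") -> dict[str, set[str]]:
    """Remove the uninformative phenotype term from every gene."""
    return {gene: {t for t in terms if t != drop} for gene, terms in gene_terms.items()}


def pair_shares(annotation: AnnotationSet, channel: str, pair: Pair) -> bool:
    """Whether the two genes of *pair* share the feature of *channel*.

    Symmetric in the pair. Term channels match when the genes' term sets
    intersect; pair channels when the pair is in the relation.
    """
    a, b = pair
    key = canonical_pair(a, b)
    if channel in annotation.gene_terms:
        terms = annotation.gene_terms[channel]
        return bool(terms.get(key[0], set()) & terms.get(key[1], set()))
    if channel in annotation.pair_relations:
        return key in annotation.pair_relations[channel]
    raise KeyError(f"unknown annotation channel {channel!r}")
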