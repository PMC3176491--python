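"""Reading, merging and writing E-MAP S-score matrices.

An E-MAP (epistasis map) reports a quantitative S-score for each tested
gene pair: the deviation of the observed double-mutant colony size from
the neutral expectation. Scores are symmetric in the pair and most pairs
are untested, so the in-memory container is a partial symmetric map from
unordered gene pairs to scores rather than a dense array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

#: Strings accepted as "missing" in matrix cells, besides the empty cell.
DEFAULT_NA_VALUES = ("", "NA", "NaN", "nan", "N/A")


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class MatrixDialect:
    """Descriptor for the on-disk matrix TSV layout."""

    sep: str = "\t"
    na_values: tuple[str, ...] = DEFAULT_NA_VALUES


@dataclass
class ScoreMatrix:
    """Partial symmetric map from unordered gene pairs to S-scores.

    Parameters
    ----------
    genes
        Ordered list of unique gene identifiers.
    scores
        Map from canonical unordered pair to S-score. Scores are
        dimensionless colony-size deviation scores; negative values mark
        synthetic-sick/lethal-like epistasis, positive values suppression.
    n_sources
        Map from pair to the number of source datasets that contributed
        to the (averaged) stored score.
    """

    genes: list[str]
    scores: dict[Pair, float]
    n_sources: dict[Pair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if not self.n_sources:
            self.n_sources = {p: 1 for p in self.scores}
        gene_set = set(self.genes)
        for a, b in self.scores:
            if a >= b:
                raise ValueError(f"pair ({a!r}, {b!r}) is not in canonical order")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"pair ({a!r}, {b!r}) references unknown gene")
        for p, k in self.n_sources.items():
            if k < 1:
                raise ValueError(f"n_sources < 1 for pair {p}")

    @property
    def n_pairs(self) -> int:
        return len(self.scores)

    def missing_fraction(self) -> float:
        """Fraction of possible unordered pairs with no stored score."""
        total = comb(len(self.genes), 2)
        if total == 0:
            return 0.0
        return 1.0 - len(self.scores) / total

    def partners(self, gene: str) -> dict[str, float]:
        """All genes scored against *gene*, with their S-scores."""
        out: dict[str, float] = {}
        for (a, b), s in self.scores.items():
            if a == gene:
                out[b] = s
            elif b == gene:
                out[a] = s
        return out


def read_matrix(path: str | Path, dialect: MatrixDialect | None = None) -> ScoreMatrix:
    """Read a gene×gene S-score TSV into a :class:`ScoreMatrix`.

    The file must be rectangular, with gene labels on the first row and
    first column and empty cells denoting missing scores. Self-cells
    (diagonal) are ignored. If both orientations of a pair are present
    with different values their mean is stored and the event is logged.

    Raises
    ------
    ValueError
        On duplicate gene labels, or on a non-numeric non-empty cell
        (the error names the offending row and column).
    """
    dialect = dialect or MatrixDialect()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(dialect.sep)[1:]
    # pandas de-duplicates repeated column labels silently; check first
    dupes = {lab for lab in header if header.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate column gene label {sorted(dupes)[0]!r}")
    df = pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=list(dialect.na_values),
        keep_default_na=False,
        dtype=str,
    )
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    for labels, axis in ((row_labels, "row"), (col_labels, "column")):
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"duplicate {axis} gene label {lab!r}")
            seen.add(lab)

    genes: list[str] = []
    seen_genes: set[str] = set()
    for lab in row_labels + col_labels:
        if lab not in seen_genes:
            genes.append(lab)
            seen_genes.add(lab)

    cells: dict[Pair, list[float]] = {}
    values = df.to_numpy()
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            raw = values[i, j]
            if raw is None or (isinstance(raw, float) and pd.isna(raw)):
                continue
            text = str(raw).strip()
            if text in dialect.na_values:
                continue
            try:
                score = float(text)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {r!r}, column {c!r}: {text!r}"
                ) from None
            if r == c:
                continue
            cells.setdefault(canonical_pair(r, c), []).append(score)

    scores: dict[Pair, float] = {}
    for pair, vals in cells.items():
        if len(vals) > 1 and len(set(vals)) > 1:
            logger.info(
                "asymmetric duplicate cell for pair %s: %s averaged", pair, vals
            )
        scores[pair] = sum(vals) / len(vals)
    return ScoreMatrix(genes=genes, scores=scores, n_sources={p: 1 for p in scores})


def merge_matrices(matrices: Sequence[ScoreMatrix]) -> ScoreMatrix:
    """Merge several score matrices by averaging shared pairs.

    The merged gene list is the union (first-seen order); each pair's
    score is the arithmetic mean over the matrices in which it is
    non-missing, and ``n_sources`` records that count.
    """
    if not matrices:
        raise ValueError("merge_matrices requires at least one matrix")
    genes: list[str] = []
    seen: set[str] = set()
    sums: dict[Pair, float] = {}
    counts: dict[Pair, int] = {}
    for m in matrices:
        for g in m.genes:
            if g not in seen:
                genes.append(g)
                seen.add(g)
        for pair, s in m.scores.items():
            sums[pair] = sums.get(pair, 0.0) + s
            counts[pair] = counts.get(pair, 0) + 1
    scores = {p: sums[p] / counts[p] for p in sums}
    return ScoreMatrix(genes=genes, scores=scores, n_sources=counts)


def write_matrix(matrix: ScoreMatrix, path: str | Path, dialect: MatrixDialect | None = None) -> None:
    """Write a square gene×gene TSV (empty cells for missing pairs)."""
    dialect = dialect or MatrixDialect()
    genes = matrix.genes
    df = pd.DataFrame("", index=genes, columns=genes, dtype=object)
    for (a, b), s in matrix.scores.items():
        df.loc[a, b] = repr(s)
        df.loc[b, a] = repr(s)
    df.to_csv(path, sep=dialect.sep)


def write_edge_table(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write the canonical long-form TSV ``gene_a gene_b score n_sources``."""
    rows = [
        {"gene_a": a, "gene_b": b, "score": matrix.scores[(a, b)],
         "n_sources": matrix.n_sources.get((a, b), 1)}
        for (a, b) in sorted(matrix.scores)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "n_sources"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_table(path: str | Path) -> ScoreMatrix:
    """Read a long-form pair table back into a :class:`ScoreMatrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    scores: dict[Pair, float] = {}
    n_sources: dict[Pair, int] = {}
    genes: list[str] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        pair = canonical_pair(row.gene_a, row.gene_b)
        scores[pair] = float(row.score)
        n_sources[pair] = int(getattr(row, "n_sources", 1))
        for g in pair:
            if g not in seen:
                genes.append(g)
                seen.add(g)
    return ScoreMatrix(genes=genes, scores=scores, n_sources=n_sources)
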