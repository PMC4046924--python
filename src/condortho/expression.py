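"""Gene-level expression from transcript abundances, and cross-species
comparison through an intermediary reference.

Transcript-level abundance estimates are summed over all assembled
variants assigned to the same reference gene, normalized between samples
with DESeq's median-of-ratios size factors, and validated by Spearman
rank concordance against an independent quantification. Two species
without reference genomes are compared by mapping each of their gene sets
onto a shared, well-annotated intermediary genome and intersecting at the
intermediary-gene level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import HomologyMap

__all__ = [
    "AggregationResult",
    "aggregate_to_reference_genes",
    "median_ratio_size_factors",
    "spearman_concordance",
    "CrossSpeciesLink",
    "link_via_intermediary",
    "DirectionalOverlap",
    "directional_overlap",
    "ASCENDING",
    "DESCENDING",
]

ASCENDING = "ascending"
DESCENDING = "descending"


@dataclass
class AggregationResult:
    """Gene-level abundance table plus what was left behind."""

    table: pd.DataFrame  # genes x samples
    dropped_features: pd.Index  # abundance features absent from the map

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_features)


def aggregate_to_reference_genes(
    abundance: pd.DataFrame,
    hmap: Union[HomologyMap, Mapping[str, str]],
) -> AggregationResult:
    """Sum transcript abundances over all variants assigned to each
    reference gene, per sample.

    Abundance features absent from the homology map are dropped and
    reported in ``dropped_features``. Genes with no assigned transcript in
    the table are absent from the output.
    """
    gene_of = hmap.gene_map() if isinstance(hmap, HomologyMap) else dict(hmap)
    mapped = abundance.index.intersection(list(gene_of))
    dropped = abundance.index.difference(mapped)
    if len(mapped) == 0:
        empty = pd.DataFrame(
            np.empty((0, abundance.shape[1])), columns=abundance.columns
        )
        return AggregationResult(table=empty, dropped_features=dropped)
    genes = pd.Series({t: gene_of[t] for t in mapped}, name="gene")
    table = abundance.loc[mapped].groupby(genes).sum()
    table = table.sort_index()
    table.index.name = "gene_id"
    return AggregationResult(table=table, dropped_features=dropped)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    For each gene with strictly positive counts in every sample, compute
    the ratio of its count in a sample to its geometric mean across
    samples; the sample's factor is the median of those ratios. Genes
    with any zero are excluded from the median (no pseudo-count).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError("empty count table")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has all-positive counts across samples; median-of-ratios "
            "is undefined (consider adding a pseudo-count upstream)"
        )
    lg = np.log(counts.loc[positive].to_numpy(dtype=float))
    log_geomean = lg.mean(axis=1, keepdims=True)
    # median taken on the ratio scale (ties with an even gene count are
    # averaged arithmetically, matching the reference estimator)
    factors = np.median(np.exp(lg - log_geomean), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def spearman_concordance(
    x: pd.Series, y: pd.Series
) -> tuple[float, int]:
    """Spearman rank correlation (average ranks for ties) over the
    intersection of feature ids. Returns (rho, intersection size).

    Fewer than 3 shared features is an error.
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared features; need at least 3"
        )
    rho = stats.spearmanr(x.loc[shared], y.loc[shared]).statistic
    return float(rho), len(shared)


@dataclass
class CrossSpeciesLink:
    """All (geneA, geneB, intermediary) triples where both species' genes
    map to the same intermediary reference gene. Many-to-many across the
    two species."""

    triples: list[tuple[str, str, str]]

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.triples]

    def by_intermediary(self) -> dict[str, tuple[list[str], list[str]]]:
        """intermediary id -> (linked A genes, linked B genes)."""
        out: dict[str, tuple[list[str], list[str]]] = {}
        for a, b, i in self.triples:
            ga, gb = out.setdefault(i, ([], []))
            if a not in ga:
                ga.append(a)
            if b not in gb:
                gb.append(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.triples, columns=["gene_a", "gene_b", "intermediary_id"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CrossSpeciesLink":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([tuple(r) for r in df.itertuples(index=False)])


def link_via_intermediary(
    map_a: Mapping[str, str], map_b: Mapping[str, str]
) -> CrossSpeciesLink:
    """Link two species' genes through a shared intermediary gene space:
    every (a, b, i) with map_a[a] = map_b[b] = i."""
    by_inter_b: dict[str, list[str]] = {}
    for b, i in map_b.items():
        by_inter_b.setdefault(i, []).append(b)
    triples = [
        (a, b, i)
        for a, i in map_a.items()
        if i in by_inter_b
        for b in by_inter_b[i]
    ]
    triples.sort()
    return CrossSpeciesLink(triples)


@dataclass(frozen=True)
class DirectionalOverlap:
    """Counts of intermediary genes whose expression direction is shared
    (or contradictory) between the two species."""

    ascending_shared: int
    descending_shared: int
    discordant: int


def directional_overlap(
    class_a: Mapping[str, str],
    class_b: Mapping[str, str],
    link: CrossSpeciesLink,
) -> DirectionalOverlap:
    """Directional overlap counted at the intermediary-gene level with
    any-link semantics.

    An intermediary gene counts as ascending_shared if at least one linked
    A-gene and at least one linked B-gene are ascending (analogously
    descending; one intermediary can count in both). It is discordant when
    both species have classified linked genes but only in opposite
    directions. Genes without a direction contribute nothing.
    """
    valid = {ASCENDING, DESCENDING}
    asc = desc = disc = 0
    for inter, (genes_a, genes_b) in link.by_intermediary().items():
        dirs_a = {class_a[g] for g in genes_a if class_a.get(g) in valid}
        dirs_b = {class_b[g] for g in genes_b if class_b.get(g) in valid}
        shared = False
        if ASCENDING in dirs_a and ASCENDING in dirs_b:
            asc += 1
            shared = True
        if DESCENDING in dirs_a and DESCENDING in dirs_b:
            desc += 1
            shared = True
        if not shared and dirs_a and dirs_b:
            disc += 1
    return DirectionalOverlap(asc, desc, disc)
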