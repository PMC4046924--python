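"""Supervised classification of expression profiles over an ordered
developmental gradient into behaviourally discrete groups.

A gene's behaviour is the set of ordered stage pairs (i, j), i < j, whose
expression change is statistically significant, together with a common
direction. Because significance over a sub-interval of stages implies a
real change over every enclosing interval, valid behaviours are the
non-empty, *containment-closed* sets of stage-pair intervals: if (i, j)
is in the set, so is every (k, l) with k <= i and l >= j. For four stages
there are exactly 13 such sets, hence 13 ascending and 13 descending
behaviour groups. Unlike k-means-style clustering, membership is defined
purely by which pairwise comparisons are significant, never by expression
level.

The catalogue for any number of stages is enumerated through the
antichains of the interval-containment order (each closed set is the
upward closure of its minimal intervals), which also fixes a canonical
ordering and stable pattern ids (A01..A13 / D01..D13 for four stages).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .expression import ASCENDING, DESCENDING, median_ratio_size_factors

__all__ = [
    "UNCLASSIFIED",
    "INCONSISTENT",
    "BehaviorPattern",
    "StageProfile",
    "PatternCatalogue",
    "enumerate_behavior_patterns",
    "containment_closure",
    "bh_adjust",
    "pairwise_de_pvalues",
    "profiles_from_counts",
    "classify_gene_profile",
    "classify_profiles",
    "ClassificationResult",
]

UNCLASSIFIED = "unclassified"
INCONSISTENT = "inconsistent"

Interval = tuple[int, int]


@dataclass(frozen=True)
class BehaviorPattern:
    """One behaviour group: a direction plus a containment-closed set of
    significant stage-pair intervals."""

    pattern_id: str
    direction: str  # ascending | descending
    intervals: frozenset[Interval]

    @property
    def minimal_intervals(self) -> frozenset[Interval]:
        """The containment-minimal intervals (the generating antichain)."""
        return frozenset(
            iv
            for iv in self.intervals
            if not any(
                o != iv and o[0] >= iv[0] and o[1] <= iv[1] for o in self.intervals
            )
        )


def _all_intervals(n_stages: int) -> list[Interval]:
    return [
        (i, j)
        for i in range(1, n_stages)
        for j in range(i + 1, n_stages + 1)
    ]


def containment_closure(
    intervals: Iterable[Interval], n_stages: int
) -> frozenset[Interval]:
    """Upward closure: add every interval that contains one of the inputs."""
    return frozenset(
        (k, l)
        for (i, j) in intervals
        for k in range(1, i + 1)
        for l in range(j, n_stages + 1)
    )


def _antichains(intervals: Sequence[Interval]) -> list[frozenset[Interval]]:
    """All non-empty antichains of the interval-containment order."""

    def contains(a: Interval, b: Interval) -> bool:
        return a[0] <= b[0] and a[1] >= b[1]

    found: list[frozenset[Interval]] = []

    def extend(start: int, chosen: list[Interval]) -> None:
        if chosen:
            found.append(frozenset(chosen))
        for k in range(start, len(intervals)):
            iv = intervals[k]
            if all(not contains(iv, o) and not contains(o, iv) for o in chosen):
                chosen.append(iv)
                extend(k + 1, chosen)
                chosen.pop()

    extend(0, [])
    return found


def enumerate_behavior_patterns(n_stages: int) -> list[BehaviorPattern]:
    """The full behaviour catalogue for ``n_stages`` ordered stages: every
    non-empty containment-closed interval set, in both directions.

    Closed sets are generated as upward closures of antichains (a
    bijection), ordered canonically by earliest minimal interval
    (lexicographic), then closed-set size, then the sorted interval list.
    Ids are ``A``/``D`` plus a zero-padded rank.
    """
    if n_stages < 2:
        raise ValidationError(f"need at least 2 stages, got {n_stages}")
    ivs = _all_intervals(n_stages)
    closed = {
        containment_closure(ac, n_stages): ac for ac in _antichains(ivs)
    }
    ordered = sorted(
        closed.items(),
        key=lambda kv: (min(kv[1]), len(kv[0]), sorted(kv[0])),
    )
    width = len(str(len(ordered)))
    patterns: list[BehaviorPattern] = []
    for direction, prefix in ((ASCENDING, "A"), (DESCENDING, "D")):
        for rank, (cset, _) in enumerate(ordered, start=1):
            patterns.append(
                BehaviorPattern(f"{prefix}{rank:0{width}d}", direction, cset)
            )
    return patterns


class PatternCatalogue:
    """Indexed behaviour catalogue for a fixed number of stages."""

    def __init__(self, n_stages: int):
        self.n_stages = n_stages
        self.patterns = enumerate_behavior_patterns(n_stages)
        self._by_key = {
            (p.direction, p.intervals): p for p in self.patterns
        }
        self._by_id = {p.pattern_id: p for p in self.patterns}

    def lookup(
        self, direction: str, intervals: frozenset[Interval]
    ) -> BehaviorPattern | None:
        return self._by_key.get((direction, intervals))

    def __getitem__(self, pattern_id: str) -> BehaviorPattern:
        return self._by_id[pattern_id]

    def __contains__(self, pattern_id: str) -> bool:
        return pattern_id in self._by_id

    def __len__(self) -> int:
        return len(self.patterns)

    def direction_of(self, pattern_id: str) -> str:
        return self._by_id[pattern_id].direction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    p.pattern_id,
                    p.direction,
                    ";".join(f"{i}-{j}" for i, j in sorted(p.intervals)),
                )
                for p in self.patterns
            ],
            columns=["pattern_id", "direction", "intervals"],
        )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(k) = min_{m >= k} (p_(m) * n / m), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StageProfile:
    """Per-gene classification input: ordered stage means (normalized,
    replicate-averaged) and a BH-adjusted p-value per ordered stage pair."""

    gene_id: str
    stage_means: np.ndarray
    pair_pvalues: dict[Interval, float]

    @property
    def n_stages(self) -> int:
        return len(self.stage_means)

    def pair_direction(self, pair: Interval) -> int:
        i, j = pair
        return int(np.sign(self.stage_means[j - 1] - self.stage_means[i - 1]))


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample p-values with a deterministic convention
    for degenerate rows: when both groups have zero variance the p-value
    is 1 for equal means and 0 otherwise."""
    with warnings.catch_warnings():
        # near-identical rows trigger a scipy precision warning; the
        # degenerate-row convention below handles them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        diff = a.mean(axis=1) - b.mean(axis=1)
        p[degenerate] = np.where(np.isclose(diff[degenerate], 0.0), 1.0, 0.0)
    return p


def pairwise_de_pvalues(
    counts: pd.DataFrame,
    stages: Sequence[str],
    size_factors: pd.Series | None = None,
    stage_order: Sequence[str] | None = None,
) -> tuple[dict[Interval, pd.Series], pd.DataFrame]:
    """Per-gene adjusted p-values for every ordered stage pair.

    ``stages`` gives the stage label of each sample (column), in column
    order; ``stage_order`` fixes the developmental ordering (default:
    order of first appearance). Counts are normalized by median-of-ratios
    size factors (computed here unless supplied), a Welch two-sample test
    is applied to log2(normalized count + 1) per gene per stage pair, and
    p-values are BH-adjusted within each pair's family across genes.

    This is deliberately generic plumbing: studies with a dedicated count
    model (e.g. a negative-binomial test) should supply their own adjusted
    p-values to :func:`classify_profiles` instead.

    Returns (pair -> Series of adjusted p-values, stage-mean table of
    normalized replicate-averaged values, genes x stages).
    """
    if len(stages) != counts.shape[1]:
        raise ValidationError(
            f"{len(stages)} stage labels for {counts.shape[1]} samples"
        )
    order = list(dict.fromkeys(stages)) if stage_order is None else list(stage_order)
    cols_by_stage = {
        s: [c for c, lab in zip(counts.columns, stages) if lab == s] for s in order
    }
    for s, cols in cols_by_stage.items():
        if len(cols) < 2:
            raise ValidationError(
                f"stage {s!r} has {len(cols)} replicate(s); need at least 2"
            )
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    norm = counts / size_factors
    logn = np.log2(norm + 1.0)

    stage_means = pd.DataFrame(
        {s: norm[cols_by_stage[s]].mean(axis=1) for s in order}
    )
    pvals: dict[Interval, pd.Series] = {}
    for i, j in _all_intervals(len(order)):
        a = logn[cols_by_stage[order[i - 1]]].to_numpy()
        b = logn[cols_by_stage[order[j - 1]]].to_numpy()
        raw = _welch_pvalues(a, b)
        pvals[(i, j)] = pd.Series(bh_adjust(raw), index=counts.index)
    return pvals, stage_means


def profiles_from_counts(
    counts: pd.DataFrame,
    stages: Sequence[str],
    size_factors: pd.Series | None = None,
    stage_order: Sequence[str] | None = None,
) -> list[StageProfile]:
    """Build one :class:`StageProfile` per gene from a replicated count
    matrix (see :func:`pairwise_de_pvalues` for the testing convention)."""
    pvals, stage_means = pairwise_de_pvalues(
        counts, stages, size_factors=size_factors, stage_order=stage_order
    )
    profiles = []
    means = stage_means.to_numpy()
    for row, gene in enumerate(counts.index):
        profiles.append(
            StageProfile(
                gene_id=str(gene),
                stage_means=means[row],
                pair_pvalues={pair: float(s.iloc[row]) for pair, s in pvals.items()},
            )
        )
    return profiles


def classify_gene_profile(
    profile: StageProfile,
    alpha: float = 0.05,
    mode: str = "strict",
    catalogue: PatternCatalogue | None = None,
) -> str:
    """Assign one gene to a behaviour pattern.

    The significant set S holds the pairs with adjusted p < alpha. An
    empty S is ``unclassified``. Mixed directions among significant pairs
    (or an exact tie on a significant pair) is ``inconsistent``. In
    ``strict`` mode the gene is classified only if S is itself
    containment-closed (otherwise ``inconsistent``); in ``closure`` mode
    S is replaced by its containment closure first.
    """
    if mode not in ("strict", "closure"):
        raise ValidationError(f"mode must be 'strict' or 'closure', got {mode!r}")
    n = profile.n_stages
    if catalogue is None:
        catalogue = PatternCatalogue(n)
    elif catalogue.n_stages != n:
        raise ValidationError(
            f"catalogue is for {catalogue.n_stages} stages, profile has {n}"
        )
    sig = frozenset(
        pair for pair, p in profile.pair_pvalues.items() if p < alpha
    )
    if not sig:
        return UNCLASSIFIED
    signs = {profile.pair_direction(pair) for pair in sig}
    if len(signs) != 1 or 0 in signs:
        return INCONSISTENT
    direction = ASCENDING if signs == {1} else DESCENDING
    if mode == "strict":
        pattern = catalogue.lookup(direction, sig)
        return pattern.pattern_id if pattern is not None else INCONSISTENT
    closed = containment_closure(sig, n)
    pattern = catalogue.lookup(direction, closed)
    assert pattern is not None, "closure of a non-empty set must be in the catalogue"
    return pattern.pattern_id


@dataclass
class ClassificationResult:
    """Gene -> label map plus per-pattern gene counts. Labels are pattern
    ids or the ``unclassified`` / ``inconsistent`` sentinels."""

    assignments: dict[str, str]
    counts: Counter
    catalogue: PatternCatalogue

    @property
    def n_classified(self) -> int:
        return sum(v for k, v in self.counts.items() if k in self.catalogue)

    def directions(self) -> dict[str, str]:
        """gene -> ascending/descending, classified genes only."""
        return {
            g: self.catalogue.direction_of(label)
            for g, label in self.assignments.items()
            if label in self.catalogue
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                g,
                label,
                self.catalogue.direction_of(label) if label in self.catalogue else "",
            )
            for g, label in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "pattern_id", "direction"])


def classify_profiles(
    profiles: Sequence[StageProfile],
    alpha: float = 0.05,
    mode: str = "strict",
    catalogue: PatternCatalogue | None = None,
) -> ClassificationResult:
    """Classify every gene; counts partition the classified genes (each
    classified gene lands in exactly one pattern)."""
    if catalogue is None:
        if not profiles:
            raise ValidationError("no profiles to classify")
        catalogue = PatternCatalogue(profiles[0].n_stages)
    assignments = {
        p.gene_id: classify_gene_profile(p, alpha=alpha, mode=mode, catalogue=catalogue)
        for p in profiles
    }
    return ClassificationResult(
        assignments=assignments,
        counts=Counter(assignments.values()),
        catalogue=catalogue,
    )
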