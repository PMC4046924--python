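"""Monte Carlo co-occupancy enrichment test.

Given behaviour classifications for two species linked gene-by-gene
through an intermediary reference, the test asks whether the number of
transcription-factor homologue pairs that share behaviour groups with a
focal gene set (e.g. the genes of the C4 photosynthetic cycle) in *both*
species is larger than chance. The null distribution is built by
repeatedly drawing focal-sized sets of linked gene pairs from the
classified universe and recomputing the same statistic; the empirical
p-value uses the (r + 1) / (N + 1) plug-in estimator, which can never be
exactly zero at finite N.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .profiles import INCONSISTENT, UNCLASSIFIED

__all__ = [
    "EnrichmentResult",
    "occupied_behaviors",
    "monte_carlo_cooccupancy_test",
]

Pair = tuple[str, str]

_NON_PATTERNS = {UNCLASSIFIED, INCONSISTENT, None, ""}


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one co-occupancy test; fully determined by the inputs
    and the seed."""

    observed: int
    n_iter: int
    n_ge: int  # simulated values >= observed
    p_empirical: float  # (n_ge + 1) / (n_iter + 1)
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def occupied_behaviors(
    genes: Iterable[str], assignment: Mapping[str, str]
) -> set[str]:
    """The set of behaviour pattern ids occupied by the classified members
    of a gene set; unclassified or inconsistent genes contribute nothing."""
    return {
        assignment[g]
        for g in genes
        if assignment.get(g) not in _NON_PATTERNS
    }


def _pattern_codes(
    pairs: Sequence[Pair],
    assign_a: Mapping[str, str],
    assign_b: Mapping[str, str],
    code_of: dict[str, int],
    sentinel: int,
) -> tuple[np.ndarray, np.ndarray]:
    def code(assignment: Mapping[str, str], gene: str) -> int:
        label = assignment.get(gene)
        return sentinel if label in _NON_PATTERNS else code_of[label]

    a = np.array([code(assign_a, pa) for pa, _ in pairs], dtype=np.intp)
    b = np.array([code(assign_b, pb) for _, pb in pairs], dtype=np.intp)
    return a, b


def monte_carlo_cooccupancy_test(
    focal_pairs: Iterable[Pair],
    tf_pairs: Iterable[Pair],
    assign_a: Mapping[str, str],
    assign_b: Mapping[str, str],
    universe: Iterable[Pair],
    n_select: int | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte Carlo test of transcription-factor co-occupancy with a focal
    gene set in both species.

    The statistic is the number of TF pairs (tfA, tfB) whose behaviour in
    species A lies in the behaviours occupied by the focal genes in A
    *and* whose behaviour in B lies in the focal behaviours in B. Each
    null iteration draws ``n_select`` pairs (default: the focal set size)
    from ``universe`` without replacement and recomputes the statistic.

    All inputs are sorted internally, so the result is reproducible from
    the seed regardless of set iteration order.
    """
    focal = sorted(set(focal_pairs))
    tfs = sorted(set(tf_pairs))
    univ = sorted(set(universe))
    if not univ:
        raise ValidationError("empty sampling universe")
    missing = [p for p in focal if p not in set(univ)]
    if missing:
        raise ValidationError(
            f"{len(missing)} focal pair(s) not in the sampling universe"
        )
    if n_select is None:
        n_select = len(focal)
    if n_select > len(univ):
        raise ValidationError(
            f"n_select={n_select} exceeds universe size {len(univ)}"
        )
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")

    pattern_ids = sorted(
        {v for v in assign_a.values() if v not in _NON_PATTERNS}
        | {v for v in assign_b.values() if v not in _NON_PATTERNS}
    )
    code_of = {pid: k for k, pid in enumerate(pattern_ids)}
    sentinel = len(pattern_ids)  # occupancy slot that is forced False

    tf_a, tf_b = _pattern_codes(tfs, assign_a, assign_b, code_of, sentinel)
    univ_a, univ_b = _pattern_codes(univ, assign_a, assign_b, code_of, sentinel)

    occ_a = np.zeros(sentinel + 1, dtype=bool)
    occ_b = np.zeros(sentinel + 1, dtype=bool)

    def statistic(idx_a: np.ndarray, idx_b: np.ndarray) -> int:
        occ_a.fill(False)
        occ_b.fill(False)
        occ_a[idx_a] = True
        occ_b[idx_b] = True
        occ_a[sentinel] = False
        occ_b[sentinel] = False
        return int(np.count_nonzero(occ_a[tf_a] & occ_b[tf_b]))

    focal_a, focal_b = _pattern_codes(focal, assign_a, assign_b, code_of, sentinel)
    observed = statistic(focal_a, focal_b)

    rng = np.random.default_rng(seed)
    n_univ = len(univ)
    n_ge = 0
    for _ in range(n_iter):
        idx = rng.choice(n_univ, size=n_select, replace=False)
        if statistic(univ_a[idx], univ_b[idx]) >= observed:
            n_ge += 1
    return EnrichmentResult(
        observed=observed,
        n_iter=n_iter,
        n_ge=n_ge,
        p_empirical=(n_ge + 1) / (n_iter + 1),
        seed=seed,
    )
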