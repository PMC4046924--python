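"""Self-training, length-conditioned orthology assignment.

The method targets de novo assembled transcriptomes, where one gene locus
is typically represented by several assembled transcript variants of
varying length and completeness. It proceeds in four steps:

1. **Reciprocal best BLAST (RBB).** From mutual similarity searches
   (transcripts vs reference genes, and the reverse), keep the pairs that
   are each other's best hit. These are high-confidence homologue anchors
   and serve as self-training data.
2. **Length binning.** RBB pairs are grouped into equal-count bins on
   assembled transcript length; per bin, a nearest-rank percentile of the
   RBB e-value distribution is recorded (on the log10 scale, with exact
   zeros floored).
3. **Curve fit.** An ordinary least-squares quadratic is fit through the
   per-bin percentile points in (length, log10 e-value) space, giving a
   length-conditioned acceptance threshold.
4. **Conditional classification.** Non-RBB hits whose e-value is at least
   as significant as the curve at their query length are accepted; each
   remaining transcript is assigned its best accepted hit's gene.

The default percentile (99, counted on ascending e-values) places the
threshold at the least-significant edge of the self-training cloud: the
curve tracks where genuine homologue e-values bottom out for a given
transcript length, so additional assembled variants whose matches are as
strong as the anchors are accepted while spurious cross-gene hits are
rejected. Lowering the percentile tightens the threshold.

All tie-breaking is deterministic: higher bit score, then smaller
e-value, then lexicographically smallest subject id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .exceptions import ValidationError
from .io import BlastHit, HomologyEntry, HomologyMap

__all__ = [
    "RbbPair",
    "LengthBinSummary",
    "ThresholdCurve",
    "AssignmentResult",
    "AssignmentScore",
    "best_hit_per_query",
    "reciprocal_best_hits",
    "bin_rbb_by_length",
    "fit_threshold_curve",
    "classify_nonrbb_hits",
    "assign_homology",
    "build_homology_map",
    "evaluate_assignment",
    "DEFAULT_PERCENTILE",
    "DEFAULT_EVALUE_FLOOR",
    "DEFAULT_N_BINS",
    "DEFAULT_MIN_PER_BIN",
]

DEFAULT_PERCENTILE = 99.0
DEFAULT_EVALUE_FLOOR = 1e-180
DEFAULT_N_BINS = 50
DEFAULT_MIN_PER_BIN = 20


@dataclass(frozen=True, slots=True)
class RbbPair:
    """A transcript and reference gene that are each other's best hit."""

    transcript_id: str
    gene_id: str
    forward_hit: BlastHit
    reverse_hit: BlastHit


@dataclass(frozen=True, slots=True)
class LengthBinSummary:
    """Self-training summary of one transcript-length bin."""

    bin_index: int
    length_min: int
    length_max: int
    representative_length: float  # median query length in the bin
    n_hits: int
    percentile_evalue: float
    log10_percentile: float


@dataclass(frozen=True, slots=True)
class ThresholdCurve:
    """Quadratic acceptance threshold y = a*L^2 + b*L + c in
    (length, log10 e-value) space.

    Evaluation clamps the query length into the fitted domain, since a
    quadratic extrapolates badly outside its training range.
    """

    a: float
    b: float
    c: float
    percentile: float
    evalue_floor: float
    domain_min: float
    domain_max: float

    def __call__(self, length):
        L = np.clip(np.asarray(length, dtype=float), self.domain_min, self.domain_max)
        out = self.a * L * L + self.b * L + self.c
        return float(out) if np.isscalar(length) else out

    def accepts(self, evalue: float, length: float) -> bool:
        """True when the e-value is at least as significant as the
        length-conditioned threshold (<= convention: a hit exactly on the
        curve is accepted)."""
        return math.log10(max(evalue, self.evalue_floor)) <= self(length)


def _hit_rank_key(hit: BlastHit) -> tuple:
    # higher bit score wins; ties by smaller e-value, then smallest subject id
    return (-hit.bit_score, hit.evalue, hit.subject_id)


def best_hit_per_query(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """For each query, the single best hit (bit score, then e-value, then
    lexicographically smallest subject id)."""
    best: dict[str, BlastHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank_key(hit) < _hit_rank_key(cur):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    forward: Iterable[BlastHit], reverse: Iterable[BlastHit]
) -> list[RbbPair]:
    """Pairs (t, g) where g is t's best forward hit and t is g's best
    reverse hit. Each transcript and each gene occurs in at most one pair.

    Sorted by transcript id for determinism.
    """
    fwd_best = best_hit_per_query(forward)
    rev_best = best_hit_per_query(reverse)
    pairs = []
    for t, fhit in fwd_best.items():
        g = fhit.subject_id
        rhit = rev_best.get(g)
        if rhit is not None and rhit.subject_id == t:
            pairs.append(RbbPair(t, g, fhit, rhit))
    pairs.sort(key=lambda p: p.transcript_id)
    return pairs


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: rank = ceil(p/100 * n) on ascending-sorted
    values, clamped to [1, n]. Deterministic; no interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValidationError("percentile of empty sequence")
    rank = min(max(math.ceil(percentile / 100.0 * n), 1), n)
    return float(v[rank - 1])


def bin_rbb_by_length(
    pairs: Sequence[RbbPair],
    lengths: Mapping[str, int],
    n_bins: int = DEFAULT_N_BINS,
    percentile: float = DEFAULT_PERCENTILE,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
    min_per_bin: int = DEFAULT_MIN_PER_BIN,
) -> list[LengthBinSummary]:
    """Equal-count (quantile) bins of RBB pairs on transcript length, with
    the nearest-rank percentile of forward-hit e-values per bin.

    E-values of exactly 0 are replaced by ``evalue_floor`` before the
    log10. If fewer than ``min_per_bin * n_bins`` pairs are available the
    bin count is reduced automatically (with a warning); zero pairs is an
    error, since there is then no self-training data at all.
    """
    if not pairs:
        raise ValidationError("no RBB pairs: cannot self-train a threshold curve")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if not 0 < percentile <= 100:
        raise ValidationError(f"percentile must be in (0, 100], got {percentile}")
    if evalue_floor <= 0:
        raise ValidationError("evalue_floor must be positive")
    missing = [p.transcript_id for p in pairs if p.transcript_id not in lengths]
    if missing:
        raise ValidationError(
            f"no length for transcripts {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    n = len(pairs)
    n_eff = min(n_bins, max(1, n // min_per_bin))
    if n_eff < n_bins:
        warnings.warn(
            f"only {n} RBB pairs for {n_bins} bins at >= {min_per_bin} "
            f"hits/bin; reducing to {n_eff} bins",
            stacklevel=2,
        )

    order = sorted(pairs, key=lambda p: (lengths[p.transcript_id], p.transcript_id))
    bins: list[LengthBinSummary] = []
    for idx, chunk in enumerate(np.array_split(np.arange(n), n_eff)):
        members = [order[i] for i in chunk]
        ls = [lengths[p.transcript_id] for p in members]
        evs = [p.forward_hit.evalue for p in members]
        pe = nearest_rank_percentile(evs, percentile)
        bins.append(
            LengthBinSummary(
                bin_index=idx,
                length_min=min(ls),
                length_max=max(ls),
                representative_length=float(np.median(ls)),
                n_hits=len(members),
                percentile_evalue=pe,
                log10_percentile=math.log10(max(pe, evalue_floor)),
            )
        )
    return bins


def fit_threshold_curve(
    bins: Sequence[LengthBinSummary],
    percentile: float = DEFAULT_PERCENTILE,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
) -> ThresholdCurve:
    """Ordinary least-squares quadratic through the per-bin points
    (representative_length, log10 percentile e-value).

    With fewer than 3 bins (or fewer than 3 distinct representative
    lengths) the fit degenerates to a constant curve a = b = 0 with c the
    hit-count-weighted mean of the bins' log10 percentile values — for a
    single bin this is exactly the global percentile threshold, i.e. a
    plain fixed e-value cutoff.
    """
    if not bins:
        raise ValidationError("cannot fit a threshold curve to zero bins")
    xs = np.array([b.representative_length for b in bins], dtype=float)
    ys = np.array([b.log10_percentile for b in bins], dtype=float)
    ws = np.array([b.n_hits for b in bins], dtype=float)
    if len(bins) >= 3 and np.unique(xs).size >= 3:
        a, b, c = np.polyfit(xs, ys, 2)
    else:
        if len(bins) > 1:
            warnings.warn(
                "fewer than 3 distinct length bins; falling back to a "
                "constant (fixed-cutoff) threshold",
                stacklevel=2,
            )
        a, b = 0.0, 0.0
        c = float(np.average(ys, weights=ws))
    return ThresholdCurve(
        a=float(a),
        b=float(b),
        c=float(c),
        percentile=percentile,
        evalue_floor=evalue_floor,
        # the observed self-training length range: clamping at an interior
        # point (e.g. the first bin's median) would hold queries shorter
        # than it to a threshold fitted for longer sequences
        domain_min=float(min(b_.length_min for b_ in bins)),
        domain_max=float(max(b_.length_max for b_ in bins)),
    )


def classify_nonrbb_hits(
    hits: Iterable[BlastHit],
    rbb: Sequence[RbbPair],
    curve: ThresholdCurve,
) -> list[BlastHit]:
    """Accept non-RBB hits whose e-value is at least as significant as the
    threshold curve at their query length.

    Hits whose query transcript is already an RBB member are skipped
    (those transcripts are accepted unconditionally in the RBB pass).
    A missing query length is an error naming the transcript.
    """
    rbb_transcripts = {p.transcript_id for p in rbb}
    accepted = []
    for hit in hits:
        if hit.query_id in rbb_transcripts:
            continue
        if hit.query_length is None:
            raise ValidationError(
                f"hit for transcript {hit.query_id!r} has no query length; "
                "supply a FASTA length index or a 13-column hit file"
            )
        if curve.accepts(hit.evalue, hit.query_length):
            accepted.append(hit)
    return accepted


@dataclass
class AssignmentResult:
    """Full output of one assignment run: the transcript -> gene map plus
    the self-training diagnostics behind it."""

    homology_map: HomologyMap
    curve: ThresholdCurve
    bins: list[LengthBinSummary]
    rbb_pairs: list[RbbPair]

    @property
    def n_rbb(self) -> int:
        return self.homology_map.method_counts()["rbb"]

    @property
    def n_conditional(self) -> int:
        return self.homology_map.method_counts()["conditional"]

    def rbb_only_map(self) -> HomologyMap:
        """The RBB-only baseline map (anchors alone, no conditional pass)."""
        m = HomologyMap()
        for p in self.rbb_pairs:
            m.add(
                p.transcript_id,
                HomologyEntry(
                    p.gene_id, "rbb", p.forward_hit.evalue, p.forward_hit.bit_score
                ),
            )
        return m

    def bins_frame(self):
        """Per-bin diagnostics as a DataFrame (bin ranges, hit counts,
        percentile e-values) — the ingredients of the threshold fit."""
        import pandas as pd

        return pd.DataFrame(
            [
                (
                    b.bin_index, b.length_min, b.length_max,
                    b.representative_length, b.n_hits,
                    b.percentile_evalue, b.log10_percentile,
                )
                for b in self.bins
            ],
            columns=[
                "bin_index", "length_min", "length_max",
                "representative_length", "n_hits",
                "percentile_evalue", "log10_percentile",
            ],
        )


def _fill_query_lengths(
    hits: Sequence[BlastHit], lengths: Mapping[str, int] | None
) -> list[BlastHit]:
    if lengths is None:
        return list(hits)
    return [
        replace(h, query_length=lengths[h.query_id])
        if h.query_length is None and h.query_id in lengths
        else h
        for h in hits
    ]


def assign_homology(
    forward: Sequence[BlastHit],
    reverse: Sequence[BlastHit],
    lengths: Mapping[str, int] | None = None,
    *,
    n_bins: int = DEFAULT_N_BINS,
    percentile: float = DEFAULT_PERCENTILE,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
    min_per_bin: int = DEFAULT_MIN_PER_BIN,
) -> AssignmentResult:
    """Run the full assignment: RBB anchors, self-trained threshold curve,
    conditional acceptance of remaining hits, transcript -> gene map.

    The map contains every RBB pair (method ``rbb``) plus, for every other
    transcript with at least one accepted hit, the gene of its best
    accepted hit (method ``conditional``). Transcripts with no accepted
    hit are absent.
    """
    forward = _fill_query_lengths(forward, lengths)
    rbb = reciprocal_best_hits(forward, reverse)
    length_index = dict(lengths) if lengths is not None else {
        p.transcript_id: p.forward_hit.query_length
        for p in rbb
        if p.forward_hit.query_length is not None
    }
    bins = bin_rbb_by_length(
        rbb, length_index, n_bins=n_bins, percentile=percentile,
        evalue_floor=evalue_floor, min_per_bin=min_per_bin,
    )
    if len(bins) < 3:
        # too little training data for a quadratic: re-bin globally so the
        # constant fallback is the exact global percentile cutoff
        bins = bin_rbb_by_length(
            rbb, length_index, n_bins=1, percentile=percentile,
            evalue_floor=evalue_floor, min_per_bin=1,
        )
    curve = fit_threshold_curve(bins, percentile=percentile, evalue_floor=evalue_floor)
    accepted = classify_nonrbb_hits(forward, rbb, curve)

    hmap = HomologyMap()
    for p in rbb:
        hmap.add(
            p.transcript_id,
            HomologyEntry(p.gene_id, "rbb", p.forward_hit.evalue, p.forward_hit.bit_score),
        )
    best_accepted = best_hit_per_query(accepted)
    for t in sorted(best_accepted):
        hit = best_accepted[t]
        hmap.add(t, HomologyEntry(hit.subject_id, "conditional", hit.evalue, hit.bit_score))
    return AssignmentResult(homology_map=hmap, curve=curve, bins=bins, rbb_pairs=rbb)


def build_homology_map(
    forward: Sequence[BlastHit],
    reverse: Sequence[BlastHit],
    lengths: Mapping[str, int] | None = None,
    **params,
) -> HomologyMap:
    """Convenience wrapper around :func:`assign_homology` returning only
    the transcript -> gene map."""
    return assign_homology(forward, reverse, lengths, **params).homology_map


class AssignmentScore(NamedTuple):
    precision: float
    recall: float
    f1: float


def evaluate_assignment(
    hmap: HomologyMap, truth: Mapping[str, str]
) -> AssignmentScore:
    """Precision/recall/F1 of a homology map against a planted
    transcript -> gene truth.

    precision = correct / assignments made (reported as 0 for an empty
    map); recall = correct / |truth|; F1 is the harmonic mean, 0 when
    both are 0.
    """
    n_assigned = len(hmap)
    correct = sum(
        1 for t, e in hmap.entries.items() if truth.get(t) == e.gene_id
    )
    precision = correct / n_assigned if n_assigned else 0.0
    recall = correct / len(truth) if truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return AssignmentScore(precision, recall, f1)
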