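"""Synthetic datasets with planted ground truth for every pipeline stage.

Three generators cover the whole workflow without any external data:

* :func:`simulate_homology_truth` — a toy reference gene set represented
  by multiple assembled transcript variants per gene, with simulated
  forward/reverse hit tables, transcript lengths, planted transcript ->
  gene truth and planted abundances. True-pair log10 e-values sit at or
  below a planted quadratic threshold curve (an additive half-normal on
  the log10 scale models assembly- and divergence-driven scatter); decoy
  cross-gene hits sit a fixed margin above it. Bit scores are
  anti-monotone in e-value. Exactly one variant per gene is made the
  reciprocal best pair.
* :func:`simulate_count_matrix` — replicated stage-count matrices whose
  genes realize planted behaviour patterns through monotone step
  functions of the stage means, with negative-binomial noise and planted
  per-sample size factors.
* :func:`simulate_two_species` — two such matrices linked through a
  shared intermediary gene space, with planted concordant / discordant /
  species-specific directions, a designated transcription-factor subset
  and a focal gene set, for the cross-species overlap and Monte Carlo
  enrichment machinery.

Only behaviour patterns whose minimal intervals join *adjacent* stages
can be realized exactly by a monotone step mean profile: making a
non-adjacent interval significant forces some sub-interval to carry at
least half the effect, which is then itself significant at any useful
power. The count generators therefore plant the step-realizable
sub-catalogue by default (7 per direction for four stages); an explicit
``patterns=`` argument overrides this.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression import ASCENDING, DESCENDING
from .io import BlastHit, write_abundance_table, write_blast_tab
from .profiles import BehaviorPattern, PatternCatalogue

__all__ = [
    "HomologySimulation",
    "CountSimulation",
    "TwoSpeciesSimulation",
    "simulate_homology_truth",
    "simulate_count_matrix",
    "simulate_two_species",
    "realizable_patterns",
    "DEFAULT_PLANTED_CURVE",
]

#: planted quadratic (a, b, c) in (length, log10 e-value) space; decreasing
#: over the default length range 200..3000 and clear of the 1e-180 floor
DEFAULT_PLANTED_CURVE = (-8e-6, -0.01, -30.0)


def _quad(curve: tuple[float, float, float], length: float) -> float:
    a, b, c = curve
    return a * length * length + b * length + c


def _bit_score(log10_evalue: float) -> float:
    # any strictly decreasing map of log10(e-value) keeps ranking consistent
    return 30.0 - 2.0 * log10_evalue


def _make_hit(query, subject, length, log10_evalue, rng) -> BlastHit:
    aln = max(1, int(0.8 * length))
    return BlastHit(
        query_id=query,
        subject_id=subject,
        percent_identity=round(float(rng.uniform(60.0, 99.9)), 2),
        alignment_length=aln,
        mismatches=int(rng.integers(0, max(1, aln // 10))),
        gap_opens=int(rng.integers(0, 4)),
        qstart=1,
        qend=aln,
        sstart=1,
        send=aln,
        evalue=10.0 ** log10_evalue,
        bit_score=_bit_score(log10_evalue),
        query_length=None,
    )


@dataclass
class HomologySimulation:
    """Hit tables, lengths, abundances and the planted truth behind them."""

    forward: list[BlastHit]
    reverse: list[BlastHit]
    lengths: dict[str, int]
    truth: dict[str, str]  # transcript -> true gene
    anchors: dict[str, str]  # gene -> RBB anchor transcript
    planted_curve: tuple[float, float, float]
    transcript_abundance: pd.DataFrame  # transcripts x samples
    gene_abundance: pd.DataFrame  # true gene totals, genes x samples
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every on-disk artefact (hit tables, length TSV, abundance
        TSV, truth JSON); returns the path of each file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "forward": outdir / "forward_hits.tsv",
            "reverse": outdir / "reverse_hits.tsv",
            "lengths": outdir / "transcript_lengths.tsv",
            "abundance": outdir / "transcript_abundance.tsv",
            "gene_abundance": outdir / "true_gene_abundance.tsv",
            "truth": outdir / "truth.json",
        }
        write_blast_tab(self.forward, paths["forward"])
        write_blast_tab(self.reverse, paths["reverse"])
        with open(paths["lengths"], "w") as fh:
            fh.write("transcript_id\tlength\n")
            for t in sorted(self.lengths):
                fh.write(f"{t}\t{self.lengths[t]}\n")
        write_abundance_table(self.transcript_abundance, paths["abundance"])
        write_abundance_table(self.gene_abundance, paths["gene_abundance"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "planted_curve": list(self.planted_curve),
                    "transcript_genes": self.truth,
                    "anchors": self.anchors,
                    "noise_model": "additive half-normal below the planted "
                    "curve on the log10 e-value scale",
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return paths


def simulate_homology_truth(
    n_genes: int = 500,
    variants_per_gene: tuple[int, int] = (1, 4),
    length_range: tuple[int, int] = (200, 3000),
    curve: tuple[float, float, float] = DEFAULT_PLANTED_CURVE,
    noise_sd: float = 0.1,
    decoy_rate: float = 0.1,
    decoy_margin: float = 10.0,
    n_samples: int = 1,
    seed: int = 0,
) -> HomologySimulation:
    """Simulate forward/reverse hit tables for a fragmented assembly.

    Each gene receives between ``variants_per_gene[0]`` and
    ``variants_per_gene[1]`` transcript variants with lengths uniform on
    ``length_range``. A variant's true-pair log10 e-value is
    ``curve(length) - |N(0, noise_sd)|`` (at or more significant than the
    planted curve); the variant with the most significant hit is the
    reciprocal best pair of its gene. With probability ``decoy_rate`` a
    transcript additionally hits a random wrong gene at
    ``curve(length) + decoy_margin + |N(0, noise_sd)|`` — many orders of
    magnitude less significant, as spurious cross-gene hits are in real
    searches. Transcript abundances split a per-gene total across
    variants by a symmetric Dirichlet.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    vmin, vmax = variants_per_gene
    if not (1 <= vmin <= vmax):
        raise ValidationError(f"bad variants_per_gene {variants_per_gene}")
    lmin, lmax = length_range
    if not (1 <= lmin <= lmax):
        raise ValidationError(f"bad length_range {length_range}")
    if not 0 <= decoy_rate < 1:
        raise ValidationError("decoy_rate must be in [0, 1)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    forward: list[BlastHit] = []
    reverse: list[BlastHit] = []
    lengths: dict[str, int] = {}
    truth: dict[str, str] = {}
    anchors: dict[str, str] = {}
    abundance_rows: dict[str, np.ndarray] = {}
    gene_rows: dict[str, np.ndarray] = {}
    genes = [f"g{k + 1:05d}" for k in range(n_genes)]

    for gi, gene in enumerate(genes):
        k = int(rng.integers(vmin, vmax + 1))
        variant_ids = [f"{gene}.v{v + 1}" for v in range(k)]
        log10_true: dict[str, float] = {}
        for t in variant_ids:
            L = int(rng.integers(lmin, lmax + 1))
            lengths[t] = L
            truth[t] = gene
            y = _quad(curve, L) - abs(rng.normal(0.0, noise_sd)) if noise_sd > 0 else _quad(curve, L)
            log10_true[t] = y
            forward.append(_make_hit(t, gene, L, y, rng))
            if decoy_rate > 0 and n_genes > 1 and rng.random() < decoy_rate:
                other = genes[(gi + 1 + int(rng.integers(0, n_genes - 1))) % n_genes]
                y_d = _quad(curve, L) + decoy_margin + abs(rng.normal(0.0, noise_sd))
                forward.append(_make_hit(t, other, L, min(y_d, 1.0), rng))
        # reverse search: the gene hits each of its variants; the most
        # significant (the anchor) becomes the reciprocal best hit
        for t in variant_ids:
            reverse.append(_make_hit(gene, t, lengths[t], log10_true[t], rng))
        anchors[gene] = min(variant_ids, key=lambda t: (log10_true[t], t))

        totals = rng.lognormal(mean=math.log(300.0), sigma=1.2, size=n_samples)
        shares = rng.dirichlet(np.ones(k))
        tvals = np.outer(shares, totals) * rng.lognormal(0.0, 0.05, size=(k, n_samples))
        for row, t in zip(tvals, variant_ids):
            abundance_rows[t] = row
        gene_rows[gene] = tvals.sum(axis=0)

    samples = [f"S{j + 1}" for j in range(n_samples)]
    transcript_abundance = pd.DataFrame.from_dict(
        abundance_rows, orient="index", columns=samples
    ).sort_index()
    gene_abundance = pd.DataFrame.from_dict(
        gene_rows, orient="index", columns=samples
    ).sort_index()
    return HomologySimulation(
        forward=forward,
        reverse=reverse,
        lengths=lengths,
        truth=truth,
        anchors=anchors,
        planted_curve=curve,
        transcript_abundance=transcript_abundance,
        gene_abundance=gene_abundance,
        seed=seed,
    )


def realizable_patterns(catalogue: PatternCatalogue) -> list[BehaviorPattern]:
    """Patterns exactly realizable by a monotone step mean profile: those
    whose minimal intervals all join adjacent stages."""
    return [
        p
        for p in catalogue.patterns
        if all(j == i + 1 for i, j in p.minimal_intervals)
    ]


def _pattern_stage_means(
    pattern: BehaviorPattern | None,
    n_stages: int,
    base_mean: float,
    fold_change: float,
) -> np.ndarray:
    """Stage means (linear scale) realizing a pattern's significant
    intervals via log2(fold_change) steps at its minimal intervals.
    ``None`` gives a flat profile (no planted behaviour)."""
    if pattern is None:
        return np.full(n_stages, base_mean)
    step = math.log2(fold_change)
    d = np.zeros(n_stages - 1)
    for i, j in sorted(pattern.minimal_intervals):
        d[i - 1 : j - 1] += step / (j - i)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    if pattern.direction == ASCENDING:
        log2m = math.log2(base_mean) + cum
    else:
        log2m = math.log2(base_mean) + (cum[-1] - cum)
    return np.exp2(log2m)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2; the
    dispersion-0 limit is deterministic rounding of the means."""
    if dispersion == 0:
        return np.rint(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _normalize_factors(factors, n_samples: int) -> np.ndarray:
    if factors is None:
        return np.ones(n_samples)
    f = np.asarray(factors, dtype=float)
    if f.shape != (n_samples,):
        raise ValidationError(
            f"size_factors must have length {n_samples}, got {f.shape}"
        )
    if (f <= 0).any():
        raise ValidationError("size factors must be positive")
    return f / np.exp(np.mean(np.log(f)))  # geometric mean 1


@dataclass
class CountSimulation:
    """A replicated stage-count matrix with planted behaviours."""

    counts: pd.DataFrame  # genes x samples
    stages: list[str]  # stage label per column
    stage_order: list[str]
    truth_patterns: dict[str, str]  # gene -> planted pattern id
    background_genes: list[str]  # flat (no planted behaviour)
    size_factors: pd.Series  # planted, geometric mean 1
    catalogue: PatternCatalogue
    seed: int

    def truth_directions(self) -> dict[str, str]:
        return {
            g: self.catalogue.direction_of(pid)
            for g, pid in self.truth_patterns.items()
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "stages": outdir / "sample_stages.tsv",
            "truth": outdir / "truth.json",
        }
        write_abundance_table(self.counts, paths["counts"])
        with open(paths["stages"], "w") as fh:
            fh.write("sample_id\tstage\n")
            for col, stage in zip(self.counts.columns, self.stages):
                fh.write(f"{col}\t{stage}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "gene_patterns": self.truth_patterns,
                    "size_factors": self.size_factors.to_dict(),
                    "count_model": "negative binomial, var = mu + disp*mu^2",
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return paths


def simulate_count_matrix(
    genes_per_pattern: int = 40,
    n_stages: int = 4,
    n_replicates: int = 4,
    base_mean: float = 200.0,
    fold_change: float = 8.0,
    dispersion: float = 0.05,
    size_factors: Sequence[float] | None = None,
    patterns: Sequence[BehaviorPattern] | None = None,
    background_fraction: float = 0.5,
    seed: int = 0,
) -> CountSimulation:
    """Replicated count matrix over ordered stages with planted behaviour
    patterns (the step-realizable catalogue by default).

    Stage means realize each pattern through log2(fold_change) steps at
    its minimal intervals; counts are negative binomial with the given
    dispersion, scaled by the planted size factors (normalized internally
    to geometric mean 1; default all 1). A ``background_fraction`` of the
    genes are stably expressed at ``base_mean`` across all stages —
    median-of-ratios normalization assumes a majority of non-differential
    genes, and real staged transcriptomes have one.
    """
    if not 0 <= background_fraction < 1:
        raise ValidationError("background_fraction must be in [0, 1)")
    if fold_change <= 1:
        raise ValidationError("fold_change must be > 1")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates per stage")
    catalogue = PatternCatalogue(n_stages)
    if patterns is None:
        patterns = realizable_patterns(catalogue)

    rng = np.random.default_rng(seed)
    n_samples = n_stages * n_replicates
    factors = _normalize_factors(size_factors, n_samples)
    stage_order = [f"S{s + 1}" for s in range(n_stages)]
    columns = [
        f"{stage}_r{r + 1}" for stage in stage_order for r in range(n_replicates)
    ]
    stages = [stage for stage in stage_order for _ in range(n_replicates)]
    stage_idx = np.repeat(np.arange(n_stages), n_replicates)

    rows = []
    gene_ids = []
    truth: dict[str, str] = {}
    gi = 0
    for pattern in patterns:
        means = _pattern_stage_means(pattern, n_stages, base_mean, fold_change)
        for _ in range(genes_per_pattern):
            gene = f"gene{gi:05d}"
            gi += 1
            mu = means[stage_idx] * factors
            rows.append(_nb_counts(rng, mu, dispersion))
            gene_ids.append(gene)
            truth[gene] = pattern.pattern_id
    n_background = int(round(len(gene_ids) * background_fraction / (1 - background_fraction)))
    background: list[str] = []
    flat = np.full(n_stages, base_mean)[stage_idx] * factors
    for k in range(n_background):
        gene = f"bg{k:05d}"
        rows.append(_nb_counts(rng, flat, dispersion))
        gene_ids.append(gene)
        background.append(gene)
    counts = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=columns)
    return CountSimulation(
        counts=counts,
        stages=stages,
        stage_order=stage_order,
        truth_patterns=truth,
        background_genes=background,
        size_factors=pd.Series(factors, index=columns, name="size_factor"),
        catalogue=catalogue,
        seed=seed,
    )


@dataclass
class TwoSpeciesSimulation:
    """Two linked stage-count matrices with planted cross-species truth."""

    counts_a: pd.DataFrame
    counts_b: pd.DataFrame
    stages: list[str]  # same design for both species
    stage_order: list[str]
    map_a: dict[str, str]  # species-A gene -> intermediary id
    map_b: dict[str, str]
    tf_pairs: list[tuple[str, str]]
    focal_pairs: list[tuple[str, str]]
    truth_patterns_a: dict[str, str | None]  # None = flat (species-specific)
    truth_patterns_b: dict[str, str | None]
    catalogue: PatternCatalogue
    seed: int

    def truth_directions(self, species: str) -> dict[str, str]:
        src = self.truth_patterns_a if species == "a" else self.truth_patterns_b
        return {
            g: self.catalogue.direction_of(pid)
            for g, pid in src.items()
            if pid is not None
        }


def simulate_two_species(
    shared_fraction: float = 0.7,
    n_intermediary: int = 800,
    background_fraction: float = 0.5,
    n_stages: int = 4,
    n_replicates: int = 3,
    base_mean: float = 200.0,
    fold_change: float = 8.0,
    dispersion: float = 0.05,
    tf_fraction: float = 0.04,
    n_focal: int = 29,
    planted_tf_enrichment: bool = False,
    pattern_weight_decay: float = 0.5,
    seed: int = 0,
) -> TwoSpeciesSimulation:
    """Two species' staged count matrices linked through an intermediary
    gene space.

    A ``background_fraction`` of intermediary genes are stably expressed
    (flat) in both species — median-of-ratios normalization, like the
    method it emulates, assumes a majority of non-differential genes. Of
    the differentially expressed remainder, ``shared_fraction`` get
    concordant planted directions in both species (patterns drawn
    uniformly from the realizable catalogue of that direction); the rest
    split evenly between discordant (opposite directions) and
    species-specific (flat in one species). A ``tf_fraction`` subset
    (relative to ``n_intermediary``, drawn among the differentially
    expressed genes) is designated as transcription factors and
    ``n_focal`` concordant ascending non-TF pairs form the focal set.
    Behaviour frequencies follow geometric weights with ratio
    ``pattern_weight_decay`` (1.0 = uniform) over the canonical pattern
    order. With ``planted_tf_enrichment`` the focal genes and the TFs are
    re-planted into the two rarest ascending behaviours in both species,
    so the co-occupancy statistic is genuinely enriched over its null.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must be in [0, 1]")
    if not 0 <= background_fraction < 1:
        raise ValidationError("background_fraction must be in [0, 1)")
    catalogue = PatternCatalogue(n_stages)
    asc = [p for p in realizable_patterns(catalogue) if p.direction == ASCENDING]
    desc = [p for p in realizable_patterns(catalogue) if p.direction == DESCENDING]

    rng = np.random.default_rng(seed)
    inter_ids = [f"i{k:05d}" for k in range(n_intermediary)]
    genes_a = [f"a{k:05d}" for k in range(n_intermediary)]
    genes_b = [f"b{k:05d}" for k in range(n_intermediary)]

    if not 0 < pattern_weight_decay <= 1:
        raise ValidationError("pattern_weight_decay must be in (0, 1]")

    def geometric_weights(n: int) -> np.ndarray:
        # behaviour-group sizes in staged expression atlases are heavily
        # skewed (a few early/late-step behaviours dominate); decay 1 gives
        # uniform frequencies
        w = pattern_weight_decay ** np.arange(1, n + 1)
        return w / w.sum()

    def pick(pool: list[BehaviorPattern]) -> str:
        w = geometric_weights(len(pool))
        return pool[int(rng.choice(len(pool), p=w))].pattern_id

    pat_a: list[str | None] = []
    pat_b: list[str | None] = []
    concordant_asc: list[int] = []
    de_idx: list[int] = []
    for k in range(n_intermediary):
        if rng.random() < background_fraction:
            pat_a.append(None)
            pat_b.append(None)
            continue
        de_idx.append(k)
        u = rng.random()
        if u < shared_fraction:
            if rng.random() < 0.5:
                pat_a.append(pick(asc))
                pat_b.append(pick(asc))
                concordant_asc.append(k)
            else:
                pat_a.append(pick(desc))
                pat_b.append(pick(desc))
        elif u < shared_fraction + (1 - shared_fraction) / 2:
            if rng.random() < 0.5:
                pat_a.append(pick(asc))
                pat_b.append(pick(desc))
            else:
                pat_a.append(pick(desc))
                pat_b.append(pick(asc))
        else:
            if rng.random() < 0.5:
                pat_a.append(pick(asc) if rng.random() < 0.5 else pick(desc))
                pat_b.append(None)
            else:
                pat_a.append(None)
                pat_b.append(pick(asc) if rng.random() < 0.5 else pick(desc))

    n_tf = int(round(tf_fraction * n_intermediary))
    if n_tf > len(de_idx):
        raise ValidationError(
            f"cannot designate {n_tf} TFs among {len(de_idx)} DE genes"
        )
    tf_idx = sorted(
        de_idx[i]
        for i in rng.choice(len(de_idx), size=n_tf, replace=False).tolist()
    )
    tf_set = set(tf_idx)

    focal_candidates = [k for k in concordant_asc if k not in tf_set]
    if len(focal_candidates) < n_focal:
        raise ValidationError(
            f"only {len(focal_candidates)} concordant ascending non-TF pairs; "
            f"cannot pick a focal set of {n_focal}"
        )
    if n_focal > 0:
        focal_idx = sorted(
            rng.choice(len(focal_candidates), size=n_focal, replace=False).tolist()
        )
        focal_idx = [focal_candidates[i] for i in focal_idx]
    else:
        focal_idx = []

    if planted_tf_enrichment:
        # co-occupancy in a distinctive minority behaviour: focal genes and
        # TFs are re-planted into the two rarest ascending behaviours in
        # both species, emulating a specialized pathway and its regulators
        rare = [p.pattern_id for p in asc[-2:]]
        for k in focal_idx + tf_idx:
            pat_a[k] = rare[int(rng.integers(len(rare)))]
            pat_b[k] = rare[int(rng.integers(len(rare)))]

    def species_counts(gene_ids, planted) -> pd.DataFrame:
        sim_patterns = {
            g: (catalogue[pid] if pid is not None else None)
            for g, pid in zip(gene_ids, planted)
        }
        stage_order = [f"S{s + 1}" for s in range(n_stages)]
        columns = [
            f"{stage}_r{r + 1}" for stage in stage_order for r in range(n_replicates)
        ]
        stage_idx = np.repeat(np.arange(n_stages), n_replicates)
        rows = []
        for g in gene_ids:
            means = _pattern_stage_means(
                sim_patterns[g], n_stages, base_mean, fold_change
            )
            rows.append(_nb_counts(rng, means[stage_idx], dispersion))
        return pd.DataFrame(np.vstack(rows), index=list(gene_ids), columns=columns)

    counts_a = species_counts(genes_a, pat_a)
    counts_b = species_counts(genes_b, pat_b)
    stage_order = [f"S{s + 1}" for s in range(n_stages)]
    stages = [stage for stage in stage_order for _ in range(n_replicates)]

    return TwoSpeciesSimulation(
        counts_a=counts_a,
        counts_b=counts_b,
        stages=stages,
        stage_order=stage_order,
        map_a=dict(zip(genes_a, inter_ids)),
        map_b=dict(zip(genes_b, inter_ids)),
        tf_pairs=[(genes_a[k], genes_b[k]) for k in tf_idx],
        focal_pairs=[(genes_a[k], genes_b[k]) for k in focal_idx],
        truth_patterns_a=dict(zip(genes_a, pat_a)),
        truth_patterns_b=dict(zip(genes_b, pat_b)),
        catalogue=catalogue,
        seed=seed,
    )
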