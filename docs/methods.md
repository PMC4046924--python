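# Methods

## The problem

De novo assembled transcriptomes represent most gene loci by several
assembled transcript variants — SNP haplotypes, alternative splice forms,
and partial or chimeric contigs — of widely varying length. Comparative
expression analysis across species without reference genomes needs a
many-to-one map from those variants to the genes of a well-annotated
reference, tolerant of both assembly artefacts and the sequence
divergence that grows with phylogenetic distance. A fixed e-value cutoff
cannot do this: the e-value of a genuine homologous alignment depends
strongly on query length, so any single cutoff is simultaneously too
strict for short contigs and too lax for long ones.

## Conditional orthology assignment

The assignment method self-trains a length-conditioned threshold from the
data being assigned:

1. **Anchors.** Reciprocal best BLAST (RBB) pairs between the transcript
   set and the reference gene set are taken as high-confidence homologue
   anchors. Best hits are chosen by bit score, ties broken by smaller
   e-value and then lexicographically smallest subject id, so the map is
   reproducible byte-for-byte.
2. **Binning.** Anchors are split into equal-count bins on transcript
   length (default 50 bins, at least 20 anchors per bin, auto-reducing
   for small inputs). Per bin, a nearest-rank percentile of the anchor
   e-values is recorded on the log10 scale; e-values of exactly 0 are
   floored at 1e-180 first (exact zeros occur in real BLAST output, and
   the fit spans many orders of magnitude).
3. **Fit.** An ordinary least-squares quadratic through the per-bin
   points (median length, log10 percentile e-value) gives the threshold
   curve y = aL² + bL + c.
4. **Classification.** A non-anchor hit is accepted when
   log10(max(e, floor)) ≤ curve(L) — at least as significant as the
   self-trained threshold at its length, with equality accepted. Each
   remaining transcript gets its best accepted hit's gene
   (method `conditional`); anchors keep theirs (method `rbb`).

**Percentile orientation.** The percentile is counted on ascending
e-values with the nearest-rank rule (rank = ceil(p/100·n)). The default
is 99: the threshold tracks the *least-significant* edge of the genuine
homologue cloud, so an additional assembled variant is accepted exactly
when its match is as strong as the weakest percent of self-training
anchors at that length. Equivalently this is the "1st percentile"
counted from the insignificant tail. Lowering the percentile tightens
the threshold; with a single bin the method degenerates exactly to a
fixed global e-value cutoff, which is the natural baseline to compare
against.

**Domain clamping.** The quadratic is evaluated with the query length
clamped into the observed self-training length range (quadratics
extrapolate badly). The range used is the full min–max of anchor
lengths, not the span of bin medians: anchors skew long (the anchor is a
gene's most significant variant), and clamping at the first bin's median
would hold every shorter query to a threshold fitted for longer
sequences.

## Expression aggregation and normalization

Transcript-level estimated counts are summed over all variants assigned
to one reference gene, per sample (summing TPM across variants is only
meaningful within a sample and is not the default). Samples are
normalized by median-of-ratios size factors: for each gene positive in
every sample, the ratio of its count to its geometric mean across
samples; the sample's factor is the median of these ratios, taken on the
ratio scale. Genes with any zero are excluded rather than pseudo-counted.
Estimated factors are identified up to a common scale — the estimator
returns factors whose reference is the per-gene geometric mean, so
planted factors are recovered exactly when they are normalized to
geometric mean 1, and only factor ratios are scale-equivariant.

Assignment quality is validated by Spearman rank concordance between the
gene-level aggregate and an independent quantification of the same
samples, computed over the intersection of gene ids with average ranks
for ties. Concordance punishes false assignments, missed variants and
fragmented contigs alike, which is what makes it a useful single number.

## Behaviour-pattern classification

Genes measured over an ordered developmental gradient (n stages,
replicated) are classified by which ordered stage pairs (i, j), i < j,
change significantly and in which common direction. Because a real
change over a sub-interval implies a real change over every enclosing
interval, admissible significance sets are the non-empty,
containment-closed interval sets: if (i, j) is in the set, so is every
(k, l) with k ≤ i, l ≥ j. For four stages there are exactly 13 such sets
per direction — 26 behaviour groups. The catalogue for any n is
enumerated through the antichains of the interval containment order
(each closed set is the upward closure of its minimal intervals) and
ordered canonically (earliest minimal interval, then set size), giving
stable ids A01..A13 / D01..D13.

Per-pair significance calls use BH-adjusted p-values at α = 0.05, the
family being all genes within one stage-pair comparison. The bundled
`pairwise_de_pvalues` (Welch's t on log2(normalized count + 1)) is
deliberately generic plumbing — studies with a dedicated count model
should supply their own adjusted p-values. Degenerate rows (both groups
zero-variance) get p = 1 for equal means and 0 otherwise, so the
noiseless limit behaves deterministically.

Two classification modes handle statistically inconsistent genes (a
sub-interval significant but an enclosing interval not): `strict` (the
default) reports them as `inconsistent`; `closure` classifies the
containment closure of the significant set. Mixed directions among
significant pairs, or an exact tie on a significant pair, are always
`inconsistent`. Negating all stage means maps each ascending
classification to its mirror descending one.

## Cross-species comparison and the co-occupancy test

Two species are linked through an intermediary reference genome: every
(geneA, geneB, intermediary) triple where both genes map to the same
intermediary gene. Directional overlap is counted at the intermediary
level with any-link semantics — an intermediary gene is
ascending-shared when at least one linked gene on each side is ascending
(one intermediary can count in both directions; it is discordant only
when both sides are classified but only in opposite directions). This is
the one counting scheme that yields a single number per intermediary
gene despite many-to-many homology.

The Monte Carlo co-occupancy test asks whether the number of
transcription-factor homologue pairs sharing behaviour groups with a
focal gene set in *both* species exceeds chance. The statistic counts TF
pairs whose behaviour lies in the focal set's occupied behaviours in
each species; the null resamples focal-sized sets of linked pairs
without replacement from the universe of pairs classified in both
species (the statistic is undefined outside it, which is why that is the
universe; it is an explicit argument). The empirical p-value is
(r + 1)/(N + 1) over N iterations — never exactly zero, and conservative
when the statistic is coarse. The default is 10⁴ iterations; 10⁶ is
practical for final figures.

## The synthetic-data generators

The generators produce every input with planted truth; their defaults
are the study conditions under which the package validates itself.

**Homology generator.** Each of 500 genes gets 1–4 transcript variants,
lengths uniform on 200–3000 nt. True-pair log10 e-values sit at
curve(L) − |N(0, 0.1)| below a planted quadratic
(a, b, c) = (−8·10⁻⁶, −0.01, −30) — an additive half-normal models
divergence- and assembly-driven scatter on the log10 scale (the
generative model is the harness's own choice; it is recorded in the
truth JSON). The most significant variant of each gene is its reciprocal
best pair. With probability 0.1 a transcript also hits a wrong gene 10
orders of magnitude above the curve, as spurious cross-gene hits are in
practice. Bit scores are strictly anti-monotone in e-value. Per-gene
abundance totals (log-normal) are split across variants by a symmetric
Dirichlet, so the RBB-only baseline sees only one variant's share of
each gene while the conditional map recovers the total — the ordering of
their concordances with truth is the planted analogue of the
fixed-cutoff-vs-conditional comparison on real data.

**Count generator.** For each planted behaviour, stage means follow a
monotone step function: log2(fold change) at each of the pattern's
minimal intervals (default fold 8). Counts are negative binomial with
var = μ + φμ² (φ = 0.05 by default; φ = 0 degenerates to rounded means),
scaled by planted size factors (normalized to geometric mean 1). Half of
the genes are a flat background at the base mean (200): median-of-ratios
normalization assumes a non-differential majority, and staged
transcriptomes have one. Only behaviours whose minimal intervals join
*adjacent* stages are exactly realizable by a step profile — making a
non-adjacent interval significant forces some sub-interval to carry at
least half the effect, which is then itself significant at any usable
power — so the generator plants the step-realizable sub-catalogue (7 per
direction for four stages) by default; `patterns=` overrides. Genes in
the remaining behaviours arise in real data from borderline effect
sizes, and the classifier handles them when given p-values; the
generator just cannot plant them cleanly, which is a statement about
step-function means, not about the classifier.

**Two-species generator.** Intermediary genes (default 800) are 50%
flat background; of the rest, a shared fraction (0.7) get concordant
directions in both species, the remainder splitting between discordant
and species-specific. Behaviour frequencies follow geometric weights
(ratio 0.5 by default — a few behaviours dominate real staged atlases;
1.0 gives uniform). Three replicates per stage mirror a triplicated
gradient design. A TF subset is designated among the differential genes,
and 29 concordant ascending non-TF pairs form the focal set. With
`planted_tf_enrichment`, focal genes and TFs are re-planted into the two
rarest ascending behaviours in both species — a specialized pathway and
its regulators co-occupying a distinctive minority behaviour, which is
precisely the situation the test is meant to detect.

## Validation experiments (the `benchmarks` module)

Problem sizes are chosen so each experiment finishes in seconds on one
core while leaving comfortable statistical margins:

* *Assignment*: 500 genes, 1–4 variants, decoys at 10%, noise 0.1 —
  F1 against planted truth and conditional-vs-RBB-only concordance.
* *Curve recovery*: 2400 single-variant genes, 40 bins, percentile 50.
  The bin median is used because the default 99th-percentile statistic
  is the bin's max e-value, which tracks the curve at the bin's minimum
  length and biases the linear coefficient by about 2a·(half bin width)
  regardless of sample size; the median has no location bias (lengths
  are uniform within a bin and the median commutes with the monotone
  curve), leaving only a small constant offset absorbed by the intercept.
* *Normalization*: planted factors uniform on 0.6–1.6 over 16 samples,
  recovered by median-of-ratios within 5%.
* *Pattern recovery*: 40 genes per realizable pattern, 4 stages, 4
  replicates, fold 8, dispersion 0.05, strict mode at α = 0.05.
* *Null calibration*: 200 co-occupancy tests at 2000 iterations each,
  focal sets drawn from the universe, against a Kolmogorov–Smirnov
  uniformity check at the 1% level. This configuration uses uniform
  behaviour frequencies and a large TF panel (2000 intermediaries, 12%
  TFs) so the statistic has rich support: empirical p-values of a coarse
  discrete statistic are conservative rather than uniform by
  construction, which would be a property of the statistic, not a defect
  of the sampler.
* *Power*: the planted-enrichment configuration (3000 intermediaries, 1%
  TFs, skewed frequencies) at 10⁴ iterations.

## What the synthetic results do and do not show

The generators emulate variant multiplicity, length-dependent e-value
structure, decoy hits, overdispersed counts, library-size biases and
many-to-many cross-species homology. They do not emulate chimeric
contigs spanning two genes, isoform-specific expression, length biases
in quantification, correlated noise across genes, or genuinely
borderline effect sizes. Passing tests therefore demonstrate that the
machinery is correct and calibrated under its stated model — not that
any particular accuracy will be attained on real data, where the
corresponding figures must be re-measured (e.g. by the concordance
validation against a reference-guided quantification).

## Numerical choices and degenerate inputs

* E-value floor 1e-180 before log10; evaluation and fitting are
  otherwise in double precision.
* Nearest-rank percentile (no interpolation); all tie-breaks are
  deterministic (bit score, e-value, lexicographic id).
* Fewer than 3 length bins: the pipeline re-bins globally so the
  constant fallback is the exact global percentile cutoff.
* Empty abundance aggregations, empty gene sets and empty maps return
  empty-but-well-formed objects; zero RBB pairs, all-zero genes and
  out-of-range parameters raise typed validation errors that the CLI
  maps to exit code 3 (missing files: 2; anything unexpected: 4).
* Single seeded NumPy generator per simulation or test; identical seeds
  give byte-identical outputs.

## Known limitations

* The assignment is many-to-one by construction; co-orthologous
  reference genes (one transcript legitimately matching two genes)
  collapse to the single best hit.
* No alignment-coverage or identity floor is imposed beyond the curve;
  if a use case needs one it must be filtered upstream.
* `pairwise_de_pvalues` is a generic replicate test, not a count model;
  with 2–3 replicates its power and its null behaviour are those of a
  t-test at very low degrees of freedom.
* The co-occupancy test conditions on the classification; classification
  errors propagate into both the observed statistic and the null in the
  same way, which preserves calibration but dilutes power.
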