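# Methods

This note documents the models, conventions and design choices behind
mirglass: what each stage computes, which knobs matter, what the synthetic
generator does and does not emulate, and the numerical conventions that tests
depend on.

## Quantification

Reads are assumed pre-aligned against hairpin reference sequences whose names
equal locus ids (the aligner itself is upstream of this package). Counting
rules:

- Only mapped reads of 19–24 nt are retained (`CountingConfig.min/max_read_len`).
- A read whose alignments cover *k* distinct loci contributes 1/*k* to each
  locus ("fractional" multi-mapper correction). Uniform splitting is the
  minimal-assumption rule and conserves read mass: the per-library counts
  (mature arms plus the hairpin-other bucket) sum exactly to the number of
  retained query names, which the tests assert to 1e-9.
- Within a locus a read is attributed to the mature arm whose hairpin-local
  interval contains the read's 5′-most aligned base. miRNA 5′ ends are
  processing-defined and nearly invariant, so the 5′ anchor is robust to 3′
  trimming heterogeneity. For reverse-complement alignments the 5′ base sits
  at `reference_end − 1`. Reads anchored outside every arm accumulate in a
  per-locus "hairpin-other" bucket that is excluded from mature counts.
- Rows with a summed raw count < 10 over *all* libraries of a species are
  dropped. The boundary is strict: a row totalling exactly 10 survives.
- RPM normalization scales each library column to 1e6 over the retained
  mature rows. The filter precedes normalization, so the RPM denominator is
  "reads mapping to retained miRNAs"; noise rows never influence library
  size. Whether hairpin-other reads belong in the denominator is genuinely
  open; they are excluded here, pinned once for reproducibility.
- Stage pooling sums raw-count columns (e.g. the default map
  e0-2+e2-4 → e0-4, e4-6+e6-8+e8-10 → e4-10, e10-12+e12-14+e14-16 → e10-16)
  and is followed by an explicit re-normalization; replicate averaging acts
  on RPM values, keyed by replicate group (separate-sex adult libraries in
  one group average into a single adult column).

## Sequence divergence

`align_pair` is a Gotoh global aligner with affine gaps, default scoring
(match, mismatch, open, extend) = (+1, −1, −5, −2), where a gap of length L
costs `open + L·extend` (the first gap residue pays both). The horizontal
gap state unrolls to a running maximum per DP row (the gap cost is linear in
length once opened), so the forward pass is vectorised per row; traceback is
deterministic with preference diagonal → up → left. The aligner is checked
three ways: against exhaustive enumeration of all alignments for short
sequences, against an independent column-wise rescoring of its own output,
and against Biopython's `PairwiseAligner` under the equivalent
parameterisation.

Divergence is the raw p-distance of the alignment — substituted columns over
gap-free columns, U and T identical, gap columns excluded from both counts —
with no multiple-hit correction: at congeneric distances (here ≤ ~0.25
substitutions/site) the correction is small and the uncorrected proportion
is the quantity of interest. Mature divergence pools both arms: summed
substitutions over summed gap-free sites of the shared-arm alignments (a
pair annotated with one arm in a species uses the shared arm alone).

Rate classes are tertiles: sort ascending on the chosen divergence, first
⌈n/3⌉ are `low`, last ⌈n/3⌉ `high`, remainder `medium`; ties are resolved by
a stable sort on (value, id) and logged.

Genomic clusters chain loci on the same chromosome and strand whose
inter-locus gap is ≤ 10 kb (inclusive; the gap is `next.start − max end so
far`, which with half-open intervals is the exact number of intervening
bases, and using the running maximum end makes the chaining equal to
all-pairs single linkage even for nested loci).

## Stage similarity and the hourglass summary

Stage vectors are RPM values over ortholog-matched rows (arm-level ids
mapped through the hairpin-level 1-to-1 table; miRNAs without an ortholog
are excluded from cross-species cells — they carry <1% of reads in the kind
of data emulated here). Spearman's ρ (Pearson of midranks) is the primary
metric for its robustness to outliers and nonlinearity; Euclidean distance
of per-gene z-scores (each gene z-scored across its own species' stages;
zero-variance genes dropped from both sides) is the alternative.

Hierarchical stage ordering uses average linkage on 1 − ρ (or the stored
distances), implemented as an explicit UPGMA loop with scan-order
tie-breaking so the leaf order is deterministic and testable against a
from-scratch average-linkage oracle; scipy's implementation serves as an
independent cross-check of the merge structure.

The hourglass profile extracts ρ along the homologous-stage diagonal
(developmental-time-ordered stage pairs), reports the argmax pair and each
stage's best partner in the other species, and scores
`mean(ρ over mid pairs) − mean(ρ over first and last pair)`. The default mid
window is the middle third of the pairs (indices ⌊n/3⌋ … n−1−⌊n/3⌋); the
window is a reporting convention, configurable per run. Replicate SDs of the
coefficients come from repeating the cross-species comparison with each
replicate's matrix (ddof = 1).

## Temporal conservation

Per-ortholog profiles are locus-level (mature-arm rows summed) RPM vectors
over the homologous pooled stages, six points at the default granularity,
correlated with Pearson's *r* (the profile shapes, not ranks, are the
object here, matching how single-miRNA time courses are read). Controls:

- within-cluster pairs per species (all unordered pairs of multi-member
  clusters) — co-transcribed miRNAs, the ceiling;
- random non-orthologous cross-species pairs drawn uniformly without
  replacement, seeded; the default draw count equals the number of ortholog
  records so box plots are size-matched.

Group comparisons use the two-sided Wilcoxon rank-sum test; the reported
statistic is the first group's midrank sum W with the normal-approximation
p-value. Rank-based testing is used because r distributions are bounded and
left-skewed. The divergence/conservation association is the Pearson
correlation of per-pair divergence against temporal r with the t-based
two-sided p, plus per-rate-class r distributions.

Constant profiles (e.g. a miRNA expressed in only one species) are skipped
with a log entry rather than given an arbitrary r.

## Synthetic data generator

The generator emulates the study design end to end; its defaults are the
study conditions: 118 ortholog families, 54/5 species-specific loci, 8
clusters of 2–4 members, 90-nt hairpins with 22-nt arms, substitution rates
uniform on [0, 0.2], species-A stage grid {e0-1, e2-6, e6-10, e12-24,
larva, adult} with 2 replicates, species-B grid of eight 2-h embryonic
windows plus e16-30, larva, adult at 1 replicate on a 1.5× slower clock,
library depth 1e6, 10% of species-specific loci duplicated as
identical-arm paralogs.

- **Genomes.** Hairpins are i.i.d. random nucleotides; species-B ortholog
  hairpins derive from A by i.i.d. per-site substitution at the family rate
  (substitution always changes the base, and never to the U/T equivalent, so
  the realized p-distance is an unbiased binomial estimate of the rate). No
  indels by default, keeping the divergence oracle exact. Cluster members
  are placed with gaps drawn in [200, 9000] bp on one strand; all other
  gaps exceed 12 kb. Rates are drawn independently of everything else, which
  is what makes the rate-vs-conservation null test meaningful.
- **Expression.** Each family has a smooth continuous profile on the
  species-A clock: maternal exponential decay (τ ~ U(2, 6) h), a Gaussian
  zygotic pulse with log-uniform center over 1–240 h and width
  max(2, center·U(0.2, 0.6)), or constant, plus a 2% baseline; mixture
  weights 0.25/0.65/0.10 and log-normal abundances (σ = 1.5). Larva and
  adult stages additionally carry family-specific log-normal multipliers
  (σ = 1) shared between species: post-embryonic expression reflects tissue
  identity rather than a smooth continuation of the embryonic curve. This
  shape diversity is what makes random cross-species pairs essentially
  uncorrelated — the property a negative control requires — while orthologs,
  which share profile and multipliers, stay correlated.
- **Stage means** are the time-average of the profile over the stage window
  (species B on the rescaled clock, t_A = t_B/1.5). Species B means are
  multiplied by per-(family, stage) log-normal noise with a configurable
  per-stage SD: the default is U-shaped over the B stages (1.0 → 0.3 at the
  gastrulation/germband windows → 1.1 at adult), embedding an hourglass
  whose designed conservation peak is the pooled pairs (e2-6 ↔ e4-10) and
  (e6-10 ↔ e10-16); a flat profile embeds none. Cluster members multiply a
  shared primary-transcript profile by small per-member per-stage log-normal
  noise (σ = 0.15 default) and a member-specific scale.
- **Counts** per library are one multinomial draw of the library depth over
  the arm rows (replicates are independent draws). Multinomial rather than
  negative binomial keeps the error bounds analytic; count-recovery tests
  use a χ² goodness-of-fit with small-expectation cells pooled (< 5) and
  multi-mapping rows excluded, since identical-arm paralogs are provably
  only recoverable as a pair total.
- **Reads** are 19–24 nt sequences anchored at the arm 5′ end with 0–1 nt
  start jitter (the 5′ anchor stays inside the arm, matching the
  attribution rule), emitted once per identical-arm locus under a shared
  query name, plus a 2% fraction of 18-nt decoys that the length filter
  must remove. No sequencing-error or adapter model.
- **Reproducibility.** All randomness flows from one integer seed through
  named `SeedSequence` sub-streams (genomes / profiles / noise / per-library
  counts / reads), so the emitted file tree is byte-identical across runs.

What the generator does not emulate: alignment errors and mismatches
(reads are exact substrings), sequencing error, adapter artefacts,
overdispersion between biological replicates, indel evolution (available
via the alignment path but off by default), and annotation errors. Passing
tests therefore demonstrate the correctness and calibration of the
analysis, not robustness to those artefacts in real libraries.

## Test-design conditions

Statistical tests freeze their experimental design up front:

- Divergence-recovery trials use aligned length L = 1000 so the ±3-binomial-SD
  band has its asymptotic ≈99.7% coverage; at 90 nt the binomial is too
  discrete at p = 0.01 for a 99% band (P(|p̂−p| ≤ 3SD) ≈ 0.986 by exact
  calculation).
- The cluster-vs-ortholog comparability check runs under an exchangeable
  design — every family clustered, zero cross-species divergence noise,
  matched stage grids (B = 1.5× the A windows), single replicates — in which
  ortholog pairs and within-cluster pairs have identical noise structure by
  construction, so their r distributions must agree; under the default
  heterochronic design they differ slightly and systematically (window
  mismatch, un-replicated B libraries), which a rank-sum test at n ≈ 120
  can detect even when medians agree to two decimals.
- Scaled-down problem sizes (40 families, 20 k reads) are used for the
  read-level simulations; all dataset-level claims run at the full default
  design.

## Known limitations

- Tertile boundaries inside ties are stable-sort determined, not
  re-partitioned; with coarse divergence values (multiples of 1/90) ties at
  the boundary are common and logged.
- The hourglass score compares configured mid pairs against the two
  terminal pairs only; it is a descriptive summary, not a fitted model, and
  no formal hourglass-vs-early-conservation test is provided.
- `euclidean_z` matrices store distances; dendrograms and hourglass
  extraction handle the sign convention, but the replicate-SD machinery is
  defined for correlation metrics.
- The CLI is a thin wrapper; programmatic use via
  `mirglass.pipeline.analyze_counts` is the primary interface.
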