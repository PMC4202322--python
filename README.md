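# mirglass

Cross-species comparison of microRNA expression across development, for
small-RNA biologists and evolutionary genomicists asking whether the *timing*
of miRNA expression is conserved even when miRNA *sequences* are not — and
whether stage-wise expression conservation follows the developmental
hourglass (mid-embryonic stages most conserved, earlier and later stages more
divergent).

The library takes two species' miRNA annotations (miRBase-dialect GFF3 +
FASTA), aligned small-RNA reads (SAM) or raw count tables, a 1-to-1 ortholog
table and a sample sheet, and produces stage-correlation matrices, ortholog
divergence estimates, and temporal-conservation statistics. A synthetic
two-species generator with full ground truth (ortholog map, substitution
rates, clusters, stage-divergence profile) makes every stage testable without
any external data.

## Method

- **Counting.** 19–24 nt reads aligned to hairpin references are counted per
  mature arm; a read hitting *k* distinct loci contributes 1/*k* to each, so
  read mass is conserved. Arm attribution uses the read's 5′-most aligned
  base (the processing-defined end). Rows with fewer than 10 total reads
  across all libraries are removed, then columns are normalized to RPM
  (reads per million mapping to miRNAs) and replicates averaged. Stage
  pooling (e.g. eight 2-h embryonic windows of the slower species onto the
  coarser grid of the other) operates on raw counts before normalization.
- **Divergence.** Orthologous hairpins and mature arms are globally aligned
  (affine gaps, deterministic traceback) and divergence is the p-distance:
  substituted columns / gap-free columns, with U ≡ T; mature divergence
  pools the sites of both arms. Pairs split into low/medium/high rate
  tertiles.
- **Stage similarity.** All-versus-all Spearman's ρ between stage expression
  vectors over ortholog-matched miRNAs (Euclidean distance of per-gene
  z-scores as an alternative metric), hierarchically clustered (average
  linkage on 1 − ρ) with replicate-derived SDs. The homologous-stage
  diagonal is summarised as an **hourglass score** = mean ρ over mid
  developmental pairs − mean ρ over the first and last pair; positive means
  mid-development is the conservation peak.
- **Temporal conservation.** Per-ortholog Pearson *r* between RPM time
  courses on homologous (pooled) stages, compared against genomically
  clustered miRNAs (same strand within 10 kb, expected co-transcribed; a
  positive control) and random cross-species pairs (negative control) with
  the two-sided Wilcoxon rank-sum test, and correlated against sequence
  divergence.

## Worked example

`python examples/05_ortholog_profiles.py` simulates a study-sized dataset
(118 ortholog pairs, 6 + 11 stage groups, 1.5× slower clock in species B)
and runs the temporal-conservation analysis:

```
         ortholog: n=118  median r = +0.903
 cluster_within_a: n= 24  median r = +0.990
 cluster_within_b: n= 24  median r = +0.771
     random_cross: n=118  median r = -0.213

ortholog vs random rank-sum: W = 19200, p = 2.56e-23
  -> ortholog time courses are far more conserved than chance pairs

rate vs conservation: Pearson r = -0.107, p = 0.25 (n = 118)
    high rate class: median temporal r = +0.881
     low rate class: median temporal r = +0.930
  medium rate class: median temporal r = +0.910
```

Orthologs correlate almost as strongly as miRNAs sharing a primary
transcript, far above random pairs, and the conservation of timing is
independent of how fast the sequences evolve. `examples/04_...` prints the
stage diagonal, peaking mid-development (gastrulation/germband pairs,
ρ ≈ 0.99) with lower terminal values — the hourglass:

```
     e0-1 ~ e0-4    rho = 0.916
     e2-6 ~ e4-10   rho = 0.987 <-- peak
    e6-10 ~ e10-16  rho = 0.983
   e12-24 ~ e16-30  rho = 0.950
    larva ~ larva   rho = 0.935
    adult ~ adult   rho = 0.906
hourglass score (mid minus terminal mean rho): +0.055
```

The other examples cover dataset simulation, fractional read counting,
divergence/clusters, and the end-to-end file pipeline (also available as a
CLI: `mirglass simulate | quantify | homology | compare | profiles | run`).

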