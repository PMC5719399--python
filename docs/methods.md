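# Methods

## Association model

The association strength of a TF on gene *i* is a_i = Σ_k g_k·exp(−d_k/D₀)
over the TF's peaks, with g_k the peak intensity, d_k = |peak midpoint −
TSS| and D₀ = 10 kb; peaks beyond 1 Mb are excluded. D₀ = 10 kb weights the
enhancer/silencer distance range; the 1 Mb radius bounds the computation
without affecting scores materially (exp(−100) ≈ 4e−44). The peak location
is the interval midpoint: it is computable from interval data alone,
whereas a summit would require signal-level input; a summit column can be
substituted upstream by supplying point intervals. A peak may contribute to
every gene within range — there is no exclusive assignment, because the
score is defined per gene as a sum over all admissible peaks. Distances are
taken to the TSS only, not the gene body, matching the nearest-TSS framing
used for silencer assignment. Scores are linear in intensity and monotone
non-increasing in distance; both properties are under test.

Top-N target sets (default N = 3000) order by score descending with ties
broken by gene identifier so the ordering is total and reproducible.

## Interval geometry

Coordinates are 0-based half-open throughout (BED native). The gap between
two intervals is the distance between their nearer borders; touching or
overlapping intervals have gap 0, so a tolerance of 0 admits touching
intervals — the most permissive reading of a border-to-border rule, and
configurable. Co-occupancy between two peak sets uses a 200 bp tolerance by
convention; the silencer triple rule defaults to 0 (plain intersection),
since the tolerance convention is attested only for two-TF comparisons.
Overlap queries run on per-chromosome interval trees with the query
envelope widened by max_gap + 1 to capture border equality; brute-force
quadratic scans serve as independent oracles in the tests.

Nearest-TSS assignment measures from the integer midpoint
floor((start+end)/2) to each TSS on the same chromosome; minimal absolute
distance wins, equidistant genes resolve to the lexicographically smaller
identifier, and strand affects only the reported sign (negative = midpoint
5′ of the TSS in the gene's orientation). A locus on a gene-free chromosome
is explicitly unassigned rather than an error, since real inputs contain
scaffolds without annotation.

## Differential expression and the window profile

The fold-change rule calls a gene when |log2 FC| ≥ log2(2) — boundary
inclusive — and the p-value of a Welch (unequal-variance) two-sample t-test
on log2(value + 1) is strictly below 0.05. The Welch test on logs is the
standard deterministic choice for small-replicate expression contrasts; no
moderated variance and no multiple-testing correction are applied, because
the rule is a fixed filter, not an inference procedure. The pseudocount of
1 on linear values guards exact zeros. A degenerate test (both groups
constant and equal) reports p = 1.

The genome is ranked by descending log2 FC (ties alphabetical; rank 1 =
most up-regulated; log or raw fold change give the same order). The window
profile averages association scores over windows of `window` consecutive
ranks advancing by `step` (defaults 500 and 1; a 1000-gene variant is a
config change). Window means are computed by cumulative sums; centers are
midpoint ranks. The profile is shift-equivariant in the scores, which the
tests exploit.

## Silencer calling

A candidate is any TF peak overlapping (under the configured gap rule) at
least one DHS interval and one H3K27me3 interval. The candidate footprint
is the TF peak itself — the candidate is a binding site with co-marks, not
the geometric three-way intersection — and the recorded witnesses are the
nearest qualifying DHS/K27 intervals by midpoint distance. H3K27me3
"enrichment" is membership in the supplied K27 interval set; signal-level
thresholding belongs to upstream peak calling. Enlarging the gap tolerance
can only add candidates (monotonicity, under test).

## qPCR genotyping

Per embryo and gene, Ct is the mean over detected technical replicates
(three by convention); relative expression is 2^(Ct_ref − Ct_gene) against
Actb, and a gene undetected in every replicate has expression 0. Genotype
calls: null = target transcript undetected in all replicates AND the Neo
cassette clearly expressed; wild type = Neo negligible (undetected or below
1% of the cohort median Neo level); heterozygous otherwise; target-absent
AND Neo-negligible contradicts the cross design and is flagged ambiguous
rather than silently assigned. The negligible threshold is a declared
convention — the per-embryo decision does not admit a hypothesis test — and
is configurable. Calls are invariant to replicate order and to a constant
Ct shift within an embryo (only ΔCt and detection flags enter).

Embryo clustering is average-linkage agglomerative clustering on
1 − Pearson correlation of log2(expression + ε), ε = 1e−3 chosen because
null embryos contain exact zeros. A constant embryo would make Pearson
undefined; its correlations are set to 0 with a warning.

The correlation map computes, per gene, Pearson correlation with the
anchor gene on log2(expr + ε) independently across single cells and across
embryos (Spearman available by option). Cluster labels follow a quadrant
rule with threshold τ = 0.3: cluster 1 (positively regulated) r_sc > τ and
r_emb > τ; cluster 3 (negatively regulated — the ICM/pluripotency pattern)
r_emb < −τ; cluster 2 (parallel TE program) r_sc > τ with |r_emb| ≤ τ.
τ is an explicit heuristic re-creation of visually defined clusters, not an
estimate. Zero-variance genes get r = 0 and no cluster.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments and a seed; reruns are
bit-identical.

* **Genome** — TSSs on a 1 kb lattice, uniformly placed with ≥ 1 kb
  spacing, random strands. No gene structure, clustering, or chromatin
  domains.
* **Peaks** — each planted target receives 1–5 peaks at truncated-
  exponential distances from its TSS (mean 20 kb, all < 1 Mb, making the
  1 Mb cutoff binding-relevant); negative targets receive 1–3 peaks with
  intensities scaled by 0.4, modelling the moderate binding observed at
  repressed targets. Intensities are lognormal (log-space μ = 2, σ = 0.5);
  background peaks are Poisson-placed at 5/Mb. Real peak sets have
  sequence-dependent placement and width–intensity correlation; none of
  that is modelled.
* **Epigenome** — each planted silencer is an isolated TF peak (≥ 1.1 kb
  border gap from any other peak) given a 300 bp DHS at its midpoint and a
  K27 interval padded 800 bp beyond the peak; decoys carry exactly two of
  the three marks in an even mix; remaining marks scatter away from all TF
  peaks. Construction is verified by an exhaustive triple scan, so
  precision/recall of the caller is well-defined (and expected to be 1.0 —
  the planted task is unambiguous by design; it demonstrates correctness
  of the rule, not robustness to marginal overlaps).
* **Expression** — per-gene lognormal baselines (log2 mean 7, sd 1.5);
  planted ± targets shifted by ±effect (default 2 in log2) in condition A;
  multiplicative lognormal noise (log2-sd 0.1). No normalisation artefacts
  or probe effects.
* **Embryo cohort** — Ct = 20 − log2(expression) + N(0, 0.2) per technical
  replicate, with per-embryo-gene biological variation of log2-sd 0.3
  (0.05 for Actb, so the reference is always detected with the lowest
  variance); Ct > 28 records as undetected. Relative levels: Actb 1000;
  target gene 32 (wt) / 16 (het) / absent (null); Neo mirrored; ICM genes
  doubled in nulls; anchor-dependent TE genes reduced 4-fold in nulls;
  parallel TE genes genotype-independent. The doubling of ICM markers and
  the 4-fold TE reduction are free generator parameters chosen as a clear
  but realistic effect, not estimates from real embryos. Because parallel
  genes are genotype-independent, their embryo-axis correlation is pure
  sampling noise (sd ≈ 1/√24 at 27 embryos), so a τ = 0.3 quadrant rule
  misplaces roughly a tenth of them by chance — the map-recovery check is
  therefore pooled over genes and seeds rather than per gene.
* **Single cells** — a TE/ICM mixture (60% TE of 60 cells) with
  lineage-specific levels and log2-sd 0.4 noise; no dropout or
  zero-inflation, so single-cell correlations are cleaner than real data.

Passing recovery tests on these inputs shows the pipeline implements its
rules correctly and recovers structure the rules can see; it does not show
robustness to the noise sources the generators omit.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale instances: genomes of
100–1000 genes on 2 × 20 Mb chromosomes, ≤ 5000 peaks, 27-embryo cohorts,
20 epigenome seeds — sizes at which every result can be cross-checked
against brute-force oracles. The sliding window scales with the genome
(window 50 on 1000 genes where the genome-scale default of 500 would span
half the ranking). Window means use cumulative sums (float64; relative
error ≪ 1e−9 at these sizes); association tables use per-chromosome sorted
midpoint arrays with binary search. All orderings break ties by
identifier so outputs are total and reruns byte-identical.

## Known limitations

Peak calling, motif discovery, microarray/scRNA-seq preprocessing, GO
enrichment and genome-browser visualisation are out of scope. The DE rule
is a fixed filter without FDR control. The correlation-map clusters are
threshold heuristics. The BED reader handles BED3–BED6 with column 5 as
intensity; it is not a general BED12 parser.
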