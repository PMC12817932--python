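# Methods

This note documents the statistical procedures implemented in `xcoex`, the
choices made where the analysis was genuinely open, the synthetic data model
used for validation, and the limits of what the tests demonstrate.

## Normalization model

Community RNA-seq counts confound three things: the sample's sequencing
depth, each organism's relative abundance, and the per-gene regulation that
the analysis is actually after. `xcoex` removes the first two per taxon:

* **Low-expression filter.** A gene is kept iff it has at least
  `min_count` (default 10) reads in at least `ceil(min_sample_frac ×
  n_samples)` samples (default half). The denominator is *all* samples, not
  only those where the gene's taxon is detectable; this is deterministic
  and errs toward excluding genes of intermittently present organisms, the
  same way a low-abundance community member would be excluded outright.
* **Taxon presence.** A taxon counts as present in a sample when its total
  assigned reads reach `min_species_reads` (default 1,000). Below that,
  expression values are missing (NaN), never zero: absence of evidence at
  40 reads of depth is not evidence of silence. Taxa present in fewer than
  two samples are dropped with a warning.
* **TMM.** Scaling factors follow Robinson–Oshlack exactly as edgeR
  implements them: reference column = upper quartile of library-scaled
  counts closest to the mean upper quartile; per gene, M = log2 ratio of
  library-scaled proportions against the reference, A = mean log2
  proportion; genes zero in either column excluded; double trim (30% on M,
  5% on A, rank-based with average ties); inverse-asymptotic-variance
  weighted mean of the kept M values; factors rescaled to geometric mean 1.
  The test suite pins this to an independently coded implementation of the
  same formulas (50 random NB matrices, 1e-8) and to Bioconductor edgeR on
  a fixture matrix (1e-6). TMM assumes a majority of non-changing genes;
  see the generator notes below for why this matters.
* **Unit.** Normalized expression is per-taxon CPM — counts divided by the
  taxon's effective library (assigned reads × TMM factor) times 1e6 —
  which makes values comparable across taxa of very different sequencing
  depth. The variance-stabilizing transform is arcsinh (defined at zero,
  log-like for large values); it is applied after KO-level summation in the
  module branch, and directly to gene CPM in the gene branch.

## Module scoring

Modules are ordered reaction steps; each step lists alternative KOs or KO
complexes. The scoring rules are: complex abundance = min over members
(absent KO = 0); step abundance = max over alternatives; a step is
*detected* when some alternative has every member present in the KO matrix
(presence, not a value threshold — the low-expression filter upstream is
the detection gate); coverage = detected / total steps; score = median (the
default estimator) over detected steps only, per sample; modules below
`min_coverage` (default 0.5) are not reported. Undetected steps are
excluded rather than zero-filled — zero-filling would make the coverage
threshold redundant and drag every partially annotated module toward zero.
These step semantics are conventional for KO-based module abundance; they
are isolated behind the estimator interface so an alternative rule can be
swapped in.

## BGC refinement

Upstream BGC detection delimits regions with fixed offsets, so regions
carry flanking genes. Refinement chains *genomic neighbours* that are
within 300 bp (intergenic distance = next.start − prev.end − 1, 1-based
inclusive coordinates) **and** correlated with r > 0.5; a gene removed by
the low-expression filter breaks the chain and is recorded as unassigned.
Chaining by adjacent pairs was chosen over all-pair single linkage for
determinism and locality (a distant in-region gene cannot bridge two
operons); single linkage is available behind the `linkage="single"` flag.
Sub-clusters are suffixed a, b, … in coordinate order. Retention requires:
at least one core biosynthetic gene (else discarded at refinement); a core
gene passing the expression filter; at most 70% of members failing the
filter; and some core gene with r > 0.5 to another member. A singleton
cluster fails the last rule vacuously and is discarded unless it is the
entire surviving region, in which case it is retained with a flag — the
rule is undefined for singletons and destroying a whole region on a
technicality seemed wrong. Manual curation in the original workflow is
replaced by these two automatic rules plus optional per-region
include/exclude lists in the configuration.

Cluster activity is summarized by the eigengene: genes are log2(x+1)
transformed, centred and scaled to unit variance across samples, and the
first principal component's sample scores (unit norm) are reported,
sign-aligned so correlation with the mean member profile is non-negative.

## Correlation and network

Correlations pool all qualifying samples across conditions and reactors.
For each feature pair, samples are restricted to those where both taxa are
present and both values non-missing; pairs sharing fewer than `min_shared`
(default 5) samples are withheld rather than reported. Pearson and
Spearman (average ranks for ties) are both computed; an edge whose
coefficients differ by strictly more than 0.3 is removed as
outlier-driven. The filter operates on r, so it runs before power scaling.
Scaling is `weight = sign(r)·|r|^β` with β = 6; the scale-free fit
procedure (`pick_soft_threshold`) bins log connectivity, regresses log
frequency on log k, and scores `−sign(slope)·R²`, returning the smallest β
reaching the target fit (0.8). Edge weights at the display thresholds 0.2 /
0.3 / 0.5 correspond to |r| = 0.2^(1/6) ≈ 0.76, 0.3^(1/6) ≈ 0.82,
0.5^(1/6) ≈ 0.89. Within-species module edges carry the Jaccard fraction
of shared KOs so that edges inflated by definition overlap can be excluded
from interpretation. Cluster–cluster correlation is the Fisher-z average,
`tanh(mean(atanh r))` with r clipped at ±(1 − 1e−6), over all inter-cluster
gene pairs.

## Bootstrap mean-shift test

The pool is, by default, the union of all retained cross-species
correlation values — the most conservative exchangeability assumption for
"higher than expected by chance". B sets of the observed size are drawn
with replacement (default B = 50,000); both one-sided p-values are reported
with the +1 correction, p = (1 + #{null ≥ obs}) / (B + 1), so p is never
zero at finite B. No multiplicity correction is applied by default;
Benjamini–Hochberg is available behind a flag in the CLI workflow. Whether
the original procedure resampled correlation values or underlying samples
is an open question; correlation-value resampling is implemented as the
direct reading. Calibration is tested: under a simulated exchangeable null
the rejection rate at α = 0.05 is 0.05 ± 0.01 (B = 2,000, 1,000
replicates), and power is monotone in the planted shift.

## Synthetic data model

The generator emulates a bioreactor time-course over a multi-species
community. For gene g of taxon t in sample s:

    counts ~ NB(mean = L_s · a_{t,s} · π_{g,s},  var = μ + φ·μ²)

with library size L_s log-uniform on (1e6, 1e7) — deep metatranscriptomes
spanning one decade; relative abundances a_{t,s} a softmax over per-taxon
log random walks (step σ 0.15/sample, visible drift without routine
collapse over 40 samples); dispersion φ = 0.1, appropriate for a
controlled time course rather than cross-subject comparisons; and within-
taxon proportions π from log e = base + amplitude·trajectory + noise.
Latent trajectories are standardized AR(1) series (autocorrelation 0.3 —
mildly smooth; strong smoothness would shrink the effective sample size and
is exactly the regime where chance correlations explode). Only 30% of
background genes respond strongly to their program (amplitude ~ 1);
the rest are near-constitutive. This majority-stable core matches real
transcriptomes and is what the TMM assumption requires — with every gene
responsive, the within-taxon compositional denominator fluctuates enough to
attenuate even noiseless cross-species correlations to ≈ 0.8. An optional
shared confounder enters every taxon's programs with random-signed
loadings, reproducing environment-driven spurious cross-species edges.

Planted interactions couple two gene groups ("features", default 8 genes)
across taxa through a shared trajectory: partner B's trajectory is
sign·(c·u + √(1−c²)·v), so the latent correlation is exactly the coupling
c. Planted genes are operon-like — well expressed (baseline log-mean 1.0)
with similar levels (sd 0.2) — as befits an active pathway; widely spread
baselines would let the median estimator track a single member.

What the generator does **not** emulate: strain-level genome realism,
condition-structured designs (drop-outs, mutants), compositional coupling
between abundance and expression, batch effects, or fitting to any real
community's parameters. Passing recovery tests therefore shows that the
pipeline's inference chain is correct under its assumptions, not that real
communities are this benign; the confounder scenario deliberately
demonstrates the opposite — with strong shared environmental drive and no
planted interactions, spurious cross-species edges with |r| > 0.8 appear
in most simulated experiments.

## Problem sizes and numerical choices

The validation suite runs communities up to 8 taxa × 300 genes × 40
samples and bootstrap calibrations at B = 2,000 × 1,000 replicates; these
sizes exercise every code path at full statistical strength while keeping
the whole suite around ten seconds on one core. Fisher-z clips r at
±(1 − 1e−6); correlations are clipped into [−1, 1] after matrix products;
TMM ties are ranked with averages (as in edgeR) and exact M ties are kept
exact by computing M in ratio form; zero-variance features yield recorded,
unemitted edges rather than NaN propagation; all randomness flows from a
single numpy Generator per entry point, so identical configs and seeds are
bit-reproducible.

## Known limitations

* Correlation is symmetric: the method suggests *partners*, not directions
  or mechanisms, and cannot distinguish interaction from shared response
  without condition design.
* Per-taxon CPM makes profiles comparable within a taxon over time, but
  cross-taxon comparisons of absolute levels remain meaningless; only
  profile shapes are compared.
* The discrepancy filter removes outlier-driven edges but also genuinely
  nonlinear monotone relationships with heavy ties.
* Module scores inherit annotation quality; missing KO assignments lower
  coverage and can silently drop real pathways at the 0.5 threshold.
* The bootstrap's exchangeability assumption pools heterogeneous taxon
  pairs; a strongly coupled pair (e.g. two congeneric species) inflates
  the pool and makes the test conservative for everything else — the tail
  and matched-module utilities accept exclusion lists for this reason.
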