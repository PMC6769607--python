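# Methods

## Model and test

Each 500 bp genomic bin is summarized by its CpG dinucleotide count *c*
(the substrate of MeDIP enrichment) and its MRE recognition-site count *r*
(the substrate of methylation-sensitive restriction digestion; default
motif set CCGG/GCGC/CCGC, configurable because the enzyme panel is a
protocol choice). Raw per-sample counts are modeled as independent Poisson
variables whose rates couple to the bin's methylation level *m* with
opposite signs: MeDIP rate κ·c·s·m, MRE rate κ·r·s·(1−m), with s the
sample/assay library-size factor (sample total over across-sample mean of
totals) and κ a common sequencing scale.

The two-sample comparison conditions on the bin total T, under which the
four counts are multinomial with cell probabilities proportional to
(a₁m₁, a₂m₂, b₁(1−m₁), b₂(1−m₂)), aᵢ = c·sᵢᵐᵉᵈⁱᵖ, bᵢ = r·sᵢᵐʳᵉ; κ cancels
and is never needed at test time. The statistic is the conditional
likelihood-ratio for H₀: m₁ = m₂.

Two estimation facts keep this fast and exact:

* The **pooled H₀ MLE** has a closed form. The score equation of the
  conditional likelihood in the common m is a quadratic whose leading
  coefficient carries the factor (T − X₊ − Y₊) = 0, so it is linear, giving
  m̂₀ = (X₊/A)/(X₊/A + Y₊/B) with A = a₁+a₂, B = b₁+b₂ — the pooled
  normalized-coverage ratio.
* The **unrestricted (m₁, m₂) MLE** is found by coordinate ascent in which
  each coordinate update is itself exact: for fixed m₂ the score in m₁ is a
  quadratic (coefficients in closed form), and the update picks the best of
  its two roots and the endpoints {0, 1} by direct likelihood comparison.
  Each sweep is monotone in the likelihood, so convergence is guaranteed,
  including at boundary configurations (zero cells) where simpler
  fixed-point schemes oscillate between root branches. Agreement with a
  generic 2-D numerical optimizer is at the 1e-9 level.

The reported per-sample estimates are the normalized-coverage ratios
m̂ᵢ = (Xᵢ/aᵢ)/(Xᵢ/aᵢ + Yᵢ/bᵢ) (1 when Yᵢ = 0 < Xᵢ, 0 when Xᵢ = 0 < Yᵢ);
they also fix the direction label. The likelihood-ratio statistic itself
uses the exact MLE: the plug-in ratio estimates are not the conditional
maximizer when aᵢ/bᵢ differ between samples, and plugging them in distorts
the null distribution near zero (the chi-square tail approximation degrades
from mean deviation 0.008 to 0.028 against exact enumeration).

**Reference distribution.** For T > 20 (configurable `exact_threshold`) the
statistic is referred to χ²(1). For 0 < T ≤ 20 the p-value is computed by
exact enumeration of all C(T+3, 3) outcomes of the conditional multinomial
at m̂₀, summing the probabilities of outcomes whose statistic is ≥ the
observed one (tie tolerance 1e-9). T = 0 bins with positive content are
kept with p = 1 and direction "none". The threshold 20 balances enumeration
cost (≤ 1,771 outcomes) against chi-square accuracy; at T between 30 and
100 the chi-square and enumeration p-values agree to 0.008 on average under
the generator's study conditions, with worst-case deviations ~0.03–0.04 at
the low end of that range — an intrinsic discreteness floor: the
conditional distribution at T ≈ 30 has probability atoms of that size, so
no continuous reference can do better uniformly.

Bins with c = r = 0 are excluded from testing and from the BH denominator
(no information under the model). Bins whose counts contradict their
content (MeDIP reads with c = 0, or MRE reads with r = 0, applied
symmetrically) are flagged untested rather than silently scored.
Benjamini–Hochberg is implemented as the standard step-up with monotone
enforcement; DMRs are tested bins with q < α (default 0.05). Merging of
touching same-direction significant bins into multi-bin regions is off by
default (a DMR is a single bin) and available behind a flag.

## Annotation

CpG islands follow the three classical criteria — length > 200 bp (strict,
i.e. ≥ 201), GC > 50 %, observed/expected CpG > 0.6 with
O/E = (N<sub>CpG</sub>·L)/(N<sub>C</sub>·N<sub>G</sub>) (Gardiner-Garden
convention). Detection is a Takai–Jones-style scan: 200 bp seed windows at
1 bp step, runs of passing seeds merged when separated by < 100 bp, then
greedy 1-bp trimming (dropping whichever end scores worse on GC + capped
O/E) until the whole segment satisfies the criteria; every emitted island
is re-verified by assertion. Shores are the 2,000 bp flanks, clipped at
chromosome ends, island-subtracted and merged.

DMR classification uses any-overlap (≥ 1 bp) with fixed precedence —
island > shore > open, and promoter > intragenic > downstream > intergenic
— so each DMR gets exactly one label per axis and category percentages sum
to 100. Promoter and downstream flanks (1,500 bp each) are strand-aware:
upstream means 5′ of the TSS on the gene's own strand. Reported percentages
are rounded half-up to one decimal.

## Enrichment

Per term: p = P[Hypergeom(N, K, n) ≥ k] with N the background (all genes in
the supplied annotation — the only locally computable convention), K the
term size within the background, n the query, k the hits; fold enrichment
(k/n)/(K/N); BH across all tested terms. The reported list keeps terms with
k ≥ 2 and fold ≥ 1.5. Annotation clusters approximate fuzzy functional
clustering: terms are linked when Cohen's kappa of their query-membership
vectors is ≥ 0.5, clusters are connected components, the score is −log₁₀ of
the geometric mean of member p-values, and reported clusters need ≥ 2 terms
with a strict majority at q < 0.05. Identical constant membership vectors
get kappa 1 by convention (they co-cluster).

## TAD linkage of intergenic DMRs

Intergenic DMRs are first filtered on conservation: the mean per-base score
over the bin must exceed 0.5 strictly; bases without a score count 0.
Cross-assembly transfer goes through an offset-preserving block table; an
interval maps only if a single block covers it entirely (configurable
fraction), otherwise it is dropped — a deliberate, reproducible stand-in
for interactive genome-browser lift-over. The containing TAD is searched
within ± 1 Mb of the (mapped) DMR; containment of the whole DMR is
required, DMRs spanning a domain boundary yield no link, and the smallest
containing domain wins when domains nest. Genes whose bodies overlap the
TAD are the DMR's contact genes and feed the enrichment module.

## Validation statistics

Percent methylation = M/(M+U)·100. Relative expression = target quantity
over the geometric mean of three housekeeping quantities (scale-invariant).
Standard-curve efficiency = 100·(10^(−1/slope) − 1); a perfect doubling
(slope −1/log₁₀2 ≈ −3.32) gives exactly 100 %, and slopes −3.1 / −3.6 give
≈ 110.2 % / 89.6 %. Group comparisons use two-tailed t-tests, Welch by
default (the pooled-variance variant is behind a flag), both per MSP site
and on per-animal means across sites.

## Synthetic data

The generator produces the full study world with known truth:

* **Sequence** — background at 40 % GC with strong CpG depletion
  (O/E ≈ 0.2), mirroring vertebrate genome statistics; islands planted at
  60 % GC, O/E 0.75, 300 bp by default, so the detector separates them
  unambiguously. CG dinucleotides are planted explicitly and fills avoid
  accidental CG formation. MRE motifs are planted on a jittered 100 bp grid
  (the motifs are GC/CpG-rich; spacing keeps the background subcritical),
  and a deterministic repair pass demotes CpGs in any residual background
  window that would pass the island criteria. Planted islands are
  re-verified by assertion after all planting.
* **Annotation truth** — genes (2–8 kb, random strand) are placed in
  per-gene slots so bodies plus 1.5 kb flanks never collide; TADs tile 80 %
  of each chromosome as disjoint blocks; conservation is uniform(0, 0.2)
  background with uniform(0.8, 1.0) blocks placed bin-aligned outside gene
  neighborhoods, so conserved intergenic bins exist by construction.
* **Methylation** — both groups at base level 0.5; exactly
  round(dmr_frac·n_bins) bins differ by delta, direction Bernoulli(0.5)
  (both directions occur in real comparisons). Defaults dmr_frac 0.1,
  delta 0.5.
* **Counts** — Poisson draws from the model above, with a single κ shared
  by both assays chosen so the mean per-bin count averaged over assays
  equals `mean_depth` (default 30; a per-assay κ would bias m̂).
  Library-size factors default to a mild uniform 1.0–1.3× imbalance to
  exercise normalization. The sequencing depth and the number of animals
  sequenced per group are configurable, not inferred: the test as
  formulated compares exactly two count columns (one representative sample
  per group), and the pipeline documents rather than hides that limitation.
* **Validation panels** — mean-1 lognormal multiplicative noise at a given
  CV around the true site methylation (MSP) and around group means with a
  planted fold change (expression), 3 housekeeping genes, n ≥ 2 animals per
  group.

What the generator does *not* emulate: read-level artifacts (duplicates,
mappability, GC bias), fragment-length effects, biological replicate
variability beyond Poisson noise, and correlated methylation along the
genome. Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Statistical calibration runs use 10,000 bins (type-I error, FDR,
sensitivity; seconds of runtime), 3,000 bins at depth 500 for estimate
accuracy (mean |m̂ − m| ≈ 0.01–0.03), and 100–200 kb chromosomes for
sequence-level end-to-end runs. Coordinate-ascent tolerance is 1e-12 with
at most 60 sweeps; probability atoms are compared with a 1e-9 tie
tolerance; statistics below 1e-10 are snapped to zero (exact-null bins
carry rounding dust); percentages are rounded half-up to one decimal.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations produce byte-identical
output bundles.

## Known limitations

* Two samples per group: no replicate-level dispersion estimation; the
  Poisson model understates biological variance if replicates are pooled.
* The exact branch conditions on m̂₀ (an estimated nuisance), as is
  standard; it is exact given that plug-in, not unconditionally.
* Chi-square/enumeration agreement has the discreteness floor described
  above for totals near 30.
* The island trimmer is greedy; a pathological sequence could admit a
  larger criteria-satisfying sub-segment than the one found (never observed
  on generator output; every emitted island is still criteria-verified).
* Cross-assembly mapping handles colinear blocks only (no strand flips).
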