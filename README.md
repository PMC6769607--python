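# medipmre

Integrative differential DNA-methylation analysis from paired **MeDIP-seq**
and **MRE-seq** data, for epigenomics researchers comparing two conditions
(e.g. two dietary groups) genome-wide.

The two assays carry complementary signal: MeDIP-seq immunoprecipitates
methylated fragments, so coverage **rises** with methylation, while MRE-seq
sequences fragments cut by methylation-sensitive restriction enzymes at
unmethylated CpG sites, so coverage **falls** with it. `medipmre` combines
both in a single per-bin test, then annotates, enriches and links the
resulting differentially methylated regions (DMRs).

## The statistical model

The genome is tiled into fixed 500 bp bins. For bin *b* with CpG content
*c* and MRE-site content *r*, and samples *i* ∈ {1, 2} with per-assay
library-size factors *s<sub>i</sub>*, raw counts are modeled as independent
Poisson variables

```
X_i ~ Poisson(κ · c · s_i^medip · m_i)          (MeDIP)
Y_i ~ Poisson(κ · r · s_i^mre · (1 − m_i))      (MRE)
```

where *m<sub>i</sub>* ∈ [0, 1] is the bin's methylation level. Conditional
on the bin total *T = X₁+X₂+Y₁+Y₂*, the four counts are multinomial with
cell probabilities ∝ (a₁m₁, a₂m₂, b₁(1−m₁), b₂(1−m₂)) — the sequencing
scale κ cancels. The test of H₀: *m₁ = m₂* is the conditional
likelihood-ratio statistic, referred to χ²(1 df) for large *T* and to exact
enumeration of the conditional multinomial for small *T*. Per-bin q-values
come from Benjamini–Hochberg; bins with q < 0.05 are DMRs, with direction
from the per-sample estimates m̂ᵢ = (Xᵢ/aᵢ)/(Xᵢ/aᵢ + Yᵢ/bᵢ).

Downstream modules:

* **annotation** — CpG island detection (length > 200 bp, GC > 50%,
  observed/expected CpG > 0.6, Gardiner-Garden O/E), 2 kb shores, and
  strand-aware promoter (1.5 kb upstream of TSS) / intragenic / downstream
  (1.5 kb past TES) / intergenic classification.
* **enrichment** — hypergeometric term enrichment of differentially
  methylated genes with reporting filters (≥ 2 genes, fold ≥ 1.5) and
  kappa-linked annotation clusters.
* **tad_linkage** — intergenic DMRs filtered by mean per-base conservation
  (> 0.5), optionally mapped across assemblies through a block table, and
  assigned to genes sharing their topologically associating domain (TAD)
  within a ±1 Mb window.
* **validation** — methylation-specific PCR percent-methylation
  (M/(M+U)·100), qPCR expression normalized to the geometric mean of three
  housekeeping genes, standard-curve efficiency, and two-tailed t-tests.
* **simulate** — generates every input with planted ground truth (islands,
  genes, TADs, conservation blocks, DMRs, Poisson counts, validation
  panels), so the full pipeline is testable without downloads.

## Worked example

```python
from medipmre import RunConfig, run_pipeline

cfg = RunConfig(outdir="example_run", seed=42, chrom_len=100_000, mean_depth=60.0)
bundle = run_pipeline(cfg)
print(bundle["summary"]["directions"])
print(bundle["summary"]["truth"])
```

prints

```
{'total': 19, 'group1_higher': 8, 'group2_higher': 11,
 'pct_group1_higher': 42.1, 'pct_group2_higher': 57.9}
{'n_true_dmr_bins': 20, 'sensitivity': 1.0, 'fdr': 0.0}
```

i.e. on a 100 kb synthetic chromosome (200 bins, 20 planted DMRs, mean
depth 60) the test calls 19 DMRs — 8 more methylated in group 1, 11 in
group 2 — recovering every planted DMR with no false calls. The output
directory contains `dmrs.bed` (name = direction, score = −log10 q),
`dmr_annotation.tsv`, `summary.json`, `enrichment.tsv`, `tad_links.tsv`,
`validation_stats.tsv` and a manifest with the config hash; reruns of the
same config are byte-identical.

The same stages are available from the shell:

```bash
medipmre simulate --seed 42 --outdir data/
medipmre test --counts data/counts.tsv --out-results res.tsv --out-dmrs dmrs.tsv
medipmre run-all --outdir run/ --seed 42
```

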