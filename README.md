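# striatax

Interneuron-taxonomy toolkit for single-nucleus RNA-seq count matrices:
quality control, iterative marker-based classification, compositional
region comparison, pseudobulk differential expression and single-factor
expression gradients — plus a synthetic-data generator with planted ground
truth that exercises every stage.

## Components

| module | what it does |
| --- | --- |
| `striatax.simulate` | Multi-donor, two-region UMI counts with NB noise, hierarchical class/subclass marker programs, heterotypic doublets, region-dependent composition and DE, a latent within-subclass gradient, and full ground-truth records. |
| `striatax.qc` | Five-stage nucleus QC: multi-run consensus doublet calling (simulated-doublet kNN scorer), hard depth/mito filters, a quadratic log(genes)~log(UMI) outlier rule, per-type two-Gaussian marker-score thresholds with multi-type doublet flags, and regional contamination removal. Emits an auditable waterfall report. |
| `striatax.taxonomy` | Log-normalization, dispersion-based HVG selection, PCA/kNN/Louvain clustering, marker-panel annotation, neuron refinement, GAD1/GAD2 interneuron selection, one-vs-rest Wilcoxon marker ranking, correlation-threshold merging of subtypes into classes (strict r > 0.49, clique semantics), average-linkage correlation dendrograms, receptor/ion-channel gene-panel subsetting. |
| `striatax.compose` | Per-sample class fractions, centered log-ratio transform, and two-sided rank-sum comparison of CLR values between regions (exact permutation null for small sample counts). |
| `striatax.de` | Pseudobulk aggregation by (sample, region), vectorized NB-GLM likelihood-ratio tests with Cox-Reid moderated dispersion estimation, strict DEG selection (|log2FC| > 0.5, BH-adjusted p < 0.05), and hypergeometric over-representation against user-supplied GMT gene sets. |
| `striatax.gradient` | Maximum-likelihood single-latent-factor model (EM with spectral initialization) on centered HVG expression within one (subclass, region) stratum; canonicalized gene weights and posterior cell scores. |

## CLI

All stages are exposed through one entry point:

```bash
striatax simulate --config sim.yaml --out data/ --seed 1
striatax qc       --in data/ --out qcd/ --config qc.yaml --seed 1
striatax classify --in qcd/filtered --out taxa/ --seed 1
striatax compose  --labels taxa/labels.tsv --out comp/
striatax de       --in qcd/filtered --labels taxa/labels.tsv --cls C1 --out de/
striatax ora      --degs de/degs_up.txt --gmt sets.gmt --out ora/
striatax gradient --in qcd/filtered --labels taxa/labels.tsv \
                  --subclass C1a --region CN --out grad/ --seed 1
```

Inputs and outputs are plain text: 10x-style MTX triplets
(`matrix.mtx` + `features.tsv` + `barcodes.tsv`) with a `metadata.tsv`
sidecar for per-cell sample/region labels, TSV tables, JSON summaries and
Newick dendrograms.

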