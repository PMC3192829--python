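# glyconet

Reconstruction of carbon-utilization ("glycobiome") gene co-expression
networks from substrate × growth-phase microarray designs, with
random-matrix-theory (RMT) threshold selection and fast-greedy modularity
module detection.

The package is aimed at systems-biology analyses of bulk two-color
expression profiles of the kind collected for fermentative bacteria grown
on different carbon sources (glucose, xylose, fructose, cellobiose, and a
glucose+xylose mixture) across exponential growth phases: 11 conditions ×
3 biological replicates = 33 arrays, ~2300 genes. It provides

- **expression I/O** — validated gene × sample log2-ratio matrices with
  signal-to-noise (SNR) masks (`SNR < 2` ⇒ unquantifiable), sample designs
  and COG annotations, all as plain TSV;
- **a synthetic-data generator** — planted condition-responsive
  co-expression modules with calibrated within-module Pearson correlation,
  hub genes, negative-control probes and SNR dropout, plus ground truth
  for recovery experiments;
- **differential expression** — replicate summaries with the
  `|log2R| ≥ 1.0` and `|Z| ≥ 2.0` significance filter and peak-phase
  dynamics classification;
- **network inference** — pairwise-complete Pearson correlation,
  nearest-neighbor eigenvalue spacing statistics (Poisson vs the Wigner
  surmise), an RMT cutoff scan, and thresholded signed networks;
- **module detection** — deterministic fast-greedy (agglomerative ΔQ)
  modularity optimization with a ≥5-gene module floor;
- **reporting** — COG composition, hub rankings, inter-module link
  matrices, first-neighbor subnetworks, SIF/GML/TSV exports and
  machine-readable run reports.

## The model in brief

Genes *i*, *j* are linked when their expression profiles across all
samples satisfy `r_ij ≥ τ` (Pearson). The cutoff τ is chosen spectrally:
unfolded nearest-neighbor eigenvalue spacings *s* of the thresholded
correlation matrix follow the GOE law `P(s) = (πs/2)·exp(−πs²/4)` while
noise links mix the system, and the Poisson law `P(s) = exp(−s)` once the
matrix decomposes into independent modular blocks. The scan selects the
smallest τ whose Poisson fit is accepted (χ² with p > 0.001) with no
GOE-leaning rejection at any denser cutoff. Modules then maximize
modularity `Q = Σ_c [l_c/m − (d_c/2m)²]` by greedy agglomeration, and a
module is reported when it has more than four genes.

## Worked example

`python examples/04_modules_and_hubs.py` runs the study-scale preset
(2322 genes, 33 arrays, 13 planted modules totalling 614 genes) end to end
and prints:

```
selected cutoff tau = 0.7
network: 640 genes (27.6% of the genome), 21272 links
modules (>= 5 genes): 13, Q = 0.760
module sizes: [138, 70, 65, 60, 55, 50, 45, 40, 35, 25, 16, 10, 6]
agreement with planted modules: ARI = 1.00, 100% of planted members in a reported module
standalone modules: 13 of 13
```

Read: at the selected cutoff the network retains essentially the planted
module members (640 recovered vs 614 planted, the excess being background
genes whose noise correlations pass the cutoff), the greedy partition
reproduces the planted 13-module structure exactly (adjusted Rand index
1.0), and — since the preset plants no cross-module correlation — every
module is standalone. The other examples demonstrate dataset generation,
the differential-expression filter, and the spacing-statistics transition
along the cutoff grid.

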