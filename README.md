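# synpas

Proteostasis-network activity scoring and perturbation analysis for
α-synuclein, exercised end-to-end on synthetic data with planted ground
truth.

Cells keep α-synuclein (the protein of the `SNCA` gene) soluble through a
proteostasis network (PN) of chaperones, degradation machinery and
trafficking factors. Each PN member either promotes or attenuates
α-synuclein aggregation. This package scores how strongly a transcriptome
pushes that network toward aggregation, builds the network from interaction
and expression evidence, ranks genes by their influence inside it, fits a
linear "digital twin" of PN gene dependencies from single-cell expression to
simulate knockdown/overexpression, and screens dose-response drug signatures
for compounds that move the score.

## The score

For a sample with within-sample z-scored expression `z_i` over the `K`
network genes, the proteostasis activity score is the signed mean

```
PAS = (1/K) * Σ_i a_i * z_i,      a_i = +1 (promoter) / −1 (attenuator)
```

Higher PAS means the network state favors aggregation. The same contraction
applied to a differential expression signature `e_i` gives ΔPAS for a
treatment.

## Modules

| module | contents |
| --- | --- |
| `synpas.io` | expression matrices (TSV/GCT/GCTX), edge lists, roles, network JSON, probe collapsing, deterministic table writers |
| `synpas.stats` | exact/enumerated/asymptotic Wilcoxon rank-sum, BH/Bonferroni adjustment, Cohen's d |
| `synpas.network` | relative expression (log2 gene:SNCA), per-dataset differential tests, cross-dataset consensus, first-degree/upstream network assembly |
| `synpas.pas` | within-sample z-scores, PAS/ΔPAS, group and age contrasts, cell-line ranking |
| `synpas.influence` | heat-diffusion influence (1 − diag exp(−tL)), personalized PageRank, quadrant classification |
| `synpas.twin` | per-cell normalization, shrinkage Gaussian graphical model with empirical-null q-values, linear twin, perturbation simulation and screen |
| `synpas.screen` | ΔPAS per drug signature, dose-response correlation, inhibitor/promoter classification, cross-line concordance, ranking |
| `synpas.simulate` | generators for every input with planted ground truth |
| `synpas.pipeline` / `synpas.cli` | one-seed end-to-end run; `synpas` command-line interface |

## Worked example

```bash
synpas run-all --seed 1 --out results/run1
```

runs simulate → build-network → score → influence → twin-fit →
twin-perturb → cell-line ranking → drug-screen from one seed and prints the
summary. The equivalent staged workflow lives in `analysis/01...07`; with
the committed configuration (`analysis/common.py`, seed 1) it prints, among
other things:

```
consensus: 10 genes (10/10 planted recovered, 0 background)
network: K=18 (12 first-degree, 6 upstream, ...)
DS1: case-control PAS median diff +0.1724 (p=1.08e-05)
GGM: 17 edges at q<0.05 (17/17 planted recovered, lambda=0.09416)
ranked 24 detectable lines of 40; Spearman vs planted activity gradient: 0.995
18 inhibitors among 50 cross-line calls; 10/10 strong planted inhibitors recovered
  rank 1: DRUG002 (mean |r|=0.999, planted slope -1.00)
```

Every input is synthetic with a planted truth object, so each stage's
recovery is checked against what was planted rather than eyeballed.

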