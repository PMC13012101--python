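# Methods

This document records the model, the default parameters and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
decisions that affect results.

## 1. Scoring model

**Within-sample z-score.** Expression is standardized per sample across all
genes in the matrix using the population standard deviation (ddof = 0). A
constant sample would have sd 0; single-gene matrices are rejected, and a
constant column is zeroed with a warning rather than producing NaNs.

**PAS.** For the `K` network genes with aggregation signs
`a_i ∈ {+1, −1}` (promoter/attenuator), `PAS = (1/K) Σ a_i z_i`. Genes
absent from the matrix are handled by a `missing_policy`: the default
`renormalize` divides by the number of genes actually present; `error`
demands full coverage. PAS is linear in z and exactly antisymmetric under a
global sign flip — both are tested against brute-force sums.

**ΔPAS.** The same contraction applied to a differential expression
signature `e_i` (log2 treatment-vs-control). Linearity of ΔPAS in the
signature is an exact contract used by the generators and tests.

## 2. Network assembly

**Relative expression.** `log2(gene) − log2(SNCA)` per sample. Inputs must
already be on the log2 scale; linear matrices are converted explicitly
(`to_log2`, pseudocount 1 by default) so the transformation is never
silent.

**Differential testing.** Case vs control per gene with the Wilcoxon
rank-sum test (below), effect = difference of group means of the
log-ratios, direction = sign of that difference, BH adjustment per dataset
(Bonferroni selectable).

**Consensus rule.** A gene is a consensus gene when, in at least
`ceil(min_fraction · n_datasets)` datasets (default half), it passes
`q < 0.05` and `|fc| > 0.3` *in the same direction*. The reference gene is
excluded. Ties between directions resolve to the direction with more
supporting datasets; the implementation is tested for equality against an
independent brute-force restatement on random instances.

**First-degree interactors.** Curated PN members with an inward edge into
the focal gene — a directed edge into it or an undirected edge touching
it. Outward-only neighbors and non-members are excluded.

**Upstream integration.** Consensus genes adjacent (either direction) to a
first-degree member join the network as the upstream tier; consensus genes
touching only the focal gene are reported separately and not integrated.

**Signs.** Role annotation (promoter +1 / attenuator −1) takes precedence;
upstream genes without an annotation inherit their consensus direction.
Missing roles on first-degree genes are a hard error naming the genes.

## 3. Wilcoxon rank-sum

Three regimes, chosen by feasibility rather than fixed size cutoffs:

1. no ties and `min(n, m) ≤ 25`: scipy's exact null distribution;
2. ties present and `C(n+m, min) ≤ 100,000`: own full enumeration of rank
   assignments over midranks (the exact two-sided p with ties);
3. otherwise: normal approximation with tie correction.

Identical pooled values short-circuit to p = 1. The enumeration branch is
validated against an independently written enumeration oracle for all group
sizes ≤ 8.

## 4. Influence

The influence graph is the undirected simple graph over the network genes
plus the focal node.

**Heat diffusion.** `H = expm(−tL)` with the combinatorial Laplacian;
influence of node i is `1 − H_ii`, the heat it sheds into the network at
time `t` (default 0.1 — small enough that scores reflect local structure,
checked to be monotone in `t`). Rows of `H` conserve mass to 1e-10.

**Personalized PageRank.** Power iteration of
`r ← (1−α) s + α Wᵀ r` with damping α = 0.85, seed mass on the focal node,
dangling nodes teleporting to the seed, convergence tolerance 1e-12. Tested
against a direct linear solve and the two-node closed form
(0.5405/0.4595).

**Quadrants.** Per-axis median split with "≥ median" counting as high:
high/high = master_regulator, high heat only = signal_modulator, high PPR
only = hub, low/low = peripheral. With all-identical scores every node is
high on both axes by this convention.

## 5. Digital twin

**Normalization.** z-score per cell across genes with frozen mean/sd
(population sd); the frozen statistics are reused when perturbing, so
simulated shifts do not leak into the normalization.

**GGM.** Schäfer–Strimmer identity-target shrinkage of the gene–gene
correlation matrix (`λ* = Σ Var(r) / Σ r²`, clipped to [0, 1]); partial
correlations from the inverse. Edge significance uses an empirical-null
mixture: the null density of partial correlations
`(1−r²)^((κ−3)/2) / B(1/2, (κ−1)/2)` with κ estimated from the median
absolute off-diagonal (clipped ≥ 5), a Storey estimate of the null
proportion at λ = 0.5, and `q = min(1, eta0 · BH(p))`. A plain Fisher-z +
BH fallback (`normal_bh`) is available for cross-checking.

**Compositional caveat.** Per-cell standardization over only a handful of
genes forces each cell's gene vector to sum to zero, which makes the
correlation matrix near-singular and manufactures spurious partial
correlations. The single-cell generator therefore includes ~200 independent
background genes, and the GGM is fitted on the z-matrix restricted to the
network genes *after* normalization over all genes. This mirrors real
pipelines, where normalization happens over the whole transcriptome.

**Linear twin.** For each significant edge, the OLS slope of target-z on
query-z (`cov/var`). Perturbation multiplies the query's linear-scale
expression by a factor (knockdown ladder 0.06–0.75, overexpression
1.25–8), recomputes its z with the frozen statistics, and propagates one
linear step: `Δz_target = slope · Δz_query`. No iteration — the twin is a
local linear model, not a dynamical system. Factor 1 is the bitwise
identity. Effects are summarized as Cohen's d (pooled sd, ddof = 1) between
perturbed and baseline PAS distributions over cells.

## 6. Cell-line ranking

Lines whose focal-gene expression is at or below 2 nTPM are dropped
(strictly greater than 2 passes). Within each line, log2 gene:SNCA ratios
are z-scored and contracted to PAS; PAS is then z-scored across lines,
two-sided normal p-values attached, and lines ranked by descending PAS
(stable mergesort).

## 7. Drug screen

Each signature record (drug × line × concentration) is reduced to ΔPAS.
Per drug and line, replicates at a dose are averaged, then Pearson r of
ΔPAS against log10(concentration) is computed over ≥ 3 distinct doses
(fewer → invalid record; constant response → r = 0, p = 1 by convention).
Classification: `|r| > 0.5` and `p < 0.05`; inhibitor if r < 0. Cross-line
calls need a concordant sign in every line, `|r|` above the cutoff in every
line, and p < 0.05 in at least one. Candidates are ranked by mean |r|
(ties broken by drug id). Since Pearson r is invariant to affine maps of
log-concentration, calls do not depend on the concentration unit.

## 8. Synthetic data: what it does and does not emulate

Generators are pure functions of parameters and seed, and every generator
returns a truth object (planted genes, edges, slopes, activities, expected
ranks) so downstream recovery is measurable.

- **Edgelist**: directed inward edges from first-degree genes, upstream
  genes touching only first-degree members, background genes talking only
  to each other, plus non-member inward edges to exercise the membership
  filter. It does not emulate scale-free topology or edge confidence
  scores.
- **Case/control sets**: i.i.d. Gaussian log2 expression around per-gene
  baselines with planted shifts of the gene:SNCA ratio in a chosen number
  of datasets. No batch effects, no missingness, no count noise.
- **Single cells**: multivariate Gaussian from a planted precision matrix
  (chain or pairs, exact partial correlations), plus independent background
  genes and a positive offset. No dropout, no library-size variation — the
  GGM recovery numbers are an upper bound on real-data performance.
- **Dose signatures**: per-gene effects `e_i = a_i · ΔPAS + jitter` with
  the jitter projected orthogonal to the sign vector, so the planted
  log-dose line holds exactly in ΔPAS before noise.
- **Cell lines**: log2 ratios `a_i · c0 · (1 + g·t)` with centered shared
  background ratios. This construction makes within-line-z-scored PAS
  `A·u/sqrt(B + C·u²)` with positive constants — provably strictly
  increasing in the planted activity at zero noise, so rank recovery is a
  meaningful test rather than a coincidence.

## 9. Determinism and numerics

- All stage seeds derive from one seed via `SeedSequence.spawn`, reduced
  mod 2³¹.
- Result tables are written with 6 significant digits and sorted rows;
  expression matrices with `%.17g` and re-read with round-trip float
  parsing, so write→read is bitwise exact.
- PAS forces a C-contiguous array before its matrix-vector contraction so
  the BLAS accumulation order — and hence the last bit of the score — does
  not depend on pandas' internal block layout.
- JSON outputs use sorted keys. Two pipeline runs with the same seed are
  byte-identical (tested).

## 10. Limitations

- The twin is a one-step linear model on z-scores; it cannot express
  saturation, feedback, or higher-order dependencies.
- The empirical-null q-values assume the bulk of partial correlations is
  null; in tiny networks with dense true structure eta0 is overestimated
  and calls become conservative.
- With few distinct planted slope magnitudes, rank–slope Spearman has a
  midrank ceiling (~0.94 for three tied groups); values near 0.9 reflect
  that ceiling, not ranking noise.
- Synthetic recoveries (often 100%) characterize the implementation, not
  expected performance on noisy biological data.
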