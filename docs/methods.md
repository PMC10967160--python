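# Methods

This note documents the statistical model behind `nssinet`, the choices
made where the design was genuinely open, and what the tests do and do
not establish.

## The estimand: a Gaussian graphical model over symptoms

The object of interest is a sparse precision matrix `K` over p symptom
nodes. Its off-diagonal entries define partial correlations

    rho_ij = -K_ij / sqrt(K_ii * K_jj),

the association between symptoms i and j conditional on all others.
Nodes are the 19 ANSSIAQ NSSI-function items (F1–F19, 1–5 anchors) plus
two total-score nodes, PHQ-9 (0–27) and GAD-7 (0–21); the community
partition {NSSI-function, depressive, anxious} drives the bridge
indices. The node set and partition are configuration, not hard-coded:
whether behavior items belong in the network is left to the analyst.

## Estimation

1. **Correlation matrix.** Default Spearman (rank-based; robust for 4–5
   category Likert items). Pearson and pairwise two-step polychoric are
   options. Polychoric fixes thresholds from the marginal cumulative
   proportions and maximises the bivariate-normal likelihood of each
   pairwise contingency table over the latent correlation (Owen's-T
   based bivariate normal CDF; Brent search, tolerance 1e-4).
   Indefinite matrices are repaired by eigenvalue clipping at 1e-8 and
   rescaling to unit diagonal.
2. **Graphical lasso.** The L1-penalized Gaussian MLE is solved by
   coordinate descent (scikit-learn's solver) along a descending
   100-point logarithmic penalty path from `lambda_max` (the smallest
   penalty giving an empty graph, `max_ij |S_ij|`) down to
   `lambda_max / 100`, warm-starting each fit from the previous one.
   Sweeps are capped at 200 per penalty: a couple of boundary penalties
   exhibit a duality-gap plateau around 2e-4 that no budget resolves;
   the capped solution differs from the long-run one by ~1e-4, well
   below the reported precision. At `lambda = 0` the solver reproduces
   the direct inverse to machine precision (tested against an
   independent inversion oracle).
3. **Model selection.** `EBIC = -2 loglik + E log n + 4 E gamma log p`
   with `gamma = 0.5`, E the number of nonzero off-diagonal pairs.
   Ties go to the larger penalty (sparser network). Weights below 1e-8
   are treated as exact zeros. All selection settings are recorded in
   the network's metadata.

## Centrality conventions

* Strength `sum_j |w_ij|`; expected influence `sum_j w_ij` (negative
  edges enter strength by absolute value, expected influence signed).
* Distances are `1/|w|`. Closeness is component-restricted:
  (number of reachable nodes) / (sum of distances to them), 0 for
  isolated nodes, so disconnected graphs stay finite.
* Betweenness counts unordered pairs whose shortest path crosses the
  node, with fractional credit under ties; path-length ties are compared
  with tolerance 1e-12. Computed by an in-house Dijkstra + Brandes pass
  so the tie rule is explicit; tests verify it against exhaustive
  simple-path enumeration on networks of up to 7 nodes.
* Bridge strength / bridge expected influence are 1-step sums over
  cross-community neighbors (the 1-step variant is a deliberate choice;
  recorded in output metadata). Bridge closeness restricts targets, and
  bridge betweenness restricts path endpoints, to other communities.
* Z-standardization uses the sample SD over nodes; zero-SD indices map
  to all-zero z-scores.
* Layout: seeded Fruchterman–Reingold (networkx spring layout) with
  attraction proportional to |w|; a single node sits at the origin.

## Bootstrap diagnostics

* **Edge accuracy:** B resamples of participants with replacement; the
  network is re-estimated per resample with the same pipeline config;
  per node pair the 2.5/97.5 percentile bounds are reported (absent
  edges count as weight 0). Resamples that leave an item constant are
  redrawn (capped at 10·B).
* **Stability:** for each drop proportion in {0.05, …, 0.75}, B
  subsamples without replacement are re-analysed and their node indices
  Pearson-correlated with the full-sample values. The CS coefficient is
  the largest drop proportion at which that correlation is ≥ 0.7 in
  ≥ 95% of replicates (both thresholds configurable). Zero-variance
  index vectors (e.g. an empty subsample network) contribute r = 0 with
  an aggregate warning.
* **What the CIs mean.** Percentile CIs from the *regularized* pipeline
  describe the sampling variability of the shrunken weights — the usual
  accuracy plot. They are **not** calibrated against the latent truth:
  lasso shrinkage plus rank/discretization attenuation put the true
  weight above the interval most of the time (~20% coverage in our
  simulations). Where truth-coverage is the goal, the package's
  consistent configuration — polychoric correlations with an
  unpenalized fit (`lambdas=[0.0]`) — achieves the nominal ~95%
  (verified in the acceptance suite at n = 1000, B = 200).

## Synthetic cohort

The generator realises the estimand directly:

* **Structure.** Edges are placed uniformly among within- and
  between-community pairs; counts follow the sparsity parameters
  (defaults: 30 of 210 pairs for the 21-node world). Signed
  partial-correlation targets are drawn from the configured magnitude
  ranges (default |rho| ∈ [0.1, 0.4], 10% negative — the empirical
  networks this emulates are predominantly positive).
* **Positive definiteness.** `K_ij = -rho_ij`, and the diagonal is set
  to `max(1, 1.05 × absolute row sum)` — strict diagonal dominance, so
  K is always PD without retries, while the implied partial correlation
  equals the drawn magnitude whenever a node's row sum stays below
  ~0.95 (true for almost all nodes at the default density).
* **Ordinality.** Responses are drawn through a Gaussian copula: latent
  N(0, R) vectors (R from the standardized `K^{-1}`) are cut at
  per-node thresholds. Thresholds come from target marginal category
  probabilities: for the function items a moment-matched discretized
  normal on support 1–5 hits each item's cohort-realistic mean/SD (e.g.
  F4: 3.890 ± 1.121); the total-score nodes use discretized normals on
  0–27 (mean 18.575) and 0–21 (mean 13.301). A single root seed
  (`numpy.random.SeedSequence`) drives structure and sampling through
  separate child streams, so regenerating the truth never perturbs the
  draws and every artifact is byte-reproducible.
* **What it does not emulate.** No missing data, demographic effects,
  longitudinal dynamics, response styles (acquiescence, careless
  responding) or differential item functioning. A green recovery test
  therefore establishes that the estimation chain is correct for
  copula-ordinal data with a sparse latent GGM — not that any
  particular empirical network is true.

## Numerical and policy choices

* Validation policy: listwise deletion; "outlier" = any value outside
  its item's declared response bounds; dropped and retained counts
  always sum to the input count. A note on printed retention rates:
  412/436 = 94.4954%, which *truncates* to the conventionally printed
  94.49.
* Sample SD uses the n−1 denominator throughout.
* GAD-7/PHQ-9 items are 0–3 (totals 0–21 / 0–27); ANSSIAQ function
  items 1–5; behavior items 0–5 frequency anchors with factor sums B1
  (no obvious tissue injury) + B2 (obvious tissue injury) = behavior
  total. All ranges are per-scale configuration.
* Output tables are rounded to 3 decimals (configurable); manifests
  carry no timestamps so reruns are byte-identical.

## Known limitations

* The graphical-lasso solver is scikit-learn's; its sweep-order
  dependence means node relabeling reproduces the weight matrix only to
  ~1e-4, the solver tolerance.
* Polychoric estimation is pairwise (two-step); the assembled matrix
  may need PSD smoothing, and it is ~20× slower than Spearman on the
  21-node world (~0.6 s per matrix).
* CS coefficients are quantised to the drop grid; coarse grids (used in
  fast tests) can only return values from that grid.
* Mixed graphical models, Bayesian estimation, directed discovery and
  community detection are out of scope; the partition is an input.
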