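# nssinet

Psychometric network analysis of adolescent non-suicidal self-injury
(NSSI), depressive and anxious symptoms.

Clinical questionnaires for an adolescent NSSI cohort — the 19
NSSI-function items F1–F19 of the ANSSIAQ, plus PHQ-9 (depression) and
GAD-7 (anxiety) — are modelled as nodes of a **Gaussian graphical model
(GGM)**: an undirected network whose edge weights are *regularized partial
correlations*, the pairwise associations that remain after conditioning on
every other symptom. The package implements the full analysis chain used
in applied symptom-network studies, together with a synthetic-data
generator that provides a known ground truth, so every stage of the
pipeline can be validated by parameter recovery rather than by eyeballing.

## What it computes

Given a participant × item response table (or a simulated one):

1. **Correlation input** — Spearman (default), Pearson, or two-step
   polychoric correlations for ordinal items; indefinite matrices are
   smoothed to the nearest PSD matrix with unit diagonal.
2. **Network estimation** — graphical lasso over a descending logarithmic
   penalty path: maximise `log det K − tr(SK) − λ Σ_{i≠j} |K_ij|`;
   the extended BIC, `EBIC = −2ℓ + E·log n + 4·E·γ·log p` (γ = 0.5),
   selects λ; edges are `w_ij = −K_ij / √(K_ii K_jj)`.
3. **Centrality** — strength `Σ_j |w_ij|`, expected influence `Σ_j w_ij`,
   closeness and betweenness on `1/|w|` distances, each z-standardized.
4. **Bridge centrality** — the same indices restricted to the
   {NSSI-function, depressive, anxious} community partition, identifying
   symptoms that connect the clusters.
5. **Bootstrap diagnostics** — nonparametric bootstrap 95% CIs for edge
   weights, and case-dropping bootstrap with the correlation-stability
   (CS) coefficient: the largest fraction of participants that can be
   dropped while subsample centralities correlate ≥ 0.7 with the
   full-sample values in ≥ 95% of replicates.
6. **Simulation** — a sparse, diagonally dominant precision matrix with
   community structure and edge magnitudes 0.1–0.4 defines the truth;
   ordinal Likert responses are drawn through a Gaussian copula whose
   thresholds match cohort-realistic item marginals.

## Worked example

The numbered scripts under `analysis/` run the study-scale analysis on a
simulated 412-participant cohort (seed 1):

```sh
cd analysis
python 01_simulate_cohort.py   --seed 1 --out ../results/analysis
python 03_estimate_network.py  --seed 1 --out ../results/analysis
python 04_centrality_bridge.py --seed 1 --out ../results/analysis
python 05_stability.py         --seed 1 --out ../results/analysis
```

which prints, among other things:

```
True network: 30 edges, |rho| in [0.098, 0.377]
Selected lambda = 0.1241 (gamma = 0.5), 34 edges
Strongest edges:
  F11 -- F14: 0.281
  GAD7 -- PHQ9: 0.279
Recovery vs truth: edge-weight correlation = 0.912, sensitivity = 0.93, specificity = 0.97
Top nodes by strength (z-score):
  F9: z = 1.407
  F4: z = 1.230
CS coefficient (strength): 0.4  [acceptable: >= 0.25]
```

Reading: from 412 ordinal response vectors the pipeline recovers the
generating network's edge weights with correlation 0.91; the strongest
conditional association (0.281) links two NSSI-function items; the node
with the highest strength z-score is the one most broadly connected to
the rest of the network; a CS of 0.4 means 40% of participants can be
dropped before strength rankings destabilise — acceptable, though below
the 0.5 mark one would want for firm centrality claims at this sample
size.

The same pipeline is scriptable end to end from a config file:

```sh
nssinet all --config run.yaml --seed 1 --out results/run
```

with subcommands `simulate`, `analyze`, `bootstrap`, `report`, `all`.
Every run writes a manifest (config, seed, input hash) from which all
artifacts are byte-identically regenerable.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — simulating the
default cohort from the given seed, estimating the network, computing
centrality/bridge indices and desk-scale bootstrap diagnostics — and
writes its results JSON to `--out`, with the full artifact set in
`results/acceptance_run/`.

## Layout

```
src/nssinet/        library: scales, simulate, ggm, metrics, stability,
                    pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. statistical acceptance checks
scripts/            acceptance entry point
docs/methods.md     model, assumptions, parameter choices, limitations
```
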