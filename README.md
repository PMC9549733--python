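# motilitylab

Single-cell motility analysis for time-lapse tracking experiments:
per-track trajectory statistics, motility state-space clustering with
condition testing, and fiducial drift correction for migration assays on
3D bioengineered tissue.

The package targets the common question in cell-therapy and regeneration
research: *does a treatment shift cells into a more motile state?* Given
per-cell tracking tables (e.g. TrackMate or Imaris exports of myogenic
progenitors imaged every 10 min for 12 h), it extracts a battery of
displacement statistics per track, embeds cells in a "motility state
space", clusters them into phenotypes, and tests whether treated and
untreated cells occupy those phenotypes in different proportions. Because
raw tracking data is often unavailable, a first-class synthetic generator
reproduces the statistical structure of such experiments — two-regime
mixtures of slow and motile/persistent cells, localization noise, and
rigidly drifting 3D scenes — so every stage is verifiable against planted
ground truth.

## The statistics at the core

For a track x(t) sampled every Δt minutes:

- **Path metrics** — total distance Σ|Δx|, net distance |x(T) − x(0)|,
  progressivity (straightness) = net/total, and max/min/mean step speed.
- **MSD slope** — the exponent α of the time-averaged mean-squared
  displacement, MSD(τ) = ⟨|x(t+τ) − x(t)|²⟩ ∝ τ^α, fitted on log–log
  axes; α ≈ 1 is diffusive, α = 2 ballistic.
- **Hurst exponent (R/S)** — rescaled-range persistence of the increment
  series, debiased with the Anis–Lloyd small-sample expectation;
  H = 0.5 memoryless, H > 0.5 persistent.
- **Non-Gaussian parameter** — α₂ = ⟨Δx⁴⟩/(3⟨Δx²⟩²) − 1 per axis; 0 for
  Gaussian displacements.
- **Random-walk deltas** — linearity, net distance and sub-track kurtosis
  minus their means over isotropic random walks resampled from the
  track's own step lengths.
- **Occupancy & autocorrelation** — fraction of time moving above speed
  thresholds, mean moving speed, and the mean cosine between step vectors
  τ frames apart.
- **TrackMate-style summaries** — total distance, total displacement,
  mean straight-line speed, mean step velocity.

The state space is built by median-imputing and z-scoring the feature
matrix, keeping the principal components that capture ≥ 95 % of variance
(capped at 30), Ward-clustering the PC scores into k = 2 phenotypes, and
testing the condition × cluster table with Pearson's χ² (t-SNE at
perplexity 35 is emitted for visualization only). For 3D tissue scenes,
construct drift is first removed by averaging the start-anchored paths of
fiducial tracks whose step series exceed cosine similarity 0.95.

## Worked example

Run the default simulated 2D assay (120 tracks per condition, 73 frames at
10 min; untreated cells 1/24 motile, treated 11/24 motile):

```sh
motilitylab run --seed 7 --out results/demo
```

which prints

```
analyzed 240 tracks; silhouette 0.614; chi2 p=5.44e-14; outputs in results/demo
```

and writes `tracks.csv`, `truth.csv`, `features.csv`, `labels.csv`,
`chi2_report.txt`, `embedding.csv` and `normalized_means.csv`. The
silhouette (~0.6) says the two motility phenotypes are well separated in
PC space, and the χ² p-value says the treated condition holds
significantly more cells in the motile cluster (cluster 2) — the planted
effect, recovered end to end. `chi2_report.txt` contains the
condition × cluster counts and per-condition proportions behind that
p-value.

The same chain is available as a library:

```python
import motilitylab as ml

ts, truth = ml.simulate_tracks(ml.default_2d_config(n_tracks=216, seed=0),
                               "treated")
fm = ml.feature_table(ml.filter_tracks(ts, min_length=61))
res = ml.reduce_and_cluster(fm)         # PCA -> Ward -> silhouette
```

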