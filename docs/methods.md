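# Methods

This note documents the models, estimators and numerical choices behind
motilitylab, and what the synthetic benchmarks do and do not establish
about real tracking data.

## Track model and ingestion

A track is a time-ordered series of d-dimensional positions (μm, d ∈ {2,3})
at strictly increasing integer frame indices with a fixed frame interval
(minutes). Tables are delimited text (comma or tab, auto-detected) with a
mandatory header; a TrackMate-export column dialect
(`TRACK_ID`/`FRAME`/`POSITION_*`) is read-only. Single-point tracks are
dropped (tracking exports routinely contain them) with a logged count;
duplicate (id, frame) rows are treated as corruption and rejected.

**Length and field filters.** The default analysis keeps tracks with at
least 61 observed frames (strictly more than 60) and, when field-of-view
bounds are provided, drops any track that ever leaves the field — cells
exiting the frame have censored trajectories whose features would be
biased toward low motility.

**Gaps.** Tracking tools occasionally skip frames. Step speeds are always
normalized by each step's own Δt, so gap-containing tracks are valid for
path/speed metrics. Lag-based statistics (MSD, R/S, autocorrelation, α₂)
require evenly sampled series; tracks whose gaps are all ≤ 2 frames are
linearly interpolated, and tracks with larger gaps are excluded from the
feature table with a logged reason. Interpolation slightly smooths the
step series; with the ≤ 2-frame cap the effect on the Brownian oracle
statistics is below their sampling noise.

## Feature battery

All features are translation-invariant. Distances, speeds, the MSD slope
and the directional autocorrelation are exactly rotation-invariant;
linearity/spearmanrsq are axis-dependent by construction (they measure
alignment of the x–y scatter), and the per-axis statistics (Hurst, α₂)
are rotation-invariant in distribution but not per sample. Undefined
features (stationary tracks, zero-variance series) are NaN, never 0, and
are median-imputed only at the state-space stage, with logged counts.

- **Progressivity** = net/total distance; defined as 0 for a stationary
  track (total = 0).
- **Linearity** is the squared Pearson correlation of the planar
  coordinates (the two largest-variance axes for 3D tracks). The squared
  correlation is symmetric in x and y, unlike a y-on-x regression R²,
  which is singular for vertical tracks. A track with one constant
  coordinate is perfectly straight, so the degenerate case maps to 1;
  spearmanrsq (squared Spearman rank correlation, average ranks on ties)
  uses the same policy.
- **MSD slope**: time-averaged MSD over all overlapping origin pairs,
  least-squares slope of log MSD vs log τ over lags 1..min(20, L/4). The
  L/4 cap keeps the high-lag estimates from being dominated by a handful
  of origins. Ballistic tracks give exactly 2; a 200-track Brownian
  ensemble averages within [0.95, 1.05].
- **Hurst (R/S)**: per axis, the increment series is split into
  non-overlapping windows of dyadic sizes from 8 to L/2; each window
  contributes the range of its cumulative mean-deviations divided by its
  SD. The raw log(R/S)–log(w) slope is biased upward at these window
  sizes (≈ 0.59 for white noise at 72 frames), so the estimator reports
  0.5 + slope of [log R/S − log E(R/S | white noise)], with the exact
  Anis–Lloyd gamma-function expectation (population-SD convention,
  verified against Monte Carlo). The debiased estimate is ≈ 0.49 on
  Brownian ensembles and is clipped to [0, 1]. At 72 frames only three
  window sizes exist, which caps resolution: strongly persistent motion
  reads ≈ 0.8–0.9 rather than 1.
- **Non-Gaussian parameter**: α₂ = ⟨Δx⁴⟩/(3⟨Δx²⟩²) − 1 per axis on lag-1
  displacements, averaged over axes; 0 for Gaussian steps, −2/3 for
  Rademacher (±1) steps, > 0 for heavy tails.
- **Random-walk deltas**: each track is compared to 100 simulated
  isotropic walks with the same step count and step lengths resampled
  (with replacement) from its own steps, so the null preserves the cell's
  speed distribution and destroys only directional memory. Deltas are
  observed − mean(null) for linearity, net distance, and mean sub-track
  excess kurtosis of the step-magnitude series. Null streams are keyed by
  a CRC of the track id, so results are independent of table order and
  reproducible across processes.
- **Occupancy**: within non-overlapping sub-tracks of 20 frames, a step
  is "moving" if its speed exceeds a threshold (defaults 0.5, 1, 2,
  5 μm/min); the reported values are across-sub-track means of the moving
  fraction and of the mean moving speed (0 when nothing moves).
- **Autocorrelation**: the reported `autocorr_lag{τ}` is the mean cosine
  between step vectors τ frames apart (1 for constant velocity, −1 for
  strict alternation, 0 for memoryless steps). The Pearson correlation of
  the step-magnitude series is also emitted (`autocorr_mag_lag{τ}`) as a
  diagnostic; it is undefined (NaN) for constant-speed tracks.

Defaults (`FeatureParams`): msd_lag_max 20, rw_n_sim 100, move thresholds
{0.5, 1, 2, 5} μm/min, subtrack_len 20 frames, autocorr lags {1, 2, 5},
hurst_min_window 8. None of these are dictated by the underlying assay;
they are exposed as configuration and the defaults were chosen for
72-frame movies (sub-tracks ≈ 3 h, MSD fit within the reliable lag
range).

## State space

Features are median-imputed, z-scored, and projected by PCA; the kept
component count is the smallest m reaching 95 % cumulative variance,
capped at 30. Z-scoring before PCA is assumed (the features span four
orders of magnitude in scale, so unstandardized PCA would be dominated by
total distance). Ward-linkage agglomerative clustering with Euclidean
distance on the kept scores is cut at k = 2; cluster labels are then
fixed by mean total distance so that cluster 2 is always the motile
phenotype — raw dendrogram labels are arbitrary and would flip between
seeds. The silhouette is computed in the same kept-PC space the
clustering used (clustering space = evaluation space). The t-SNE
embedding (perplexity 35, PCA initialization, fixed seed) is for
visualization only and never feeds the clustering.

Condition effects are tested with Pearson's χ² on the condition × cluster
contingency table, no continuity correction, df = (r−1)(c−1); empty
margins are an error naming the offending condition or cluster. Group
summaries min–max scale each feature to [0, 1] across all tracks before
averaging per group (constant features scale to 0, logged), with SEMs.

For 3D assays where the feature of record is total distance travelled,
`cluster_1d` Ward-clusters that single standardized feature and reports
ordered cluster means and the silhouette.

## Drift correction (3D scenes)

A tissue construct drifts rigidly under the objective; landmarks on the
construct ("fiducials") share that motion while cells move relative to
it. Similarity between fiducials is the cosine of their flattened step
series over the common frame range — steps, not absolute positions,
because cosine similarity of positions depends on the coordinate origin,
whereas correlated *motion* is what identifies the construct. The
correlated set is the largest connected component of the graph with edges
at similarity ≥ 0.95 (ties broken by higher mean internal similarity);
requiring a component rather than a clique tolerates one noisy pair
inside an otherwise coherent set. The drift path is the members' mean
start-anchored displacement (position[t] − position[0]); anchoring
removes each fiducial's arbitrary location so spatially dispersed
landmarks do not bias the path. Correction subtracts the path from every
cell position. Translation-only drift is assumed; rotational or affine
construct deformation is out of scope.

## Synthetic generator

The generator emulates the acquisition designs the analysis is meant for:
2D nuclei tracked every 10 min for 12 h (73 frames) and 3D tissue scenes
imaged every 12 min for 8 h (41 frames; the imaging session may be
longer, but 8 h of tracking is the default and the duration is
configuration). Cell populations are mixtures of a low-motility Brownian
regime and a motile persistent regime, with motile fractions 1/24
(untreated) vs 11/24 (treated) — i.e. 4.17 % vs 45.83 %. Localization
noise is i.i.d. Gaussian per coordinate (0.3 μm in 2D, 0.2 μm in 3D).

- **Brownian**: i.i.d. Normal(0, σ²) steps per axis. Default slow-regime
  σ = 0.8 μm/frame in 2D (mean speed ≈ 0.1 μm/min).
- **Persistent random walk**: Ornstein–Uhlenbeck velocity with
  persistence time P and per-axis stationary velocity SD S, integrated
  with the exact joint (position, velocity) Gaussian update — not an
  Euler step — so the discrete-time ensemble MSD equals the Fürth form
  2dS²P(t − P(1 − e^(−t/P))) at any frame interval. This makes the
  closed-form oracle test discretization-robust. Default motile regime in
  2D: S = 0.35 μm/min, P = 40 min.
- **Directed**: constant velocity plus Gaussian step noise. **Lévy**:
  Pareto(α, min_step) step lengths with isotropic directions.
- **3D regimes** are scaled so the slow and motile populations travel
  ≈ 47 and ≈ 75 μm of total path over 8 h, the regime the 3D
  total-distance clustering is designed to separate.
- **Drift scenes**: cells plus fiducials share a cumulative drift path
  (linear, sinusoidal with default period n_frames/4 ≈ 2 h, or random
  walk; default sinusoidal amplitude 5 μm). The period default matters:
  drift must move the construct by more than the fiducial jitter each
  frame for step-series correlation to be detectable at similarity 0.95,
  and a ~2 h oscillation of a few μm does that while a movie-length
  oscillation does not.

Seeding: one integer seed spawns per-track substreams
(`numpy.random.SeedSequence`), so enlarging a simulated experiment never
reshuffles previously generated tracks, and every stage is bit-reproducible
under a fixed seed.

**What the synthetic benchmarks do not show.** The generator produces
independent cells with stationary regimes and isotropic noise. Real
assays have cell–cell contact, division and death, segmentation/tracking
errors (identity switches, gap closing), regime switching within a track,
and spatially structured drift. Passing the planted-mixture and drift
round-trip tests therefore demonstrates that the estimators and the
analysis chain are correct and well-calibrated, not that any particular
biological dataset will separate as cleanly.

## Numerical choices and degenerate inputs

- Stationary tracks: progressivity 0; MSD slope, Hurst, α₂ undefined
  (NaN); occupancy 0.
- Median imputation precedes z-scoring; constant features are dropped
  from the state space (logged) and scale to 0 in group summaries.
- χ² without continuity correction (df is printed alongside).
- Tie-breaks: equally large fiducial components resolved by mean internal
  similarity; cluster identity fixed by mean total distance.
- Problem sizes used by the test suite and the acceptance script —
  200-track Brownian ensembles, 600-track PRW ensembles, 216 tracks per
  condition for mixture recovery, 120-track 3D scenes with 10 fiducials —
  were chosen so ensemble statistics sit well inside their asymptotic
  bands while a full run stays interactive on a laptop-class CPU.

## Known limitations

- The R/S Hurst estimator saturates near 0.9 for strongly persistent
  motion at 72-frame track lengths (three dyadic window sizes).
- Turning-angle features are deliberately absent from the battery.
- Drift correction is translation-only and assumes ≥ 2 usable fiducials
  with a shared frame range of ≥ 3 frames.
- t-SNE is not run when perplexity ≥ (n − 1)/3; small runs simply omit
  the embedding.
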