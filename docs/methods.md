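# Methods

This note documents the models, conventions and numerical choices behind
`cortnet`, and what the synthetic validation does and does not establish.

## Synthetic cortex

**Surfaces.** Two mesh families: a planar n×n grid (1 mm spacing, each
cell split along one diagonal) used for analytic distance oracles, and a
subdivided icosphere (radius 100 mm; 10·4^r + 2 vertices at subdivision
r) as the closed-surface stand-in for a hemisphere. Landmarks are
geodesic caps around configurable anchors — a point landmark at radius 0
— emulating the central, transverse temporal and calcarine sulci.
Anatomically realistic folding is out of scope; caps must be pairwise
disjoint.

**Parcellation.** Seeded multi-source region growing on the vertex
adjacency graph: parcel seeds are drawn uniformly without replacement and
claim unassigned neighbours in deterministic breadth-first waves, giving
spatially contiguous parcels; parcels are assigned round-robin to
networks. Identical seeds reproduce identical labelings byte for byte.

**Time series.** Each network n carries a latent AR(1) signal z_n(t)
with coefficient φ_n driven by unit-variance Gaussian innovations
(variance 1/(1−φ_n²)); a parcel of network k observes
x_p(t) = Σ_n M[k,n]·z_n(t) + σ·ε_p(t) with white observation noise.
A burn-in of 100 samples is discarded so initial transients do not bias
autocorrelation estimates. Per-(subject, run) generator streams are
derived from (seed, subject, run), so any subject subset is reproducible
in isolation. This is the minimal model exhibiting everything the
pipeline measures — per-network timescales, block covariance, and
condition-dependent coupling; it has no hemodynamic nonlinearity,
spatially correlated noise, or motion structure, so passing tests
establish correctness of the *methods*, not performance on real fMRI.

**Defaults (the simulated study conditions).** 8 networks (Visual,
Somatomotor, DAN-A/B, FPCN-A/B, DMN-A/B), 68 parcels, T = 400 samples at
TR = 1.5 s, 12 subjects × 2 runs. φ = (0.1, …, 0.8): a graded timescale
hierarchy from fast sensory to slow default-mode networks. σ = 1.0,
on the order of the latent signal SD: with weaker noise the networks
become near-perfectly separable, unlike real parcel data, and confusion
probabilities — the quantity the classifier analysis interprets — carry
no information.

**Coupling convention.** A scalar coupling c between networks a and b is
applied on the correlation scale with variance-preserving mixing:
network a observes √(1−Σc²) of its own standardized latent plus c of
each partner's, rescaled to its own latent SD (`make_coupling`). c is
then exactly the correlation between a's signal and b's latent. A naive
additive weight was rejected because it changes signal variance with c,
turning a strongly coupled network into a *distinct* cluster in feature
space rather than one resembling its partner, which destroys the graded
confusion structure the coupling is meant to produce. The two default
task conditions couple FPCN-A to DAN-A at 0.6 / FPCN-B at 0.3 ("wm") and
the reverse ("sem"); these effect sizes are package choices exposed in
config, not estimates from data.

**Task runs** add canonical-HRF-convolved boxcar regressors (task mean,
demeaned parametric modulator, per-trial-type, incorrect-trial nuisance)
scaled by per-parcel true effects to the background series. The HRF is
the double-gamma form (peak 6 s, undershoot 16 s, ratio 6, unit peak);
the same kernel is used by the GLM and the Wiener deconvolution, so
noiseless recovery is exact by construction.

## Geodesic distances

Multi-source Dijkstra on the mesh graph augmented with triangle-crossing
shortcuts: for every interior edge the two apex vertices of its adjacent
triangles are joined by a Euclidean-length edge. On a split grid this
adds both cell diagonals and knight-move edges; the worst-case error
versus the true planar distance is ≈2.8% (measured max 2.7% on a 50×50
grid), inside the documented 5% target. An exact polyhedral solver
(MMP/heat method) is deliberately not used: the downstream statistics are
means over parcels and networks, far coarser than the residual metric
error. Masked vertices (medial wall) are removed from the traversal
graph; unreachable vertices get distance ∞ and are excluded from
averages. Parcel means are unweighted over vertices, network means
unweighted over parcels.

## Diffusion gradients

Per row of the connectivity matrix the top 10% of entries are kept
(sparsity 0.9), negatives are clamped to 0 (a diffusion affinity must be
nonnegative; at 90% sparsity few negatives survive anyway), and the
matrix is symmetrized by transpose-averaging since row-wise thresholding
breaks symmetry. Anisotropic normalization with α = 0.5, eigensolution
via the symmetric conjugate of the row-stochastic operator, diffusion
time 0 (multiscale scaling λ/(1−λ)). Explained variance is each
eigenvalue over the sum of nontrivial nonnegative eigenvalues — a
convention, since diffusion embeddings have no canonical variance
decomposition. Component signs are fixed by nonnegative skewness before
any alignment. The trivial eigenvector is normalized by a scalar
(median) so the embedding stays defined when sparsification disconnects
the graph. Procrustes alignment is a pure rotation after column
centering, iterated 10 times against the running reference.

## Feature catalog and similarity

The frozen ~26-feature catalog spans moments (mean, SD, skewness,
kurtosis), autocorrelations at lags 1–10 plus first 1/e and first zero
ACF crossings, relative spectral power in low/mid/high frequency thirds
and the spectral centroid, permutation entropy (order 3), sample entropy
(m = 2, r = 0.2·SD, equal-template-count convention, incremental
Chebyshev matching), the time-reversal asymmetry statistic, lag-1
increment statistics, and a 5-window StatAv stationarity ratio. It is a
compact stand-in for exhaustive feature toolboxes: rich enough to
discriminate networks with distinct temporal structure, small enough
that every feature has a unit-test oracle. Normalization is the
outlier-robust sigmoid with the 1.35·IQR robust-sigma scale; zero-IQR
and partially missing features are dropped and logged. Feature
similarity is the Fisher z of the Pearson correlation between parcels'
normalized feature vectors, with |r| clipped at 1−1e−7 so duplicate
parcels stay finite. Network-pair averages exclude the diagonal, so a
single-parcel network has an undefined within-network entry.

## Classification

Linear one-vs-rest maximum-margin classification (C = 1, no class
weighting — imbalance is handled by the metric), stratified 5-fold CV
with runs of a subject concatenated as samples; features are already in
[0,1] so no re-standardization. Balanced accuracy is macro-averaged
recall, the multiclass generalization of the mean of sensitivity and
specificity. The permutation null shuffles labels over the pooled
samples and re-runs the full CV; p uses the (1+count)/(1+n) convention.
Train and test sets deliberately mix same-run and different-run samples,
as the null shares that structure. The feature-subset curve ranks
features by summed absolute weight from a full fit and re-runs CV on
top-k subsets.

## Interaction metrics

**Persistent redundancy.** Gaussian time-delayed MI, I = −½ln(1−ρ²),
evaluated at lag τ = 1 sample (τ is a free choice exposed in config; the
analysis is not sensitive to it under AR(1) latents). The redundancy is
the minimal-mutual-information double redundancy: the minimum of the
four lagged pairwise MIs. Only this redundancy atom is computed; the
full information decomposition (synergy/unique atoms) is out of scope.
HRF deconvolution (Wiener, regularization = noise_level) is applied to
task runs by default before redundancy, mirroring how the measure is
used on evoked data; rest runs are used raw.

**Adjusted FC.** The variance of the sample correlation of jointly
stationary Gaussian series is estimated by the Bartlett-type expansion
over sample auto- and cross-correlations (the k = 0 term collapses to
(1−r²)²; ±k terms combined symmetrically), truncated at ⌈2√N⌉ lags with
a Tukey taper, floored at 1/N if numerically nonpositive. The z score
is atanh(r) rescaled by the delta-method SE. Fidelity criterion is
calibration, not code-path equivalence with any particular reference
implementation: under independent AR(1) (φ = 0.5, N = 200) nulls the
measured |z|>1.96 rate is ≈0.05–0.07 versus ≈0.12–0.14 for the naive
√(N−3) z. Task runs are first cleared of mean evoked responses by FIR
regression (n_lags = ⌈trial duration / TR⌉ impulse regressors per
condition, collinear columns dropped in first-kept order, residuals
demeaned).

## Group inference

Two-sided t contrasts throughout; zero-variance paired differences with
nonzero mean are reported as degenerate at p < 1e−10. FDR is
Benjamini–Hochberg. The task GLM fits canonical-HRF regressors plus
intercept and linear drift per run, combines runs within subject by
inverse-variance-weighted fixed effects (equal weighting by option), and
tests the contrast across subjects with a one-sample t and FDR over
parcels.

**Max/min permutation test.** Task labels are exchanged within subject
(independent row permutations, jointly for all pairs); the max and min
pair-mean statistics per permutation form the null envelopes. Each
observed pair difference is referred to the symmetric envelope
max(max-null, −min-null): referring positive values only to the max-null
and negative only to the min-null — the construction sometimes described
for this test — doubles the two-sided family-wise error (measured ≈0.10
over 6 pairs); the symmetric envelope restores the nominal level
(measured 0.05 over 400 null replicates) while preserving the max/min
construction. FWE p values are therefore never anti-conservative
relative to single-pair permutation p values.

**QC rules.** A run is dropped when mean relative RMS FD exceeds
0.2 mm, more than 15% of frames exceed 0.25 mm, or behavioural accuracy
falls 3 SD below the group mean; a subject's task is dropped entirely if
only one run survives. The alternative ruleset flags runs with >25% of
frames above 0.2 mm and excludes subjects adverse in ≥2 of 4 summary
motion measures by the 1.5×IQR rule.

## Problem sizes and determinism

Tests and the acceptance script run at the default study scale
(68 parcels, 8 networks, T = 400, 12–27 subjects depending on the
analysis) with replicate counts of 20–400 and permutation counts of
200–2,000 chosen so each check resolves its target rate with adequate
Monte-Carlo precision. All generators and analyses are deterministic
given (seed, config); per-(subject, run) streams come from hashed seed
sequences.

## Known limitations

- The generator's white observation noise and block-constant coupling
  are idealizations; calibration results on real fMRI will differ.
- Geodesics are graph-based, not exact polyhedral; error is bounded and
  measured, not zero.
- The feature catalog is a curated surrogate, not a reimplementation of
  any exhaustive toolbox; absolute accuracy values are not comparable
  across catalogs.
- Gradient explained-variance ratios are an eigenvalue convention and
  should be compared only within this package.
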