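# Methods

This note documents the models, numerical choices and limitations behind
`interomap`, in the order data flows through the pipeline.

## Synthetic cohort model

Each subject's data is a voxels × frames matrix on a shared isotropic grid
(default 24³ at 3 mm; most shipped analyses use 16³ for speed). A voxel's
series is a weighted sum of latent signals plus confound leakage plus noise:

```
x_v(t) = Σ_L w_subj(L) · s_L(t) · [v ∈ support(L)]  +  c_v · C(t)  +  σ ε_v(t)
```

All latent signals `s_L` and the per-voxel noise `ε_v` are independent
stationary unit-variance AR(1) processes (default φ = 0.3), so filtering and
detrending act on signal and noise alike. The latent families are:

- **Cortical network signals** (2): each cortical seed loads on its network
  with mean 0.9; the two hub seeds (aMCC, dpIns) additionally load 0.25 on
  the other network. This realizes overlapping default-mode-like and
  salience-like subsystems that share hubs.
- **Subcortical cluster signals** (3): small lower-brainstem nuclei
  (LC, PBN, VSM), small upper-brainstem nuclei plus hypothalamus (PAG, DR,
  hypothalamus), and the larger nuclei (mdThal, LGN, hippocampus, dAmy,
  NAcc, SC, SN, VTA), loading 0.9. Each cluster also projects (amplitude
  0.5) to a disjoint 100-voxel cortical "territory", giving each cluster a
  distinct projection profile for the k = 3 recovery.
- **Network territories**: each network signal drives a disjoint 150-voxel
  non-seed territory at amplitude 0.5, giving discovery maps extent beyond
  the seed ROIs.
- **Private seed signals**: every seed has its own latent on its ROI
  (loading 0.7) and on a private 120-voxel territory (amplitude 0.5). This
  is essential realism: without seed-specific structure, same-network group
  maps are near-duplicates (η² ≈ 0.995) and the Calinski–Harabasz criterion
  degenerately prefers splitting hub seeds into singletons; real seeds always
  carry unique connectivity. With it, CH selects the planted k.
- **Edge latents**: every planted edge (a, b) with weight w adds a shared
  latent to both ROIs with per-subject loading ~ N(w, τ²) truncated at 0
  (τ = 0.1 for all loadings). Shared-latent coupling keeps the implied
  covariance positive semidefinite by construction.
- **System factors**: dense documented edge lists (50 and 75 edges) cannot
  be realized by independent per-edge latents alone — with d edges per seed
  the attainable per-edge correlation is capped near 1/d because each
  latent inflates the seed's variance. Scenario builders therefore model the
  densely interconnected system as a small set of broad shared factors
  (loading 0.6) computed as a greedy clique cover of the supported-pair
  graph: every supported pair shares at least one factor, while designated
  exception edges ("unsupported": anatomically documented pairs that must
  show no functional connectivity) share none, so their expected correlation
  is exactly zero. Small per-edge latents (w = 0.3) remain on top.

Confounds: three tissue signals (white matter, CSF, aqueduct; AR(1),
leakage amplitude 0.4 per voxel with standard-normal coefficients) and six
motion parameters simulated as random walks (translation step s.d. 0.03 mm,
rotation step s.d. 0.0008 rad). The step sizes were chosen so the framewise
displacement summary lands near typical resting-state values (FD mean
≈ 0.17 mm); leakage amplitude 0.2 per motion column. Because leakage is
linear in the recorded confounds, nuisance regression removes it exactly.

Defaults: n = 30 subjects, three 200-frame runs at TR = 1 s — large enough
for stable group t tests, small enough for desk-scale runtimes. Everything
is reproducible bit-for-bit from (config, seed); per-subject generators are
spawned from the cohort seed.

What the generator does **not** emulate: hemodynamic response shapes,
spatial autocorrelation of noise, susceptibility dropout, subject-specific
anatomy/registration error, or non-Gaussian motion artifacts. Passing tests
therefore demonstrate correctness of the analysis machinery and its
statistical calibration on a faithful-but-idealized signal model, not
robustness to every property of real 7T data.

## Signal conditioning

Order: nuisance regression → temporal filter → detrend + normalize, with
smoothing available as a separate volumetric operation.

- **Nuisance regression**: per-voxel least squares against the 9 confounds
  plus intercept; residuals are orthogonal to the design. Rank-deficient
  designs are rejected with the offending columns named.
- **Temporal filter**: order-2 Butterworth band-pass, 0.008–0.09 Hz
  (standard resting-state band), applied forward–backward (zero phase) and
  strictly within runs so no signal bleeds across run boundaries. An
  optional flag band-passes the confounds identically before regression
  (off by default, matching the regression-then-filter order).
- **Detrend/normalize**: per run and per voxel, linear detrend then scaling
  to unit sample variance; zero-variance voxels are zeroed and flagged, not
  fatal. The full chain is idempotent at this step.
- **Smoothing**: per-frame 3D Gaussian with σ = FWHM/(2√(2 ln 2)) converted
  to voxels, nearest-edge padding (constant volumes are unchanged).
- **Framewise displacement**: FD_t = Σ|Δtrans| + r·Σ|Δrot| with the 50 mm
  small-angle head-radius convention; frame 1 is defined 0 and excluded
  from the summary; "subvoxel" means FD below the active grid's voxel size.

## Mapping and inference

Correlations are clipped to |r| ≤ 1 − 1e-7 before atanh. Group inference
uses the exact Student t distribution (not a normal approximation; bootstrap
subsamples can be small). Zero-variance cells are flagged: p = 1 when the
mean is also 0, p = 0 (degenerate) otherwise. The bootstrap draws one
subject subsample per iteration, shared across all seeds, without
replacement (floor(f·n) subjects, f = 0.8); the consistency mask keeps
voxels with counts strictly greater than floor(0.95·B). No multiple-testing
correction is applied anywhere — consistency masking is the reliability
control, and matrix significance is deliberately uncorrected.

## Aggregation

η² between two maps is 1 − (within-pair SS)/(total SS about the grand mean
of both maps); identical maps give exactly 1 (short-circuited), two equal
constant maps are defined as 1, other zero-variance cases are NaN. k-means
runs on the rows of the η² matrix (each map represented by its similarity
profile; a raw feature matrix is accepted for direct map-vector clustering)
via scikit-learn's Lloyd algorithm with random centroid initialization,
`restarts` restarts and 1000 max iterations; CH is computed in the same row
space. Solutions with zero within-cluster scatter are scored CH = +∞ so the
smallest-k tie-break resolves perfectly separable inputs; ties always go to
the smallest k. The default η² input is the full-sample unthresholded t
map; consistency-count maps can be substituted via the pipeline.

Dice correspondence uses a parcel-level label permutation: parcel geometry
is fixed and parcel-to-network-label assignments are shuffled;
p = (1 + #{null ≥ observed})/(1 + n_perm). This is a volumetric substitute
for surface spin tests, appropriate because the package is volumetric
throughout; it preserves parcel size structure but not spatial
autocorrelation between neighboring parcels.

## Verification

An edge is confirmed by `matrix_significant` (group test positive and
p < α) or, failing that, by `map_cluster_only`: either seed's binarized
full-sample map, intersected with its bootstrap consistency mask, covers at
least max(1, ⌈5% of ROI size⌉) voxels of the other seed's ROI. The map tier
exists because a noisy averaged time course can miss a connection that a
subregion-level cluster still shows. Only positive connectivity confirms.
Percentages are rounded to integers (raw fractions are always reported
alongside).

## Problem sizes

The shipped acceptance tests run on a 16³ grid at 3 mm with the generator's
default cohort conditions (n = 30 subjects, three 200-frame runs) and
B = 150 subsampling iterations at the 95% criterion (cutoff > 142);
replicate loops use 20 cohorts. `scripts/acceptance.py` uses the same grid
and n but three 150-frame runs, because its majority-over-replicates
aggregation is insensitive to the occasional alpha-level false positive
that shorter runs leave room for, and the shorter runs keep the full sweep
comfortably inside desk-scale runtimes. Both regimes preserve the
statistical structure of the analysis (group t tests on 30 subjects,
24-subject subsamples). The statistical-calibration suite uses
250 null cohorts of 12 subjects × 60 frames with 6 seeds and conditions
with regression + normalization only, since a 0.008 Hz high-pass is not
meaningful on 60-frame runs and the group-level calibration under test is
filter-independent.

## Known limitations

- The edge-confirmation rule inherits the alpha-level noise of its
  components: each exactly-null edge has a ~2.5% chance of a false matrix
  confirmation, and for very small nuclei the default map-cluster floor of
  max(1, ⌈5% of ROI⌉) = 1 voxel lets a single cohort-level voxel fluke
  through the consistency cutoff (~2–3% per edge). Tallies over edge lists
  with several null exception edges therefore fluctuate by one edge between
  replicate cohorts; aggregate across replicates (as the acceptance script
  does) when an exact percentage matters.

- The CH criterion is intrinsically unstable for very small map sets when k
  approaches the number of maps; the package follows the convention of
  restricting k to at most n_maps − 1 and breaking ties toward small k, but
  selection among large k on near-duplicate maps should not be
  over-interpreted.
- The permutation Dice null treats parcels as exchangeable units and is not
  a spin test; spatial autocorrelation of parcel labels is not preserved.
- Confound removal assumes leakage linear in the recorded confounds (true
  for the generator; an approximation for real data).
- The verification scorer assumes the ROI geometry used for mapping matches
  the edge list's seed labels; it does not search subdivisions of ROIs.
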