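# Methods

## The analysis

`rsgfc` implements a change analysis for two-session resting-state fMRI
designs: one scan before (`rest1`) and one after (`rest2`) an intervention,
with the question "which brain regions changed their global functional
connectivity, and through which specific connections?"

Per subject and session, functional connectivity between parcels *i* and *j*
is the Pearson correlation `r_ij` of their cleaned signals, transformed to
`z_ij = arctanh(r_ij)` (Fisher Z, variance-stabilizing). For each parcel the
**global FC** statistics are row sums over the off-diagonal:

- `gFC_i  = Σ_{j≠i} z_ij`
- `gFC+_i = Σ_{j≠i, z>0} z_ij`, `gFC-_i = Σ_{j≠i, z<0} z_ij`

so `gFC = gFC+ + gFC-` holds exactly (zeros contribute to neither; that is a
measure-zero event pinned only so the identity is exact). Splitting the sum
avoids positive and negative correlations cancelling. Session change is
`ΔgFC = rest2 − rest1` per subject and parcel; a one-sample t-test across
subjects on each parcel's three change values, with FDR step-up control,
screens the whole brain. Two follow-ups qualify a hit:

- **Fixed-positive-set validation.** `ΔgFC+` can change because different
  edges are positive in each session. The validation freezes the set of
  parcels whose FC with the seed is significantly positive (two-tailed
  p < α = 0.05, uncorrected, positive mean z) in *both* sessions, then
  re-tests the change of the seed's summed z restricted to that set. Every
  member edge is summed regardless of its per-subject sign — per-subject sign
  filtering would reintroduce exactly the variable-support problem the
  validation removes.
- **Seed edge screen.** All P−1 connections of the seed parcel are tested
  individually (paired Δz, one-sample t, FDR over the P−1 family) to
  individuate contributing connections. The whole-brain edge screen (all
  P(P−1)/2 edges) is also provided; with ~10⁵ edges and n = 44 it is
  expected to be null, which is the motivation for the gFC summary statistic.

### FDR

Both Benjamini–Yekutieli (BY, valid under arbitrary dependence; thresholds
`i·q/(m·c(m))` with `c(m) = Σ 1/j`) and Benjamini–Hochberg (BH) step-up
procedures are available; BY is the default, BH the option. Note the two can
disagree materially: at m = 462 and q = 0.05 the first-rank BY threshold is
1.6e-5 versus BH's 1.1e-4, so a single edge at p = 1e-4 survives BH but not
BY. The gFC screen's FDR family is per-measure (three corrections of family
size P) by default, with a pooled 3P-family switch; the per-measure reading
is the more common one for "three change values per parcel" but neither is
asserted as canonical.

### Statistics

One-sample t: `t = mean / (sd/√n)`, df = n−1, two-tailed central-t p.
`t_from_summary` recomputes the same statistic from reported (mean, SD, n)
summaries. Welch's t for group contrasts. Spearman rank correlation (average
ranks for ties, p via the t approximation — standard at the n = 21–60 range
these designs have) for brain–behavior associations, with BY adjustment
applied within declared association families; raw p is always reported
alongside the adjusted value because single associations are conventionally
also read uncorrected. Behavioral missingness is handled by
pairwise-complete deletion with the n used always reported, never imputed.

## Preprocessing

Fixed stage order, enforced by provenance flags (re-running a stage is an
error): trim → band-pass → (parcellate, voxel input only) → nuisance
regression.

- **Trim:** drop the first 6 volumes (T2* equilibration), so a 6-min scan at
  TR = 3 s keeps 114 of 120 volumes.
- **Band-pass:** ideal (FFT bin-zeroing) filter to 0.01–0.08 Hz, two-sided,
  per column, after demeaning; a bin exactly on a band edge is kept. The
  ideal filter is the dialect of the standard resting-state toolboxes and
  makes the contract bit-exactly testable.
- **Parcellation:** mean signal over a parcel's gray-matter voxels; parcels
  sharing fewer than 5 voxels with the gray-matter mask are excluded.
- **Nuisance regression:** OLS residual on [intercept | 6 motion params | WM
  | CSF], optionally a global channel. Confounds are trimmed and band-pass
  filtered identically to the signals before regression, so regression cannot
  reintroduce out-of-band variance; the source pipelines are silent on this
  and filtering confounds is the standard defensive choice.
- **Motion QC:** framewise displacement per Power (sum of absolute
  translation steps plus rotation steps converted to arc length on a 50 mm
  sphere, degrees→radians; FD₁ = 0), and a hard exclusion when any volume
  deviates from the session's first volume by strictly more than 2 mm
  translation or 2° rotation.

Degenerate parcels (zero variance after cleaning) are flagged and carried,
never silently dropped; correlation on them is a loud error.

## The synthetic generator

The generator emulates the target study's design — 44 subjects × 2 sessions
× 463 parcels × 114 retained timepoints at TR = 3 s — with full ground truth,
so every downstream stage is testable without fMRI data.

- **Baseline network:** block-community correlation structure, 8 communities,
  within-community r = 0.4, between r = 0.05 — values in the range typical of
  functional parcel correlation matrices; a `random_sparse` alternative
  exists. All planted specs are repaired to the nearest PSD correlation
  matrix by eigenvalue clipping at zero plus diagonal rescaling (simplest
  repair with a verifiable bound; construction fails loudly if the repair
  moves a planted edge by more than 0.01).
- **Planted effect:** session 2 equals session 1 with selected seed-node
  edges shifted on the Fisher-Z scale, `r → tanh(arctanh(r) + δ_z)`, because
  the analysis operates in Fisher-Z units. Focal mode shifts named edges;
  diffuse mode shifts a fraction (default 30%) of the seed's edges. The
  default per-edge δ_z = 0.04 matches the scale implied by a restricted-set
  change of ≈ 5.7 z-units spread over ≈ 145 edges; the focal study condition
  uses δ_z = 0.17 with between-subject SD 0.15, which reproduces an
  across-subject SD of the sampled edge change of ≈ 0.26 at 114 timepoints.
  Each subject draws one shift `N(δ_z, subject_sd_z)` shared by all planted
  edges (session 2 only); baseline structure is shared across subjects — the
  minimal heterogeneity model sufficient for power and FDR calibration.
  Per-subject repair is best-effort (no 0.01 gate): a rare large draw may be
  slightly attenuated by the PSD projection.
- **Temporal model:** stationary Gaussian AR(1) with lag-1 coefficient 0.3
  (moderate BOLD autocorrelation at TR = 3 s; no hemodynamic model), with
  innovation covariance chosen so the stationary cross-correlation equals the
  target matrix exactly.
- **Nuisance:** motion random walks (step SD 0.02 mm/°), AR(1) WM and CSF
  series, and a slow scanner-drift component (linear trend plus random-phase
  cosines below 0.008 Hz), mixed into the parcels through random loadings at
  a configurable amplitude (default 0.5 × neural SD). Drift is deliberately
  *not* a confound column: filtering and regression then remove
  complementary artifacts, which is what the preprocessing-synergy property
  verifies.
- **Determinism:** everything derives from one integer seed through spawned
  generator streams; identical specs give byte-identical serialized datasets.

What the generator does **not** emulate: voxel-level spatial structure and
smoothing (beyond an optional trivial label-replication path for the
parcellation code), physiological noise spectra (cardiac/respiratory),
non-Gaussian BOLD features, distance-dependent motion artifacts, and
session-order effects other than the planted shift. Passing tests therefore
demonstrate correctness of the statistics and calibration under a
second-order-accurate model of resting-state data, not robustness to every
artifact of real fMRI.

## Study sizes and calibration

Replicate studies (null calibration and power) run on a scaled design of
44 subjects × 100 parcels × 114 timepoints with zero nuisance amplitude and
no lead volumes, going straight from generated signals to correlation — on
zero-nuisance data the cleaning chain is a near-identity, and the smaller
parcel count keeps hundreds of replicates cheap. The acceptance checks use
200 null replicates (family false-positive rate ≤ 0.10 at q = 0.05) and 60
replicates per power condition.

Power thresholds were fixed by a single calibration run before the test
suite was finalized and not revisited: diffuse-effect seed detection on
ΔgFC+ of ≥ 0.40 at per-edge δ_z = 0.10 (observed 0.59), monotone in δ_z over
(0, 0.05, 0.10); focal-edge (δ_z = 0.17) seed-scope detection ≥ 0.70
(observed 0.85) and strictly more detections than the whole-brain screen on
the same data (observed 0.42). The δ_z = 0.05 diffuse operating point is
deliberately weak under BY over 100 parcels (observed 0.04) and serves only
the monotonicity check.

## Numerical choices

- Fisher-Z clamp: |r| ≥ 1−1e-7 is clamped before arctanh (z ≈ ±8.1), counted
  on the matrix; realistic data never reach it, degenerate synthetic cases
  can.
- The connectivity diagonal is NaN and excluded from every sum.
- Zero-SD test units in the gFC screen (e.g. an all-zero `gFC-` column when
  every edge is positive) get NaN statistics and are excluded from the FDR
  family instead of aborting the screen; `one_sample_t` called directly on a
  degenerate sample still raises.
- Motion exclusion uses strict inequality (">") and deviation from the first
  volume.
- "Increased" seed edges are counted by comparing per-session group t values
  (t₂ > t₁), matching a t-vs-t scatter construction, not raw means.

## Known limitations

- The whole-brain edge screen materializes a subjects × P × P array
  (~75 MB at P = 463); fine at this scale, not designed for P ≫ 10³.
- The fixed-positive-set α = 0.05 (uncorrected, two-tailed) is a selection
  heuristic, not an error-controlled procedure; it is only ever used to
  define a validation set, never to claim significance.
- The generator's between-subject variability lives only on planted edges;
  baseline connectivity is homogeneous across subjects, so between-subject
  gFC variance is smaller than in real cohorts.
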