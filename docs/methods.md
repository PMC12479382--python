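# Methods

`fcgrad` implements a parcel-level resting-state fMRI analysis chain for
a two-group (drug / placebo), two-session (pre / post intervention)
design: scan-level denoising, functional-connectivity (FC) metrics,
diffusion-map cortical gradients with Procrustes alignment and network
dispersion, the four pre/post x drug contrasts with BH-FDR correction,
and OLS brain-behavior association models. A synthetic-cohort generator
plants every statistical structure the analysis assumes, so the whole
chain is verifiable end to end without any imaging data.

## Denoising

Each scan is a frames x parcels matrix with TR = 1.8 s (240 frames by
default). The chain runs in a fixed order:

1. **Spike identification.** Frames with framewise displacement
   strictly greater than 0.5 mm are flagged. One indicator regressor
   per flagged frame is added, and the frames are deleted after
   regression and filtering, before any correlation.
2. **Nuisance regression.** The design contains an intercept, the
   Friston-24 motion expansion (6 rigid-body parameters, their
   one-frame-lagged copies with the first frame backfilled with 0, and
   the squares of both sets), the leading principal components of
   externally supplied noise channels up to 50% cumulative variance
   (component-based physiological correction; at parcel resolution
   there are no white-matter/CSF voxels, so the noise channels are an
   explicit input and the synthetic generator emits dedicated ones),
   the spike indicators, and optionally the global mean signal (GSR).
   Rank-deficient designs are solved by pseudoinverse; residuals are
   orthogonal to every regressor by construction.
3. **Band-pass filtering.** Zero-phase frequency-domain masking of
   0.008–0.09 Hz with a 2-bin raised-cosine taper at each band edge and
   the DC component removed. A frequency-domain mask was chosen over an
   IIR design because its response is exact and directly testable.

The **continuous** nuisance regressors (motion, components, global
signal) are band-passed with the same filter before regression.
Regressing unfiltered confounds against filtered data reintroduces
out-of-band variance, so without this step a second application of the
chain would measurably shift FC; with it, the chain is idempotent up to
the edge taper (whose gain g becomes g² on re-application — a vanishing
fraction of the pass band as frequency resolution grows). Spike
indicators stay impulses because their frames are removed outright.

## Connectivity

All correlations are Pearson r over retained frames, capped at
|r| ≤ 1 − 1e−5 (so exact duplicates give a finite Fisher z ≈ 6.1; cap
hits are counted and surfaced as QC), then Fisher z-transformed.
Metrics: the full parcel x parcel matrix; per-network seed maps
(correlation of every parcel with a network's unweighted mean series —
the weighted-GLM formulation reduces to bivariate correlation for a
single continuous resting condition, and an optional per-frame weight
vector is accepted for forward compatibility); within-network FC (mean
of the seed map over the network's own parcels, own-network parcels
included); the 6 x 6 between-network matrix of network-mean-series
correlations; and per-parcel global FC (row mean excluding the
diagonal). Six networks are analyzed — VIS, ASM, DAN, SAL, FPN, DMN —
with the limbic network excluded for its low reproducibility and
signal-to-noise ratio.

## Gradients

Per scan: (1) row-wise thresholding of the Fisher-z matrix keeping the
ceil(0.10 · (P−1)) largest off-diagonal entries per row (40 of 399 at
P = 400), ties broken toward the lower parcel index, result left
asymmetric; (2) cosine similarity between thresholded rows, negative
similarities clipped to 0 (the Markov normalization needs a
nonnegative kernel) with the clipped count surfaced; (3) diffusion-map
embedding with density normalization α = 0.5: W′ = D^−α W D^−α,
M = D′^−1 W′, eigendecomposition via the symmetric conjugate
D′^−1/2 W′ D′^−1/2, trivial constant eigenvector dropped, component c
scaled by λ_c/(1−λ_c) (diffusion time 0), variance explained
λ_c / Σλ over the 10 computed components. A disconnected similarity
graph is an error that advises raising the density — at toy parcel
counts (≤ ~50) the 10% threshold keeps so few edges per row that a
denser threshold (we use 0.35 at P = 24) is required.

Ten components are computed; the first three are analyzed. Embeddings
are aligned by Procrustes rotation (orthogonal, reflections allowed,
**no scaling** — scaling would distort dispersion magnitudes) to a
group template built from all baseline (pre) scans: start from their
mean, align everyone to it, replace the template with the mean of the
aligned embeddings, iterate 10 times. The mean squared Frobenius
disparity is recorded per iteration and is non-increasing (both the
rotation step and the mean update decrease the generalized-Procrustes
objective). Dispersion in the 3-D gradient space: within-network = sum
of squared Euclidean distances of the network's parcels to the network
centroid; between-network = Euclidean distance between centroids.

## Contrasts and associations

Four named contrasts over any per-scan metric:

- **Synergy** (group-by-time interaction): two-way repeated-measures
  ANOVA, computed through the exact 2x2 decomposition — the
  interaction F equals the squared pooled two-sample t on per-subject
  (post − pre) differences; the time and group main effects are the
  unweighted-mean-change t and the t on subject means. This is
  Type-III sums of squares and remains exact under the study's 20/19
  imbalance.
- **GroupPost**: between-group ANCOVA of post scores with the pre
  score as covariate (OLS, group-coefficient t, df = n − 3).
- **Meditation** / **PsychMed**: within-group change tests — the
  description "baseline values of the other group included as
  covariates" cannot hold literally (a covariate must vary within the
  modeled rows), so these are implemented as (post − pre) ~ intercept +
  centered within-group baseline, testing the intercept. This reading
  is a recorded choice, not an inference of intent.

Multiplicity: Benjamini-Hochberg step-up within each metric family
(15 network pairs, 6 networks, or all parcels), with q-values made
monotone by the reverse cumulative minimum. Parcel-level BH-FDR
deliberately replaces voxel-level Gaussian-random-field cluster
inference, which needs smoothness estimates that do not exist at
parcel resolution; this is a prominent non-goal, not an approximation
of it. Tests are two-sided; α and q default to 0.05.

Brain-behavior: OLS of a per-subject FC change on questionnaire score,
group, and their interaction, with BH correction across the
questionnaire family (five questionnaires by default) and per-group
Pearson/Spearman follow-ups; "delta mode" replaces the day-2 score
with day-2 minus day-1 (baseline). An exact fit (zero residual
variance) resolves the 0/0 t-statistic to t = 0, p = 1 when the
coefficient is itself zero.

## Synthetic cohorts

`simulate_cohort` draws every scan from a zero-mean multivariate
normal with a block covariance: ones on the diagonal, a within-network
coupling w inside each network block, and between-network values
derived from the target **network-mean correlations**. This
parameterization is the load-bearing choice: averaging k parcels with
within-coupling w gives the mean series variance v = (1 + (k−1)w)/k,
so a parcel-block value of b·sqrt(v_a v_b) makes the correlation
between the two network means come out exactly b. Planted couplings
and injected group x session deltas therefore have exact closed-form
truth on the scale the analysis actually measures.

Temporal smoothness is an AR(1) filter (φ = 0.3 by default) applied
identically to every parcel with innovation scaling sqrt(1−φ²) and a
stationary start, which preserves all planted cross-correlations
exactly. FD traces are |N(0.15, 0.05)| mm with 3% spike probability of
magnitude +0.8 mm (so spikes exceed the 0.5 mm scrub threshold);
motion parameters are small random walks; both are independent of the
signal. Questionnaire scores are linear-Gaussian in the subject's
planted atanh-scale FC change with group-specific slopes. Group sizes
default to 20/19; defaults are 400 parcels allocated across the six
networks proportionally to a standard 400-parcel/7-network cortical
parcellation with the limbic network removed, 240 frames, TR 1.8 s.
Coupling defaults (w = 0.25, b = 0.05) are chosen for test power — the
source study reports no empirical per-network FC distributions — and
an identical seed reproduces a cohort bit for bit.

`simulate_gradient_connectome` plants gradient geometry directly in an
FC matrix. The `line` geometry places parcels on a 1-D coordinate with
exponentially decaying connectivity. The `two_block` geometry is two
equal blocks (within r = 0.6, between r = 0.05) plus a small set of
hub parcels per block (~6% of parcels, elevated coupling to their
block, hubs cohering more strongly among themselves) of which two per
block bridge to the opposite block at moderate strength. The hubs are
essential, not decorative: with homogeneous blocks, top-10%-per-row
thresholding keeps only within-block edges, the thresholded rows of
the two blocks have disjoint supports, every cross-block cosine
similarity is exactly zero, and the similarity graph is provably
disconnected. Hubs concentrate each row's strongest edges on a shared
support — as hub regions do in real connectomes — and the bridges keep
the graph connected while the first gradient still separates the
blocks with full sign purity.

### What the generator does not emulate

No hemodynamic response, no voxel/surface geometry, no spatially
structured or physiological noise, no coupling between motion and
signal, and Gaussian marginals throughout. Passing recovery tests
therefore demonstrates that the analysis correctly extracts the
statistical structures it claims to measure — block covariance,
gradient axes, group x time effects, score-FC interactions — under the
study's design and noise scale, not that it is robust to artifacts of
real BOLD acquisition.

## Numerical choices

- Correlation cap 1e−5 before atanh; counted and reported.
- Eigen-solver: LAPACK `eigh` on the symmetric conjugate; eigenvalues
  clipped to [0, 1−1e−12] before the λ/(1−λ) scaling.
- Threshold ties toward the lower parcel index; retained count uses
  ceil.
- Constant-parcel detection by exact peak-to-peak (a constant column's
  floating-point standard deviation is not exactly zero).
- Covariance feasibility is validated per design cell up front by
  Cholesky; infeasible injections are rejected naming the cell and the
  injections in play.
- TSV writers use `%.10g`; identical config + seed gives byte-identical
  outputs.

## Problem sizes in simulation checks

Calibration and recovery simulations run at 12 parcels (two per
network), 240 frames, n = 20 per group, FD scrubbing active: the
group-level interaction statistic operates on per-subject network-mean
Fisher-z values, and parcel count affects only the noise level of the
network means, so two parcels per network exercises the identical
inferential path at a fraction of the cost. Null calibration uses 500
replicate cohorts; effect recovery 200. The Procrustes cohort check
uses 20 scans of 24 parcels with threshold density 0.35 (see above on
connectivity at toy parcel counts).

## Known limitations

- Voxel/surface analyses (seed-to-voxel maps, cluster inference,
  surface rendering) are out of scope by design.
- The within-group ANCOVA reading is one of several defensible
  interpretations of the source description (see above); results for
  those two contrasts depend on it.
- Whether within-network averages should include the seed's own
  contribution voxel-wise is unknowable at parcel resolution; the
  parcel-level analog includes own-network parcels.
- Variance explained is computed over the 10 retained components; a
  full-spectrum convention would give smaller fractions.
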