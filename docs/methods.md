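# Methods

`parcelfit` implements a complete, desk-scale version of a whole-brain
dynamical-modeling study: personalized oscillator network models are derived
from parcellation-level connectome data, fitted to functional and structural
connectivity by exhaustive grid search, and the variability of the resulting
goodness of fit is analyzed across subjects and parcellations.  Because real
multi-subject imaging data is out of scope, the package ships a synthetic
cohort generator whose outputs have the statistical shape the analysis
expects and, crucially, a known ground truth.

## Models

Two network models of regional BOLD dynamics are supported, both coupled
through the subject's structural connectome with heterogeneous conduction
delays and driven by additive uniform noise.

**Phase model** (Kuramoto type). For regions j = 1..N,

    dphi_j/dt = 2 pi f_j + (C/N) sum_n w_jn sin(phi_n(t - tau_jn) - phi_j(t)) + eta_j,

with BOLD observable x_j = sin(phi_j).  Only synchronization structure is
modeled; amplitudes are uniform.

**Limit-cycle model** (normal form of the supercritical Hopf bifurcation).
For complex states z_j = x_j + i y_j,

    dz_j/dt = (a_j + i 2 pi f_j - |z_j|^2) z_j
              + (C/N) sum_n w_jn (z_n(t - tau_jn) - z_j) + xi_j,

with observable x_j = Re(z_j).  For a_j > 0 the uncoupled oscillator settles
on a limit cycle of radius sqrt(a_j); a_j < 0 puts the region in the
subcritical, noise-driven regime.  (The amplitude parameter controls the
squared radius scale; the stable orbit radius is sqrt(a_j), which follows
directly from the radial equation r' = (a - r^2) r.)

Two global parameters are fitted: the coupling strength C and the global
delay tau (equivalently a propagation velocity V = <L>/tau).

## Personalized model derivation

Per subject and parcellation:

- **Weights** w_jn = k_jn / <k>, with k_jn the streamline count and <.> the
  ensemble mean over the zero-diagonal N x N matrix.  The default divides by
  N^2 (the zero diagonal counts toward the denominator); a
  `mean_convention="offdiag"` switch divides by N(N-1) instead.  Diagonal
  weights are zero (no self-coupling).
- **Delays** tau_jn = tau * L_jn / <L> with L_jn the mean streamline path
  length, discretized to integration steps by round-half-to-even.
- **Frequencies** f_j: the largest ordinate of a single, untapered FFT
  periodogram of the mean-removed concatenated BOLD signal, restricted to
  the resting-state band [0.01, 0.1] Hz.  Concatenated rather than
  per-session data is used because it gives four times the spectral
  resolution; no Welch averaging or multitaper smoothing is applied.
- **Amplitudes** a_j: the regional temporal standard deviations of the
  concatenated BOLD, affinely standardized so that across regions
  mean(a) = 0.5 and population SD(a) = 0.4 exactly.  Population (not sample)
  SDs make the moment contract exact.  If all regional SDs coincide the
  calibration is degenerate; all a_j are set to 0.5 with a warning rather
  than raising, so toy fixtures remain usable.

## Numerical integration

The stochastic Heun scheme with fixed step dt = 0.06 s integrates both
models; production runs last 4000 s with the first 500 s discarded as
transient.  Delayed states are read from a circular history buffer at
integer step offsets; the buffer is pre-filled with the (random) initial
state, i.e. constant history.  Initial phases are uniform on [0, 2 pi);
initial limit-cycle states are uniform in the complex unit disk.

Noise is drawn per step and region, uniformly in [-0.3, 0.3] (for the
limit-cycle model independently for the real and imaginary components), and
added after the Heun corrector scaled by sqrt(dt) — the diffusion
interpretation.  A `noise_convention="dt"` flag scales by dt instead (the
literal ODE-term reading); the convention affects the effective noise
intensity but not the qualitative dynamics, and the default is the one
consistent with an SDE interpretation of the noise term.

Non-finite states (possible for the limit-cycle model when an explicit step
overshoots the cubic nonlinearity, e.g. extremely large a_j or coupling)
raise a divergence error naming the parameter point; during grid fitting
such points are logged, stored as missing, and excluded from the optimum.

One practical stability note: with dt = 0.06 s the explicit scheme requires
C/N * max(w_jn) well below 1/dt.  Lognormal weight tails mean that extreme
couplings (far outside the fitted grid) can destabilize the phase model
numerically; the fitted grid range is safely inside the stable region.

## Grid-search fitting

Simulated FC (sFC) is the Pearson correlation matrix of the retained
observables at every integration step.  The similarity between sFC and a
target matrix is the Pearson correlation of their strictly upper triangular
parts, and the goodness of fit per target is

    Fit(sFC, target) = max_(tau, C) corr(sFC, target)

over a grid of (tau, C) values.  The default grid has 48 uniformly spaced
tau values on [0, 94] s (step 2) and 64 C values on [0, 0.945] (step 0.015).
Each subject's six targets (four session FC matrices, the concatenated FC,
and the streamline-count matrix) are evaluated from the same simulation at
each grid point — one stochastic realization per point, with the seed
derived deterministically from (base seed, subject rank, model, grid
indices) so planes are reproducible and cohort results are independent of
input ordering.  Argmax ties are broken by scan order (tau ascending, then C
ascending); the five best points are retained per plane.

## Synthetic cohorts

The generator emulates the statistical shape of a parcellation-level
resting-state dataset:

- **Parcellation hierarchy.** `n_fine` "finest units" (stand-ins for voxel
  clusters) are placed uniformly in a 140 x 180 x 120 mm box and merged by
  Ward clustering of their coordinates; cutting the single dendrogram at
  each requested granularity yields nested levels, mimicking atlas
  granularity variation.  Region centroids are member means; sizes are
  member counts.
- **Structural connectome.** Streamline counts follow
  log k ~ Normal(log(count_scale) - d/decay_length, 0.8) with d the
  centroid distance (defaults: count_scale 500, decay length 30 mm),
  rounded to integers and symmetrized — a heavy-tailed, distance-decaying
  law matching tractography phenomenology, not a fit to any dataset.  Path
  lengths are centroid distances with 10% multiplicative lognormal noise.
- **Subjects.** Each subject receives multiplicative lognormal jitter
  (sigma 0.2) on the upper-triangular counts and lognormal jitter
  (sigma 0.1) on a shared regional frequency profile drawn uniformly from
  [0.02, 0.09] Hz; limit-cycle amplitudes are drawn Normal(0.5, 0.4).
  These random effects are what give the downstream fit statistics their
  inter-subject variance.
- **BOLD.** The ground-truth model is simulated on the subject's own
  network at a known (tau*, C*); the observable is downsampled from
  dt = 0.06 s to TR = 0.72 s by taking every 12th retained sample (exact
  integer ratio, no interpolation) to give 4 sessions of 1200 volumes.
  Gaussian measurement noise with SD equal to 0.5 times each region's
  signal SD is added.  Five empirical-style FC matrices (4 sessions +
  concatenated) are computed per subject.

What the generator does **not** emulate: hemodynamics (no Balloon-Windkessel
forward model — BOLD is the oscillator observable directly, as in the
modeled study), spatial autocorrelation of measurement noise, scanner
drifts, motion artifacts, anatomical asymmetries, or any empirical SC count
distribution.  Passing tests therefore demonstrate the internal consistency
and statistical machinery of the pipeline, not its behavior on real imaging
data.

## Data variables and statistics

Seventeen per-subject scalar indices are computed (regional BOLD fluctuation
statistics; column-wise mean/SD statistics of FC and of the mean-normalized
SC and path-length matrices; upper-triangular correlations among the three
connectivity matrices; mean/SD of the natural frequencies).  Column
statistics exclude the diagonal so that aver(eFC) is a region's average
connectivity to the rest of the brain; population SDs are used throughout.

The variability analyses provide: pairwise Pearson correlation of
Fit patterns between parcellations with Fisher-z intra-/inter-atlas means;
one-sided paired Wilcoxon signed-rank matrices (alternative
Fit(row) > Fit(column)) with Bonferroni correction (Holm available) and
matched-pairs rank-biserial effect sizes; per-parcellation/joint/group-median
variable-fit correlations with an intra/inter/both/neither classification
(margin delta = 0.1, floor 0.3, significance alpha = 0.05, all configurable
and reported); OLS regression of Fit on z-scored variables; and Euclidean
distances between grid-normalized optima (tau/94, C/0.945).

The signed-rank p-value uses the exact null distribution for n <= 25 pairs,
enumerated by convolution over doubled midranks so ties are handled exactly;
larger n uses a normal approximation with tie and continuity correction.

## Desk-scale study sizes

The default test and example runs are deliberately small so the whole
pipeline executes on one CPU in minutes: cohorts of 2-6 subjects, networks
of 8-48 regions, reduced grids of 4-192 points, and 600 s fitting
simulations (100 s transient).  The parameter-recovery study uses 40-region
subjects generated at (tau*, C*) = (6 s, 0.3) under the phase model and a
reduced 12 x 16 grid (tau 0..22 step 2; C 0..0.9 step 0.06).  C* is placed
in the partially synchronized regime: below the synchronization transition
the FC pattern only sharpens as C grows, so the similarity-vs-C profile is
monotone and the coupling is not identifiable from the FC pattern alone.

## Known limitations

- **Frequency-derivation circularity.** Natural frequencies are estimated
  as BOLD spectral peaks, but in coupled data those peaks are shifted toward
  the entrained cluster frequencies.  On synthetic subjects this compresses
  the estimated detuning relative to the generating frequencies, so the
  refitted model synchronizes at a lower coupling and the fitted C is
  biased downward by one to two grid steps.  The recovery study therefore
  fits with the generator's recorded regional parameters to isolate the
  (tau, C) estimator; with estimated frequencies, tau is still recovered
  well but C localization degrades.  On real data the same circularity is
  present and invisible — there is no ground truth — which is worth keeping
  in mind when interpreting fitted couplings.
- A single stochastic realization per grid point (the protocol's choice)
  makes similarity planes noisy at desk-scale simulation lengths; optima
  from short runs should be read as one-grid-step estimates.
- The independent-hierarchy contrast used in the analysis-structure checks
  compares a nested refinement against a partition from an unrelated
  clustering of different random coordinates; the latter is spatially
  incoherent with respect to the cohort's geometry.  At desk scale the
  nested-versus-independent gap in Fit-pattern correlations is modest and is
  carried by shared-refinement aggregation overlap: it shows for
  granularity-matched comparisons (nested 24-to-12 versus cross-hierarchy
  24-to-12) but washes out when same-granularity independent partitions are
  added, because any partition of the same subjects' units preserves subject
  identity.  Real atlas families share construction traits (region-size
  profiles, spatial layout philosophy) that the generator does not model,
  so the synthetic analog understates the atlas-family effect seen in
  empirical work.
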