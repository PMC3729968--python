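# Methods

`megconn` re-creates, end to end and with known ground truth, a
resting-state MEG functional-connectivity analysis of the kind used to
compare clinical groups: source reconstruction by beamforming onto an
atlas, phase-lag-index (PLI) connectivity in six frequency bands,
whole-brain / per-ROI / resting-state-network (RSN) summaries, and a
nonparametric, hierarchy-gated statistical battery.  Because clinical MEG
recordings cannot be shipped, every stage is exercised on a synthetic
cohort whose coupling structure and covariates are generated with
controllable, analytically checkable parameters.

## Connectivity measure

For two band-limited signals with instantaneous phases φ_x, φ_y (analytic
signal per epoch, after zero-phase band-pass filtering), the phase-lag
index is

    PLI = | ⟨ sign(Δφ) ⟩ |,   Δφ = φ_x − φ_y wrapped to (−π, π],

the absolute time-average of the sign of the wrapped phase difference.
PLI = 0 for a symmetric phase-difference distribution — in particular for
exactly zero lag, the signature of field spread / volume conduction — and
1 for a consistent non-zero lag.  sign(0) contributes 0, so identical
signals give exactly 0.  The PLI is computed per epoch over the first five
epochs and averaged; the first and last 1/(2·lo) seconds of each epoch
(lo = band low edge) are excluded to suppress filter and analytic-signal
edge transients.  For independent phases over m retained samples the
estimator concentrates near √(2/(πm)) (mean absolute value of an average
of m iid ±1 signs), which the surrogate tests check by Monte Carlo.

Bands: delta 0.5–4, theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30,
gamma 30–48 Hz.  Filters are Butterworth band-passes designed by
`buttord` for <1 dB passband ripple and >40 dB attenuation at band edges
±25% after forward–backward (`sosfiltfilt`) application.  An epoch
shorter than three nominal impulse responses (one impulse response taken
as fs/lo samples, the period of the low edge) is rejected.

Summaries per subject, band: the 78×78 adjacency matrix (3003 unordered
pairs); node strength = mean off-diagonal row entry (divisor n−1, the
structural zero diagonal excluded); whole-brain mean = mean node strength
= mean over all pairs; RSN mean = mean over the N(N−1)/2 within-network
pairs (the natural reading of "mean PLI within an RSN"; no other
normalization).

## Atlas and RSNs

The 78 cortical ROIs are the AAL 90-label cerebral parcellation minus the
12 subcortical labels (bilateral hippocampus, amygdala, caudate, putamen,
pallidum, thalamus).  The shipped RSN memberships (default-mode, left and
right fronto-parietal, executive, sensorimotor, temporo-parietal, visual)
are best-effort reconstructions of the literature-based networks, with
the two conventional uniqueness modifications (superior parietal gyrus in
place of the precuneus in the fronto-parietal networks; inferior frontal
gyrus split between the temporo-parietal and fronto-parietal networks).
No ROI belongs to two networks, so within-network connections are
pairwise unique.  Memberships are configuration (JSON), not ground truth.

## Forward and inverse model

Geometry is synthetic: a homogeneous conducting sphere (default radius
9 cm), radially oriented magnetometers on a helmet-like cap at 12 cm, and
ROI voxel clusters on an interior shell.  The lead field is the closed
form for a current dipole in a conducting sphere; radial dipoles are
exactly silent, which both constrains source orientations to the
tangential plane and provides a sharp unit test.  An independent check
exploits the fact that volume currents contribute no radial field: for
radially oriented sensors the sphere field must equal the free-space
dipole field's radial component, a second closed form coded separately.

The inverse operator is a scalar (SAM-style) linearly constrained
minimum-variance beamformer: weights w = C⁻¹l / (lᵀC⁻¹l) with unit gain
wᵀl = 1 at the target voxel, computed from the broadband (0.5–48 Hz) data
covariance pooled over all epochs.  The dipole orientation at each voxel
is chosen in the tangential plane to maximize pseudo-power
1/(l(u)ᵀC⁻¹l(u)), a 2×2 eigenvalue problem in the tangential basis.
Regularization is diagonal loading, C + reg_fraction·mean(diag C)·I with
reg_fraction = 0.05 by default; weights remain finite for any
reg_fraction > 0 even with rank-deficient covariance, and a singular
regularized covariance raises an error naming the parameter.  Per ROI and
band, the member voxel with maximum band power (variance of the
band-passed series summed over epochs, ties to the lowest index)
contributes its raw series downstream — "power" is not defined
operationally in the literature this mirrors, so the variance convention
is fixed here.

## Synthetic cohort

Default conditions: 21 patients and 17 controls; per subject five epochs
of 4096 samples at 625 Hz (6.5536 s per epoch); 151 channels; 78 ROIs
with 5 voxels each.

Coupling model.  Oscillations are phase-imposed, not dynamical: each ROI
carries one narrowband oscillation per band — cos of a phase built from a
carrier detuned uniformly within 70% of the band half-width around the
band midpoint, plus a slow Ornstein–Uhlenbeck wander (σ = 0.8 rad,
τ = 0.4 s) — plus 1/f background noise (band-oscillation–to–background
power ratio 2 by default).  Detuning makes uncoupled phase differences
sweep through full cycles rather than dwell.  ROIs of a coupled component
share one carrier; member k receives a fixed offset (a simple pair
realizes the specified lag exactly; larger cliques are staggered over
(0.12π, 0.88π) so every pairwise lag is bounded away from 0 and π) and,
except for the first member, von Mises jitter of concentration κ.  The
jitter is an AR(1) Gaussian copula (correlation time 0.15 s) mapped
through the von Mises quantile function, so its marginal is exactly von
Mises while remaining smooth enough for analytic-signal tracking; the
expected pair PLI therefore has a brute-force oracle (`expected_pli`,
averaging sign(sin(lag + jitter)) over 10⁶ draws).  This phase-imposed
design was chosen over Kuramoto-style dynamics precisely because the
PLI's expected value is then controllable.

Implanted effects.  Every (band, RSN) combination carries baseline
coupling κ = 2 in both groups.  The implanted effects follow the
directionality the pipeline is meant to detect: alpha2 coupling in the
default-mode and visual networks is κ = 6 in controls vs 0.7 in patients;
beta coupling in the default-mode and temporo-parietal networks is 0.7 in
controls vs 6 in patients.  Per subject, each combination's concentration
is lognormally dispersed (σ = 0.35 on log κ) around its group value; the
standard-normal latent behind that dispersion is what covariates link to.

Covariates.  Gaussian distributions anchored to the study population:
thalamic volume 0.021 ± 0.001 L (controls) vs 0.019 ± 0.002 L (patients);
NBV 1.53 ± 0.07 vs 1.47 ± 0.05 L; NGMV 0.84 ± 0.05 vs 0.81 ± 0.04 L;
cognition z 0.04 ± 0.64 vs −0.19 ± 0.84.  EDSS exists only in patients
and is mapped from a latent normal onto the ordinal 0–10 half-point grid
(2 + 1.3·latent, rounded to 0.5, clipped to the observed 0–4.5 range;
median 2).  Links are Gaussian copulas between a covariate's latent and a
combination's coupling latent: thalamic volume ↔ alpha2 visual-network
coupling (ρ = +0.60, both groups), EDSS ↔ beta default-mode coupling
(+0.60, patients), cognition ↔ beta default-mode coupling (−0.60,
patients).  ρ = 0.60 was chosen from the rank-correlation identity for
Gaussian copulas, ρ_S = (6/π)·asin(ρ/2) ≈ 0.58, placing the cohort-level
Spearman correlation in the 0.5–0.6 regime; being rank-preserving, the
links make Spearman recovery well-defined.

Forward simulation places one dipole per ROI at its centroid voxel with
tangential orientation and adds white sensor noise at a signal-to-noise
power ratio of 5 by default (∞ = noiseless).

What the generator does not emulate: real anatomy and sensor layouts,
physiological/environmental artifacts, eyes-open vs eyes-closed spectra
(one condition is simulated), amplitude correlations, and realistic —
i.e. far weaker and sparser — coupling.  Passing tests therefore show
that the estimator chain and statistics behave correctly under controlled
coupling, not that effect sizes in real cohorts would be detectable.

## Statistics

Mann-Whitney U (two-sided, mid-ranks, exact p for small tie-free samples)
compares whole-brain and RSN PLI between groups.  Per-ROI comparisons use
a permutation test: group labels are permuted, a pooled-variance
two-sample t is computed per ROI, and the two-sided p is the proportion
of permuted |t| at or above the observed |t|.  When all C(n, n₁)
assignments number at most n_perm the null is enumerated exhaustively
(for two separated groups of 3, both tails of the exhaustive null are hit,
so the smallest two-sided p is 2/C(6,3)); otherwise n_perm (default 5000)
random permutations are drawn with the identity included, so
p ≥ 1/(n_perm+1) > 0.  Per-ROI p-values are uncorrected by default;
max-statistic family-wise correction is available as a flag.  ROIs with
zero variance in both groups are flagged and given p = 1.

The hierarchy is gated: RSN and per-ROI tests run only for bands whose
whole-brain test is significant (α = 0.05), and covariate correlations
(Spearman, per group) only for networks with a significant group
difference in that band.  Effect modification — whether a volume's
association with network PLI differs by group — is tested by OLS with a
group × volume interaction; per-group unstandardized B, standardized β
(B·SD(volume)/SD(y) within group) and p come from group-specific fits.
Normality checks use the Kolmogorov–Smirnov test with estimated mean/SD
(Lilliefors correction — the fixed-parameter variant would be
anti-conservative with estimated moments).  An optional outlier rule
re-runs correlations after discarding points with |externally studentized
residual| > 3, logging the count.

## Replicate validation and problem sizes

`megconn.validation` re-runs the generator many times to measure
detection power, specificity, Spearman-link recovery and type-I error.
Replicate cohorts keep the full design (21 + 17 subjects, six bands, all
networks, five epochs) but run on the generator's ground-truth phases
with 1024-sample epochs: skipping the forward/inverse step isolates what
is being measured (the estimator-plus-statistics chain), and shorter
epochs only add estimator noise, making the power figures conservative;
the full-length sensor-level path is exercised separately by the
forward→inverse round-trip tests and the pipeline smoke runs.  Null
calibration uses 200 null cohorts on a reduced 12-ROI atlas (group sizes
unchanged — they, not the ROI count, drive test calibration) with one
Mann-Whitney and one permutation p-value recorded per cohort and compared
to the 99% binomial band around 0.05.

## Numerical and degenerate-input conventions

Determinism: every stochastic routine takes a seed; cohorts derive
per-subject generators through `SeedSequence.spawn`, so identical seeds
give bit-identical cohorts and `run_study` records a config hash and
result digest.  Degenerate inputs raise rather than guess: all-zero
series have no phase; dipoles at the sphere center or outside are
invalid; empty ROIs, RSNs with fewer than two members, unknown labels,
constant inputs to rank tests, and collinear effect-modification designs
are all errors.  Adjacency validation enforces symmetry, zero diagonal
and entries in [0, 1] at 1e-12.  Voxel-selection ties break to the lowest
index.  The O(n²m) pairwise sign accumulation is JIT-compiled (numba)
with a pure-numpy fallback; both routes are tested against each other.

## Known limitations

The sphere/one-dipole-per-ROI world is far cleaner than subject anatomy:
beamformer leakage between the synthetic ROIs is mild, so the PLI's
robustness to field spread is demonstrated in principle (zero-lag mixing
is discounted by construction) but not at realistic leakage levels.
Coupling values producing the implanted effects are strong compared with
resting-state PLI values in patient data.  The permutation test assumes
exchangeability under the null, satisfied here by construction.  The
ordinal EDSS attenuates rank correlations relative to its latent; only
the thalamic-volume link is used for quantitative recovery checks.
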