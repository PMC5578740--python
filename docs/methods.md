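# Methods

## The model

`statevar` operationalizes global gain modulation as trial-to-trial scaling
of the amplitude of whole-brain activity patterns.  Each task process p ∈
{VME, maintenance, retrieval} has a canonical pattern; splitting activity by
target hemifield gives a *mean* component (hemifield average) and a
*spatial* component (right-target minus left-target), so per-hemifield
activity is `mean ± spatial/2`.  The measured quantity, per session, is the
fraction of residual (mean-trial-removed) BOLD variance around correct
memory-guided saccades that projects onto the six state patterns:

    total brain state variability = SS_brain / (SS_brain + SS_error),
    SS_brain = SS_VME + SS_Maint + SS_Retrieval  (exact by construction).

Attribution uses jointly fit weights on a basis orthonormalized in the
order nuisance → VME → maintenance → retrieval, so the additivity identity
holds to rounding error regardless of correlations among regressors.

## Synthetic generator

The generator defines the study conditions for every test:

* **Task.** 3 runs, TR = 1.5 s; presentations of 1.5/3 s, delays of 1.5/9 s,
  targets at ±3/6/9° on the horizontal meridian; one trial per
  condition×hemifield cell per run by default (24 trials/session), with
  inter-trial gaps of 15 TRs so FIR windows never overlap.  Trial counts and
  gaps are configuration, since real designs vary.
* **Signal.** BOLD(v,t) = Σ_c pattern_c(v) Σ_i g_c(i) r_{c,i}(t) + drift +
  motion artifact + ε.  VME and retrieval regressors are unit impulses at
  the encoding saccade and the MGS convolved with a double-gamma HRF (peak
  6 s, undershoot 16 s, unit peak — a standard, reproducible choice).
  Maintenance is a delay-period boxcar convolved with the HRF and
  normalized to unit peak: it starts one TR after presentation offset
  (consolidation gap) and ends two TRs before the MGS (memory readout
  precedes the movement), placing its hemodynamic peak at the pre-MGS TR —
  the TR from which the maintenance pattern is extracted — and putting the
  trial-wise brain/behavior coupling peak just after the saccade, matching
  the qualitative timing the method is meant to exhibit.  Short delays
  leave room for a single maintenance TR.
* **Gains.** Mean-component gains are N(1, σ_c); spatial gains are
  N(hemifield, σ_c).  Default σ_c = 0.3.  Construction is exactly linear in
  the gains.
* **Ground-truth patterns.** Smooth Gaussian random fields on a paired
  two-hemisphere voxel grid; mean components exactly mirror-symmetric,
  spatial components antisymmetric, all zero-mean and unit-norm.  The mean
  triplet and the spatial triplet are each orthonormalized (QR within
  symmetry class): distinct gain signals are modeled as targeting distinct,
  non-overlapping patterns, and basis overlap would otherwise be
  confounded with extraction error in recovery tests.  The mirror pairing
  is an index involution; geometric warping is not modeled.
* **Behavior.** RT = base + Σ_c β_c·dev_c + ε, dev_c the gain deviation
  (hemifield-aligned for spatial components); analogously for saccadic
  error.  Defaults: β(maint_mean) = −60 ms per unit gain (faster responses
  with stronger maintenance expression), SE coupled to VME (+0.3°), RT
  noise 120 ms, SE noise 1°, 5% incorrect trials.
* **Noise.** Per-voxel i.i.d. N(0, 0.05) BOLD noise; per-run random cubic
  Legendre drift (σ = 0.02 per coefficient); motion as a 6-parameter random
  walk (step 0.02 mm/deg) coupled into BOLD through a rank-8 set of random
  artifact maps applied to the 28 lead/lagged motion series.
* **Cohort.** Accelerated-longitudinal: entry ages spread over 8–33 years,
  sessions 1.5 years apart.  Per-subject gain SD follows
  base + slope·s_i·(age − 20.5) + u_i, clipped at 0.02, where s_i is a
  latent stabilization rate (SD 0.3) that also scales the inverse-age
  decline of behavioral noise — so individual brain and behavioral
  stabilization are coupled, the target of the slope-correlation analysis.
  RT means and SDs follow inverse-age trajectories with magnitudes in the
  range reported for MGS tasks (≈600→370 ms mean RT from age 8 to 33).

What the generator does **not** emulate: physiological (cardiac/respiratory)
noise, spatial autocorrelation beyond the smoothness parameter, realistic
anatomy or registration error, non-linear HRF effects, and eye-tracker
artifacts (blinks, lost corneal lock) beyond a flat incorrect-trial rate.
Passing tests therefore demonstrate correctness of the estimators under the
stated signal model, not robustness to every property of real fMRI.

## Stage-specific choices

* **Deconvolution.** Shared-design OLS per voxel, no prewhitening.  FIR
  window = trial duration + 15 TRs (22.5 s).  Rank deficiency is detected
  by pivoted QR at 1e-10 relative tolerance and reported as an error naming
  the collinear columns.  Lead/lag motion copies use edge replication at
  run boundaries.  All trials, including incorrect ones, enter the FIR
  model.  Framewise displacement converts rotations to arc length at a
  50 mm head radius; the first TR is 0.
* **Idealized time courses.** The group average trial time course is a
  fixed-effects OLS with mean-centered age, displacement, and
  incorrect-trial-proportion covariates, evaluated at mean age, zero
  displacement, perfect performance.  A subject-level random effect would
  only reweight subjects for this estimand at these cohort sizes.
* **State extraction.** VME and retrieval patterns are taken 4 TRs (6 s)
  after their events; maintenance at the TR before the MGS.  Maintenance is
  residualized on the encoding-saccade-TR patterns and on the extracted VME
  mean/spatial patterns; retrieval on every pattern before the MGS TR.
  References are noisy estimates, so targets are residualized on the
  *principal subspace* of the reference set: reference volumes below 5% of
  the largest reference norm are dropped, and only directions with
  relative singular value ≥ 0.08 are used.  Without this, reference noise
  and FIR window-truncation leakage span the entire pattern space and the
  regression removes the target state itself (verifiable in the noise-free
  limit).  Mirror symmetrization averages each component with its
  (sign-inverted, for spatial) voxel-pairing mirror, making the symmetry
  exact; components are returned unit-norm.
* **Nuisance templates.** Motion-template PCA is uncentered across the 28
  maps (they are already spatial-mean-centered and norm-equalized); the
  template count is data-determined by the >90% variance rule.  The
  state-mask constant template is included only when the state mask is a
  proper subset of the volume (otherwise it duplicates the whole-volume
  constant and the projection design would be singular).  Gradients use
  voxel coordinates relative to the mask center of mass; degenerate
  (coplanar) geometry warns rather than errors.
* **Projection.** States and nuisance templates are fit jointly per TR;
  weights are not renormalized (states carry the unit-norm convention).
  Fluctuation series are temporally z-scored per component per session.
* **Trajectories.** statsmodels MixedLM with a random subject intercept
  (optionally a random age slope), fit by maximum likelihood so
  log-likelihoods and AIC are comparable between the linear-age and
  inverse-age forms.  Singular or non-converged fits fall back to OLS with
  a warning.  Endpoint change is computed from fixed effects at ages 8 and
  33.
* **Mean-matched subsampling.** Importance resampling on 20 equal-count
  bins of pooled FD; bin weights are tilted geometrically until the
  expected FD gap reaches 0.2 pooled SD in the requested direction, then a
  seeded bootstrap draws both groups with those weights.  An unachievable
  bias raises an explicit error.
* **Trial-wise regression.** Null model: run, hemifield, eccentricity and
  its square, the other behavioral measure and its square, subject.  Full
  model adds the three mean-state terms and three spatial×hemifield
  interactions at the probed relative TR.  RT is z-scored within
  subject×condition cells; SE is z-scored then rectified.  Both models are
  Gaussian linear models (subject as fixed intercepts); the simulated LRT
  is a parametric bootstrap of the fitted null — `n_sim` datasets drawn
  from it, both models refit to each (vectorized), p = (1 + #{LRT* ≥
  LRT})/(n_sim + 1).  Edge snippets are excluded as missing rather than
  padded.  Saccade detection uses a 30°/s minimum peak velocity (no floor
  is standard; this one suppresses noise maxima) with event boundaries at
  a tenth of the peak.
* **Mechanism simulations.** 400 trials, 60 ms bins, ±0.25 linear
  amplitude modulation (fastest trial → +0.25); the simulation window
  covers the slowest RT plus the full 32 s HRF so a pure time shift leaves
  trial integrals exactly unchanged.  Stand-alone runs draw RTs from a
  log-normal (median 0.45 s, σ = 0.30) matched to plausible MGS reaction
  times; cohort RTs can be passed through instead.  "Converge to zero" is
  operationalized as a terminal integral below 5% of the closed-form
  amplitude-mode magnitude (mean modulation × HRF integral) at the same
  RTs; amplitude vs mixed classification uses the re-convergence ratio
  (terminal/peak of the cumulative integral, threshold 0.75), and
  ambiguous inputs return "indeterminate".

## Problem sizes

The test-suite and reproduction script run everything at desk scale, chosen
as the smallest sizes at which the estimators are well conditioned: the
developmental cohort uses 20 subjects × 2 sessions × ~2,000 voxels with
maintenance/retrieval gain-SD slopes of −0.008/year; the trial-wise
coupling run uses 10 sessions × ~1,000 voxels × 48 trials with a −120 ms
maintenance coupling (a deliberately strong "design effect size" for the
discrimination test; the generator default of −60 ms represents a
realistic, smaller share of RT variance); null calibration uses 200
replicates of 250 trials with 500 bootstrap draws.

## Known limitations

* Component SS attribution depends on the orthogonalization order
  (nuisance first, then VME, maintenance, retrieval); this matches the
  extraction hierarchy but is a convention.
* The principal-subspace residualization trades exact orthogonality to the
  raw reference volumes for robustness to reference noise; orthogonality
  is exact only with respect to the retained subspace.
* The OLS route of the trial-wise models treats subjects as fixed
  intercepts; the mixed-effects route exists but is slow inside the
  bootstrap and is not used by the default scans.
* Real-data mode consumes preprocessed, MNI-registered NIfTI series; no
  raw-MRI preprocessing (slice timing, motion correction, smoothing,
  high-pass filtering) is performed here.
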