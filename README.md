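# statevar

Brain-state variability analysis of memory-guided-saccade (MGS) task fMRI.

During an MGS task, three cognitive processes — the visuomotor/encoding
saccade (VME), working-memory maintenance, and retrieval — each evoke a
characteristic whole-brain pattern of BOLD activity (a *brain state*).
Global gain signals are hypothesized to scale the *amplitude* with which
these states are expressed from trial to trial without changing their
spatial structure.  `statevar` measures that brain-state variability and
relates it to saccadic behavior:

1. **FIR deconvolution** estimates voxel-wise average trial time courses per
   trial type (4 conditions × 2 hemifields), with third-order Legendre drift
   and 28 lead/lagged motion regressors; trial averages are rescaled by the
   per-voxel residual SD.
2. **State extraction** builds six canonical patterns — (VME, maintenance,
   retrieval) × (mean, spatial) — from long-delay trial averages at a 4-TR
   (6 s) hemodynamic lag, sequentially orthogonalized and mirror-symmetrized.
3. **Nuisance templates** (motion-artifact principal components capturing
   >90% of the lagged-motion coefficient maps, plus constant and spatial
   gradient templates) absorb trivial modes of whole-volume signal change.
4. **Projection** regresses each whole-brain volume on the six states plus
   nuisance templates, turning average trial series into expression time
   courses and residual series into fluctuation time courses.
5. **Variance decomposition** over the TRs around each correct MGS splits
   residual squared error into SS_VME + SS_Maint + SS_Retrieval = SS_brain,
   SS_motion, and SS_error; *total brain state variability* is
   SS_brain/(SS_brain + SS_error).  Developmental change is modeled with
   mixed-effects linear-age or inverse-age trajectories, with a biased
   mean-matched bootstrap as the motion control.
6. **Trial-wise regression** relates ±15-TR fluctuation snippets around each
   MGS to z-scored reaction time and rectified saccadic error, comparing
   full (state terms + spatial×hemifield interactions) and null models by
   ΔR² and a simulated (parametric-bootstrap) likelihood-ratio test.
7. **Mechanism simulations** discriminate amplitude- from timing-based
   brain/behavior coupling via the time integrals of fast/slow-RT mean
   residual HRF series (timing → both integrals converge to zero; amplitude
   → opposite-signed non-zero integrals).

A first-class **synthetic-data generator** emulates gain-modulated task BOLD
(six ground-truth patterns, per-trial multiplicative gains whose variance
can decline with age, behavior coupled to the same gains, drift,
motion-locked artifacts, i.i.d. noise) and provides exact ground truth for
every stage.

## Worked example

```python
import numpy as np
from statevar.synthetic import (GainAgeModel, generate_cohort)
from statevar.deconvolution import FIRDeconvolver, build_fir_design
from statevar.states import COMPONENTS, StateExtractor, group_average_timecourses
from statevar.nuisance import build_nuisance_set
from statevar.variability import decompose_variance, fit_trajectory

slopes = {c: -0.008 if c.startswith(("maint", "retr")) else 0.0
          for c in COMPONENTS}
cohort = generate_cohort(20, age_model=GainAgeModel(slope=slopes),
                         sessions_per_subject=2,
                         n_voxels_per_hemisphere=1000, seed=42)

decs, ages = [], []
for sub in cohort.subjects:
    for age, sess in zip(sub.ages, sub.sessions):
        fir = build_fir_design(sess.trials, sess.design.n_tr_per_run,
                               sess.design.n_runs, motion=sess.motion)
        decs.append(FIRDeconvolver().fit(sess.bold, fir))
        ages.append(age)

group = group_average_timecourses([d.trial_averages_ for d in decs], ages=ages)
states = StateExtractor().fit(group).states_
print(np.round(np.abs(np.diag(states.matrix().T @ cohort.patterns.matrix())), 3))
# [0.983 0.989 0.981 0.985 0.994 0.995]   <- recovered vs true patterns
```

The six extracted states match the generator's ground-truth patterns with
absolute cosine similarity 0.98–0.99.  Continuing with the variance
decomposition and a linear-age mixed model (mean-FD and correct-trial-count
covariates) on the 40 sessions prints

```
maint slope -3.69e-04 p 0.0000
retr  slope -2.15e-04 p 0.0000
vme   slope -4.28e-05 p 0.1163
```

i.e. maintenance- and retrieval-related brain-state variability decline
significantly with age while the VME component does not — the sign pattern
the generator injected (maintenance/retrieval gain SD falling ~0.008 per
year, VME flat).

A command-line pipeline wraps the same stages:

```sh
statevar run --config cohort.yaml --out results/ --seed 1
statevar rtsim --out results/ --seed 1
```

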