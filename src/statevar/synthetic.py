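"""Synthetic gain-modulated task fMRI with coupled saccadic behavior.

The generator emulates a memory-guided-saccade (MGS) session: on each trial a
target appears at +/-3, 6 or 9 deg on the horizontal meridian for 1.5 or 3 s,
is maintained over a 1.5 or 9 s delay, and is then acquired with an MGS.
Three canonical whole-brain states (visuomotor/encoding, maintenance,
retrieval), each with a mirror-symmetric mean and a mirror-antisymmetric
spatial component, are expressed with hemodynamic time courses whose
amplitudes fluctuate trial-to-trial by multiplicative gains.  Reaction time
and saccadic error are linear in the same gain deviations, so the generator
provides exact ground truth for every downstream recovery test.

Signal model per voxel v and TR t::

    BOLD(v,t) = sum_c pattern_c(v) * sum_i g_c(i) * r_c,i(t)
                + drift(v,t) + motion_artifact(v,t) + eps(v,t)

where r_c,i is the canonical HRF locked to the encoding saccade (VME), a
delay-period boxcar convolved with the HRF (maintenance), or the HRF locked
to the MGS (retrieval).  Mean-component gains are centered on 1, spatial
gains on the target hemifield sign.  Construction is exactly linear in the
gains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .deconvolution import lagged_motion_regressors
from .hrf import hrf_kernel
from .masks import Mask, MaskedVolume, MotionSeries, VolumeSeries
from .states import COMPONENTS, BrainStateSet

__all__ = [
    "TaskDesign",
    "make_task_design",
    "GainGroundTruth",
    "GainAgeModel",
    "SessionData",
    "Cohort",
    "generate_state_patterns",
    "generate_session",
    "generate_cohort",
    "state_regressors",
    "make_velocity_trace",
    "make_eye_trace",
    "write_session",
]

TR_SECONDS = 1.5
PRESENTATIONS_S = (1.5, 3.0)
DELAYS_S = (1.5, 9.0)
ECCENTRICITIES_DEG = (3, 6, 9)
MIN_GAP_TR = 15

TRIAL_COLUMNS = [
    "run_index", "hemifield", "eccentricity_deg", "eccentricity_code",
    "presentation_s", "delay_s", "encode_tr", "mgs_tr",
    "rt_ms", "se_deg", "correct",
]


def _duration_tr(pres_s: float, delay_s: float) -> int:
    return int(round((pres_s + delay_s) / TR_SECONDS))


@dataclass(frozen=True)
class TaskDesign:
    """Trial layout of one session (3 runs by default)."""

    trials: pd.DataFrame  # run_index, presentation_s, delay_s, hemifield, ecc..., encode_tr, mgs_tr
    n_runs: int
    n_tr_per_run: int
    tr_seconds: float = TR_SECONDS

    def __post_init__(self):
        t = self.trials
        if not (t["encode_tr"] < t["mgs_tr"]).all():
            raise ValueError("encode_tr must precede mgs_tr")
        combos = set(zip(t["presentation_s"], t["delay_s"]))
        if len(combos) < 4:
            raise ValueError("all four presentation x delay combinations required")
        for run, sub in t.groupby("run_index"):
            starts = sub["encode_tr"].to_numpy()
            ends = sub["mgs_tr"].to_numpy()
            order = np.argsort(starts)
            gaps = starts[order][1:] - ends[order][:-1] - 1
            if np.any(gaps < MIN_GAP_TR):
                raise ValueError("inter-trial gap below 15 TRs")
            # trials carry global TR indices; run ends at run * n_tr_per_run
            if ends[order][-1] + MIN_GAP_TR >= run * self.n_tr_per_run:
                raise ValueError("trial window exceeds run length")

    @property
    def n_tr(self) -> int:
        return self.n_runs * self.n_tr_per_run

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def make_task_design(
    n_runs: int = 3,
    trials_per_cell_per_run: int = 1,
    gap_tr: int = MIN_GAP_TR,
    start_pad_tr: int = 3,
    seed: int = 0,
) -> TaskDesign:
    """Build a balanced session design.

    Each run contains ``trials_per_cell_per_run`` trials of every
    presentation x delay x hemifield cell (8 cells), in seeded random order,
    with eccentricities cycling through 3, 6, 9 deg.  Inter-trial gaps are
    ``gap_tr`` TRs so FIR windows of neighbouring trials never overlap.
    """
    rng = np.random.default_rng(seed)
    cells = [
        (p, d, h)
        for p in PRESENTATIONS_S
        for d in DELAYS_S
        for h in (-1, +1)
    ] * trials_per_cell_per_run

    rows = []
    run_len = 0
    ecc_cycle = 0
    for run in range(1, n_runs + 1):
        order = rng.permutation(len(cells))
        t = start_pad_tr
        for idx in order:
            p, d, h = cells[idx]
            ecc = ECCENTRICITIES_DEG[ecc_cycle % 3]
            ecc_cycle += 1
            encode = t
            mgs = t + _duration_tr(p, d)
            rows.append(dict(
                run_index=run, presentation_s=p, delay_s=d, hemifield=h,
                eccentricity_deg=ecc, eccentricity_code=ECCENTRICITIES_DEG.index(ecc) + 1,
                encode_tr=encode, mgs_tr=mgs,
            ))
            t = mgs + 1 + gap_tr
        run_len = max(run_len, t + 1)
    n_tr_per_run = run_len

    df = pd.DataFrame(rows)
    # shift each run's trials onto the global TR axis
    df["encode_tr"] += (df["run_index"] - 1) * n_tr_per_run
    df["mgs_tr"] += (df["run_index"] - 1) * n_tr_per_run
    return TaskDesign(df.reset_index(drop=True), n_runs, n_tr_per_run)


def _full(value: float) -> dict:
    return {c: float(value) for c in COMPONENTS}


@dataclass(frozen=True)
class GainGroundTruth:
    """Generator parameters: gain variability, couplings, and noise levels.

    gain_sd are dimensionless SDs of the per-trial multiplicative gains;
    rt_coupling is in ms per unit gain deviation and se_coupling in degrees
    per unit gain deviation (spatial couplings act on the hemifield-aligned
    deviation).  noise_sd is the i.i.d. BOLD noise SD per voxel (a.u.).
    """

    gain_sd: dict = field(default_factory=lambda: _full(0.3))
    rt_coupling: dict = field(default_factory=lambda: {"maint_mean": -60.0})
    se_coupling: dict = field(default_factory=lambda: {"vme_mean": 0.3})
    noise_sd: float = 0.05
    drift_sd: float = 0.02
    motion_amplitude_mm: float = 0.02
    motion_coupling: float = 0.5
    rt_base_ms: float = 450.0
    rt_noise_ms: float = 120.0
    se_noise_deg: float = 1.0
    p_incorrect: float = 0.05

    def __post_init__(self):
        if any(v < 0 for v in self.gain_sd.values()):
            raise ValueError("gain_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def replace(self, **kw) -> "GainGroundTruth":
        return dataclasses.replace(self, **kw)


def generate_state_patterns(
    n_voxels_per_hemisphere: int, smoothness: float = 2.0, seed: int = 0
) -> tuple[BrainStateSet, Mask]:
    """Six smooth random ground-truth patterns on a paired two-hemisphere mask.

    Mean components are exactly mirror-symmetric, spatial components exactly
    antisymmetric; all are centered to zero spatial mean and unit norm.  The
    mean set and the spatial set are each orthonormalized (which preserves
    their mirror symmetry class and zero mean), so the six ground-truth
    patterns are mutually orthogonal -- distinct gain signals target
    distinct, non-overlapping activity patterns.
    """
    n = int(n_voxels_per_hemisphere)
    if n < 10:
        raise ValueError("need at least 10 voxels per hemisphere")
    if 2 * n < len(COMPONENTS):
        raise ValueError("degenerate basis: fewer voxels than components")

    nz = max(2, int(np.ceil(n ** (1 / 3))))
    ny = nz
    nx = int(np.ceil(n / (ny * nz)))
    grid_idx = np.indices((nx, ny, nz)).reshape(3, -1).T[:n]

    right = grid_idx.copy()
    right[:, 0] += nx + 1  # midline gap at x = nx
    left = grid_idx.copy()
    left[:, 0] = nx - 1 - left[:, 0]
    coords = np.vstack([left, right])
    pairing = np.concatenate([np.arange(n) + n, np.arange(n)])
    mask = Mask(coords, pairing, mask_id=f"synthetic-{n}")

    rng = np.random.default_rng(seed)
    raw = {}
    for name in COMPONENTS:
        field3d = gaussian_filter(rng.standard_normal((nx, ny, nz)), smoothness)
        vals = field3d.reshape(-1)[:n]
        sign = -1.0 if name.endswith("_spatial") else 1.0
        full = np.concatenate([sign * vals, vals])
        full = full - full.mean()
        nrm = np.linalg.norm(full)
        if nrm == 0:
            raise ValueError("degenerate pattern draw")
        raw[name] = full / nrm

    # orthonormalize within symmetry class (QR keeps symmetric combinations
    # symmetric, antisymmetric combinations antisymmetric, zero mean intact)
    vols = {}
    for suffix in ("_mean", "_spatial"):
        names = [c for c in COMPONENTS if c.endswith(suffix)]
        M = np.column_stack([raw[c] for c in names])
        Q, R = np.linalg.qr(M)
        if np.abs(np.diag(R)).min() <= 1e-10:
            raise ValueError("degenerate basis: patterns not linearly independent")
        Q = Q * np.sign(np.diag(R))  # keep each pattern aligned with its draw
        for j, c in enumerate(names):
            q = Q[:, j]
            # re-impose the symmetry exactly (QR is exact only to rounding)
            mirrored = q[pairing]
            q = (q + mirrored) / 2 if suffix == "_mean" else (q - mirrored) / 2
            vols[c] = MaskedVolume(q / np.linalg.norm(q), mask)
    return BrainStateSet(vols, provenance={"synthetic_seed": seed}), mask


def state_regressors(design: TaskDesign) -> np.ndarray:
    """Per-trial state time courses, (n_trials, 3, n_tr) for (VME, maint, retr).

    VME and retrieval are unit impulses at the encoding saccade and MGS TRs
    convolved with the canonical HRF; maintenance is a delay-period boxcar
    convolved with the HRF and normalized to unit peak, so long and short
    delays differ in duration of sustained expression, not amplitude.  The
    boxcar starts one TR after the presentation ends (a consolidation gap
    separating encoding-epoch activity from sustained maintenance) and ends
    two TRs before the MGS (memory readout begins before the movement), so
    the hemodynamic peak of maintenance expression falls at the pre-MGS TR.
    Short delays leave room only for a single maintenance TR at mgs-1.
    """
    kern = hrf_kernel(design.tr_seconds)
    n_tr = design.n_tr
    out = np.zeros((design.n_trials, 3, n_tr))
    for i, row in enumerate(design.trials.itertuples(index=False)):
        run0 = (row.run_index - 1) * design.n_tr_per_run
        run1 = run0 + design.n_tr_per_run
        enc, mgs = int(row.encode_tr), int(row.mgs_tr)
        pres_tr = int(round(row.presentation_s / design.tr_seconds))
        for j, stim in enumerate(("vme", "maint", "retr")):
            imp = np.zeros(design.n_tr_per_run)
            if stim == "vme":
                imp[enc - run0] = 1.0
            elif stim == "retr":
                imp[mgs - run0] = 1.0
            else:
                start = enc + pres_tr + 1
                stop = mgs - 1  # exclusive: boxcar covers start..mgs-2
                if start >= stop:  # short delays: single TR at mgs-1
                    start, stop = mgs - 1, mgs
                imp[start - run0 : stop - run0] = 1.0
            conv = np.convolve(imp, kern)[: design.n_tr_per_run]
            if stim == "maint" and conv.max() > 0:
                conv = conv / conv.max()
            out[i, j, run0:run1] = conv
    return out


@dataclass
class SessionData:
    """One generated session with its realized ground truth."""

    bold: VolumeSeries
    trials: pd.DataFrame
    motion: MotionSeries
    gains: pd.DataFrame  # n_trials x 6 realized gain multipliers
    truth: GainGroundTruth
    design: TaskDesign
    seed: int


def generate_session(
    design: TaskDesign,
    patterns: BrainStateSet,
    truth: GainGroundTruth,
    seed: int = 0,
) -> SessionData:
    """Generate one session of gain-modulated BOLD plus coupled behavior."""
    rng = np.random.default_rng(seed)
    mask = patterns.mask
    V = mask.n_voxels
    n_tr = design.n_tr
    P = patterns.matrix()  # V x 6

    regs = state_regressors(design)  # trials x 3 x n_tr
    hemi = design.trials["hemifield"].to_numpy(dtype=float)
    n_trials = design.n_trials

    gains = np.empty((n_trials, 6))
    for k, comp in enumerate(COMPONENTS):
        mu = np.full(n_trials, 1.0) if comp.endswith("_mean") else hemi
        gains[:, k] = mu + rng.normal(0.0, truth.gain_sd[comp], n_trials)

    group_of = {"vme": 0, "maint": 1, "retr": 2}
    W = np.zeros((6, n_tr))
    for k, comp in enumerate(COMPONENTS):
        g = group_of[comp.split("_")[0]]
        W[k] = gains[:, k] @ regs[:, g, :]
    bold = P @ W

    # per-run Legendre drift with per-voxel random coefficients
    from .deconvolution import legendre_drift

    if truth.drift_sd > 0:
        L = legendre_drift(design.n_tr_per_run, 3)
        for run in range(design.n_runs):
            coeffs = rng.normal(0.0, truth.drift_sd, (V, 4))
            sl = slice(run * design.n_tr_per_run, (run + 1) * design.n_tr_per_run)
            bold[:, sl] += coeffs @ L.T

    params = np.cumsum(rng.normal(0.0, truth.motion_amplitude_mm, (n_tr, 6)), axis=0)
    motion = MotionSeries(params)
    if truth.motion_coupling > 0:
        # low-rank spatial artifact structure: a few shared artifact patterns
        # mixed into all 28 lagged-motion couplings, plus a small diffuse part
        lagged = lagged_motion_regressors(motion)  # n_tr x 28
        G = rng.standard_normal((V, 8)) / np.sqrt(V)
        M = rng.standard_normal((8, 28))
        A = truth.motion_coupling * (
            G @ M + 0.1 * rng.standard_normal((V, 28)) / np.sqrt(V)
        )
        bold += A @ lagged.T

    bold += rng.normal(0.0, truth.noise_sd, (V, n_tr))

    # behavior linear in gain deviations (hemifield-aligned for spatial comps)
    dev = gains.copy()
    for k, comp in enumerate(COMPONENTS):
        if comp.endswith("_mean"):
            dev[:, k] -= 1.0
        else:
            dev[:, k] = (dev[:, k] - hemi) * hemi
    rt = np.full(n_trials, truth.rt_base_ms)
    se = np.zeros(n_trials)
    for k, comp in enumerate(COMPONENTS):
        rt += truth.rt_coupling.get(comp, 0.0) * dev[:, k]
        se += truth.se_coupling.get(comp, 0.0) * dev[:, k]
    rt += rng.normal(0.0, truth.rt_noise_ms, n_trials)
    se += rng.normal(0.0, truth.se_noise_deg, n_trials)

    correct = rng.random(n_trials) >= truth.p_incorrect
    trials = design.trials.copy()
    trials["rt_ms"] = np.where(correct, rt, np.nan)
    trials["se_deg"] = np.where(correct, se, np.nan)
    trials["correct"] = correct

    gains_df = pd.DataFrame(gains, columns=list(COMPONENTS))
    return SessionData(
        bold=VolumeSeries(bold, mask, design.tr_seconds),
        trials=trials,
        motion=motion,
        gains=gains_df,
        truth=truth,
        design=design,
        seed=seed,
    )


@dataclass(frozen=True)
class GainAgeModel:
    """Age dependence of the injected gain variability and behavior noise.

    Per-session gain SD for component c of a subject with latent
    stabilization rate s_i and subject offset u_i at age a is::

        clip(base[c] + slope[c] * s_i * (a - reference_age) + u_i, min_sd)

    Behavioral noise follows inverse-age trajectories whose decline rate is
    scaled by the same s_i, coupling individual brain and behavior
    stabilization.
    """

    base: dict = field(default_factory=lambda: _full(0.3))
    slope: dict = field(default_factory=lambda: {c: 0.0 for c in COMPONENTS})
    reference_age: float = 20.5
    subject_sd: float = 0.03
    min_sd: float = 0.02
    stabilization_heterogeneity: float = 0.3
    rt_base_intercept_ms: float = 297.0
    rt_base_age_coeff: float = 2524.0
    rt_noise_base_ms: float = 50.0
    rt_noise_age_coeff: float = 1400.0
    se_noise_base_deg: float = 0.9
    se_noise_age_coeff: float = 4.0

    def __post_init__(self):
        if not all(np.isfinite(list(self.slope.values()))):
            raise ValueError("non-finite slope spec")


@dataclass
class SubjectRecord:
    subject_id: int
    ages: list
    stabilization: float
    gain_sd_by_session: list  # dict per session
    sessions: list  # SessionData per session


@dataclass
class Cohort:
    patterns: BrainStateSet
    mask: Mask
    subjects: list
    age_model: GainAgeModel
    seed: int

    def sessions_frame(self) -> pd.DataFrame:
        """One row per session: subject, age, injected gain SDs, mean FD."""
        rows = []
        for sub in self.subjects:
            for age, gsd, sess in zip(sub.ages, sub.gain_sd_by_session, sub.sessions):
                row = dict(subject=sub.subject_id, age=age,
                           mean_fd=float(sess.motion.total_displacement.mean()),
                           n_correct=int(sess.trials["correct"].sum()))
                row.update({f"gain_sd_{c}": gsd[c] for c in COMPONENTS})
                rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (8.0, 33.0),
    age_model: GainAgeModel | None = None,
    sessions_per_subject: int = 2,
    session_interval_years: float = 1.5,
    n_voxels_per_hemisphere: int = 1000,
    design: TaskDesign | None = None,
    base_truth: GainGroundTruth | None = None,
    smoothness: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Generate an accelerated-longitudinal cohort sharing one pattern basis.

    Subject entry ages are spread uniformly over ``age_range`` (shrunk so all
    sessions fit); each subject contributes ``sessions_per_subject`` sessions
    spaced ``session_interval_years`` apart.  Per-subject gain SDs follow
    ``age_model``.  Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    age_model = age_model or GainAgeModel()
    base_truth = base_truth or GainGroundTruth()
    design = design or make_task_design(seed=seed)
    rng = np.random.default_rng(seed)

    patterns, mask = generate_state_patterns(
        n_voxels_per_hemisphere, smoothness=smoothness, seed=int(rng.integers(2**31))
    )

    span = (sessions_per_subject - 1) * session_interval_years
    lo, hi = age_range[0], age_range[1] - span
    entry_ages = np.linspace(lo, max(lo, hi), n_subjects)

    subjects = []
    for sid in range(n_subjects):
        s_i = max(0.2, 1.0 + rng.normal(0.0, age_model.stabilization_heterogeneity))
        u_i = rng.normal(0.0, age_model.subject_sd)
        ages, gsds, sessions = [], [], []
        for k in range(sessions_per_subject):
            a = float(entry_ages[sid] + k * session_interval_years)
            gsd = {
                c: float(np.clip(
                    age_model.base[c]
                    + age_model.slope.get(c, 0.0) * s_i * (a - age_model.reference_age)
                    + u_i,
                    age_model.min_sd, None,
                ))
                for c in COMPONENTS
            }
            truth = base_truth.replace(
                gain_sd=gsd,
                rt_base_ms=age_model.rt_base_intercept_ms + age_model.rt_base_age_coeff / a,
                rt_noise_ms=age_model.rt_noise_base_ms + age_model.rt_noise_age_coeff * s_i / a,
                se_noise_deg=age_model.se_noise_base_deg + age_model.se_noise_age_coeff / a,
            )
            sess = generate_session(design, patterns, truth,
                                    seed=int(rng.integers(2**31)))
            ages.append(a)
            gsds.append(gsd)
            sessions.append(sess)
        subjects.append(SubjectRecord(sid, ages, s_i, gsds, sessions))
    return Cohort(patterns, mask, subjects, age_model, seed)


def make_velocity_trace(
    events,
    total_s: float,
    rate_hz: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize a 60 Hz eye-velocity trace with triangular saccade pulses.

    ``events`` is a list of ``(onset_s, peak_deg_per_s, duration_s)``; the
    pulse rises linearly to its peak at mid-duration and falls back.
    """
    rng = np.random.default_rng(seed)
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    v = np.zeros(n)
    for onset, peak, dur in events:
        half = dur / 2.0
        tri = peak * np.clip(1.0 - np.abs(t - (onset + half)) / half, 0.0, None)
        v += tri
    if noise_sd > 0:
        v += np.abs(rng.normal(0.0, noise_sd, n))
    return v


def make_eye_trace(
    saccades,
    total_s: float,
    rate_hz: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize paired 60 Hz velocity-magnitude and position traces.

    ``saccades`` is a list of ``(onset_s, amplitude_deg, duration_s)`` with
    signed amplitudes; each produces a triangular velocity pulse whose time
    integral equals the amplitude.  Returns ``(velocity_abs, position_deg)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    v_signed = np.zeros(n)
    for onset, amp, dur in saccades:
        half = dur / 2.0
        peak = 2.0 * amp / dur  # triangle area = amplitude
        v_signed += peak * np.clip(1.0 - np.abs(t - (onset + half)) / half, 0.0, None)
    position = np.cumsum(v_signed) / rate_hz
    velocity = np.abs(v_signed)
    if noise_sd > 0:
        velocity = velocity + np.abs(rng.normal(0.0, noise_sd, n))
    return velocity, position


def write_session(session: SessionData, outdir, write_bold: bool = True) -> dict:
    """Write a session to standard formats; returns the path manifest.

    BOLD and mask go to NIfTI-1, trial and motion tables to CSV, and the
    generator ground truth to a YAML + CSV sidecar pair.
    """
    import pathlib

    from .masks import mask_to_nifti, motion_to_csv, series_to_nifti

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if write_bold:
        series_to_nifti(session.bold).to_filename(outdir / "bold.nii.gz")
        mask_to_nifti(session.bold.mask).to_filename(outdir / "mask.nii.gz")
        paths["bold"] = str(outdir / "bold.nii.gz")
        paths["mask"] = str(outdir / "mask.nii.gz")
    session.trials.to_csv(outdir / "trials.csv", index=False)
    motion_to_csv(session.motion, outdir / "motion.csv")
    session.gains.to_csv(outdir / "gains.csv", index=False)
    truth = dataclasses.asdict(session.truth)
    truth["seed"] = session.seed
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
    paths.update(trials=str(outdir / "trials.csv"), motion=str(outdir / "motion.csv"),
                 gains=str(outdir / "gains.csv"), truth=str(outdir / "truth.yaml"))
    return paths
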