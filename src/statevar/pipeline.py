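"""End-to-end orchestration: simulate/load -> deconvolve -> states ->
templates -> project -> variability -> trialwise -> rtsim.

A run is driven by a YAML config (or an equivalent dict).  Every stage
writes CSV tables with a header row into the output directory and a JSON
manifest records package version, seeds, parameters, and a SHA-256 checksum
per written file.  Stage failures abort with the failing stage named;
tables already written are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import FIRDeconvolver, build_fir_design
from .nuisance import build_nuisance_set
from .projection import StateProjector
from .rtsim import integral_signature, simulate_mechanism
from .states import COMPONENTS, StateExtractor, group_average_timecourses
from .synthetic import GainAgeModel, GainGroundTruth, generate_cohort, make_task_design
from .trialwise import extract_snippets, prepare_behavior, trialwise_scan
from .variability import decompose_variance, fit_trajectory

log = logging.getLogger("statevar")

ALL_STAGES = (
    "simulate", "deconvolve", "states", "templates",
    "project", "variability", "trialwise", "rtsim",
)

__all__ = ["run_pipeline", "load_config", "ALL_STAGES"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: dict):
    if "simulate" not in config and "paths" not in config:
        raise ValueError("config must contain a 'simulate' or 'paths' block")
    if "paths" in config and "simulate" not in config:
        req = ("bold", "mask", "trials", "motion")
        missing = [k for k in req if k not in config["paths"]]
        if missing:
            raise ValueError(f"real-data config missing paths: {missing}")
        absent = [k for k in req
                  if not pathlib.Path(config["paths"][k]).exists()]
        if absent:
            raise ValueError(f"referenced files do not exist: {absent}")


def run_pipeline(config: dict, outdir, seed: int | None = None, stages=None) -> dict:
    """Execute the requested stages and return the manifest dict."""
    _validate(config)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages or ALL_STAGES)
    params = dict(config.get("params") or {})
    seed = int(config.get("seed", 0) if seed is None else seed)
    rng = np.random.default_rng(seed)

    manifest = {
        "statevar_version": __version__,
        "seed": seed,
        "params": params,
        "stages": [],
        "files": {},
    }

    def write_table(name, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["files"][name] = _sha256(path)

    state = {}
    try:
        for stage in stages:
            t0 = time.monotonic()
            log.info("stage=%s status=start", stage)
            _STAGE_FUNCS[stage](config, params, state, rng, write_table)
            dt = time.monotonic() - t0
            manifest["stages"].append({"stage": stage, "seconds": round(dt, 3)})
            log.info("stage=%s status=done seconds=%.2f", stage, dt)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _iter_sessions(state):
    for rec in state["subjects"]:
        for age, sess in zip(rec.ages, rec.sessions):
            yield rec.subject_id, age, sess


def _load_real_session(paths, params):
    """Load a preprocessed session (NIfTI + CSV) into pipeline state."""
    import types

    import nibabel as nib

    from .masks import Mask, motion_from_csv, series_from_nifti
    from .synthetic import SessionData

    mask_img = nib.load(paths["mask"])
    grid = np.asanyarray(mask_img.dataobj) > 0
    coords = np.column_stack(np.nonzero(grid))
    # left/right pairing by x-mirror about the mask bounding box; voxels
    # without a partner map to themselves
    lo, hi = coords[:, 0].min(), coords[:, 0].max()
    lookup = {tuple(c): i for i, c in enumerate(coords)}
    pairing = np.array([
        lookup.get((lo + hi - x, y, z), i)
        for i, (x, y, z) in enumerate(coords)
    ])
    pairing = np.where(pairing[pairing] == np.arange(len(coords)),
                       pairing, np.arange(len(coords)))
    mask = Mask(coords, pairing, mask_id=str(paths["mask"]))

    tr_s = float(params.get("tr_seconds", 1.5))
    bold = series_from_nifti(nib.load(paths["bold"]), mask, tr_s)
    trials = pd.read_csv(paths["trials"])
    motion = motion_from_csv(paths["motion"])
    n_runs = int(trials["run_index"].max())
    design = types.SimpleNamespace(
        n_runs=n_runs, n_tr_per_run=bold.n_tr // n_runs,
        tr_seconds=tr_s, trials=trials, n_tr=bold.n_tr,
    )
    return SessionData(bold=bold, trials=trials, motion=motion,
                       gains=pd.DataFrame(), truth=None, design=design, seed=-1)


def _stage_simulate(config, params, state, rng, write_table):
    if "simulate" not in config and "paths" in config:
        import types

        sess = _load_real_session(config["paths"], params)
        age = float(config.get("age", np.nan))
        rec = types.SimpleNamespace(subject_id=0, ages=[age], sessions=[sess])
        state["subjects"] = [rec]
        write_table("sessions.csv", pd.DataFrame([{
            "subject": 0, "age": age,
            "mean_fd": float(sess.motion.total_displacement.mean()),
            "n_correct": int(sess.trials["correct"].sum()),
        }]))
        return
    sim = dict(config.get("simulate") or {})
    design = make_task_design(
        n_runs=int(sim.get("n_runs", 3)),
        trials_per_cell_per_run=int(sim.get("trials_per_cell_per_run", 1)),
        seed=int(sim.get("design_seed", 0)),
    )
    slopes = {c: 0.0 for c in COMPONENTS}
    slopes.update(sim.get("gain_sd_slopes") or {})
    model = GainAgeModel(slope=slopes)
    cohort = generate_cohort(
        n_subjects=int(sim.get("n_subjects", 4)),
        age_range=tuple(sim.get("age_range", (8.0, 33.0))),
        age_model=model,
        sessions_per_subject=int(sim.get("sessions_per_subject", 2)),
        n_voxels_per_hemisphere=int(sim.get("n_voxels_per_hemisphere", 300)),
        design=design,
        base_truth=GainGroundTruth(),
        seed=int(rng.integers(2**31)),
    )
    state["cohort"] = cohort
    state["subjects"] = cohort.subjects
    state["patterns_true"] = cohort.patterns
    state["design"] = design
    write_table("sessions.csv", cohort.sessions_frame())


def _stage_deconvolve(config, params, state, rng, write_table):
    rows = []
    state["deconv"] = {}
    for sid, age, sess in _iter_sessions(state):
        design = build_fir_design(
            sess.trials, sess.design.n_tr_per_run, sess.design.n_runs,
            motion=sess.motion, tr_seconds=sess.design.tr_seconds,
        )
        dec = FIRDeconvolver().fit(sess.bold, design)
        state["deconv"][(sid, age)] = dec
        rows.append(dict(subject=sid, age=age,
                         n_regressors=design.matrix.shape[1],
                         mean_residual_sd=float(dec.residual_sd_.mean())))
    write_table("deconvolution_summary.csv", pd.DataFrame(rows))


def _stage_states(config, params, state, rng, write_table):
    avgs = [d.trial_averages_ for d in state["deconv"].values()]
    ages = [age for (_, age) in state["deconv"].keys()]
    if len(avgs) < 2 or not np.all(np.isfinite(ages)):
        ages = None
    group = group_average_timecourses(avgs, ages=ages)
    extractor = StateExtractor(lag_tr=int(params.get("lag_tr", 4))).fit(group)
    state["states"] = extractor.states_
    S = extractor.states_.matrix()
    gram = S.T @ S
    rows = []
    for i, c in enumerate(COMPONENTS):
        rows.append(dict(component=c, norm=float(np.sqrt(gram[i, i])),
                         max_cross_cosine=float(
                             np.max(np.abs(np.delete(gram[i], i))))))
    write_table("states_summary.csv", pd.DataFrame(rows))


def _stage_templates(config, params, state, rng, write_table):
    maps = np.mean(
        [d.motion_coef_maps_ / np.where(d.residual_sd_ > 0, d.residual_sd_, 1)[None, :]
         for d in state["deconv"].values()], axis=0)
    mask = state["states"].mask
    nuis = build_nuisance_set(
        maps, residual_sd=None, mask=mask,
        variance_target=float(params.get("variance_target", 0.90)),
    )
    state["nuisance"] = nuis
    write_table("templates_summary.csv", pd.DataFrame([dict(
        n_motion_templates=nuis.n_motion,
        motion_variance_captured=float(nuis.motion_variance_captured.sum()),
        n_total=len(nuis),
    )]))


def _stage_project(config, params, state, rng, write_table):
    proj = StateProjector(state["states"], state["nuisance"]).fit()
    state["fluct"] = {}
    rows = []
    for (sid, age), dec in state["deconv"].items():
        fluct = proj.transform(dec.residuals_.series).zscore()
        state["fluct"][(sid, age)] = fluct
        w = fluct.state_weights()
        for k, c in enumerate(COMPONENTS):
            rows.append(dict(subject=sid, age=age, component=c,
                             fluct_sd_raw=float(
                                 proj.transform(dec.residuals_.series)
                                 .state_weights()[k].std())))
    write_table("expression_summary.csv", pd.DataFrame(rows))


def _stage_variability(config, params, state, rng, write_table):
    window = params.get("window", list(range(6)))
    rows = []
    sessions = {(sid, age): sess for sid, age, sess in _iter_sessions(state)}
    for (sid, age), dec in state["deconv"].items():
        sess = sessions[(sid, age)]
        correct = sess.trials[sess.trials["correct"].astype(bool)]
        vd = decompose_variance(
            dec.residuals_.series, state["states"], state["nuisance"],
            correct["mgs_tr"].to_numpy(), window=window,
        )
        rows.append(dict(
            subject=sid, age=age,
            total_brain_state_variability=vd.total_brain_state_variability,
            motion_template_variance=vd.motion_template_variance,
            vme_ratio=vd.component_ratio("vme"),
            maint_ratio=vd.component_ratio("maint"),
            retr_ratio=vd.component_ratio("retr"),
            mean_fd=float(sess.motion.total_displacement.mean()),
            n_correct=int(correct.shape[0]),
        ))
    df = pd.DataFrame(rows)
    state["variability"] = df
    write_table("variability.csv", df)

    if df["subject"].nunique() < 2 or len(df) < 3 or not np.isfinite(df["age"]).all():
        return  # trajectory fits need a multi-subject cohort with ages
    fits = []
    cov = df[["mean_fd", "n_correct"]]
    for col in ("total_brain_state_variability", "vme_ratio",
                "maint_ratio", "retr_ratio"):
        for form in ("linear_age", "inverse_age"):
            fit = fit_trajectory(df[col], df["age"], df["subject"],
                                 covariates=cov, form=form)
            fits.append(dict(measure=col, form=form,
                             age_slope=fit.age_slope,
                             p_age=float(fit.pvalues["age_term"]),
                             loglik=fit.loglik, aic=fit.aic,
                             endpoint_change=fit.endpoint_change))
    write_table("trajectory_fits.csv", pd.DataFrame(fits))


def _stage_trialwise(config, params, state, rng, write_table):
    sessions = {(sid, age): sess for sid, age, sess in _iter_sessions(state)}
    stacks, tables = [], []
    for key, fluct in state["fluct"].items():
        sess = sessions[key]
        trials = sess.trials.copy()
        trials["subject"] = key[0]
        trials["session"] = f"{key[0]}_{key[1]:.2f}"
        stack = extract_snippets(fluct, trials)
        stacks.append(stack.data)
        tables.append(stack.trials)
    from .trialwise import SnippetStack

    all_trials = prepare_behavior(pd.concat(tables, ignore_index=True))
    stack = SnippetStack(np.concatenate(stacks, axis=0),
                         np.arange(-15, 16), all_trials)
    rel_trs = params.get("rel_trs", list(range(-5, 8)))
    n_sim = int(params.get("n_sim", 500))
    for behavior in ("rt", "se"):
        scan = trialwise_scan(stack, behavior, rel_trs, n_sim=n_sim,
                              seed=int(rng.integers(2**31)))
        write_table(f"trialwise_{behavior}.csv", scan)
    state["snippet_stack"] = stack


def _stage_rtsim(config, params, state, rng, write_table):
    rts = None
    if "subjects" in state:
        rt_all = pd.concat(
            [s.trials["rt_ms"] for _, _, s in _iter_sessions(state)]).dropna()
        if len(rt_all) >= 20:
            rts = rt_all.to_numpy() / 1000.0
    rows = []
    for mode in ("timing", "amplitude", "mixed"):
        sim = simulate_mechanism(mode, rt_distribution=rts,
                                 seed=int(rng.integers(2**31)))
        rows.append(dict(mode=mode,
                         terminal_fast=sim.terminal_fast,
                         terminal_slow=sim.terminal_slow,
                         classification=integral_signature(sim)))
    write_table("rtsim.csv", pd.DataFrame(rows))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deconvolve": _stage_deconvolve,
    "states": _stage_states,
    "templates": _stage_templates,
    "project": _stage_project,
    "variability": _stage_variability,
    "trialwise": _stage_trialwise,
    "rtsim": _stage_rtsim,
}
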