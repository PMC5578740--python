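"""Trial-level behavior and the trial-wise brain-state/behavior regression.

Saccades are detected from 60 Hz eye-velocity traces (local maxima above a
minimum peak velocity, event boundaries where velocity first drops below a
tenth of the peak on each flank).  Reaction time is the interval between
fixation offset and MGS onset; saccadic error the signed horizontal angle
between target and MGS endpoint.

For the brain/behavior analysis, z-scored fluctuation time courses are cut
into snippets of +/-15 TRs around each MGS.  At each relative TR a full
model (three mean-state terms plus three spatial-state x hemifield
interactions) is compared with a null model (run, hemifield, eccentricity
and its square, the other behavioral measure and its square, subject) via
the difference in ordinary R^2 and a simulated likelihood-ratio test --
a parametric bootstrap of the null model, refitting both models per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .projection import ExpressionSeries
from .states import COMPONENTS

__all__ = [
    "detect_saccades",
    "score_trials",
    "behavioral_summaries",
    "SnippetStack",
    "extract_snippets",
    "prepare_behavior",
    "trialwise_regression",
    "trialwise_scan",
    "speed_accuracy_quadratic",
    "TrialwiseFitRow",
]

SNIPPET_HALF_WIDTH = 15
MEAN_TERMS = ("vme_mean", "maint_mean", "retr_mean")
SPATIAL_TERMS = ("vme_spatial", "maint_spatial", "retr_spatial")


def detect_saccades(velocity, rate_hz: float = 60.0, min_peak: float = 30.0,
                    boundary_fraction: float = 0.1):
    """Detect saccade events in a velocity trace (deg/s).

    Candidate events are local velocity maxima of at least ``min_peak``
    deg/s; each event's start and end are the first samples, scanning
    backward and forward from the peak, where velocity drops below
    ``boundary_fraction`` of the peak.  Peaks are claimed in descending
    amplitude order and peaks falling inside an already-claimed event are
    dropped, so events never overlap.  Returns a list of
    ``(start, peak, end)`` sample indices sorted by start.
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0 or not np.any(v > 0):
        return []
    n = v.size
    peaks = [
        i for i in range(1, n - 1)
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] >= min_peak
    ]
    peaks.sort(key=lambda i: -v[i])
    events = []
    claimed = np.zeros(n, dtype=bool)
    for p in peaks:
        if claimed[p]:
            continue
        thresh = v[p] * boundary_fraction
        s = p
        while s > 0 and v[s - 1] >= thresh:
            s -= 1
        e = p
        while e < n - 1 and v[e + 1] >= thresh:
            e += 1
        if claimed[s : e + 1].any():
            continue
        claimed[s : e + 1] = True
        events.append((s, p, e))
    events.sort(key=lambda ev: ev[0])
    return events


def score_trials(
    events,
    position,
    trials: pd.DataFrame,
    rate_hz: float = 60.0,
    encode_window_s: float = 1.0,
    response_window_s: float = 1.2,
):
    """Score detected saccades against the trial schedule.

    ``trials`` needs columns ``target_onset_s`` (visually guided saccade go),
    ``fixation_off_s`` (MGS go cue), ``target_deg``, and the condition
    columns ``presentation_s``/``delay_s``.  A trial is measurably correct
    only when a saccade starts within the encoding window after target onset
    AND within the response window after fixation offset; the MGS endpoint
    is the eye position at the saccade's end sample.

    Returns ``(scored trials, flags)`` where flags mark sessions failing the
    requirement that at least 50% of trials of each of the four trial types
    be measurably correct.
    """
    pos = np.asarray(position, dtype=float)
    starts = np.array([ev[0] for ev in events], dtype=int)
    ends = np.array([ev[2] for ev in events], dtype=int)

    def first_in(window_start_s, window_len_s):
        lo = window_start_s * rate_hz
        hi = (window_start_s + window_len_s) * rate_hz
        hits = np.where((starts >= lo) & (starts < hi))[0]
        return int(hits[0]) if hits.size else None

    out = trials.copy()
    rt_ms, se_deg, correct = [], [], []
    for row in trials.itertuples(index=False):
        enc = first_in(row.target_onset_s, encode_window_s)
        mgs = first_in(row.fixation_off_s, response_window_s)
        if enc is None or mgs is None:
            rt_ms.append(np.nan)
            se_deg.append(np.nan)
            correct.append(False)
            continue
        rt = (starts[mgs] / rate_hz - row.fixation_off_s) * 1000.0
        endpoint = pos[min(ends[mgs], pos.size - 1)]
        rt_ms.append(rt)
        se_deg.append(endpoint - row.target_deg)
        correct.append(True)
    out["rt_ms"] = rt_ms
    out["se_deg"] = se_deg
    out["correct"] = correct

    frac = out.groupby(["presentation_s", "delay_s"])["correct"].mean()
    flags = {
        "measurable_fraction": frac.to_dict(),
        "excluded": bool((frac < 0.5).any()),
    }
    return out, flags


def behavioral_summaries(trials: pd.DataFrame, min_trials: int = 2) -> pd.DataFrame:
    """Per-condition mean RT, SD RT, inaccuracy and imprecision.

    Inaccuracy is |mean SE| per target, imprecision the SD of SE per target;
    both are averaged across the targets of a condition.  Cells with fewer
    than ``min_trials`` correct trials yield NaN.
    """
    rows = []
    correct = trials[trials["correct"].astype(bool)]
    for (pres, delay), sub in correct.groupby(["presentation_s", "delay_s"]):
        rec = {"presentation_s": pres, "delay_s": delay}
        rec["mean_rt_ms"] = sub["rt_ms"].mean() if len(sub) >= min_trials else np.nan
        rec["sd_rt_ms"] = sub["rt_ms"].std(ddof=1) if len(sub) >= min_trials else np.nan
        inac, imprec = [], []
        for _, tgt in sub.groupby(["hemifield", "eccentricity_deg"]):
            if len(tgt) >= min_trials:
                inac.append(abs(tgt["se_deg"].mean()))
                imprec.append(tgt["se_deg"].std(ddof=1))
        rec["inaccuracy_deg"] = float(np.mean(inac)) if inac else np.nan
        rec["imprecision_deg"] = float(np.mean(imprec)) if imprec else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SnippetStack:
    """trials x relative-TR (-15..+15) x 6 components of z-scored fluctuation."""

    data: np.ndarray
    rel_tr: np.ndarray
    trials: pd.DataFrame

    def at(self, rel_tr: int) -> np.ndarray:
        """(n_trials, 6) fluctuation values at one relative TR (NaN = edge)."""
        j = int(np.where(self.rel_tr == rel_tr)[0][0])
        return self.data[:, j, :]


def extract_snippets(
    fluct: ExpressionSeries,
    trials: pd.DataFrame,
    half_width: int = SNIPPET_HALF_WIDTH,
) -> SnippetStack:
    """Align fluctuation snippets to each MGS TR (relative TR 0 = the MGS).

    Out-of-bounds cells are NaN and are excluded from downstream fits.
    """
    W = fluct.state_weights()  # 6 x n_tr
    n_tr = W.shape[1]
    rel = np.arange(-half_width, half_width + 1)
    data = np.full((len(trials), rel.size, 6), np.nan)
    for i, mgs in enumerate(trials["mgs_tr"].to_numpy(dtype=int)):
        for j, dt in enumerate(rel):
            t = mgs + dt
            if 0 <= t < n_tr:
                data[i, j, :] = W[:, t]
    return SnippetStack(data, rel, trials.reset_index(drop=True))


def prepare_behavior(trials: pd.DataFrame, by=("presentation_s", "delay_s")) -> pd.DataFrame:
    """Add z-scored RT (``rt_z``) and rectified z-scored SE (``se_zr``).

    z-scores are computed within session x condition cells (and within
    subject when a ``subject`` column is present); SE is z-scored signed and
    then rectified so large values mean large error in either direction.
    """
    out = trials.copy()
    keys = list(by)
    if "subject" in out.columns:
        keys = ["subject"] + keys
    if "session" in out.columns:
        keys = keys + ["session"]

    def z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    out["rt_z"] = out.groupby(keys)["rt_ms"].transform(z)
    out["se_zr"] = out.groupby(keys)["se_deg"].transform(z).abs()
    return out


@dataclass(frozen=True)
class TrialwiseFitRow:
    rel_tr: int
    delta_r2: float
    r2_full: float
    r2_null: float
    lrt_stat: float
    p_sim: float
    coefficients: pd.Series
    n_trials: int


def _design_matrices(stack: SnippetStack, behavior: str, rel_tr: int):
    tr = stack.trials
    snip = stack.at(rel_tr)
    if behavior == "rt":
        y = tr["rt_z"].to_numpy(dtype=float)
        other = tr["se_zr"].to_numpy(dtype=float)
    elif behavior == "se":
        y = tr["se_zr"].to_numpy(dtype=float)
        other = tr["rt_z"].to_numpy(dtype=float)
    else:
        raise ValueError("behavior must be 'rt' or 'se'")
    hemi = tr["hemifield"].to_numpy(dtype=float)
    ecc = tr["eccentricity_code"].to_numpy(dtype=float)
    null_cols = {
        "run": tr["run_index"].to_numpy(dtype=float),
        "hemifield": hemi,
        "eccentricity": ecc,
        "eccentricity_sq": ecc**2,
        "other_behavior": other,
        "other_behavior_sq": other**2,
    }
    Xn = pd.DataFrame(null_cols)
    Xn.insert(0, "Intercept", 1.0)
    if "subject" in tr.columns and tr["subject"].nunique() > 1:
        dummies = pd.get_dummies(tr["subject"], prefix="subject", drop_first=True)
        Xn = pd.concat([Xn, dummies.astype(float)], axis=1)
    Xf = Xn.copy()
    comp_idx = {c: k for k, c in enumerate(COMPONENTS)}
    for name in MEAN_TERMS:
        Xf[name] = snip[:, comp_idx[name]]
    for name in SPATIAL_TERMS:
        Xf[f"{name}_x_hemi"] = snip[:, comp_idx[name]] * hemi
    ok = np.isfinite(y) & np.all(np.isfinite(Xf.to_numpy()), axis=1)
    return y[ok], Xn.loc[ok], Xf.loc[ok]


def _ols_r2_rss(X, y):
    Q, _ = np.linalg.qr(X)
    fit = Q @ (Q.T @ y)
    rss = float(np.sum((y - fit) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 0.0, rss, Q


def trialwise_regression(
    stack: SnippetStack,
    behavior: str,
    rel_tr: int,
    n_sim: int = 5000,
    seed: int = 0,
) -> TrialwiseFitRow:
    """Full-vs-null model comparison at one relative TR.

    Both models are Gaussian linear models fit by OLS (subject enters as
    fixed intercepts when present).  The simulated likelihood-ratio test is
    a parametric bootstrap: ``n_sim`` datasets are drawn from the fitted
    null model and both models are refit to each, giving the null
    distribution of the LRT statistic ``n*log(RSS_null/RSS_full)``.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a very coarse simulated LRT p-value",
                      stacklevel=2)
    y, Xn, Xf = _design_matrices(stack, behavior, rel_tr)
    n = y.size
    if n < Xf.shape[1] + 2:
        raise ValueError("too few complete trials at this relative TR")
    Xn_a, Xf_a = Xn.to_numpy(), Xf.to_numpy()
    r2n, rss0, Q0 = _ols_r2_rss(Xn_a, y)
    r2f, rss1, Q1 = _ols_r2_rss(Xf_a, y)
    stat = n * np.log(rss0 / rss1) if rss1 > 0 else np.inf

    coef_full, *_ = np.linalg.lstsq(Xf_a, y, rcond=None)
    coefs = pd.Series(coef_full, index=list(Xf.columns))

    # parametric bootstrap of the null, vectorized over draws
    rng = np.random.default_rng(seed)
    fit0 = Q0 @ (Q0.T @ y)
    sigma0 = np.sqrt(rss0 / n)
    Ystar = fit0[:, None] + rng.normal(0.0, sigma0, (n, n_sim))
    tot = np.sum(Ystar**2, axis=0)
    rss0_star = tot - np.sum((Q0.T @ Ystar) ** 2, axis=0)
    rss1_star = tot - np.sum((Q1.T @ Ystar) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_star = n * np.log(rss0_star / rss1_star)
    p = (1.0 + np.sum(stat_star >= stat)) / (n_sim + 1.0)

    keep = [c for c in Xf.columns if c in [*MEAN_TERMS] or c.endswith("_x_hemi")]
    return TrialwiseFitRow(
        rel_tr=rel_tr, delta_r2=r2f - r2n, r2_full=r2f, r2_null=r2n,
        lrt_stat=float(stat), p_sim=float(p), coefficients=coefs[keep],
        n_trials=n,
    )


def trialwise_scan(
    stack: SnippetStack,
    behavior: str,
    rel_trs=None,
    n_sim: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the regression at each relative TR; one row per TR."""
    if rel_trs is None:
        rel_trs = stack.rel_tr
    rng = np.random.default_rng(seed)
    rows = []
    for rt in rel_trs:
        try:
            fit = trialwise_regression(stack, behavior, int(rt), n_sim,
                                       seed=int(rng.integers(2**31)))
        except ValueError:
            continue
        row = {"rel_tr": fit.rel_tr, "delta_r2": fit.delta_r2, "p_sim": fit.p_sim,
               "lrt_stat": fit.lrt_stat, "n_trials": fit.n_trials}
        row.update({f"coef_{k}": v for k, v in fit.coefficients.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def speed_accuracy_quadratic(rt_z, se):
    """Quadratic speed/accuracy relation: SE regressed on rt_z and rt_z^2.

    Returns (coefficient, standard error, p) for the quadratic term; a
    positive coefficient means both unusually fast and unusually slow
    responses are less accurate.
    """
    import statsmodels.api as sm

    rt_z = np.asarray(rt_z, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(rt_z) & np.isfinite(se)
    rt_z, se = rt_z[ok], se[ok]
    if rt_z.size < 10:
        raise ValueError("need at least 10 trials")
    if rt_z.std() == 0 or se.std() == 0:
        raise ValueError("degenerate variance")
    X = sm.add_constant(np.column_stack([rt_z, rt_z**2]))
    res = sm.OLS(se, X).fit()
    return float(res.params[2]), float(res.bse[2]), float(res.pvalues[2])
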