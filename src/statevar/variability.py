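"""Brain-state variance decomposition and its developmental trajectories.

For the TRs around each correct memory-guided saccade (offsets 0-5), the
whole-brain residual at each TR is split -- on an orthonormalized basis in
the order nuisance, VME, maintenance, retrieval -- into squared error
attributable to each brain state (SS_VME, SS_Maint, SS_Retrieval, summing
exactly to SS_brain), to the motion templates (SS_motion), and the remaining
SS_error.  Total brain state variability is SS_brain/(SS_brain + SS_error);
motion template variance is SS_motion/(SS_brain + SS_error).

Developmental change in these per-session ratios is modeled with linear
mixed-effects trajectories (random subject intercept, optionally a random
age slope), comparing linear-age and inverse-age forms by maximum
likelihood.  A biased mean-matched bootstrap tests whether age-group
differences survive reversing the age/motion confound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .masks import VolumeSeries
from .nuisance import NuisanceSet
from .projection import ExpressionSeries
from .states import COMPONENTS, BrainStateSet

__all__ = [
    "VarianceDecomposition",
    "decompose_variance",
    "TrajectoryFit",
    "TrajectoryModel",
    "fit_trajectory",
    "per_subject_coefficients",
    "individual_slope_correlation",
    "mean_match_subsample",
]

WINDOW_TRS = tuple(range(6))  # offsets 0-5 from each correct MGS


@dataclass(frozen=True)
class VarianceDecomposition:
    ss_vme: float
    ss_maint: float
    ss_retr: float
    ss_motion: float
    ss_nuisance: float
    ss_error: float
    window: tuple
    n_tr_used: int
    component_ss: dict = field(default_factory=dict)  # per canonical component

    @property
    def ss_brain(self) -> float:
        return self.ss_vme + self.ss_maint + self.ss_retr

    @property
    def total_brain_state_variability(self) -> float:
        return self.ss_brain / (self.ss_brain + self.ss_error)

    @property
    def motion_template_variance(self) -> float:
        return self.ss_motion / (self.ss_brain + self.ss_error)

    def component_ratio(self, group: str) -> float:
        ss = {"vme": self.ss_vme, "maint": self.ss_maint, "retr": self.ss_retr}[group]
        return ss / (self.ss_brain + self.ss_error)


def decompose_variance(
    residuals: VolumeSeries,
    states: BrainStateSet,
    nuisance: NuisanceSet | None,
    mgs_trs,
    window=WINDOW_TRS,
) -> VarianceDecomposition:
    """Windowed squared-error decomposition of the residual series.

    ``mgs_trs`` are the TR indices of correct MGS events; the window offsets
    are added to each.  Attribution uses jointly-fit weights on a
    sequentially orthonormalized basis (nuisance first, then VME,
    maintenance, retrieval), so SS_brain = SS_VME + SS_Maint + SS_Retrieval
    holds exactly.
    """
    mgs_trs = np.asarray(list(mgs_trs), dtype=int)
    if mgs_trs.size == 0:
        raise ValueError("empty correct-trial set")
    trs = (mgs_trs[:, None] + np.asarray(window)[None, :]).ravel()
    if trs.min() < 0 or trs.max() >= residuals.n_tr:
        raise ValueError("window TRs fall outside the residual series")

    blocks, labels = [], []
    if nuisance is not None:
        blocks.append(nuisance.matrix())
        labels += list(nuisance.names)
    S = states.matrix()
    blocks.append(S)
    labels += list(COMPONENTS)
    X = np.column_stack(blocks)
    Q, _ = np.linalg.qr(X)

    Y = residuals.data[:, trs]  # voxels x windowed TRs
    C = Q.T @ Y  # basis x TRs contributions
    contrib = (C**2).sum(axis=1)  # per basis vector
    total = float((Y**2).sum())

    def group_ss(prefix):
        return float(sum(
            contrib[i] for i, lab in enumerate(labels) if lab.startswith(prefix)
        ))

    comp_ss = {
        lab: float(contrib[labels.index(lab)]) for lab in COMPONENTS
    }
    ss_vme = comp_ss["vme_mean"] + comp_ss["vme_spatial"]
    ss_maint = comp_ss["maint_mean"] + comp_ss["maint_spatial"]
    ss_retr = comp_ss["retr_mean"] + comp_ss["retr_spatial"]
    ss_motion = group_ss("motion_pc")
    ss_nuis = float(sum(
        contrib[i] for i, lab in enumerate(labels) if lab not in COMPONENTS
    ))
    ss_error = total - float(contrib.sum())
    return VarianceDecomposition(
        ss_vme=ss_vme, ss_maint=ss_maint, ss_retr=ss_retr,
        ss_motion=ss_motion, ss_nuisance=ss_nuis, ss_error=max(ss_error, 0.0),
        window=tuple(window), n_tr_used=trs.size, component_ss=comp_ss,
    )


@dataclass(frozen=True)
class TrajectoryFit:
    form: str
    fixed_effects: pd.Series
    fixed_se: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n_params: int
    subject_coefficients: pd.DataFrame  # per-subject intercept/slope (fixed + BLUP)
    endpoint_change: float  # fitted value at age 8 minus at age 33, fixed effects only
    used_mixed: bool

    @property
    def age_slope(self) -> float:
        return float(self.fixed_effects["age_term"])


def _age_term(age, form):
    age = np.asarray(age, dtype=float)
    if form == "linear_age":
        return age
    if form == "inverse_age":
        return 1.0 / age
    raise ValueError(f"unknown trajectory form {form!r}")


class TrajectoryModel(BaseEstimator):
    """Mixed-effects developmental trajectory of a per-session scalar.

    ``form`` selects a linear-age or inverse-age fixed effect; covariates
    (e.g. mean FD, number of correct trials) enter as fixed effects.  A
    random subject intercept is always included; a random age slope is added
    when ``random_slope`` (used for extracting per-subject brain-variability
    slopes from subjects with many sessions).  Fits use maximum likelihood so
    log-likelihoods and AIC are comparable across forms.  A singular or
    non-converged fit falls back to OLS with a warning.
    """

    def __init__(self, form: str = "linear_age", random_slope: bool = False):
        self.form = form
        self.random_slope = random_slope

    def fit(self, y, age, subject, covariates: pd.DataFrame | None = None):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        y = np.asarray(y, dtype=float)
        subject = np.asarray(subject)
        if len(np.unique(subject)) < 2 or y.size < 3:
            raise ValueError("need >=2 subjects and >=3 sessions")
        at = _age_term(age, self.form)
        X = pd.DataFrame({"Intercept": np.ones_like(y), "age_term": at})
        if covariates is not None:
            for c in covariates.columns:
                X[c] = np.asarray(covariates[c], dtype=float)

        used_mixed = True
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if self.random_slope:
                    exog_re = X[["Intercept", "age_term"]]
                else:
                    exog_re = X[["Intercept"]]
                model = MixedLM(y, X, groups=subject, exog_re=exog_re)
                res = model.fit(reml=False)
                if not res.converged or not np.all(np.isfinite(res.bse_fe)):
                    res = None
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is not None:
            fe = res.fe_params
            se = res.bse_fe
            pv = res.pvalues[fe.index]
            llf = float(res.llf)
            k = len(fe) + res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2 + 1
            re = res.random_effects
            rows = {}
            for sid, vals in re.items():
                rows[sid] = {
                    "intercept": float(fe["Intercept"] + vals.get("Intercept", vals.iloc[0])),
                    "age_term": float(
                        fe["age_term"] + (vals.get("age_term", 0.0) if self.random_slope else 0.0)
                    ),
                }
            sub_coef = pd.DataFrame(rows).T
        else:
            used_mixed = False
            warnings.warn("mixed model failed to converge; OLS fallback", stacklevel=2)
            ols = sm.OLS(y, X).fit()
            fe, se, pv, llf = ols.params, ols.bse, ols.pvalues, float(ols.llf)
            k = len(fe) + 1
            sub_coef = pd.DataFrame(
                {sid: {"intercept": fe["Intercept"], "age_term": fe["age_term"]}
                 for sid in np.unique(subject)}
            ).T

        at8, at33 = _age_term(8.0, self.form), _age_term(33.0, self.form)
        endpoint = float(fe["age_term"] * (at8 - at33))
        self.result_ = TrajectoryFit(
            form=self.form, fixed_effects=fe, fixed_se=se, pvalues=pv,
            loglik=llf, aic=2 * k - 2 * llf, n_params=k,
            subject_coefficients=sub_coef, endpoint_change=endpoint,
            used_mixed=used_mixed,
        )
        return self


def fit_trajectory(y, age, subject, covariates=None, form="linear_age",
                   random_slope=False) -> TrajectoryFit:
    """Functional wrapper over :class:`TrajectoryModel`."""
    return TrajectoryModel(form, random_slope).fit(y, age, subject, covariates).result_


def per_subject_coefficients(y, age, subject, form="inverse_age",
                             min_sessions: int = 4) -> pd.Series:
    """Per-subject OLS age-term coefficients for subjects with enough sessions."""
    df = pd.DataFrame({"y": np.asarray(y, float), "age": np.asarray(age, float),
                       "subject": np.asarray(subject)})
    out = {}
    for sid, sub in df.groupby("subject"):
        if len(sub) < min_sessions:
            continue
        at = _age_term(sub["age"], form)
        X = np.column_stack([np.ones(len(sub)), at])
        coef, *_ = np.linalg.lstsq(X, sub["y"].to_numpy(), rcond=None)
        out[sid] = float(coef[1])
    return pd.Series(out, name=f"coef_{form}")


def individual_slope_correlation(brain_slopes: pd.Series, behavior_coeffs: pd.Series):
    """Pearson correlation across subjects of brain vs behavior trajectories.

    Sign convention: brain slopes are linear-age coefficients (stabilizing
    brain = negative slope); behavior coefficients are inverse-age
    coefficients (stabilizing behavior = positive coefficient); a *negative*
    correlation therefore means subjects whose brain-state variability falls
    fastest also stabilize behaviorally fastest.
    """
    common = brain_slopes.index.intersection(behavior_coeffs.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 qualifying subjects")
    r, p = stats.pearsonr(brain_slopes[common], behavior_coeffs[common])
    return float(r), float(p)


def mean_match_subsample(
    fd_a, y_a, fd_b, y_b,
    bias: str = "a_greater",
    n_boot: int = 1000,
    n_bins: int = 20,
    min_gap: float | None = None,
    seed: int = 0,
) -> dict:
    """Biased bootstrap reversing the FD difference between two groups.

    Resampling weights are assigned on ``n_bins`` equal-count bins of the
    pooled framewise-displacement distribution, tilted geometrically until
    the expected resampled FD mean of the favoured group exceeds the other
    by at least ``min_gap`` (default: 0.2 pooled SD).  Returns bootstrap
    distributions of the group means of ``y``, their difference, and the 95%
    percentile CI.
    """
    fd_a, y_a = np.asarray(fd_a, float), np.asarray(y_a, float)
    fd_b, y_b = np.asarray(fd_b, float), np.asarray(y_b, float)
    if fd_a.size == 0 or fd_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if bias not in ("a_greater", "b_greater"):
        raise ValueError("bias must be 'a_greater' or 'b_greater'")
    sign = 1.0 if bias == "a_greater" else -1.0

    pooled = np.concatenate([fd_a, fd_b])
    if min_gap is None:
        min_gap = 0.2 * pooled.std()
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    bins_a = np.clip(np.searchsorted(edges, fd_a, side="right") - 1, 0, n_bins - 1)
    bins_b = np.clip(np.searchsorted(edges, fd_b, side="right") - 1, 0, n_bins - 1)
    centered = (np.arange(n_bins) - (n_bins - 1) / 2) / n_bins

    def weighted_means(beta):
        wa = np.exp(sign * beta * centered[bins_a])
        wb = np.exp(-sign * beta * centered[bins_b])
        wa, wb = wa / wa.sum(), wb / wb.sum()
        return wa, wb, float(wa @ fd_a - wb @ fd_b)

    beta, gap = 0.0, weighted_means(0.0)[2] * sign
    while gap < min_gap and beta < 200.0:
        beta = beta * 2 if beta else 1.0
        gap = weighted_means(beta)[2] * sign
    if gap < min_gap:
        raise ValueError("requested FD bias unachievable given group supports")
    wa, wb, _ = weighted_means(beta)

    rng = np.random.default_rng(seed)
    na, nb = fd_a.size, fd_b.size
    mean_a = np.empty(n_boot)
    mean_b = np.empty(n_boot)
    fd_mean_a = np.empty(n_boot)
    fd_mean_b = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.choice(na, size=na, replace=True, p=wa)
        ib = rng.choice(nb, size=nb, replace=True, p=wb)
        mean_a[i], mean_b[i] = y_a[ia].mean(), y_b[ib].mean()
        fd_mean_a[i], fd_mean_b[i] = fd_a[ia].mean(), fd_b[ib].mean()
    diff = mean_a - mean_b
    ci = (float(np.quantile(diff, 0.025)), float(np.quantile(diff, 0.975)))
    return {
        "mean_a": mean_a, "mean_b": mean_b, "difference": diff,
        "ci95": ci, "fd_mean_a": fd_mean_a, "fd_mean_b": fd_mean_b,
        "beta": beta, "weights_a": wa, "weights_b": wb,
    }
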