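"""Whole-brain pattern projection: volumes -> brain-state expression weights.

Each whole-brain volume is vectorized and regressed (OLS across voxels) on a
design matrix made of the six brain-state patterns and the spatial nuisance
templates, fit jointly.  The six state weights, ordered in time, form an
expression time course when applied to average trial series, or a
fluctuation time course when applied to the residual series -- positive
values mean a state was present to a greater extent than average at that TR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .masks import MaskedVolume, VolumeSeries
from .nuisance import NuisanceSet
from .states import COMPONENTS, BrainStateSet

__all__ = ["ExpressionSeries", "StateProjector", "project_volume", "expression_timecourse"]


@dataclass(frozen=True)
class ExpressionSeries:
    """components x TRs matrix of per-TR regression weights."""

    weights: np.ndarray
    labels: tuple
    tr_seconds: float = 1.5
    zscored: bool = False

    def __post_init__(self):
        if self.weights.shape[0] != len(self.labels):
            raise ValueError("weights rows must match labels")

    def component(self, name: str) -> np.ndarray:
        return self.weights[self.labels.index(name)]

    def state_weights(self) -> np.ndarray:
        """(6, n_tr) restricted to the canonical state components."""
        idx = [self.labels.index(c) for c in COMPONENTS]
        return self.weights[idx]

    def zscore(self) -> "ExpressionSeries":
        """Temporally z-score each component over the session."""
        w = self.weights
        mu = w.mean(axis=1, keepdims=True)
        sd = w.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return ExpressionSeries((w - mu) / sd, self.labels, self.tr_seconds, True)


class StateProjector(BaseEstimator, TransformerMixin):
    """Project masked volumes onto states + nuisance templates by OLS.

    Parameters
    ----------
    states : BrainStateSet (unit-norm convention from state extraction)
    nuisance : NuisanceSet or None

    ``transform`` accepts a MaskedVolume (returns a weight vector) or a
    VolumeSeries (returns an ExpressionSeries).  The combined design must be
    full rank; a rank-deficient design raises an error naming a collinear
    column.
    """

    def __init__(self, states: BrainStateSet, nuisance: NuisanceSet | None = None,
                 rank_tol: float = 1e-10):
        self.states = states
        self.nuisance = nuisance
        self.rank_tol = rank_tol

    def fit(self, X=None, y=None):
        S = self.states.matrix()
        labels = list(COMPONENTS)
        if self.nuisance is not None:
            N = self.nuisance.matrix()
            X_ = np.column_stack([S, N])
            labels += list(self.nuisance.names)
        else:
            X_ = S
        from scipy.linalg import qr

        _, R, piv = qr(X_, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > self.rank_tol * diag[0]))
        if rank < X_.shape[1]:
            bad = [labels[p] for p in piv[rank:]]
            raise ValueError(f"rank-deficient projection design; collinear: {bad}")
        self.design_ = X_
        self.labels_ = tuple(labels)
        self.pinv_ = np.linalg.pinv(X_)
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "pinv_"):
            self.fit()

    def transform(self, X):
        self._ensure_fitted()
        if isinstance(X, VolumeSeries):
            W = self.pinv_ @ X.data  # n_regressors x n_tr
            return ExpressionSeries(W, self.labels_, X.tr_seconds)
        values = X.values if isinstance(X, MaskedVolume) else np.asarray(X, float)
        return self.pinv_ @ values

    def project_volume(self, volume):
        """Weights plus the residual volume for a single pattern."""
        self._ensure_fitted()
        v = volume.values if isinstance(volume, MaskedVolume) else np.asarray(volume, float)
        w = self.pinv_ @ v
        resid = v - self.design_ @ w
        return w, resid


def project_volume(volume, states: BrainStateSet, nuisance: NuisanceSet | None = None):
    """Return (weights, labels, residual volume) for one whole-brain volume."""
    proj = StateProjector(states, nuisance).fit()
    w, resid = proj.project_volume(volume)
    return w, proj.labels_, resid


def expression_timecourse(
    series: VolumeSeries, states: BrainStateSet, nuisance: NuisanceSet | None = None,
    zscore: bool = False,
) -> ExpressionSeries:
    """Per-TR projection of a series; optionally temporally z-scored."""
    out = StateProjector(states, nuisance).fit().transform(series)
    return out.zscore() if zscore else out
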