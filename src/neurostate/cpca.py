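"""Correlation-informed PCA (cPCA).

PCA alone does not say which principal components carry task information.
The cPCA block fits an ordinary mean-centered PCA on the firing-rate matrix
and then retains only those components whose projections correlate with the
binary state labels at |r| >= a retention benchmark (default 0.2, the
conventional weak-correlation floor). This module also provides the two
supporting analyses: the per-trial PC-correlation survey that motivates the
benchmark, and the regression of per-channel PC loadings on per-channel
state rate differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import InputError, NoEligibleComponentsError, ParameterError
from .preprocess import RateMatrix, StateLabels

__all__ = [
    "PCAModel",
    "ComponentSelection",
    "LoadingRegressionResult",
    "SurveyResult",
    "fit_pca",
    "project",
    "correlate_projections",
    "select_components",
    "survey_per_trial_correlations",
    "loading_rate_regression",
]


@dataclass
class PCAModel:
    """Mean-centered PCA of the channel rate matrix.

    ``loadings`` is channels x components with orthonormal columns;
    ``explained_variance`` is non-increasing.
    """

    channel_means: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "channel_means": self.channel_means.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            channel_means=np.asarray(d["channel_means"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance=np.asarray(d["explained_variance"]),
        )


@dataclass
class ComponentSelection:
    """Outcome of the correlation-based component retention."""

    r: np.ndarray
    p: np.ndarray
    benchmark: float
    selected: list[int]

    def to_dict(self) -> dict:
        return {
            "benchmark": self.benchmark,
            "r": self.r.tolist(),
            "p": self.p.tolist(),
            "selected": list(self.selected),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentSelection":
        return cls(
            r=np.asarray(d["r"]),
            p=np.asarray(d["p"]),
            benchmark=float(d["benchmark"]),
            selected=[int(i) for i in d["selected"]],
        )


@dataclass
class LoadingRegressionResult:
    """OLS of mean |loading| (y) on mean |rate difference| (x) per channel."""

    slope: float
    intercept: float
    theta_deg: float
    r_squared: float


@dataclass
class SurveyResult:
    """Pooled per-trial PC/label correlation magnitudes and their summary.

    ``median_restricted`` is the median of |r| after excluding |r| < 0.1
    (correlations that small are treated as noise and dropped from the
    benchmark analysis).
    """

    pooled_abs_r: np.ndarray
    pooled_p: np.ndarray
    median_restricted: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    eligible_per_trial: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_array(rates) -> np.ndarray:
    if isinstance(rates, RateMatrix):
        return rates.values
    return np.asarray(rates, dtype=float)


def fit_pca(rates) -> PCAModel:
    """Fit mean-centered PCA; loadings ordered by decreasing variance."""
    X = _as_array(rates)
    if X.shape[0] < 2:
        raise InputError("PCA requires at least 2 time samples")
    n_comp = min(X.shape)
    # covariance_eigh is exact and far cheaper than a tall SVD for n >> channels
    solver = "covariance_eigh" if X.shape[0] >= X.shape[1] else "full"
    pca = PCA(n_components=n_comp, svd_solver=solver)
    pca.fit(X)
    return PCAModel(
        channel_means=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def project(rates, model: PCAModel, indices: list[int] | None = None) -> np.ndarray:
    """Project rates onto the model's components (all, or a chosen subset)."""
    X = _as_array(rates)
    if X.shape[1] != model.n_channels:
        raise InputError(
            f"channel mismatch: data has {X.shape[1]}, model has {model.n_channels}"
        )
    L = model.loadings
    if indices is not None:
        indices = list(indices)
        if len(indices) == 0:
            raise ParameterError("empty component index list")
        if min(indices) < 0 or max(indices) >= model.n_components:
            raise ParameterError("component index out of range")
        L = L[:, indices]
    return (X - model.channel_means) @ L


def correlate_projections(features: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each feature column against the 0/1 labels.

    With binary labels the product-moment r equals the point-biserial
    coefficient. Returns (r, p) per column; single-class labels give NaN with
    a warning.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = labels.labels if isinstance(labels, StateLabels) else np.asarray(labels)
    y = y.astype(float)
    if F.shape[0] != y.shape[0]:
        raise InputError("features and labels must have equal length")
    n = y.shape[0]
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Fc = F - F.mean(axis=0)
    sf = np.sqrt((Fc**2).sum(axis=0))
    if sy == 0:
        warnings.warn("labels contain a single class; correlations undefined")
        nanv = np.full(F.shape[1], np.nan)
        return nanv, nanv.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fc * yc[:, None]).sum(axis=0) / (sf * sy)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the t-approximation with n-2 df
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def select_components(r: np.ndarray, benchmark: float = 0.2,
                      p: np.ndarray | None = None) -> ComponentSelection:
    """Retain components with |r| >= benchmark, preserving PC order."""
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise InputError("empty correlation vector")
    if p is None:
        p = np.full(r.shape, np.nan)
    with np.errstate(invalid="ignore"):
        mask = np.abs(r) >= benchmark
    selected = [int(i) for i in np.flatnonzero(mask)]
    if not selected:
        raise NoEligibleComponentsError(benchmark, float(np.nanmax(np.abs(r))))
    return ComponentSelection(r=r, p=np.asarray(p), benchmark=benchmark,
                              selected=selected)


def survey_per_trial_correlations(
    trials: list[tuple],
    benchmark: float = 0.2,
    exclusion: float = 0.1,
    n_bins: int = 20,
) -> SurveyResult:
    """Fit PCA to each trial independently and pool PC/label |r| values.

    For every trial, all PC projections are correlated with that trial's
    labels; |r| values are pooled across trials. The summary median is taken
    over |r| in [``exclusion``, 1] and the per-trial count of PCs with
    |r| >= ``benchmark`` is reported.
    """
    if len(trials) == 0:
        raise InputError("empty trial list")
    pooled_r, pooled_p, eligible = [], [], []
    for rates, labels in trials:
        model = fit_pca(rates)
        feats = project(rates, model)
        r, p = correlate_projections(feats, labels)
        pooled_r.append(np.abs(r))
        pooled_p.append(p)
        with np.errstate(invalid="ignore"):
            eligible.append(int(np.sum(np.abs(r) >= benchmark)))
    abs_r = np.concatenate(pooled_r)
    p_all = np.concatenate(pooled_p)
    kept = abs_r[(abs_r >= exclusion) & (abs_r <= 1.0)]
    median = float(np.median(kept)) if kept.size else float("nan")
    counts, edges = np.histogram(abs_r[~np.isnan(abs_r)], bins=n_bins,
                                 range=(0.0, 1.0))
    return SurveyResult(
        pooled_abs_r=abs_r,
        pooled_p=p_all,
        median_restricted=median,
        histogram_counts=counts,
        histogram_edges=edges,
        eligible_per_trial=np.asarray(eligible),
    )


def loading_rate_regression(
    selected_mean_loadings: np.ndarray,
    unselected_mean_loadings: np.ndarray,
    rate_diffs: np.ndarray,
) -> tuple[LoadingRegressionResult, LoadingRegressionResult]:
    """Regress per-channel mean loadings on per-channel state rate differences.

    Returns one OLS fit for the benchmark-selected loading group and one for
    the rejected group; a selected group that tracks the rate differences
    (steep slope, high R^2) indicates those components carry the task signal.
    """
    sel = np.asarray(selected_mean_loadings, dtype=float)
    uns = np.asarray(unselected_mean_loadings, dtype=float)
    x = np.asarray(rate_diffs, dtype=float)
    if not (sel.shape == uns.shape == x.shape):
        raise InputError("loading and rate-difference vectors must match in length")
    if x.shape[0] < 3:
        raise InputError("need at least 3 channels for the regression")

    def _fit(yv: np.ndarray) -> LoadingRegressionResult:
        res = stats.linregress(x, yv)
        return LoadingRegressionResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            theta_deg=float(np.degrees(np.arctan(res.slope))),
            r_squared=float(res.rvalue**2),
        )

    return _fit(sel), _fit(uns)
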