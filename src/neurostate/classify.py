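"""Linear SVM state classification on cPCA features, with trial-level CV.

The cpSVM pipeline: fit PCA on the pooled training samples, retain components
correlated with the reference labels (|r| >= benchmark), z-score the selected
projections, and train a linear soft-margin SVM (hinge loss, box constraint
C = 1 by default, no class weighting). Evaluation uses k-fold
cross-validation partitioned at the trial level so no samples of a test trial
ever touch the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .cpca import ComponentSelection, PCAModel, correlate_projections, fit_pca, project, select_components
from .errors import InputError, ParameterError
from .evaluate import confusion_metrics
from .preprocess import RateMatrix, StateLabels

__all__ = [
    "Standardizer",
    "LinearSVMModel",
    "CVResult",
    "fit_linear_svm",
    "hinge_objective",
    "train_cpsvm",
    "predict_states",
    "run_trialwise_cv",
]


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data only."""

    feature_means: np.ndarray
    feature_sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        if np.any(sds <= 0):
            raise InputError("zero-variance feature; cannot standardize")
        return cls(feature_means=means, feature_sds=sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds


@dataclass
class LinearSVMModel:
    """Trained cpSVM: PCA + component selection + standardizer + linear SVM.

    The decision rule is ``sign(w . z + b)`` on standardized selected-PC
    features ``z``; a score of exactly zero is classified movement.
    """

    weights: np.ndarray
    bias: float
    box_constraint: float
    tolerance: float
    standardizer: Standardizer
    selection: ComponentSelection
    pca: PCAModel

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "box_constraint": self.box_constraint,
            "tolerance": self.tolerance,
            "feature_means": self.standardizer.feature_means.tolist(),
            "feature_sds": self.standardizer.feature_sds.tolist(),
            "selection": self.selection.to_dict(),
            "pca": self.pca.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVMModel":
        return cls(
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            box_constraint=float(d["box_constraint"]),
            tolerance=float(d["tolerance"]),
            standardizer=Standardizer(
                feature_means=np.asarray(d["feature_means"]),
                feature_sds=np.asarray(d["feature_sds"]),
            ),
            selection=ComponentSelection.from_dict(d["selection"]),
            pca=PCAModel.from_dict(d["pca"]),
        )


@dataclass
class CVResult:
    """Trial-level k-fold cross-validation outcome."""

    fold_assignments: np.ndarray  # trial index -> fold (0..k-1)
    fold_metrics: list[dict]      # per fold: {"movement": PM, "stationary": PM}
    predictions: list[StateLabels]  # per trial, aligned with input order
    models: list[LinearSVMModel]  # one fitted model per fold
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f["movement"].accuracy for f in self.fold_metrics]))


# The intercept enters the solver as an augmented constant feature of this
# magnitude, so it carries a light penalty b^2 / (2 * INTERCEPT_SCALING^2).
INTERCEPT_SCALING = 10.0


def hinge_objective(w: np.ndarray, b: float, X: np.ndarray, y_pm: np.ndarray,
                    C: float) -> float:
    """Primal objective 0.5(||w||^2 + (b/s)^2) + C * sum(hinge)."""
    margins = y_pm * (X @ w + b)
    return (
        0.5 * float(w @ w)
        + 0.5 * (b / INTERCEPT_SCALING) ** 2
        + C * float(np.maximum(0.0, 1.0 - margins).sum())
    )


def fit_linear_svm(X: np.ndarray, y01: np.ndarray, C: float = 1.0,
                   eps: float = 1e-3, random_state: int = 0) -> tuple[np.ndarray, float]:
    """Solve the linear soft-margin SVM to (at least) the requested tolerance.

    ``eps`` is the exposed convergence tolerance on the objective
    (:func:`hinge_objective`); the dual coordinate-descent solver is run
    tighter internally so the returned weights satisfy it on any problem the
    solver converges on. Convergence chatter from the backend is suppressed:
    the stopping criterion it reports on is far stricter than ``eps``.
    """
    if eps <= 0 or C <= 0:
        raise ParameterError("C and eps must be positive")
    clf = LinearSVC(
        C=C,
        loss="hinge",
        tol=min(eps, 1e-3) * 1e-1,
        intercept_scaling=INTERCEPT_SCALING,
        max_iter=50_000,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y01)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    # sklearn orders classes_ ascending: positive decision -> class 1 (movement)
    return w, b


def _pool_trials(trials: list[tuple[RateMatrix, StateLabels]]):
    X = np.vstack([r.values if isinstance(r, RateMatrix) else np.asarray(r)
                   for r, _ in trials])
    y = np.concatenate([lab.labels for _, lab in trials])
    return X, y


def train_cpsvm(
    train_trials: list[tuple[RateMatrix, StateLabels]],
    benchmark: float = 0.2,
    C: float = 1.0,
    eps: float = 1e-3,
    random_state: int = 0,
) -> LinearSVMModel:
    """Fit the full cpSVM pipeline on pooled training trials."""
    if len(train_trials) == 0:
        raise InputError("no training trials")
    X, y = _pool_trials(train_trials)
    if np.unique(y).size < 2:
        raise InputError("training labels contain a single class")
    pca = fit_pca(X)
    feats = project(X, pca)
    if benchmark > 0:
        r, p = correlate_projections(feats, y)
        selection = select_components(r, benchmark, p)
    else:
        r, p = correlate_projections(feats, y)
        selection = ComponentSelection(r=r, p=p, benchmark=benchmark,
                                       selected=list(range(feats.shape[1])))
    Z = feats[:, selection.selected]
    std = Standardizer.fit(Z)
    w, b = fit_linear_svm(std.transform(Z), y, C=C, eps=eps,
                          random_state=random_state)
    return LinearSVMModel(
        weights=w, bias=b, box_constraint=C, tolerance=eps,
        standardizer=std, selection=selection, pca=pca,
    )


def predict_states(model: LinearSVMModel, trial_rates) -> StateLabels:
    """Per-sample state prediction for one trial; ties (score 0) -> movement."""
    feats = project(trial_rates, model.pca, model.selection.selected)
    z = model.standardizer.transform(feats)
    score = z @ model.weights + model.bias
    labels = (score >= 0).astype(np.int8)
    tg = trial_rates.time_grid if isinstance(trial_rates, RateMatrix) else None
    return StateLabels(labels=labels, time_grid=tg)


def run_trialwise_cv(
    trials: list[tuple[RateMatrix, StateLabels]],
    k: int = 10,
    benchmark: float = 0.2,
    C: float = 1.0,
    eps: float = 1e-3,
    seed: int = 0,
) -> CVResult:
    """Trial-level k-fold cross-validation of the cpSVM.

    Trials are shuffled once with the given seed and split into k folds
    balanced to within one trial. Each fold's model is fit on the other
    folds' trials only; fold metrics pool all samples of that fold's test
    trials (per-trial predictions are also returned).
    """
    n = len(trials)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k = {k} exceeds the {n} available trials")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(folds):
        assignment[idx] = f

    predictions: list[StateLabels | None] = [None] * n
    fold_metrics: list[dict] = []
    models: list[LinearSVMModel] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = train_cpsvm([trials[i] for i in train_idx], benchmark=benchmark,
                            C=C, eps=eps, random_state=0)
        models.append(model)
        pred_cat, ref_cat = [], []
        for i in test_idx:
            rates, ref = trials[i]
            pred = predict_states(model, rates)
            predictions[i] = pred
            pred_cat.append(pred.labels)
            ref_cat.append(ref.labels)
        pred_all = StateLabels(np.concatenate(pred_cat))
        ref_all = StateLabels(np.concatenate(ref_cat))
        _, pm_mov = confusion_metrics(pred_all, ref_all, positive_class=1)
        _, pm_sta = confusion_metrics(pred_all, ref_all, positive_class=0)
        fold_metrics.append({"movement": pm_mov, "stationary": pm_sta})
    return CVResult(
        fold_assignments=assignment,
        fold_metrics=fold_metrics,
        predictions=predictions,  # type: ignore[arg-type]
        models=models,
        seed=seed,
    )
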