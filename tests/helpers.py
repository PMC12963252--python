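"""Independent oracles shared by unit and acceptance tests."""

import numpy as np
from scipy.optimize import minimize

from neurostate.classify import INTERCEPT_SCALING


def brute_force_svm_objective(X, y01, C=1.0):
    """Minimize the primal hinge objective by direct convex search.

    Independent of the package's solver: Nelder-Mead restarts on the exact
    (non-smooth) objective, adequate for the low-dimensional problems the
    solver contract is checked on.
    """
    X = np.asarray(X, float)
    ypm = 2.0 * np.asarray(y01) - 1.0
    d = X.shape[1]

    def obj(v):
        w, b = v[:d], v[d]
        m = ypm * (X @ w + b)
        return (0.5 * w @ w + 0.5 * (b / INTERCEPT_SCALING) ** 2
                + C * np.maximum(0.0, 1.0 - m).sum())

    best = np.inf
    for x0 in (np.zeros(d + 1), np.r_[np.ones(d), 0.0], np.r_[-np.ones(d), 0.5]):
        res = minimize(obj, x0, method="Nelder-Mead",
                       options=dict(maxiter=60000, xatol=1e-12, fatol=1e-12))
        best = min(best, res.fun)
    return best


def brute_force_select(X, y, benchmark):
    """Recompute every PC/label correlation from raw projections with numpy
    primitives and filter by |r| >= benchmark."""
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    picked = []
    for j in range(evecs.shape[1]):
        proj = Xc @ evecs[:, j]
        r = np.corrcoef(proj, y)[0, 1]
        if abs(r) >= benchmark:
            picked.append(j)
    return picked
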