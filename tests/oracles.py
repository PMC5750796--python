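"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form solves: the
hyperplane distance is found by general-purpose numeric minimization of
the ridge objective, and prototype selection by exhaustive sort.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def hyperplane_objective(alpha, q, prototypes, w, lam):
    centroid = prototypes.mean(axis=0)
    basis = (prototypes - centroid).T
    s = basis @ alpha + centroid
    return float(np.sum(w * (s - q) ** 2) + lam * alpha @ alpha)


def numeric_jc(q, prototypes, w, lam) -> float:
    """Minimize the ridge-regularized weighted distance numerically."""
    prototypes = np.atleast_2d(prototypes)
    k = prototypes.shape[0]
    best = np.inf
    for x0 in (np.zeros(k), 0.1 * np.ones(k)):
        res = minimize(
            hyperplane_objective, x0, args=(q, prototypes, w, lam),
            method="BFGS", options={"gtol": 1e-12, "maxiter": 2000},
        )
        best = min(best, res.fun)
    return best


def brute_force_hknn(train_x, train_y, q, k, lam):
    """Classify q with plain-Euclidean HKNN via the numeric minimizer."""
    w = np.ones(train_x.shape[1])
    scores = {}
    for c in sorted(set(train_y)):
        rows = train_x[np.asarray(train_y) == c]
        d = np.linalg.norm(rows - q, axis=1)
        protos = rows[np.argsort(d, kind="stable")[: min(k, len(rows))]]
        scores[c] = numeric_jc(q, protos, w, lam)
    return min(scores, key=lambda c: (scores[c], c)), scores
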