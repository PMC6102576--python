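"""Independent reference solvers used only by the tests.

The joint objective is convex but nonsmooth (l1 on the view matrices).  The
oracle removes the nonsmoothness by splitting each view matrix into
positive and negative parts, C_s = P_s - Q_s with P_s, Q_s >= 0, so
``||C_s||_1 = sum(P_s + Q_s)`` at the optimum.  The resulting smooth
bound-constrained problem is solved with L-BFGS-B and an analytic gradient.
This route shares no code with the package's alternating solver.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _unpack(theta, m, n, with_consensus):
    mats = []
    off = 0
    for _ in range(m):
        P = theta[off:off + n * n].reshape(n, n); off += n * n
        Q = theta[off:off + n * n].reshape(n, n); off += n * n
        mats.append((P, Q))
    C = theta[off:off + n * n].reshape(n, n) if with_consensus else None
    return mats, C


def solve_view_problem(X, C_fixed, lambda_z, lambda_c, tol=1e-14):
    """Reference minimizer of one view block with the consensus fixed.

    min ||B||_1 + lambda_z/2 ||X - X B||_F^2 + lambda_c/2 ||B - C||_F^2,
    diag(B) = 0.
    """
    n = X.shape[1]

    def fun_grad(theta):
        (P, Q) = _unpack(theta, 1, n, False)[0][0]
        B = P - Q
        R = X - X @ B
        D = B - C_fixed
        f = (P + Q).sum() + 0.5 * lambda_z * (R ** 2).sum() \
            + 0.5 * lambda_c * (D ** 2).sum()
        gB = -lambda_z * X.T @ R + lambda_c * D
        gP = 1.0 + gB
        gQ = 1.0 - gB
        return f, np.concatenate([gP.ravel(), gQ.ravel()])

    bounds = _split_bounds(n, 1)
    theta0 = np.zeros(2 * n * n)
    res = minimize(fun_grad, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 20000, "ftol": tol,
                                           "gtol": 1e-10})
    (P, Q) = _unpack(res.x, 1, n, False)[0][0]
    return P - Q, res.fun


def _split_bounds(n, m):
    """Bounds for m (P, Q) pairs: entries >= 0, diagonals pinned at 0."""
    bounds = []
    for _ in range(m):
        for _part in range(2):
            for i in range(n):
                for j in range(n):
                    bounds.append((0.0, 0.0) if i == j else (0.0, None))
    return bounds


def solve_joint_problem(X_list, L, lambda_z, lambda_c, lambda_g, tol=1e-14):
    """Reference joint minimizer over all view matrices and the consensus.

    min sum_s [ ||C_s||_1 + lambda_z/2 ||X_s - X_s C_s||_F^2
                + lambda_c/2 ||C_s - C||_F^2 ] + lambda_g tr(C' L C),
    diag(C_s) = 0.
    """
    m = len(X_list)
    n = X_list[0].shape[1]

    def fun_grad(theta):
        mats, C = _unpack(theta, m, n, True)
        f = lambda_g * float(np.trace(C.T @ L @ C))
        grads = []
        gC = 2.0 * lambda_g * L @ C
        for X, (P, Q) in zip(X_list, mats):
            B = P - Q
            R = X - X @ B
            D = B - C
            f += (P + Q).sum() + 0.5 * lambda_z * (R ** 2).sum() \
                + 0.5 * lambda_c * (D ** 2).sum()
            gB = -lambda_z * X.T @ R + lambda_c * D
            grads.append(1.0 + gB)
            grads.append(1.0 - gB)
            gC -= lambda_c * D
        grads.append(gC)
        return f, np.concatenate([g.ravel() for g in grads])

    bounds = _split_bounds(n, m) + [(None, None)] * (n * n)
    theta0 = np.zeros((2 * m + 1) * n * n)
    res = minimize(fun_grad, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 50000, "ftol": tol,
                                           "gtol": 1e-10})
    mats, C = _unpack(res.x, m, n, True)
    reps = [P - Q for P, Q in mats]
    return reps, C, res.fun


def l1_objective(X_list, reps, C, L, lambda_z, lambda_c, lambda_g):
    """Direct evaluation of the joint objective (test-side duplicate)."""
    f = lambda_g * float(np.trace(C.T @ L @ C))
    for X, B in zip(X_list, reps):
        R = X - X @ B
        f += np.abs(B).sum() + 0.5 * lambda_z * (R ** 2).sum() \
            + 0.5 * lambda_c * ((B - C) ** 2).sum()
    return f
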