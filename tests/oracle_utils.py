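"""Independent numerical oracles used by the solver tests.

These recompute the penalized objectives in plain numpy and minimize them
with scipy's L-BFGS-B restricted to the orthant (sign pattern) of the
coordinate-descent solution, with the fusion indicator frozen there. Within
that orthant the objective is smooth and convex, so the generic optimizer
provides an independent check of the CD minimizer.
"""

import numpy as np
from scipy.optimize import minimize

from omifuse.markers import _prep
from omifuse.regulations import _prep_xz


def logistic_objective(X1, y1, b1, a1, X2, y2, b2, a2, lam1, lam2, penalty):
    """The fused logistic objective exactly as the solver defines it."""

    def nll(X, y, b, a):
        lp = X @ b + a
        return np.mean(np.logaddexp(0.0, lp) - y * lp)

    val = nll(X1, y1, b1, a1) + nll(X2, y2, b2, a2)
    val += lam1 * (np.abs(b1).sum() + np.abs(b2).sum())
    if penalty == "magnitude" and lam2 > 0:
        s = (np.sign(b1) == np.sign(b2)).astype(float)
        rho = np.sum(s * 2 * (b1 - b2) ** 2 + (1 - s) * (b1**2 + b2**2))
        val += 0.5 * lam2 * rho
    return val


def orthant_bounds(b):
    out = []
    for v in b:
        if v > 0:
            out.append((0.0, None))
        elif v < 0:
            out.append((None, 0.0))
        else:
            out.append((0.0, 0.0))
    return out


def orthant_oracle_logistic(d1, d2, lam1, lam2, penalty, fit, feature="expression"):
    """Best objective achievable in the CD solution's orthant (s frozen)."""
    X1, y1, _, _ = _prep(d1, feature)
    X2, y2, _, _ = _prep(d2, feature)
    b1, b2 = fit.beta
    a1, a2 = fit.intercepts
    p = len(b1)
    sgn1, sgn2 = np.sign(b1), np.sign(b2)
    s_frozen = (sgn1 == sgn2).astype(float)

    def pack(th):
        return th[:p], th[p], th[p + 1 : 2 * p + 1], th[2 * p + 1]

    def obj(th):
        c1, i1, c2, i2 = pack(th)

        def nll(X, y, b, a):
            lp = X @ b + a
            return np.mean(np.logaddexp(0.0, lp) - y * lp)

        val = nll(X1, y1, c1, i1) + nll(X2, y2, c2, i2)
        val += lam1 * (np.sum(sgn1 * c1) + np.sum(sgn2 * c2))
        if penalty == "magnitude" and lam2 > 0:
            rho = np.sum(
                s_frozen * 2 * (c1 - c2) ** 2 + (1 - s_frozen) * (c1**2 + c2**2)
            )
            val += 0.5 * lam2 * rho
        return val

    x0 = np.concatenate([b1, [a1], b2, [a2]])
    bounds = orthant_bounds(b1) + [(None, None)] + orthant_bounds(b2) + [(None, None)]
    res = minimize(
        obj, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return float(res.fun)


def cd_logistic_objective(d1, d2, fit, lam1, lam2, penalty, feature="expression"):
    X1, y1, _, _ = _prep(d1, feature)
    X2, y2, _, _ = _prep(d2, feature)
    return float(
        logistic_objective(
            X1, y1, fit.beta[0], fit.intercepts[0],
            X2, y2, fit.beta[1], fit.intercepts[1],
            lam1, lam2, penalty,
        )
    )


def regulation_objective(Z1, X1, e1, Z2, X2, e2, lam3, lam4, penalty):
    """The fused regulation objective exactly as the solver defines it."""
    n1, n2 = Z1.shape[0], Z2.shape[0]
    val = 0.5 * ((X1 - Z1 @ e1.T) ** 2).sum() / n1
    val += 0.5 * ((X2 - Z2 @ e2.T) ** 2).sum() / n2
    val += lam3 * (np.abs(e1).sum() + np.abs(e2).sum())
    if penalty == "magnitude" and lam4 > 0:
        s = (np.sign(e1) == np.sign(e2)).astype(float)
        rho = np.sum(s * 2 * (e1 - e2) ** 2 + (1 - s) * (e1**2 + e2**2))
        val += lam4 * rho
    return float(val)


def cd_regulation_objective(d1, d2, fit, lam3, lam4, penalty):
    Z1, X1, *_ = _prep_xz(d1)
    Z2, X2, *_ = _prep_xz(d2)
    return regulation_objective(
        Z1, X1, fit.eta[0], Z2, X2, fit.eta[1], lam3, lam4, penalty
    )


def orthant_oracle_regulation(d1, d2, lam3, lam4, penalty, fit):
    """Per-gene orthant-restricted minimization, summed over genes."""
    Z1, X1, *_ = _prep_xz(d1)
    Z2, X2, *_ = _prep_xz(d2)
    n1, n2 = Z1.shape[0], Z2.shape[0]
    q, p = fit.eta[0].shape
    total = 0.0
    for j in range(q):
        b1 = fit.eta[0][j]
        b2 = fit.eta[1][j]
        sgn1, sgn2 = np.sign(b1), np.sign(b2)
        s_frozen = (sgn1 == sgn2).astype(float)

        def obj(th, j=j, sgn1=sgn1, sgn2=sgn2, s_frozen=s_frozen):
            c1, c2 = th[:p], th[p:]
            val = 0.5 * ((X1[:, j] - Z1 @ c1) ** 2).sum() / n1
            val += 0.5 * ((X2[:, j] - Z2 @ c2) ** 2).sum() / n2
            val += lam3 * (np.sum(sgn1 * c1) + np.sum(sgn2 * c2))
            if penalty == "magnitude" and lam4 > 0:
                rho = np.sum(
                    s_frozen * 2 * (c1 - c2) ** 2
                    + (1 - s_frozen) * (c1**2 + c2**2)
                )
                val += lam4 * rho
            return val

        x0 = np.concatenate([b1, b2])
        bounds = orthant_bounds(b1) + orthant_bounds(b2)
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-11},
        )
        total += float(res.fun)
    return total
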