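"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (explicit loops over risk sets, direct
linear solves) kept separate from the package so that agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def naive_cox_loglik(beta, X, time, event):
    """Breslow partial log-likelihood by explicit risk-set loops."""
    ll = 0.0
    ev_times = np.unique(time[event == 1])
    eta = X @ beta
    for t in ev_times:
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = dead.sum()
        ll += eta[dead].sum() - d * np.log(np.exp(eta[risk]).sum())
    return ll


def brute_force_cox_fit(X, time, event):
    """Maximize the naive partial likelihood with a generic optimizer."""
    p = X.shape[1]
    res = optimize.minimize(
        lambda b: -naive_cox_loglik(b, X, time, event),
        np.zeros(p),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    # polish with Newton on numerical derivatives via tighter BFGS restart
    res = optimize.minimize(
        lambda b: -naive_cox_loglik(b, X, time, event),
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x


def naive_km(time, event):
    """Kaplan-Meier by hand: deaths before censorings at tied times."""
    order = np.argsort(time)
    t, e = np.asarray(time)[order], np.asarray(event)[order]
    ev_times = np.unique(t[e == 1])
    surv = 1.0
    out_t, out_s = [0.0], [1.0]
    for tt in ev_times:
        n_risk = np.sum(t >= tt)
        d = np.sum((t == tt) & (e == 1))
        surv *= 1.0 - d / n_risk
        out_t.append(tt)
        out_s.append(surv)
    return np.array(out_t), np.array(out_s)


def naive_logrank_2group(time, event, group):
    """Two-group log-rank chi-square: sum over event times of
    observed-minus-expected in group 1, with hypergeometric variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    ev_times = np.unique(time[event == 1])
    O_minus_E = 0.0
    V = 0.0
    for t in ev_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


def radial_interpolant(x_knots, y):
    """Full 1-d thin plate spline interpolant via the bordered system
    [E T; T' 0] [delta; a] = [y; 0] with E_ij = |x_i - x_j|^3, T = [1, x]."""
    x = np.asarray(x_knots, dtype=float)
    k = x.size
    E = np.abs(x[:, None] - x[None, :]) ** 3
    T = np.column_stack([np.ones(k), x])
    A = np.zeros((k + 2, k + 2))
    A[:k, :k] = E
    A[:k, k:] = T
    A[k:, :k] = T.T
    rhs = np.r_[y, 0.0, 0.0]
    sol = np.linalg.solve(A, rhs)
    delta, a = sol[:k], sol[k:]

    def f(xs):
        xs = np.asarray(xs, dtype=float)
        return np.abs(xs[:, None] - x[None, :]) ** 3 @ delta + a[0] + a[1] * xs

    return f
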