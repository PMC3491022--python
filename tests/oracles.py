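"""Independent brute-force references used by the test suite.

These implementations deliberately share no code with the package's
observers: the continuous-time chain is approximated by a fine-step
discrete-time hidden Markov model whose one-step transition matrix is the
exact CME propagator over the step, and posteriors are computed by plain
discrete forward-backward recursions (and, on lineage trees, by explicit
message passing through the enumerated division kernel).
"""

import numpy as np
from scipy.linalg import expm


class DiscretizedHMM:
    """Uniformized discrete-time surrogate of a partially observed CTMC.

    All observation times must be (near-)multiples of the step ``delta``,
    which makes the surrogate exact up to floating-point error because the
    step matrix is the exact propagator.
    """

    def __init__(self, A, delta=1e-3):
        self.delta = float(delta)
        self.T = expm(np.asarray(A.todense() if hasattr(A, "todense") else A) * delta)
        self.n = self.T.shape[0]

    def steps(self, t0, t1):
        k = (t1 - t0) / self.delta
        ki = int(round(k))
        assert abs(k - ki) < 1e-6, "times must sit on the discretization grid"
        return ki

    def forward(self, rho0, t0, t1, obs, dens):
        """Filtering pass; returns {step: filtered dist (post-update)} plus
        the log-evidence.  ``obs`` is [(t, y)]; ``dens(y)`` the density vec."""
        grid = {}
        obs_at = {self.steps(t0, t): y for t, y in obs}
        a = np.asarray(rho0, dtype=float).copy()
        logev = 0.0
        if 0 in obs_at:
            b = dens(obs_at[0])
            w = float(b @ a)
            logev += np.log(w)
            a = b * a / w
        grid[0] = a.copy()
        for s in range(1, self.steps(t0, t1) + 1):
            a = self.T @ a
            if s in obs_at:
                b = dens(obs_at[s])
                w = float(b @ a)
                logev += np.log(w)
                a = b * a / w
            grid[s] = a.copy()
        return grid, logev

    def backward(self, t0, t1, obs, dens, beta_end=None):
        """Backward pass; {step: beta (excluding obs at that step)}."""
        K = self.steps(t0, t1)
        b = np.ones(self.n) if beta_end is None else np.asarray(beta_end, float).copy()
        grid = {K: b.copy()}
        obs_at = {self.steps(t0, t): y for t, y in obs}
        for s in range(K - 1, -1, -1):
            bb = b
            if s + 1 in obs_at:
                bb = dens(obs_at[s + 1]) * bb
            b = self.T.T @ bb
            b = b / b.max()
            grid[s] = b.copy()
        return grid

    def smoothed(self, rho0, t0, t1, obs, dens, beta_end=None):
        fwd, _ = self.forward(rho0, t0, t1, obs, dens)
        bwd = self.backward(t0, t1, obs, dens, beta_end=beta_end)
        out = {}
        for s, a in fwd.items():
            p = a * bwd[s]
            out[s] = p / p.sum()
        return out


def joint_evidence_bruteforce(A, dens, obs, rho0):
    """P(y_1..y_K) by exact matrix products (small models only)."""
    a = np.asarray(rho0, dtype=float).copy()
    t_prev = obs[0][0] if obs else 0.0
    # propagate from t=times[0] assumed start; caller passes t-ordered obs
    total = 1.0
    t_cur = None
    for t, y in obs:
        if t_cur is None:
            t_cur = t_prev
        a = expm(np.asarray(A.todense()) * (t - t_cur)) @ a
        b = dens(y)
        w = float(b @ a)
        total *= w
        a = b * a / w
        t_cur = t
    return total


def tree_posteriors(A, dens, kernel_joint, rho0, cells, delta=1e-3):
    """Exact smoothed posteriors on a one-division binary tree.

    ``cells`` maps ids 'c', 'c1', 'c2' to dicts with t0, t1, obs (list of
    (t, y)); ``kernel_joint`` maps mother state -> [(d1, d2, prob)].
    Returns {cell_id: {step: posterior}}.
    """
    hmm = DiscretizedHMM(A, delta)
    c, c1, c2 = cells["c"], cells["c1"], cells["c2"]
    agrid, _ = hmm.forward(rho0, c["t0"], c["t1"], c["obs"], dens)
    afin = agrid[max(agrid)]
    b1 = hmm.backward(c1["t0"], c1["t1"], c1["obs"], dens)
    b2 = hmm.backward(c2["t0"], c2["t1"], c2["obs"], dens)
    n = hmm.n
    # include daughters' own birth-step observations in their start betas
    def start_beta(cell, grid):
        beta = grid[0].copy()
        for t, y in cell["obs"]:
            if hmm.steps(cell["t0"], t) == 0:
                beta = dens(y) * beta
        return beta

    sb1, sb2 = start_beta(c1, b1), start_beta(c2, b2)
    Lm = np.zeros(n)
    for m, outcomes in kernel_joint.items():
        for d1, d2, p in outcomes:
            Lm[m] += p * sb1[d1] * sb2[d2]
    broot = hmm.backward(c["t0"], c["t1"], c["obs"], dens, beta_end=Lm)
    out = {"c": {}}
    for s, a in agrid.items():
        p = a * broot[s]
        out["c"][s] = p / p.sum()
    # daughters: alpha at birth couples mother filter and sibling beta
    def daughter(me, me_grid_obs, sib_beta, my_b):
        a0 = np.zeros(n)
        for m, outcomes in kernel_joint.items():
            for d1, d2, p in outcomes:
                a0[d1] += afin[m] * p * sib_beta[d2]
        agrid_d, _ = hmm.forward(a0 / a0.sum(), me["t0"], me["t1"], me["obs"], dens)
        res = {}
        for s, a in agrid_d.items():
            p = a * my_b[s]
            res[s] = p / p.sum()
        return res

    out["c1"] = daughter(c1, c1["obs"], sb2, b1)
    out["c2"] = daughter(c2, c2["obs"], sb1, b2)
    return out, hmm
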