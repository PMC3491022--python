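"""Transition rate matrix construction and chemical master equation solves.

Convention (used everywhere in this package): the generator ``A`` is
*column*-based — ``A[i, j]`` for ``i != j`` is the rate of the transition
from state ``j`` to state ``i`` and each column sums to zero, so that the
probability column vector evolves as ``drho/dt = A @ rho``.

Reactions whose firing would push a species above its truncation cap are
disallowed: they contribute neither an off-diagonal entry nor outflow on the
diagonal, matching the stochastic simulator in :mod:`crnobserver.ssa`.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import expm_multiply, splu

from .errors import IdentifiabilityError, ModelError
from .network import ReactionNetwork, StateSpace

__all__ = ["build_generator", "propagate", "Propagator", "steady_state", "choose_caps"]


def build_generator(network: ReactionNetwork, space: StateSpace) -> sp.csc_matrix:
    """Assemble the sparse truncated generator for ``network`` on ``space``."""
    n = space.n
    props = network.propensity_matrix(space)  # validates >= 0, finite
    deltas = network.change_vectors()
    rows, cols, data = [], [], []
    src = np.arange(n)
    for r in range(len(network.reactions)):
        target = space.counts + deltas[r]
        ok = np.all((target >= 0) & (target <= space.caps), axis=1) & (props[:, r] > 0)
        if not np.any(ok):
            continue
        tgt_idx = np.ravel_multi_index(target[ok].T, space.shape)
        rows.append(tgt_idx)
        cols.append(src[ok])
        data.append(props[ok, r])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        A = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    else:
        A = sp.csc_matrix((n, n))
    outflow = np.asarray(A.sum(axis=0)).ravel() - A.diagonal()
    A = A - sp.diags(A.diagonal()) - sp.diags(outflow)  # close columns to zero
    return A.tocsc()


class Propagator:
    """Repeated-use CME propagator ``v -> exp(A * dt) @ v``.

    Backends
    --------
    ``"uniformization"`` (default)
        The standard CTMC transient solver: with ``lam >= max_j |A_jj|``
        the jump matrix ``P = I + A/lam`` is substochastic and
        ``exp(A t) v = sum_k Poisson(k; lam t) P^k v``.  The Poisson series
        is truncated at tail mass 1e-15 and long horizons are split into
        chunks so the weights never underflow.  The jump matrix is built
        once, which makes repeated small steps (a fixed microscopy sampling
        interval) cheap.  Exact for generators and for the substochastic
        within-class blocks of a partitioned generator.
    ``"expm"``
        Matrix-exponential action (``scipy`` ``expm_multiply``).
    ``"ode"``
        Stiff ODE integration (BDF) with ``rtol``/``atol`` (1e-8 / 1e-10 by
        default).
    """

    def __init__(
        self,
        A: sp.spmatrix,
        backend: str = "uniformization",
        rtol: float = 1e-8,
        atol: float = 1e-10,
        series_tol: float = 1e-15,
        max_chunk: float = 50.0,
    ):
        if backend not in ("uniformization", "expm", "ode"):
            raise ValueError(f"unknown backend {backend!r}")
        self.A = A.tocsc()
        self.n = A.shape[0]
        self.backend = backend
        self.rtol = rtol
        self.atol = atol
        self.series_tol = series_tol
        self.max_chunk = max_chunk
        self._lam = None
        self._P = None

    def _uniformized(self):
        if self._P is None:
            diag = self.A.diagonal()
            self._lam = float(np.max(-diag)) if self.n else 0.0
            if self._lam <= 0.0:
                self._lam = 0.0
                self._P = sp.identity(self.n, format="csr")
            else:
                self._P = (
                    sp.identity(self.n, format="csr")
                    + self.A.multiply(1.0 / self._lam)
                ).tocsr()
        return self._lam, self._P

    def _apply_uniform(self, v: np.ndarray, dt: float) -> np.ndarray:
        from scipy.stats import poisson

        lam, P = self._uniformized()
        if lam == 0.0:
            return v.copy()
        w = v
        remaining = dt
        while remaining > 1e-300:
            step = min(remaining, self.max_chunk / lam)
            m = lam * step
            K = int(poisson.isf(self.series_tol, m)) + 1
            wts = poisson.pmf(np.arange(K + 1), m)
            acc = wts[0] * w
            for k in range(1, K + 1):
                w = P.dot(w)
                acc = acc + wts[k] * w
            w = acc
            remaining -= step
        return w

    def apply(self, v: np.ndarray, dt: float) -> np.ndarray:
        """Return ``exp(A*dt) @ v`` (linear: works on unnormalized vectors)."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        v = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ModelError("non-finite entries in input vector")
        if dt == 0:
            return v.copy()
        if self.backend == "uniformization":
            return self._apply_uniform(v, dt)
        if self.backend == "expm":
            return expm_multiply(self.A.multiply(dt).tocsc(), v)
        sol = solve_ivp(
            lambda t, y: self.A @ y,
            (0.0, dt),
            v,
            method="BDF",
            jac=lambda t, y: self.A,
            rtol=self.rtol,
            atol=self.atol,
        )
        if not sol.success:
            raise ModelError(f"CME integration failed: {sol.message}")
        return sol.y[:, -1]


def propagate(
    rho: np.ndarray,
    A: sp.spmatrix,
    dt: float,
    transpose: bool = False,
    backend: str = "uniformization",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Solve the CME for a duration ``dt``: ``rho(dt) = exp(A*dt) rho``.

    With ``transpose=True`` the transposed generator is used, which (run in
    reversed time) is the propagation rule of the backward likelihood
    ``dbeta/dt = -A^T beta``.  The operator is linear, so unnormalized
    vectors are allowed; probability mass is conserved for distributions.
    """
    op = A.T.tocsc() if transpose else A
    return Propagator(op, backend=backend, rtol=rtol, atol=atol).apply(rho, dt)


def steady_state(A: sp.spmatrix, residual_tol: float = 1e-10) -> np.ndarray:
    """Unique stationary distribution ``p`` with ``A p = 0``, ``1^T p = 1``.

    Requires the truncated chain to be irreducible on its recurrent set; if
    the transition graph has more than one closed communicating class an
    :class:`IdentifiabilityError` is raised.
    """
    A = A.tocsc()
    n = A.shape[0]
    if n == 1:
        return np.ones(1)
    # uniqueness: exactly one closed strongly-connected class
    off = A - sp.diags(A.diagonal())
    ncomp, labels = connected_components(off.T, directed=True, connection="strong")
    # a class is closed iff no edge leaves it (column j in class c, row outside)
    coo = off.tocoo()
    leaves = np.zeros(ncomp, dtype=bool)
    mask = coo.data != 0
    src_class = labels[coo.col[mask]]
    dst_class = labels[coo.row[mask]]
    leaves[src_class[src_class != dst_class]] = True
    n_closed = int(np.sum(~leaves[np.unique(labels)])) if ncomp else 1
    if n_closed != 1:
        raise IdentifiabilityError(
            f"{n_closed} closed communicating classes: stationary law not unique"
        )
    # replace one balance equation by the normalization constraint
    M = A.tolil(copy=True)
    M[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    p = splu(M.tocsc()).solve(b)
    p = np.maximum(p, 0.0)
    p /= p.sum()
    res = np.max(np.abs(A @ p))
    if res > residual_tol:
        raise IdentifiabilityError(f"stationary residual {res:.2e} > {residual_tol}")
    return p


def choose_caps(
    network: ReactionNetwork,
    tail_mass: float = 1e-8,
    growth: float = 1.25,
    max_states: int = 10**6,
) -> dict[str, int]:
    """Pick per-species caps whose stationary boundary mass is below ``tail_mass``.

    Starting from the declared caps, the stationary distribution is computed
    and any species whose at-cap marginal mass exceeds ``tail_mass`` has its
    cap grown by ``growth`` until the tail criterion holds (or the state
    space would exceed ``max_states``).
    """
    from dataclasses import replace

    caps = {s.name: int(s.cap) for s in network.free_species}
    for _ in range(50):
        net = ReactionNetwork(
            species=[
                replace(s, cap=caps[s.name]) if s.fixed is None else s
                for s in network.species
            ],
            reactions=network.reactions,
            initial_condition=network.initial_condition,
            name=network.name,
        )
        space = net.state_space(limit=max_states)
        p = steady_state(build_generator(net, space))
        bad = []
        for name in space.species_names:
            col = space.species_column(name)
            if p[col == caps[name]].sum() > tail_mass:
                bad.append(name)
        if not bad:
            return caps
        for name in bad:
            caps[name] = max(caps[name] + 1, int(np.ceil(caps[name] * growth)))
    raise ModelError("cap selection did not converge")
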