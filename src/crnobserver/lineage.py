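"""Observation fusion across a dividing colony.

A colony observed by time-lapse microscopy is a binary :class:`LineageTree`
of cells, each carrying its own observation record.  At a division every
molecule of a ``binomial`` species joins either daughter with probability
1/2 (so the daughters' counts are *dependent*: they sum to the mother's),
while ``replicate`` species are copied to both daughters.

The colony smoother computes, for every cell, the posterior of its hidden
state given the observations of the *entire* lineage by three sweeps of
message passing on the tree:

1. a forward sweep from the root, each cell's filter seeded by pushing its
   mother's final filtering distribution through the division kernel;
2. a backward sweep from the leaves, "pinching" the two daughters' backward
   likelihoods at each division into a mother-state likelihood through the
   joint (coupled) division kernel;
3. a final forward sweep in which each cell's filter is seeded by the
   colony-informed birth distribution — the mother's message combined with
   the *sibling* subtree's backward likelihood — so that the within-cell
   forward-backward product is the exact all-observation posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import scipy.sparse as sp
from scipy.stats import binom

from .errors import ModelError, SchemaError, ZeroLikelihoodError
from .generator import Propagator
from .network import ReactionNetwork, StateSpace
from .observers import (
    BackwardResult,
    ForwardResult,
    ObservationSequence,
    SmoothedResult,
    backward,
    forward_discrete,
    smooth,
)

__all__ = [
    "Cell",
    "LineageTree",
    "DivisionKernel",
    "division_marginal",
    "pinch",
    "pinch_down",
    "posterior_division_update",
    "colony_smooth",
    "colony_forward",
    "ColonyPosterior",
]


# --------------------------------------------------------------------------
# lineage trees
# --------------------------------------------------------------------------
@dataclass
class Cell:
    id: str
    parent: str | None
    birth: float
    end: float  # division time, or observation end for a leaf
    obs: ObservationSequence | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LineageTree:
    """A binary cell-division tree with per-cell observation sequences."""

    def __init__(self, cells: list[Cell]):
        self.cells = {c.id: c for c in cells}
        if len(self.cells) != len(cells):
            raise SchemaError("duplicate cell ids")
        roots = [c for c in cells if c.parent is None]
        if len(roots) != 1:
            raise SchemaError(f"expected exactly one root cell, got {len(roots)}")
        self.root = roots[0]
        for c in cells:
            c.children = []
        for c in cells:
            if c.parent is not None:
                if c.parent not in self.cells:
                    raise SchemaError(f"cell {c.id!r}: unknown parent {c.parent!r}")
                self.cells[c.parent].children.append(c.id)
        for c in cells:
            if len(c.children) not in (0, 2):
                raise SchemaError(
                    f"cell {c.id!r} has {len(c.children)} children; divisions are binary"
                )
            if c.end < c.birth:
                raise SchemaError(f"cell {c.id!r}: end before birth")
            for ch in c.children:
                if abs(self.cells[ch].birth - c.end) > 1e-9:
                    raise SchemaError(
                        f"cell {ch!r} birth differs from parent {c.id!r} division time"
                    )
            if c.obs is not None and len(c.obs):
                if c.obs.times[0] < c.birth - 1e-9 or c.obs.times[-1] > c.end + 1e-9:
                    raise SchemaError(f"cell {c.id!r}: observations outside lifetime")

    def topological(self) -> list[Cell]:
        """Cells ordered root-first (parents before children)."""
        out, stack = [], [self.root]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self.cells[ch] for ch in c.children)
        return out

    def __len__(self):
        return len(self.cells)


# --------------------------------------------------------------------------
# division kernels
# --------------------------------------------------------------------------
class DivisionKernel:
    """Joint daughter-state law given the mother state at division.

    For a ``binomial`` species with mother count ``m`` the daughter counts
    ``(d1, d2)`` satisfy ``d1 + d2 = m`` with ``P(d1) = C(m, d1) p^d1
    (1-p)^(m-d1)`` (fair partition ``p = 1/2`` by default); species are
    partitioned independently.  ``replicate`` species are copied verbatim.
    The two daughters are exchangeable when ``p = 1/2``.
    """

    def __init__(self, network: ReactionNetwork, space: StateSpace, p: float = 0.5):
        self.space = space
        self.p = float(p)
        self.rules = []
        for name in space.species_names:
            self.rules.append(network.species_by_name(name).division)
        self.shape = space.shape
        # per-species daughter matrices W[d, m] = P(d | m)
        self._W = []
        for rule, size in zip(self.rules, self.shape):
            if rule == "binomial":
                m = np.arange(size)
                d = np.arange(size)[:, None]
                self._W.append(binom.pmf(d, m, self.p))
            else:  # replicate
                self._W.append(np.eye(size))

    # -- single-daughter marginal operator ------------------------------
    def marginal(self, rho: np.ndarray) -> np.ndarray:
        """Push a mother distribution through to one daughter (linear op)."""
        t = np.asarray(rho, dtype=float).reshape(self.shape)
        for ax, W in enumerate(self._W):
            t = np.moveaxis(np.tensordot(W, t, axes=([1], [ax])), 0, ax)
        return t.reshape(-1)

    # -- coupled two-daughter contractions -------------------------------
    def pinch(self, beta1: np.ndarray, beta2: np.ndarray) -> np.ndarray:
        """Mother-state likelihood of both daughters' futures (the "pinch").

        ``L(m) = sum_{d1+d2=m} P(d1, d2 | m) beta1(d1) beta2(d2)`` with the
        exact coupled sum (daughter counts of a binomial species are tied by
        conservation; replicate species force ``d1 = d2 = m``).
        """
        b1 = np.asarray(beta1, dtype=float).reshape(self.shape)
        b2 = np.asarray(beta2, dtype=float).reshape(self.shape)
        out = np.empty(self.shape)
        for m in np.ndindex(*self.shape):
            sl1, sl2, ws = [], [], []
            for rule, W, ms in zip(self.rules, self._W, m):
                if rule == "binomial":
                    sl1.append(slice(0, ms + 1))
                    sl2.append(slice(ms, None, -1))
                    ws.append(W[: ms + 1, ms])
                else:
                    sl1.append(slice(ms, ms + 1))
                    sl2.append(slice(ms, ms + 1))
                    ws.append(np.ones(1))
            w = reduce(np.multiply.outer, ws)
            out[m] = float(np.sum(w * b1[tuple(sl1)] * b2[tuple(sl2)]))
        return out.reshape(-1)

    def pinch_down(self, alpha_mother: np.ndarray, beta_sibling: np.ndarray) -> np.ndarray:
        """Daughter-1 forward message given the mother's filtering message
        and the sibling subtree's backward likelihood.

        ``a(d1) = sum_m alpha(m) sum_{d2 = m - d1} P(d1, d2 | m) beta_sib(d2)``
        (unnormalized).
        """
        am = np.asarray(alpha_mother, dtype=float).reshape(self.shape)
        bs = np.asarray(beta_sibling, dtype=float).reshape(self.shape)
        out = np.zeros(self.shape)
        for m in np.ndindex(*self.shape):
            a = am[m]
            if a == 0.0:
                continue
            sl1, sl2, ws = [], [], []
            for rule, W, ms in zip(self.rules, self._W, m):
                if rule == "binomial":
                    sl1.append(slice(0, ms + 1))
                    sl2.append(slice(ms, None, -1))
                    ws.append(W[: ms + 1, ms])
                else:
                    sl1.append(slice(ms, ms + 1))
                    sl2.append(slice(ms, ms + 1))
                    ws.append(np.ones(1))
            w = reduce(np.multiply.outer, ws)
            out[tuple(sl1)] += a * w * bs[tuple(sl2)]
        return out.reshape(-1)

    # -- simulation ------------------------------------------------------
    def sample(self, x_mother: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        """Draw a daughter pair; binomial species conserve the mother count."""
        d1 = np.empty_like(x_mother)
        d2 = np.empty_like(x_mother)
        for j, rule in enumerate(self.rules):
            if rule == "binomial":
                d1[j] = rng.binomial(int(x_mother[j]), self.p)
                d2[j] = x_mother[j] - d1[j]
            else:
                d1[j] = d2[j] = x_mother[j]
        return d1, d2


def division_marginal(rho_mother: np.ndarray, kernel: DivisionKernel) -> np.ndarray:
    """Distribution of a single daughter's state at birth."""
    out = kernel.marginal(rho_mother)
    s = out.sum()
    return out / s if s > 0 else out


def pinch(beta1: np.ndarray, beta2: np.ndarray, kernel: DivisionKernel) -> np.ndarray:
    """Exact coupled pinch of two daughter likelihood vectors (unnormalized)."""
    if np.any(np.asarray(beta1) < 0) or np.any(np.asarray(beta2) < 0):
        raise ModelError("pinch requires nonnegative likelihood vectors")
    return kernel.pinch(beta1, beta2)


def pinch_down(alpha_mother, beta_sibling, kernel: DivisionKernel) -> np.ndarray:
    """Daughter forward message through the observation-aware division."""
    return kernel.pinch_down(alpha_mother, beta_sibling)


def posterior_division_update(
    pi_mother: np.ndarray,
    beta_daughter: np.ndarray,
    beta_sibling: np.ndarray,
    kernel: DivisionKernel,
) -> np.ndarray:
    """Daughter smoothed birth distribution from the mother's smoothed state.

    The division kernel must be reweighted by the daughters' backward
    likelihoods (given the future observations the daughters are dependent);
    marginalizing the mother posterior through the *plain* kernel is not
    consistent.  Explicitly::

        pi_d(d1)  propto  beta_d(d1) * sum_m pi_m(m) / pinch(m) *
                          sum_{d2=m-d1} K(d1, d2 | m) beta_s(d2)
    """
    pm = np.asarray(pi_mother, dtype=float)
    pinched = kernel.pinch(beta_daughter, beta_sibling)
    w = np.where(pinched > 0, pm / np.where(pinched > 0, pinched, 1.0), 0.0)
    out = np.asarray(beta_daughter, dtype=float) * kernel.pinch_down(w, beta_sibling)
    s = out.sum()
    if s <= 0:
        raise ZeroLikelihoodError("inconsistent division posteriors")
    return out / s


# --------------------------------------------------------------------------
# colony sweeps
# --------------------------------------------------------------------------
@dataclass
class ColonyPosterior:
    """Per-cell results of the colony smoother."""

    smoothed: dict[str, SmoothedResult]
    forward: dict[str, ForwardResult]
    backward_: dict[str, BackwardResult] | None = None
    log_evidence: float | None = None

    def __getitem__(self, cell_id: str) -> SmoothedResult:
        return self.smoothed[cell_id]


def _cell_obs(cell: Cell) -> ObservationSequence:
    if cell.obs is not None:
        return ObservationSequence(
            cell.obs.times, cell.obs.outputs, t_start=cell.birth, t_end=cell.end
        )
    return ObservationSequence([], [], t_start=cell.birth, t_end=cell.end)


def colony_forward(
    tree: LineageTree,
    A: sp.spmatrix,
    model,
    rho0: np.ndarray,
    space: StateSpace,
    *,
    kernel: DivisionKernel | None = None,
    network: ReactionNetwork | None = None,
    n_interior: int = 20,
    extra_times=(),
    backend: str = "uniformization",
) -> dict[str, ForwardResult]:
    """Forward-only sweep: each cell conditions on its own and its
    ancestors' past observations; daughters start from the kernel marginal
    of the mother's final filtering distribution."""
    if kernel is None:
        if network is None:
            raise ModelError("pass either kernel or network")
        kernel = DivisionKernel(network, space)
    prop = Propagator(A, backend=backend)
    results: dict[str, ForwardResult] = {}
    init: dict[str, np.ndarray] = {tree.root.id: np.asarray(rho0, dtype=float)}
    for cell in tree.topological():
        fwd = forward_discrete(
            A, model, _cell_obs(cell), init[cell.id], space,
            n_interior=n_interior, extra_times=extra_times, propagator=prop,
        )
        results[cell.id] = fwd
        for ch in cell.children:
            init[ch] = division_marginal(fwd.final, kernel)
    return results


def colony_smooth(
    tree: LineageTree,
    A: sp.spmatrix,
    model,
    rho0: np.ndarray,
    space: StateSpace,
    *,
    kernel: DivisionKernel | None = None,
    network: ReactionNetwork | None = None,
    n_interior: int = 20,
    extra_times=(),
    backend: str = "uniformization",
    independent_daughters: bool = False,
    keep_backward: bool = False,
) -> ColonyPosterior:
    """Smoothed posterior of every cell given the whole lineage's data.

    ``independent_daughters=True`` replaces the exact coupled pinch by the
    product of the two single-daughter marginal pullbacks (the literal
    product-of-sublineage-factors reading); the default keeps the exact
    coupling induced by molecule conservation at division.
    """
    if kernel is None:
        if network is None:
            raise ModelError("pass either kernel or network")
        kernel = DivisionKernel(network, space)
    prop_f = Propagator(A, backend=backend)
    prop_b = Propagator(A.T.tocsc(), backend=backend)
    cells = tree.topological()

    # -- sweep 1: plain forward pass down the tree ----------------------
    fwd: dict[str, ForwardResult] = {}
    init: dict[str, np.ndarray] = {tree.root.id: np.asarray(rho0, dtype=float)}
    for cell in cells:
        fwd[cell.id] = forward_discrete(
            A, model, _cell_obs(cell), init[cell.id], space,
            n_interior=n_interior, extra_times=extra_times, propagator=prop_f,
        )
        for ch in cell.children:
            init[ch] = division_marginal(fwd[cell.id].final, kernel)

    # -- sweep 2: backward pass up the tree with pinching ----------------
    def marginal_pullback(beta: np.ndarray) -> np.ndarray:
        # sum_d K_marg(d | m) beta(d): adjoint of the marginal operator
        t = beta.reshape(kernel.shape)
        for ax, W in enumerate(kernel._W):
            t = np.moveaxis(np.tensordot(W.T, t, axes=([1], [ax])), 0, ax)
        return t.reshape(-1)

    bwd: dict[str, BackwardResult] = {}
    for cell in reversed(cells):
        if cell.is_leaf:
            beta_end, log_end = None, 0.0
        else:
            c1, c2 = (bwd[ch] for ch in cell.children)
            if independent_daughters:
                be = marginal_pullback(c1.start_value) * marginal_pullback(c2.start_value)
            else:
                be = kernel.pinch(c1.start_value, c2.start_value)
            m = be.max()
            if m <= 0:
                raise ZeroLikelihoodError(
                    f"no mother state of cell {cell.id!r} is consistent with "
                    f"its daughters' observations"
                )
            beta_end, log_end = be / m, c1.start_log_scale + c2.start_log_scale + np.log(m)
        bwd[cell.id] = backward(
            A, model, _cell_obs(cell), cell.end, t_start=cell.birth, space=space,
            beta_end=beta_end, log_scale_end=log_end,
            n_interior=n_interior, extra_times=extra_times, propagator=prop_b,
        )

    # -- sweep 3: colony-informed forward pass + within-cell smoothing ---
    results: dict[str, SmoothedResult] = {}
    colony_fwd: dict[str, ForwardResult] = {}
    birth_msg: dict[str, np.ndarray] = {tree.root.id: np.asarray(rho0, dtype=float)}
    for cell in cells:
        cf = forward_discrete(
            A, model, _cell_obs(cell), birth_msg[cell.id], space,
            n_interior=n_interior, extra_times=extra_times, propagator=prop_f,
        )
        colony_fwd[cell.id] = cf
        results[cell.id] = smooth(cf, bwd[cell.id], A=A)
        if cell.children:
            c1, c2 = cell.children
            for me, sib in ((c1, c2), (c2, c1)):
                if independent_daughters:
                    mother_w = cf.final * marginal_pullback(bwd[sib].start_value)
                    msg = division_marginal(mother_w / mother_w.sum(), kernel)
                else:
                    msg = kernel.pinch_down(cf.final, bwd[sib].start_value)
                s = msg.sum()
                if s <= 0:
                    raise ZeroLikelihoodError(
                        f"division into cell {me!r} inconsistent with observations"
                    )
                birth_msg[me] = msg / s

    # total log-evidence of the whole lineage: root forward message times
    # root backward likelihood
    root = tree.root.id
    lev = None
    try:
        r0 = np.asarray(rho0, dtype=float)
        lev = float(
            np.log(r0 @ bwd[root].start_value) + bwd[root].start_log_scale
        )
    except (FloatingPointError, ValueError):
        lev = None
    return ColonyPosterior(
        smoothed=results,
        forward=colony_fwd,
        backward_=bwd if keep_backward else None,
        log_evidence=lev,
    )
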