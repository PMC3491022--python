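"""Forward, backward and smoothing observers for partially observed CTMCs.

The forward observer (a filter) computes ``rho(t) = P(x(t) | observations up
to t)`` by alternating chemical-master-equation propagation with Bayesian
re-weighting at observation times; it jumps discontinuously whenever new
information arrives.  The backward observer computes the unnormalized
likelihood ``beta_i(t) = P(observations after t | x(t) = i)`` by integrating
``dbeta/dt = -A^T beta`` in reversed time.  Their elementwise product,
normalized, is the smoothed posterior given *all* observations, which is
continuous (though not differentiable) across observation times.

Two observation regimes are supported: discrete snapshots (a finite sequence
of time-stamped outputs, possibly noisy) and the idealized continual regime,
where a noise-free output is watched at every instant and the data are the
initial symbol plus the times and destinations of every output change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.linalg import expm as dense_expm

from .errors import ModelError, SchemaError, ZeroLikelihoodError
from .generator import Propagator
from .network import StateSpace
from .sensing import SplitGenerator, density_vector

__all__ = [
    "ObservationSequence",
    "OutputPath",
    "PosteriorSeries",
    "ForwardResult",
    "BackwardResult",
    "SmoothedResult",
    "forward_discrete",
    "forward_continual",
    "backward",
    "smooth",
    "mmse",
    "smoother",
]


# --------------------------------------------------------------------------
# observation containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ObservationSequence:
    """Time-stamped outputs ``(t_k, y_k)`` inside a window [t_start, t_end]."""

    times: np.ndarray
    outputs: tuple
    t_start: float = None
    t_end: float = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if len(times) != len(self.outputs):
            raise SchemaError("times and outputs differ in length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise SchemaError("observation times must be strictly increasing")
        t0 = self.t_start if self.t_start is not None else (times[0] if len(times) else 0.0)
        t1 = self.t_end if self.t_end is not None else (times[-1] if len(times) else t0)
        if len(times) and (times[0] < t0 - 1e-12 or times[-1] > t1 + 1e-12):
            raise SchemaError("observations outside the window")
        object.__setattr__(self, "t_start", float(t0))
        object.__setattr__(self, "t_end", float(t1))

    def __len__(self):
        return len(self.times)

    def restrict(self, t_start: float, t_end: float) -> "ObservationSequence":
        """Observations with ``t_start < t <= t_end`` (birth-exclusive)."""
        m = (self.times > t_start + 1e-12) & (self.times <= t_end + 1e-12)
        return ObservationSequence(
            self.times[m], [self.outputs[i] for i in np.flatnonzero(m)],
            t_start=t_start, t_end=t_end,
        )


@dataclass(frozen=True)
class OutputPath:
    """A continually observed output trajectory: piecewise-constant symbols.

    ``y0`` holds on ``[t_start, jump_times[0])``; after jump ``j`` the output
    is ``jump_outputs[j]``.  Consecutive outputs must differ.
    """

    t_start: float
    y0: object
    jump_times: np.ndarray
    jump_outputs: tuple
    t_end: float

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "jump_outputs", tuple(self.jump_outputs))
        if len(jt) != len(self.jump_outputs):
            raise SchemaError("jump times and outputs differ in length")
        if len(jt) > 1 and not np.all(np.diff(jt) > 0):
            raise SchemaError("jump times must be strictly increasing")
        if len(jt) and (jt[0] <= self.t_start or jt[-1] > self.t_end + 1e-12):
            raise SchemaError("jumps outside the window")
        prev = self.y0
        for y in self.jump_outputs:
            if y == prev:
                raise SchemaError("consecutive outputs in a path must differ")
            prev = y

    @property
    def segments(self):
        """List of ``(t_from, t_to, symbol)`` covering the window."""
        knots = [self.t_start, *self.jump_times, self.t_end]
        syms = [self.y0, *self.jump_outputs]
        return [(knots[i], knots[i + 1], syms[i]) for i in range(len(syms))]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass
class PosteriorSeries:
    """A time grid with a vector per grid point.

    ``sides[k]`` is ``"pre"``/``"post"`` for the two one-sided values stored
    at each observation (or output-jump) time, ``"interior"`` elsewhere.
    """

    times: np.ndarray
    sides: np.ndarray
    values: np.ndarray  # (T, n)

    def at(self, t: float, side: str = "post") -> np.ndarray:
        hits = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))
        if len(hits) == 0:
            raise KeyError(f"time {t} not on the stored grid")
        if len(hits) == 1:
            return self.values[hits[0]]
        for h in hits:
            if self.sides[h] == side:
                return self.values[h]
        return self.values[hits[-1]]

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]


@dataclass
class ForwardResult(PosteriorSeries):
    """Filtering distributions plus accumulated log-evidence."""

    log_evidence: float = 0.0
    log_evidence_path: np.ndarray | None = None


@dataclass
class BackwardResult(PosteriorSeries):
    """Backward likelihood vectors, max-normalized with explicit log scale.

    The true (unnormalized) likelihood at row ``k`` is
    ``values[k] * exp(log_scale[k])``.
    """

    log_scale: np.ndarray | None = None

    @property
    def start_value(self) -> np.ndarray:
        """Normalized beta at the first grid time (pre side: all obs included)."""
        return self.values[0]

    @property
    def start_log_scale(self) -> float:
        return float(self.log_scale[0])


@dataclass
class SmoothedResult(PosteriorSeries):
    """Smoothed posteriors ``pi(t) ~ rho(t) * beta(t)``, normalized."""


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------
def _check_rho0(rho0: np.ndarray, n: int) -> np.ndarray:
    rho0 = np.asarray(rho0, dtype=float)
    if rho0.shape != (n,):
        raise ModelError(f"rho0 has shape {rho0.shape}, expected ({n},)")
    if np.any(rho0 < -1e-12) or not np.all(np.isfinite(rho0)):
        raise ModelError("rho0 must be a finite nonnegative vector")
    s = rho0.sum()
    if abs(s - 1.0) > 1e-6:
        raise ModelError(f"rho0 not normalized (sum {s})")
    return np.maximum(rho0, 0.0) / s


def _interior_grid(t0: float, t1: float, n_interior: int, extra=()) -> np.ndarray:
    pts = set()
    if n_interior > 0 and t1 > t0:
        pts.update(np.linspace(t0, t1, n_interior + 2)[1:-1].tolist())
    for t in extra:
        if t0 < t < t1:
            pts.add(float(t))
    return np.array(sorted(pts))


# --------------------------------------------------------------------------
# discrete-time forward observer
# --------------------------------------------------------------------------
def forward_discrete(
    A: sp.spmatrix,
    model,
    obs: ObservationSequence,
    rho0: np.ndarray,
    space: StateSpace,
    *,
    n_interior: int = 20,
    extra_times: Sequence[float] = (),
    propagator: Propagator | None = None,
    backend: str = "uniformization",
) -> ForwardResult:
    """Filter a snapshot observation sequence.

    Between observations the posterior follows the chemical master equation;
    at ``t_k`` it is re-weighted by the observation density ``b_{y_k}`` and
    renormalized, the log normalizer accumulating into the log-evidence
    ``log P(y_1..y_K)``.
    """
    n = A.shape[0]
    rho = _check_rho0(rho0, n)
    prop = propagator or Propagator(A, backend=backend)

    times, sides, rows, levs = [], [], [], []
    logev = 0.0

    def record(t, side, vec):
        times.append(t)
        sides.append(side)
        rows.append(vec.copy())
        levs.append(logev)

    t_cur = obs.t_start
    record(t_cur, "interior", rho)
    knots = list(obs.times) + [obs.t_end]
    symbols = list(obs.outputs) + [None]
    for t_k, y_k in zip(knots, symbols):
        for t_mid in _interior_grid(t_cur, t_k, n_interior, extra_times):
            rho = prop.apply(rho, t_mid - t_cur)
            rho = np.maximum(rho, 0.0)
            rho /= rho.sum()
            t_cur = t_mid
            record(t_cur, "interior", rho)
        if t_k > t_cur:
            rho = prop.apply(rho, t_k - t_cur)
            rho = np.maximum(rho, 0.0)
            rho /= rho.sum()
            t_cur = t_k
        if y_k is None:  # reached t_end
            if not times or times[-1] != t_cur or sides[-1] != "interior":
                record(t_cur, "interior", rho)
            break
        record(t_cur, "pre", rho)
        b = density_vector(model, y_k, space)
        w = float(b @ rho)
        if w <= 0.0:
            raise ZeroLikelihoodError(
                f"observation {y_k!r} at t={t_k} has zero likelihood",
                index=int(np.searchsorted(obs.times, t_k)),
                time=t_k,
            )
        rho = b * rho / w
        logev += math.log(w)
        record(t_cur, "post", rho)
    return ForwardResult(
        np.array(times), np.array(sides), np.array(rows),
        log_evidence=logev, log_evidence_path=np.array(levs),
    )


# --------------------------------------------------------------------------
# continual (noise-free) forward observer
# --------------------------------------------------------------------------
_DENSE_CLASS_LIMIT = 600


def _segment_propagator(split: SplitGenerator, y, dt: float):
    """exp(A[y,y]|_class * dt) as a dense matrix, cached per (y, dt)."""
    cache = getattr(split, "_seg_cache", None)
    if cache is None:
        cache = split._seg_cache = {}
    key = (y, round(float(dt), 12))
    if key not in cache:
        cache[key] = dense_expm(split.sub(y, y) * dt)
    return cache[key]


def forward_continual(
    split: SplitGenerator,
    path: OutputPath,
    rho0: np.ndarray,
    *,
    n_interior: int = 0,
    form: str = "linear",
    renorm_warn_tol: float = 1e-9,
) -> ForwardResult:
    """Filter a continually observed, noise-free output path.

    While the output holds at ``y`` the conditional distribution evolves
    under the within-class block ``A[y, y]`` (equivalently, in normalized
    form, ``drho/dt = A[y,y] rho - (1^T A[y,y] rho) rho``); at an output jump
    ``y -> y'`` it is pushed through the cross block and renormalized,
    ``rho+ = A[y',y] rho- / (1^T A[y',y] rho-)``.  The log normalizers
    accumulate the path log-density (survival factors plus jump rates).

    ``form="linear"`` (default) uses the exact substochastic semigroup of
    the class-restricted block; ``form="nonlinear"`` integrates the
    normalized ODE directly and serves as an independent cross-check.
    """
    if form not in ("linear", "nonlinear"):
        raise ValueError(f"unknown form {form!r}")
    n = split.A.shape[0]
    rho0 = np.asarray(rho0, dtype=float)
    if rho0.shape != (n,):
        raise ModelError(f"rho0 has shape {rho0.shape}, expected ({n},)")

    y = path.y0
    idx = split.indices(y)
    sub = rho0[idx].astype(float)
    mass = sub.sum()
    if mass <= 0:
        raise ZeroLikelihoodError(
            f"initial output {y!r} impossible under the prior", index=0,
            time=path.t_start,
        )
    if rho0.sum() - mass > renorm_warn_tol:
        warnings.warn(
            "prior mass off the initial output class zeroed and renormalized",
            stacklevel=2,
        )
    logev = math.log(mass) if mass < 1.0 else 0.0
    sub = sub / mass

    times, sides, rows, levs = [], [], [], []

    def record(t, side, sub_vec):
        full = np.zeros(n)
        full[idx] = sub_vec
        times.append(t)
        sides.append(side)
        rows.append(full)
        levs.append(logev)

    def hold(sub_vec, y, dt):
        nonlocal logev
        if dt <= 0:
            return sub_vec
        if form == "linear":
            k = len(idx)
            if k <= _DENSE_CLASS_LIMIT:
                v = _segment_propagator(split, y, dt) @ sub_vec
            else:
                from scipy.sparse.linalg import expm_multiply

                Ayy = sp.csc_matrix(split.A[np.ix_(idx, idx)])
                v = expm_multiply(Ayy.multiply(dt).tocsc(), sub_vec)
            v = np.maximum(v, 0.0)
            s = v.sum()
            if s <= 0:
                raise ZeroLikelihoodError("output dwell has zero likelihood")
            logev += math.log(s)
            return v / s
        # nonlinear normalized form, with the survival log-density augmented
        Ayy = split.sub(y, y)
        ones = np.ones(len(idx))

        def rhs(t, z):
            r = z[:-1]
            drift = Ayy @ r
            leak = ones @ drift
            return np.append(drift - leak * r, leak)

        sol = solve_ivp(
            rhs, (0.0, dt), np.append(sub_vec, 0.0),
            method="BDF", rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise ModelError(f"continual observer ODE failed: {sol.message}")
        z = sol.y[:, -1]
        logev += float(z[-1])
        r = np.maximum(z[:-1], 0.0)
        return r / r.sum()

    t_cur = path.t_start
    record(t_cur, "interior", sub)
    jumps = list(zip(path.jump_times, path.jump_outputs)) + [(path.t_end, None)]
    for t_j, y_next in jumps:
        for t_mid in _interior_grid(t_cur, t_j, n_interior):
            sub = hold(sub, y, t_mid - t_cur)
            t_cur = t_mid
            record(t_cur, "interior", sub)
        sub = hold(sub, y, t_j - t_cur)
        t_cur = t_j
        if y_next is None:
            record(t_cur, "interior", sub)
            break
        record(t_cur, "pre", sub)
        B = split.sub(y_next, y)
        v = B @ sub
        s = float(v.sum())
        if s <= 0:
            raise ZeroLikelihoodError(
                f"output jump {y!r}->{y_next!r} at t={t_j} has zero likelihood",
                time=t_j,
            )
        logev += math.log(s)
        y = y_next
        idx = split.indices(y)
        sub = np.maximum(v, 0.0) / s
        record(t_cur, "post", sub)
    return ForwardResult(
        np.array(times), np.array(sides), np.array(rows),
        log_evidence=logev, log_evidence_path=np.array(levs),
    )


# --------------------------------------------------------------------------
# backward observer
# --------------------------------------------------------------------------
def backward(
    A: sp.spmatrix,
    model,
    obs: ObservationSequence,
    t_end: float | None = None,
    *,
    t_start: float | None = None,
    space: StateSpace,
    beta_end: np.ndarray | None = None,
    log_scale_end: float = 0.0,
    n_interior: int = 20,
    extra_times: Sequence[float] = (),
    propagator: Propagator | None = None,
    backend: str = "uniformization",
) -> BackwardResult:
    """Compute the backward likelihood ``beta(t)`` over ``[t_start, t_end]``.

    ``beta`` is 1 after the final observation (or equals ``beta_end``, the
    terminal likelihood carried in from elsewhere, e.g. a lineage pinch);
    moving backwards it solves ``dbeta/dt = -A^T beta`` between observations
    and is multiplied elementwise by ``b_{y_k}`` when crossing ``t_k``.
    Values are stored max-normalized with an explicit log scale to avoid
    underflow on long windows.
    """
    n = A.shape[0]
    t_end = float(t_end if t_end is not None else obs.t_end)
    t_start = float(t_start if t_start is not None else obs.t_start)
    if len(obs) and obs.times[-1] > t_end + 1e-12:
        raise SchemaError("t_end precedes the last observation")
    beta = np.ones(n) if beta_end is None else np.asarray(beta_end, dtype=float).copy()
    if beta.shape != (n,):
        raise ModelError(f"beta_end has shape {beta.shape}, expected ({n},)")
    if np.any(beta < 0):
        raise ModelError("beta_end must be nonnegative")
    log_scale = float(log_scale_end)
    prop = propagator or Propagator(A.T.tocsc(), backend=backend)

    times, sides, rows, scales = [], [], [], []

    def record(t, side, vec):
        times.append(t)
        sides.append(side)
        rows.append(vec.copy())
        scales.append(log_scale)

    def renorm(vec):
        nonlocal log_scale
        m = vec.max()
        if m <= 0:
            raise ZeroLikelihoodError("backward likelihood vanished everywhere")
        log_scale += math.log(m)
        return vec / m

    record(t_end, "interior", beta)
    knots = list(obs.times)[::-1] + [t_start]
    symbols = list(obs.outputs)[::-1] + [None]
    t_cur = t_end
    for t_k, y_k in zip(knots, symbols):
        for t_mid in _interior_grid(t_k, t_cur, n_interior, extra_times)[::-1]:
            beta = renorm(np.maximum(prop.apply(beta, t_cur - t_mid), 0.0))
            t_cur = t_mid
            record(t_cur, "interior", beta)
        if t_cur > t_k:
            beta = renorm(np.maximum(prop.apply(beta, t_cur - t_k), 0.0))
            t_cur = t_k
        if y_k is None:
            if not times or times[-1] != t_cur:
                record(t_cur, "interior", beta)
            break
        record(t_cur, "post", beta)  # excludes observation k
        b = density_vector(model, y_k, space)
        beta = renorm(b * beta)
        record(t_cur, "pre", beta)  # includes observation k
    # lists were built in descending time with (post, pre) at each obs time;
    # a full reverse yields ascending time with pre before post.
    return BackwardResult(
        np.array(times[::-1]),
        np.array(sides[::-1]),
        np.array(rows[::-1]),
        log_scale=np.array(scales[::-1]),
    )


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------
def smooth(
    fwd: ForwardResult,
    bwd: BackwardResult,
    A: sp.spmatrix | None = None,
) -> SmoothedResult:
    """Combine forward and backward passes: ``pi(t) ~ rho(t) * beta(t)``.

    Pre-update forward values pair with pre-update backward values (and post
    with post); both products normalize to the same smoothed posterior,
    making ``pi`` continuous across observation times.  Grid points of the
    forward pass missing from the backward grid are filled by re-propagating
    the nearest later backward value (never by interpolating probabilities);
    this requires passing the generator ``A``.
    """
    key = {}
    for k, (t, s) in enumerate(zip(bwd.times, bwd.sides)):
        key[(round(float(t), 9), s)] = k
        key.setdefault(round(float(t), 9), k)

    times, sides, rows = [], [], []
    prop_T = None
    for k, (t, s) in enumerate(zip(fwd.times, fwd.sides)):
        tk = round(float(t), 9)
        j = key.get((tk, s), key.get((tk, "interior"), key.get(tk)))
        if j is None:
            if A is None:
                raise SchemaError(
                    f"grids misaligned at t={t}; pass A to re-propagate"
                )
            later = np.flatnonzero(bwd.times >= t - 1e-12)
            if len(later) == 0:
                raise SchemaError(f"no backward value at or after t={t}")
            j = later[0]
            if prop_T is None:
                prop_T = Propagator(A.T.tocsc())
            beta = prop_T.apply(bwd.values[j], float(bwd.times[j] - t))
        else:
            beta = bwd.values[j]
        prod = fwd.values[k] * beta
        s_tot = prod.sum()
        if s_tot <= 0:
            raise ZeroLikelihoodError(f"zero forward-backward product at t={t}")
        times.append(t)
        sides.append(s)
        rows.append(prod / s_tot)
    return SmoothedResult(np.array(times), np.array(sides), np.array(rows))


def mmse(
    sm: PosteriorSeries, space: StateSpace, species: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation of a species' copy number.

    Returns ``(times, mean, sd)`` evaluated on the stored grid; the mean is
    the minimum mean-square-error estimate of the hidden count.
    """
    counts = space.species_column(species).astype(float)
    mean = sm.values @ counts
    second = sm.values @ counts**2
    var = np.maximum(second - mean**2, 0.0)
    return sm.times.copy(), mean, np.sqrt(var)


def smoother(
    A: sp.spmatrix,
    model,
    obs: ObservationSequence,
    rho0: np.ndarray,
    space: StateSpace,
    *,
    n_interior: int = 20,
    extra_times: Sequence[float] = (),
    backend: str = "uniformization",
) -> tuple[ForwardResult, BackwardResult, SmoothedResult]:
    """Run forward, backward and smoothing passes on one shared grid."""
    fwd = forward_discrete(
        A, model, obs, rho0, space,
        n_interior=n_interior, extra_times=extra_times, backend=backend,
    )
    bwd = backward(
        A, model, obs, obs.t_end, t_start=obs.t_start, space=space,
        n_interior=n_interior, extra_times=extra_times, backend=backend,
    )
    return fwd, bwd, smooth(fwd, bwd, A=A)
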