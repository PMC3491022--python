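"""Bayesian model discrimination and the distinguishability test.

Discrimination stacks the candidate models' generators into one
block-diagonal CTMC whose "model index" coordinate never changes; running
the (discrete or continual) forward observer on the composed system and
summing the posterior over each block yields the posterior probability of
every model given the data.

Distinguishability asks whether the posterior can ever concentrate on the
generating model, for *any* observation schedule.  With a noise-free output
partition and the chain at stationarity, the statistics of the observed
output process are captured by the dwell-conditional output hazards: after
a steady-state output transition ``y_prev -> y``, the rate of exiting to
``y'`` after dwell time ``tau`` is ``h_{y'}(tau) = 1^T A[y',y] rho(tau)``
where ``rho(tau)`` is the normalized within-class evolution of the entry
distribution.  Two models are indistinguishable iff these hazards agree for
every context ``(y_prev, y)`` with positive steady-state flux and every
destination ``y'`` — independent of how often one samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm as dense_expm

from .errors import ModelError, SensorError
from .generator import build_generator, steady_state
from .network import ReactionNetwork, StateSpace
from .observers import ForwardResult
from .sensing import DeterministicPartition, SplitGenerator, split_generator

__all__ = [
    "CandidateModel",
    "ModelEnsemble",
    "ComposedSystem",
    "compose",
    "model_posterior",
    "HazardProfile",
    "hazard_profile",
    "model_hazard_profiles",
    "DistinguishabilityReport",
    "distinguishable",
]


# --------------------------------------------------------------------------
# ensembles and composition
# --------------------------------------------------------------------------
@dataclass
class CandidateModel:
    """One candidate: a network with its space, generator and prior state."""

    name: str
    network: ReactionNetwork
    space: StateSpace
    A: sp.spmatrix
    rho0: np.ndarray

    @classmethod
    def from_network(cls, network: ReactionNetwork, name: str | None = None):
        space = network.state_space()
        return cls(
            name=name or network.name or "model",
            network=network,
            space=space,
            A=build_generator(network, space),
            rho0=network.initial_distribution(space),
        )


@dataclass
class ModelEnsemble:
    """Named candidate models with prior weights and one shared sensor."""

    models: list[CandidateModel]
    sensor: DeterministicPartition
    weights: np.ndarray | None = None

    def __post_init__(self):
        m = len(self.models)
        if m == 0:
            raise ModelError("empty model ensemble")
        if self.weights is None:
            self.weights = np.full(m, 1.0 / m)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ModelError("prior weights must be nonnegative and sum to 1")
        alphabets = [tuple(self.sensor.alphabet(c.space)) for c in self.models]
        if len(set(alphabets)) != 1:
            raise ModelError(
                "models produce different output alphabets under the shared sensor"
            )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.models]


@dataclass
class ComposedSystem:
    """Block-diagonal composition of an ensemble.

    ``A`` is ``diag(A_1, ..., A_m)``; ``rho0`` concatenates ``w_i *
    rho0_i``; ``labels`` concatenates the per-block output symbols so the
    composed :class:`SplitGenerator` acts blockwise.  The model index is a
    frozen coordinate: there are no cross-block transitions.
    """

    ensemble: ModelEnsemble
    A: sp.csc_matrix
    rho0: np.ndarray
    labels: np.ndarray
    split: SplitGenerator
    slices: list[slice]

    def block_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum an (..., n_total) array over each model block."""
        return np.stack([values[..., s].sum(axis=-1) for s in self.slices], axis=-1)

    @property
    def sensor_view(self):
        """A partition-like view over the composed labels, usable wherever a
        deterministic sensor is expected (e.g. ``forward_discrete``)."""
        return _LabelPartition(self.labels)

    @property
    def space_view(self):
        """Placeholder 'space' for composed-system observer calls."""
        return None


class _LabelPartition:
    """Deterministic partition given directly by a per-state label array."""

    def __init__(self, labels: np.ndarray):
        self.labels = labels

    def assign(self, space=None) -> np.ndarray:
        return self.labels


def compose(ensemble: ModelEnsemble) -> ComposedSystem:
    """Build the block-diagonal system for joint state+model filtering."""
    A = sp.block_diag([c.A for c in ensemble.models], format="csc")
    rho0 = np.concatenate(
        [w * c.rho0 for w, c in zip(ensemble.weights, ensemble.models)]
    )
    labels = np.concatenate(
        [np.asarray(ensemble.sensor.assign(c.space)) for c in ensemble.models]
    )
    slices, off = [], 0
    for c in ensemble.models:
        slices.append(slice(off, off + c.space.n))
        off += c.space.n
    return ComposedSystem(
        ensemble=ensemble, A=A, rho0=rho0, labels=labels,
        split=SplitGenerator(A, labels), slices=slices,
    )


def model_posterior(fwd: ForwardResult, composed: ComposedSystem):
    """Per-model posterior time series from a composed forward run.

    Returns a DataFrame indexed by (time, side) with one column per model;
    each row sums to 1.
    """
    import pandas as pd

    block = composed.block_sums(fwd.values)
    block = block / block.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        block,
        columns=composed.ensemble.names,
        index=pd.MultiIndex.from_arrays(
            [fwd.times, fwd.sides], names=["time", "side"]
        ),
    )


# --------------------------------------------------------------------------
# steady-state output hazards
# --------------------------------------------------------------------------
@dataclass
class HazardProfile:
    """Dwell-conditional exit hazards after a steady-state ``y_prev -> y``.

    ``hazards[y'][k]`` is the instantaneous rate of an output change to
    ``y'`` at dwell time ``tau_grid[k]``, starting from the conditional
    entry distribution ``rho0`` (the normalized steady-state flux).
    """

    y_prev: object
    y: object
    flux: float
    tau_grid: np.ndarray
    rho0: np.ndarray  # restricted to the class of y
    hazards: dict  # destination symbol -> array over tau_grid
    taylor: dict | None = None  # destination -> coefficients 1^T A_{y',y} A_{y,y}^k rho0

    @property
    def total_exit(self) -> np.ndarray:
        return np.sum(np.stack(list(self.hazards.values())), axis=0)


def hazard_profile(
    A: sp.spmatrix,
    split: SplitGenerator,
    p_ss: np.ndarray,
    y_prev,
    y,
    tau_grid: np.ndarray,
    taylor_order: int | None = None,
) -> HazardProfile:
    """Hazard curves for the context ``(y_prev, y)``.

    The entry distribution is the steady-state probability flux of
    ``y_prev -> y`` transitions, normalized; it then relaxes under the
    within-class block while the per-destination exit hazards are read off.
    Raises :class:`ModelError` when ``y == y_prev`` and
    :class:`SensorError` for a zero-flux context.
    """
    if y == y_prev:
        raise ModelError("output self-transitions do not occur in a partition")
    idx_prev = split.indices(y_prev)
    idx = split.indices(y)
    B_entry = split.sub(y, y_prev)
    v = B_entry @ p_ss[idx_prev]
    flux = float(v.sum())
    if flux <= 0:
        raise SensorError(f"context ({y_prev!r} -> {y!r}) has zero steady-state flux")
    rho0 = v / flux
    Ayy = split.sub(y, y)
    # destinations: any class reachable from class y in one transition
    dests = sorted(
        {p[0] for p in split.pairs() if p[1] == y and p[0] != y}, key=str
    )
    exit_rows = {y2: split.sub(y2, y).sum(axis=0) for y2 in dests}

    tau_grid = np.asarray(tau_grid, dtype=float)
    hazards = {y2: np.empty_like(tau_grid) for y2 in dests}
    rho = rho0.copy()
    t_prev = 0.0
    for k, tau in enumerate(tau_grid):
        if tau > t_prev:
            rho = dense_expm(Ayy * (tau - t_prev)) @ rho
            rho = np.maximum(rho, 0.0)
            s = rho.sum()
            if s <= 0:
                rho = np.zeros_like(rho)
            else:
                rho = rho / s
            t_prev = tau
        for y2 in dests:
            hazards[y2][k] = float(exit_rows[y2] @ rho)

    taylor = None
    if taylor_order is not None:
        taylor = {}
        powers = [rho0]
        for _ in range(taylor_order):
            powers.append(Ayy @ powers[-1])
        for y2 in dests:
            taylor[y2] = np.array([exit_rows[y2] @ p for p in powers])
    return HazardProfile(
        y_prev=y_prev, y=y, flux=flux, tau_grid=tau_grid,
        rho0=rho0, hazards=hazards, taylor=taylor,
    )


def _default_tau_grid(A: sp.spmatrix, split: SplitGenerator, p_ss, n_points=200):
    """Log-spaced dwell grid scaled to the slowest total exit rate seen."""
    # smallest positive total exit rate over states with stationary mass
    exit_rate = -A.diagonal()
    for y in split.alphabet:
        idx = split.indices(y)
        within = np.array(split.sub(y, y), copy=True)  # sub() caches: do not mutate
        np.fill_diagonal(within, 0.0)
        exit_rate[idx] -= within.sum(axis=0)
    pos = exit_rate[(exit_rate > 1e-300) & (p_ss > 1e-12)]
    scale = 1.0 / pos.min() if len(pos) else 1.0
    return np.geomspace(1e-3 * scale, 10.0 * scale, n_points)


def model_hazard_profiles(
    network: ReactionNetwork,
    sensor: DeterministicPartition,
    tau_grid: np.ndarray | None = None,
    flux_tol: float = 1e-12,
    taylor_order: int | None = None,
):
    """All positive-flux contexts of one model under a noise-free sensor.

    Returns ``(profiles, skipped, stationary_output_dist, tau_grid)``.
    """
    space = network.state_space()
    A = build_generator(network, space)
    split = split_generator(A, sensor, space)
    p_ss = steady_state(A)
    if tau_grid is None:
        tau_grid = _default_tau_grid(A, split, p_ss)
    # steady-state flux per ordered context
    fluxes = {}
    coo = A.tocoo()
    lr, lc = split.labels[coo.row], split.labels[coo.col]
    off = lr != lc
    for r, c, a in zip(coo.row[off], coo.col[off], coo.data[off]):
        key = (split.labels[c], split.labels[r])  # (y_prev, y)
        fluxes[key] = fluxes.get(key, 0.0) + a * p_ss[c]
    total = sum(fluxes.values()) or 1.0
    profiles, skipped = {}, []
    for (y_prev, y), f in sorted(fluxes.items(), key=lambda kv: str(kv[0])):
        if f / total <= flux_tol:
            skipped.append((y_prev, y))
            continue
        profiles[(y_prev, y)] = hazard_profile(
            A, split, p_ss, y_prev, y, tau_grid, taylor_order=taylor_order
        )
    out_dist = {
        y: float(p_ss[split.indices(y)].sum()) for y in split.alphabet
    }
    return profiles, skipped, out_dist, tau_grid


# --------------------------------------------------------------------------
# the distinguishability verdict
# --------------------------------------------------------------------------
@dataclass
class DistinguishabilityReport:
    """Pairwise comparison of steady-state dwell-conditional hazards.

    ``verdict`` is ``"indistinguishable"`` iff every compared hazard curve
    agrees within the relative tolerance and no context or destination is
    present (with positive flux) in only one model.  The stationary output
    distributions are compared and reported separately; they do not enter
    the dwell-hazard condition.
    """

    model_a: str
    model_b: str
    tol: float
    contexts: dict = field(default_factory=dict)
    structural: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    stationary_output_tv: float = 0.0
    distinguishable: bool = False

    @property
    def verdict(self) -> str:
        return "distinguishable" if self.distinguishable else "indistinguishable"

    @property
    def max_relative_discrepancy(self) -> float:
        vals = [c["max_rel"] for c in self.contexts.values()]
        return max(vals) if vals else 0.0


def distinguishable(
    network_a: ReactionNetwork,
    network_b: ReactionNetwork,
    sensor: DeterministicPartition,
    tol: float = 1e-6,
    tau_grid: np.ndarray | None = None,
    n_tau: int = 200,
    taylor_order: int | None = None,
) -> DistinguishabilityReport:
    """Test whether two models can ever be told apart from the output.

    The test is schedule-free: it compares, for every steady-state entry
    context ``(y_prev, y)`` with positive flux in either model and every
    exit destination ``y'``, the dwell-conditional hazard curves on a
    shared grid.  Any context or destination alive in only one model is an
    immediate (structural) distinguishability witness.
    """
    prof_a, skip_a, out_a, grid = model_hazard_profiles(
        network_a, sensor, tau_grid=tau_grid if tau_grid is not None
        else None, taylor_order=taylor_order,
    )
    if tau_grid is None:
        tau_grid = grid
    prof_b, skip_b, out_b, _ = model_hazard_profiles(
        network_b, sensor, tau_grid=tau_grid, taylor_order=taylor_order
    )
    report = DistinguishabilityReport(
        model_a=network_a.name or "A", model_b=network_b.name or "B", tol=tol
    )
    report.skipped = sorted(set(skip_a) | set(skip_b), key=str)
    keys = sorted(set(prof_a) | set(prof_b), key=str)
    flag = False
    for key in keys:
        pa, pb = prof_a.get(key), prof_b.get(key)
        if pa is None or pb is None:
            report.structural.append(
                {"context": key, "present_in": report.model_a if pa else report.model_b}
            )
            flag = True
            continue
        dests = sorted(set(pa.hazards) | set(pb.hazards), key=str)
        max_abs = max_rel = 0.0
        for d in dests:
            ha = pa.hazards.get(d, np.zeros_like(tau_grid))
            hb = pb.hazards.get(d, np.zeros_like(tau_grid))
            diff = float(np.max(np.abs(ha - hb)))
            scale = max(float(np.max(np.abs(ha))), float(np.max(np.abs(hb))), 1e-300)
            max_abs = max(max_abs, diff)
            max_rel = max(max_rel, diff / scale)
        report.contexts[key] = {"max_abs": max_abs, "max_rel": max_rel}
        if max_rel > tol:
            flag = True
    alphabet = sorted(set(out_a) | set(out_b), key=str)
    report.stationary_output_tv = 0.5 * sum(
        abs(out_a.get(y, 0.0) - out_b.get(y, 0.0)) for y in alphabet
    )
    report.distinguishable = flag
    return report
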