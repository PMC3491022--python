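"""Gillespie simulation of single cells and dividing colonies.

The direct-method SSA here is deliberately consistent with the truncated
generator: reactions whose firing would push a species above its cap are
excluded from the propensity sum, so simulated trajectories live exactly on
the enumerated state space and empirical histograms converge to the
chemical master equation solution of :mod:`crnobserver.generator`.

Built-in models:

``birth_death``
    A single species produced at constant rate ``k`` and degraded at rate
    ``gamma`` per molecule; its stationary law is a truncated Poisson with
    parameter ``k / gamma`` (defaults 10 / 1, centred in the "MEDIUM" band
    of the three-band sensor).

``tvo_m1`` / ``tvo_m2`` / ``tvo_m3``
    The Thattai–van Oudenaarden transcription–translation model
    ``D -> D + M``, ``M -> M + P``, ``M -> 0``, ``P -> 0`` with a single
    replicated DNA copy, and the two variants with the protein rates
    (``m2``) or the mRNA rates (``m3``) scaled up tenfold.  Reference rates
    (per second): transcription 0.05, mRNA degradation 0.01, translation
    0.05 per mRNA, protein degradation 0.005; caps M <= 20, P <= 150;
    initial condition D = 1, M = 0, P = 0.  All overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError, SchemaError, SensorError
from .lineage import Cell, DivisionKernel, LineageTree
from .network import (
    InitialCondition,
    Reaction,
    ReactionNetwork,
    Species,
    StateSpace,
)
from .observers import ObservationSequence, OutputPath
from .sensing import DeterministicPartition, GaussianEmission, sample_output

__all__ = ["Trajectory", "ssa", "simulate_colony", "observe", "builtin"]


@dataclass
class Trajectory:
    """A sample path: event times and the state after each event.

    ``states[0]`` is the initial state at ``t0``; ``states[k]`` holds on
    ``[times[k], times[k+1])`` (with ``times[0] = t0``).
    """

    times: np.ndarray  # (E+1,), times[0] == t0
    states: np.ndarray  # (E+1, s)
    reactions: np.ndarray  # (E,), fired channel index per event
    t_end: float
    seed: int | None = None

    def state_at(self, t) -> np.ndarray:
        """State held at time t (vectorized over an array of times)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-12) or np.any(t > self.t_end + 1e-12):
            raise ModelError("query time outside the simulated window")
        k = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.maximum(k, 0)]

    def to_dataframe(self, species_names):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(species_names))
        df.insert(0, "time", self.times)
        return df


class _IndexedChain:
    """Per-state transition table derived from the generator columns."""

    def __init__(self, network: ReactionNetwork, space: StateSpace):
        self.space = space
        self.deltas = network.change_vectors()
        props = network.propensity_matrix(space)
        # suppress reactions breaching a cap, mirroring build_generator
        n, R = props.shape
        ok = np.ones((n, R), dtype=bool)
        for r in range(R):
            target = space.counts + self.deltas[r]
            ok[:, r] = np.all((target >= 0) & (target <= space.caps), axis=1)
        self.props = np.where(ok, props, 0.0)
        self.total = self.props.sum(axis=1)
        self.cum = np.cumsum(self.props, axis=1)
        # target state index per (state, reaction); -1 where suppressed
        self.target = np.full((n, R), -1, dtype=np.int64)
        for r in range(R):
            target = space.counts + self.deltas[r]
            m = ok[:, r]
            if m.any():
                self.target[m, r] = np.ravel_multi_index(
                    target[m].T, space.shape
                )


def ssa(
    network: ReactionNetwork,
    x0,
    t_max: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    space: StateSpace | None = None,
    t0: float = 0.0,
    chain: _IndexedChain | None = None,
) -> Trajectory:
    """Gillespie direct-method simulation up to ``t_max``.

    ``x0`` may be a count vector over the free species or a mapping
    ``{species: count}``.  If all propensities vanish the trajectory is
    absorbed and simply held to ``t_max``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if chain is None:
        if space is None:
            space = network.state_space()
        chain = _IndexedChain(network, space)
    space = chain.space
    if isinstance(x0, dict):
        x0 = np.array([int(x0.get(s, 0)) for s in space.species_names])
    x = np.asarray(x0, dtype=np.int64)
    idx = int(space.index(x))
    times = [float(t0)]
    indices = [idx]
    fired = []
    t = float(t0)
    total = chain.total
    cum = chain.cum
    target = chain.target
    n_r = chain.props.shape[1]
    expo = rng.exponential
    unif = rng.uniform
    while True:
        a0 = total[idx]
        if a0 <= 0.0:
            break  # absorbing state; hold to t_max
        t = t + expo(1.0 / a0)
        if t > t_max:
            break
        r = int(np.searchsorted(cum[idx], unif(0.0, a0), side="right"))
        if r >= n_r:
            r = n_r - 1
        idx = int(target[idx, r])
        times.append(t)
        indices.append(idx)
        fired.append(r)
    return Trajectory(
        times=np.array(times),
        states=space.counts[np.array(indices, dtype=np.int64)].copy(),
        reactions=np.array(fired, dtype=np.int64),
        t_end=float(t_max),
        seed=seed,
    )


def simulate_colony(
    network: ReactionNetwork,
    division_interval: float,
    t_max: float,
    seed: int | None = None,
    x0=None,
    partition_p: float = 0.5,
) -> tuple[LineageTree, dict[str, Trajectory]]:
    """Simulate a colony dividing at fixed intervals.

    The ancestral cell ``"c"`` is born at t = 0 and divides every
    ``division_interval``; daughters of cell ``cid`` are ``cid + "1"`` and
    ``cid + "2"``.  At division, binomial species are split molecule by
    molecule (conserving the mother's count exactly) and replicate species
    are copied.  Reproducible for a given seed.
    """
    if division_interval <= 0:
        raise ModelError("division_interval must be positive")
    rng = np.random.default_rng(seed)
    space = network.state_space()
    chain = _IndexedChain(network, space)
    kernel = DivisionKernel(network, space, p=partition_p)
    if x0 is None:
        rho0 = network.initial_distribution(space)
        x0 = space.counts[rng.choice(space.n, p=rho0)]
    elif isinstance(x0, dict):
        x0 = np.array([int(x0.get(s, 0)) for s in space.species_names])
    cells: list[Cell] = []
    trajs: dict[str, Trajectory] = {}
    queue = [("c", None, 0.0, np.asarray(x0, dtype=np.int64))]
    while queue:
        cid, parent, birth, x = queue.pop(0)
        end = min(birth + division_interval, t_max)
        traj = ssa(network, x, end, rng=rng, chain=chain, t0=birth)
        trajs[cid] = traj
        cells.append(Cell(id=cid, parent=parent, birth=birth, end=end))
        if end < t_max:  # divides
            d1, d2 = kernel.sample(traj.states[-1], rng)
            queue.append((cid + "1", cid, end, d1))
            queue.append((cid + "2", cid, end, d2))
    return LineageTree(cells), trajs


def observe(
    traj: Trajectory,
    model,
    schedule,
    space: StateSpace,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Turn a hidden trajectory into sensor data.

    ``schedule`` is ``("periodic", dt)``, an explicit array of times, or
    ``"continual"``.  Periodic/explicit schedules return an
    :class:`ObservationSequence` (noisy draws for a Gaussian sensor);
    ``"continual"`` requires a deterministic partition and returns the exact
    piecewise-constant :class:`OutputPath` with consecutive duplicate
    symbols merged.
    """
    t0, t1 = float(traj.times[0]), float(traj.t_end)
    if isinstance(schedule, str) and schedule == "continual":
        if not isinstance(model, DeterministicPartition):
            raise SensorError("continual observation requires a noise-free partition")
        outs = [sample_output(model, s, space) for s in traj.states]
        y0 = outs[0]
        jt, jy = [], []
        prev = y0
        for t, y in zip(traj.times[1:], outs[1:]):
            if y != prev:
                jt.append(t)
                jy.append(y)
                prev = y
        return OutputPath(t_start=t0, y0=y0, jump_times=np.array(jt),
                          jump_outputs=jy, t_end=t1)
    if isinstance(schedule, tuple) and schedule[0] == "periodic":
        dt = float(schedule[1])
        if dt <= 0:
            raise SchemaError("periodic observation interval must be positive")
        times = np.arange(t0, t1 + 1e-9, dt)
    else:
        times = np.asarray(schedule, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    states = traj.state_at(times)
    outputs = [sample_output(model, s, space, rng=rng if
                             isinstance(model, GaussianEmission) else None)
               for s in states]
    return ObservationSequence(times, outputs, t_start=t0, t_end=t1)


# --------------------------------------------------------------------------
# built-in models
# --------------------------------------------------------------------------
_TVO_RATES = {
    "transcription": 0.05,   # D -> D + M        (per second)
    "mrna_degradation": 0.01,  # M -> 0          (per molecule per second)
    "translation": 0.05,     # M -> M + P        (per mRNA per second)
    "protein_degradation": 0.005,  # P -> 0      (per molecule per second)
}


def _tvo(scale_protein: float = 1.0, scale_mrna: float = 1.0,
         m_cap: int = 20, p_cap: int = 150, name: str = "tvo_m1",
         **rates) -> ReactionNetwork:
    r = dict(_TVO_RATES)
    r.update(rates)
    return ReactionNetwork(
        name=name,
        species=[
            Species("D", cap=1, division="replicate", fixed=1),
            Species("M", cap=m_cap, division="binomial"),
            Species("P", cap=p_cap, division="binomial"),
        ],
        reactions=[
            Reaction(name="transcription", changes={"M": +1},
                     rate=r["transcription"] * scale_mrna, reactants={"D": 1}),
            Reaction(name="translation", changes={"P": +1},
                     rate=r["translation"] * scale_protein, reactants={"M": 1}),
            Reaction(name="mrna_degradation", changes={"M": -1},
                     rate=r["mrna_degradation"] * scale_mrna),
            Reaction(name="protein_degradation", changes={"P": -1},
                     rate=r["protein_degradation"] * scale_protein),
        ],
        initial_condition=InitialCondition(kind="point", state={"M": 0, "P": 0}),
    )


def builtin(name: str, **overrides) -> ReactionNetwork:
    """Construct a built-in reaction network by name.

    Names: ``birth_death``, ``tvo_m1``, ``tvo_m2`` (protein production and
    degradation x10), ``tvo_m3`` (mRNA production and degradation x10).
    Keyword overrides adjust rates and caps, e.g. ``builtin("birth_death",
    k=5, gamma=0.5, cap=40)``.
    """
    if name == "birth_death":
        k = float(overrides.pop("k", 10.0))
        gamma = float(overrides.pop("gamma", 1.0))
        cap = int(overrides.pop("cap", 30))
        if overrides:
            raise SchemaError(f"unknown overrides {sorted(overrides)}")
        return ReactionNetwork(
            name="birth_death",
            species=[Species("X", cap=cap, division="binomial")],
            reactions=[
                Reaction(name="birth", changes={"X": +1}, rate=k),
                Reaction(name="death", changes={"X": -1}, rate=gamma),
            ],
            initial_condition=InitialCondition(
                kind="truncated_poisson", means={"X": k / gamma}
            ),
        )
    if name == "tvo_m1":
        return _tvo(name="tvo_m1", **overrides)
    if name == "tvo_m2":
        return _tvo(scale_protein=10.0, name="tvo_m2", **overrides)
    if name == "tvo_m3":
        return _tvo(scale_mrna=10.0, name="tvo_m3", **overrides)
    raise SchemaError(f"unknown builtin model {name!r}")
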