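"""Reaction networks and their truncated state spaces.

A :class:`ReactionNetwork` is a set of species with finite population caps
and a set of reaction channels, each with an integer stoichiometry change
vector and a nonnegative propensity (stochastic mass action or a general
function of the copy-number state).  Truncating every species at its cap
makes the state space finite, so the network defines a continuous-time
Markov chain whose probability law obeys the chemical master equation.

Species whose copy number is never changed by any reaction and that are
replicated verbatim at cell division (e.g. a single chromosomal gene copy)
can be declared with a ``fixed`` value: they are substituted into the
propensities as constants and excluded from the enumeration, which keeps the
state space small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

from .errors import ModelError, SchemaError, StateSpaceSizeError

__all__ = [
    "Species",
    "Reaction",
    "InitialCondition",
    "ReactionNetwork",
    "StateSpace",
    "enumerate_states",
]

#: hard limit on the number of enumerated states unless overridden
DEFAULT_STATE_LIMIT = 10**7

DIVISION_RULES = ("binomial", "replicate")


@dataclass(frozen=True)
class Species:
    """A chemical species with a truncation cap and a division rule.

    Parameters
    ----------
    name
        Identifier; must be a valid python/sympy symbol name.
    cap
        Maximum population ``N_max`` retained in the truncation.  Reactions
        that would push the population above the cap are disallowed.
    division
        ``"binomial"``: each molecule joins either daughter with probability
        1/2 at cell division.  ``"replicate"``: the count is copied to both
        daughters (e.g. DNA).
    fixed
        If not ``None``, the species is held at this constant count, excluded
        from the state enumeration and substituted into propensities.
    """

    name: str
    cap: int
    division: str = "binomial"
    fixed: int | None = None

    def __post_init__(self):
        if not self.name.isidentifier():
            raise SchemaError(f"species name {self.name!r} is not an identifier")
        if self.division not in DIVISION_RULES:
            raise SchemaError(
                f"species {self.name!r}: unknown division rule {self.division!r}"
            )
        if not (isinstance(self.cap, (int, np.integer)) and self.cap >= 0):
            raise SchemaError(f"species {self.name!r}: cap must be a finite int >= 0")
        if self.fixed is not None and not (0 <= self.fixed <= self.cap):
            raise SchemaError(f"species {self.name!r}: fixed value outside [0, cap]")


@dataclass(frozen=True)
class Reaction:
    """A reaction channel: stoichiometry change plus a propensity.

    Exactly one of the following must describe the propensity:

    * ``rate`` (with optional ``reactants``): stochastic mass action,
      ``a(x) = rate * prod_s falling_factorial(x_s, r_s)``.  If ``reactants``
      is omitted it is inferred from the species the reaction consumes.
    * ``expression``: an arithmetic formula over species names (parsed with
      sympy; e.g. ``"0.05*M"``).
    * ``propensity``: an arbitrary python callable mapping a count vector
      (ordered as the network's free species) to a nonnegative rate.
    """

    changes: Mapping[str, int]
    rate: float | None = None
    reactants: Mapping[str, int] | None = None
    expression: str | None = None
    propensity: Callable[[np.ndarray], float] | None = None
    name: str = ""

    def __post_init__(self):
        n_forms = sum(
            x is not None for x in (self.rate, self.expression, self.propensity)
        )
        if n_forms != 1:
            raise SchemaError(
                f"reaction {self.name!r}: exactly one of rate/expression/propensity "
                f"must be given (got {n_forms})"
            )
        if self.rate is not None and self.rate < 0:
            raise SchemaError(f"reaction {self.name!r}: negative rate constant")
        if not self.changes or all(v == 0 for v in self.changes.values()):
            raise SchemaError(f"reaction {self.name!r}: empty stoichiometry change")
        for s, v in self.changes.items():
            if not isinstance(v, (int, np.integer)):
                raise SchemaError(f"reaction {self.name!r}: non-integer change for {s}")


@dataclass(frozen=True)
class InitialCondition:
    """Initial law of the chain: a point mass or truncated product-Poisson."""

    kind: str = "point"  # "point" | "truncated_poisson"
    state: Mapping[str, int] | None = None
    means: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.kind not in ("point", "truncated_poisson"):
            raise SchemaError(f"unknown initial condition kind {self.kind!r}")
        if self.kind == "point" and self.state is None:
            raise SchemaError("point initial condition requires 'state'")
        if self.kind == "truncated_poisson" and self.means is None:
            raise SchemaError("truncated_poisson initial condition requires 'means'")


class StateSpace:
    """Deterministic enumeration of all count vectors within the caps.

    States are ordered lexicographically with species in declaration order
    (the first declared species varies slowest).  The enumeration and its
    inverse are exposed through :meth:`index` and :meth:`state`.
    """

    def __init__(self, species_names: Sequence[str], caps: Sequence[int]):
        self.species_names = tuple(species_names)
        self.caps = np.asarray(caps, dtype=np.int64)
        if np.any(self.caps < 0):
            raise ModelError("caps must be >= 0")
        self.shape = tuple(int(c) + 1 for c in self.caps)
        self.n = int(np.prod(self.shape, dtype=np.int64)) if self.shape else 1
        grids = np.indices(self.shape, dtype=np.int64)
        self.counts = grids.reshape(len(self.shape), -1).T.copy()  # (n, s)

    def index(self, counts) -> np.ndarray | int:
        """Map count vector(s) to state index/indices (lexicographic)."""
        arr = np.asarray(counts, dtype=np.int64)
        scalar = arr.ndim == 1
        if scalar:
            arr = arr[None, :]
        if np.any(arr < 0) or np.any(arr > self.caps):
            raise ModelError("state outside truncation caps")
        idx = np.ravel_multi_index(arr.T, self.shape)
        return int(idx[0]) if scalar else idx

    def state(self, i: int) -> np.ndarray:
        """Inverse of :meth:`index`."""
        return self.counts[i]

    def species_column(self, name: str) -> np.ndarray:
        """Copy-number of ``name`` in every state (length-n vector)."""
        try:
            j = self.species_names.index(name)
        except ValueError:
            raise ModelError(f"unknown species {name!r}") from None
        return self.counts[:, j]

    def __len__(self):
        return self.n

    def __repr__(self):
        return f"StateSpace({dict(zip(self.species_names, map(int, self.caps)))}, n={self.n})"


def _falling_factorial(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x, dtype=float)
    for i in range(k):
        out *= np.maximum(x - i, 0)
    return out


@dataclass
class ReactionNetwork:
    """Species, reaction channels and an initial condition.

    The *free* species (those without a ``fixed`` value) span the truncated
    state space; fixed species enter the propensities as constants.
    """

    species: Sequence[Species]
    reactions: Sequence[Reaction]
    initial_condition: InitialCondition | None = None
    name: str = ""
    _evaluators: list = field(default_factory=list, init=False, repr=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate species names")
        self._by_name = {s.name: s for s in self.species}
        for r in self.reactions:
            for s in r.changes:
                if s not in self._by_name:
                    raise SchemaError(
                        f"reaction {r.name!r}: unknown species {s!r} in stoichiometry"
                    )
                if self._by_name[s].fixed is not None and r.changes[s] != 0:
                    raise SchemaError(
                        f"reaction {r.name!r}: changes fixed species {s!r}"
                    )
            if r.reactants:
                for s in r.reactants:
                    if s not in self._by_name:
                        raise SchemaError(
                            f"reaction {r.name!r}: unknown reactant {s!r}"
                        )
        self._evaluators = [self._make_evaluator(r) for r in self.reactions]

    # -- species views -------------------------------------------------
    @property
    def free_species(self) -> list[Species]:
        return [s for s in self.species if s.fixed is None]

    @property
    def fixed_species(self) -> dict[str, int]:
        return {s.name: s.fixed for s in self.species if s.fixed is not None}

    def species_by_name(self, name: str) -> Species:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown species {name!r}") from None

    # -- state space ---------------------------------------------------
    def state_space(self, limit: int = DEFAULT_STATE_LIMIT) -> StateSpace:
        return enumerate_states(self, limit=limit)

    # -- stoichiometry -------------------------------------------------
    def change_vectors(self) -> np.ndarray:
        """(R, s_free) integer matrix of per-reaction changes."""
        free = [s.name for s in self.free_species]
        out = np.zeros((len(self.reactions), len(free)), dtype=np.int64)
        for i, r in enumerate(self.reactions):
            for s, v in r.changes.items():
                out[i, free.index(s)] = v
        return out

    # -- propensities --------------------------------------------------
    def _make_evaluator(self, r: Reaction):
        free = [s.name for s in self.free_species]
        fixed = self.fixed_species

        if r.propensity is not None:
            func = r.propensity

            def general(counts: np.ndarray, f=func):
                vals = np.array([f(row) for row in counts], dtype=float)
                return vals

            return general

        if r.expression is not None:
            syms = {name: sympy.Symbol(name, nonnegative=True) for name in free}
            allowed = dict(syms)
            allowed.update({k: sympy.Integer(v) for k, v in fixed.items()})
            try:
                expr = sympy.sympify(r.expression, locals=allowed)
            except (sympy.SympifyError, SyntaxError) as exc:
                raise SchemaError(
                    f"reaction {r.name!r}: cannot parse expression {r.expression!r}"
                ) from exc
            extra = expr.free_symbols - set(syms.values())
            if extra:
                raise SchemaError(
                    f"reaction {r.name!r}: unknown symbols {sorted(map(str, extra))}"
                )
            f = sympy.lambdify([syms[name] for name in free], expr, modules="numpy")

            def from_expr(counts: np.ndarray, f=f):
                cols = [counts[:, j].astype(float) for j in range(counts.shape[1])]
                vals = f(*cols)
                return np.broadcast_to(np.asarray(vals, dtype=float), (counts.shape[0],)).copy()

            return from_expr

        # stochastic mass action
        reactants = r.reactants
        if reactants is None:
            reactants = {s: -v for s, v in r.changes.items() if v < 0}
        orders = []
        const = float(r.rate)
        for s, k in reactants.items():
            if k < 0:
                raise SchemaError(f"reaction {r.name!r}: negative reactant order")
            if s in fixed:
                const *= _falling_factorial(np.array([fixed[s]]), int(k))[0]
            else:
                orders.append((free.index(s), int(k)))

        def mass_action(counts: np.ndarray, const=const, orders=tuple(orders)):
            vals = np.full(counts.shape[0], const, dtype=float)
            for j, k in orders:
                vals *= _falling_factorial(counts[:, j], k)
            return vals

        return mass_action

    def propensity_matrix(self, space: StateSpace) -> np.ndarray:
        """Propensity of every reaction in every state, shape ``(n, R)``.

        Raises :class:`ModelError` if any propensity is negative or
        non-finite, identifying the offending state and reaction.
        """
        n = space.n
        out = np.empty((n, len(self.reactions)), dtype=float)
        for j, (r, ev) in enumerate(zip(self.reactions, self._evaluators)):
            vals = ev(space.counts)
            bad = ~np.isfinite(vals) | (vals < 0)
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ModelError(
                    f"reaction {r.name or j!r}: propensity is {vals[i]} at state "
                    f"{dict(zip(space.species_names, map(int, space.counts[i])))}"
                )
            out[:, j] = vals
        return out

    # -- initial distribution -------------------------------------------
    def initial_distribution(self, space: StateSpace) -> np.ndarray:
        """Initial probability vector on ``space`` (point or trunc. Poisson)."""
        ic = self.initial_condition
        if ic is None:
            raise ModelError("network has no initial condition")
        if ic.kind == "point":
            x = np.array(
                [int(ic.state.get(name, 0)) for name in space.species_names],
                dtype=np.int64,
            )
            rho = np.zeros(space.n)
            rho[space.index(x)] = 1.0
            return rho
        # truncated product-Poisson over the free species
        rho = np.ones(space.n)
        for name in space.species_names:
            lam = float(ic.means.get(name, 0.0))
            counts = space.species_column(name)
            if lam == 0.0:
                rho *= (counts == 0).astype(float)
            else:
                logpmf = counts * math.log(lam) - lam - np.array(
                    [math.lgamma(c + 1) for c in range(int(counts.max()) + 1)]
                )[counts]
                rho *= np.exp(logpmf)
        s = rho.sum()
        if s <= 0:
            raise ModelError("initial distribution has zero mass on the state space")
        return rho / s


def enumerate_states(
    network: ReactionNetwork, limit: int = DEFAULT_STATE_LIMIT
) -> StateSpace:
    """Enumerate the truncated state space of the free species.

    The order is lexicographic with species in declaration order.  Raises
    :class:`StateSpaceSizeError` if the product of ``cap + 1`` exceeds
    ``limit``.
    """
    free = network.free_species
    size = 1
    for s in free:
        size *= s.cap + 1
    if size > limit:
        offenders = {s.name: s.cap for s in free}
        raise StateSpaceSizeError(
            f"state space size {size} exceeds limit {limit}; caps: {offenders}"
        )
    return StateSpace([s.name for s in free], [s.cap for s in free])
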