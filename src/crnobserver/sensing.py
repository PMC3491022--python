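"""Sensor models: state-to-output maps and output-partitioned generators.

Two sensor families are supported:

* :class:`DeterministicPartition` — every state emits exactly one symbol
  from a finite alphabet, defined either by threshold bands on one species'
  copy number (e.g. "LOW"/"MEDIUM"/"HIGH") or by reading the copy number off
  directly (each count is its own symbol).  This is the noise-free
  idealization required by the continual observer.
* :class:`GaussianEmission` — a noisy continuous read-out
  ``y = gain * x_s + N(0, sd^2)``, usable with the discrete-time observer.

For a deterministic partition the generator splits into blocks
``A[y', y]`` holding exactly the transitions from states with output ``y``
into states with output ``y'``; the blocks sum entrywise to ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .errors import SchemaError, SensorError
from .network import StateSpace

__all__ = [
    "DeterministicPartition",
    "GaussianEmission",
    "density_vector",
    "split_generator",
    "SplitGenerator",
    "sample_output",
    "three_band_partition",
    "count_partition",
]


@dataclass(frozen=True)
class DeterministicPartition:
    """Noise-free sensor: a partition of the state space by output symbol.

    ``thresholds`` are closed upper bounds of consecutive bands on the
    read-out species: with thresholds ``[6, 13]`` and labels
    ``["LOW", "MEDIUM", "HIGH"]``, counts <= 6 map to "LOW", 7..13 to
    "MEDIUM" and the rest to "HIGH".  With ``mode="count"`` each copy number
    is its own (integer) symbol.
    """

    species: str
    mode: str = "bands"  # "bands" | "count"
    thresholds: tuple[int, ...] = ()
    labels: tuple = ()
    kind: str = field(default="partition", init=False)

    def __post_init__(self):
        if self.mode not in ("bands", "count"):
            raise SchemaError(f"unknown partition mode {self.mode!r}")
        if self.mode == "bands":
            if len(self.labels) != len(self.thresholds) + 1:
                raise SchemaError("need exactly len(thresholds)+1 labels")
            if list(self.thresholds) != sorted(set(self.thresholds)):
                raise SchemaError("thresholds must be strictly increasing")

    def alphabet(self, space: StateSpace) -> list:
        if self.mode == "count":
            cap = int(space.caps[space.species_names.index(self.species)])
            return list(range(cap + 1))
        return list(self.labels)

    def assign(self, space: StateSpace) -> np.ndarray:
        """Output symbol of every state (object array, length n)."""
        counts = space.species_column(self.species)
        if self.mode == "count":
            return counts.copy()
        band = np.searchsorted(np.asarray(self.thresholds), counts, side="left")
        return np.asarray(self.labels, dtype=object)[band]

    def output_of(self, x: np.ndarray, space: StateSpace):
        """Symbol emitted by the count vector ``x``."""
        j = space.species_names.index(self.species)
        c = int(x[j])
        if self.mode == "count":
            return c
        return self.labels[int(np.searchsorted(np.asarray(self.thresholds), c))]


@dataclass(frozen=True)
class GaussianEmission:
    """Noisy sensor: ``y | x ~ Normal(gain * x_s, sd^2)``."""

    species: str
    gain: float = 1.0
    sd: float = 1.0
    kind: str = field(default="gaussian", init=False)

    def __post_init__(self):
        if self.sd <= 0:
            raise SchemaError("gaussian sensor needs sd > 0")

    def density(self, y: float, space: StateSpace) -> np.ndarray:
        counts = space.species_column(self.species)
        return norm.pdf(float(y), loc=self.gain * counts, scale=self.sd)


def density_vector(model, y, space: StateSpace) -> np.ndarray:
    """Observation density vector ``b_y``: entry ``i`` is ``b(y | x_i)``.

    For a deterministic partition the entries are exactly 0/1 indicators of
    the output class of each state.
    """
    if hasattr(model, "assign"):  # deterministic partition (or a label view)
        labels = model.assign(space)
        b = (labels == y).astype(float)
        if not b.any():
            raise SensorError(f"unknown output symbol {y!r}")
        return b
    if hasattr(model, "density"):  # noisy emission family
        return model.density(y, space)
    raise SensorError(f"unsupported sensor type {type(model).__name__}")


class SplitGenerator:
    """Output-partitioned generator blocks ``A[y', y]``.

    ``block(y2, y1)`` is the full-shape sparse matrix holding exactly the
    entries of ``A`` whose column state has output ``y1`` and row state has
    output ``y2`` (diagonal entries belong to the ``(y, y)`` block).  The
    blocks sum entrywise to ``A``.  Compact dense sub-blocks restricted to
    the output classes, used by the continual observer, are cached.
    """

    def __init__(self, A: sp.spmatrix, labels: np.ndarray):
        self.A = A.tocsc()
        self.labels = labels
        self.class_index: dict = {}
        # stable class discovery in order of first appearance
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        for lab in seen:
            self.class_index[lab] = np.flatnonzero(labels == lab)
        self.alphabet = seen
        coo = self.A.tocoo()
        self._row_lab = labels[coo.row]
        self._col_lab = labels[coo.col]
        self._coo = coo
        self._sub_cache: dict = {}

    def pairs(self) -> list[tuple]:
        """All ordered output pairs ``(y2, y1)`` with a nonempty block."""
        seen = {}
        for rl, cl in zip(self._row_lab, self._col_lab):
            seen[(rl, cl)] = True
        return list(seen)

    def block(self, y2, y1) -> sp.csc_matrix:
        mask = (self._row_lab == y2) & (self._col_lab == y1)
        coo = self._coo
        return sp.csc_matrix(
            (coo.data[mask], (coo.row[mask], coo.col[mask])), shape=self.A.shape
        )

    def sub(self, y2, y1) -> np.ndarray:
        """Dense block restricted to rows in class ``y2``, columns in ``y1``."""
        key = (y2, y1)
        if key not in self._sub_cache:
            rows = self.class_index.get(y2)
            cols = self.class_index.get(y1)
            if rows is None or cols is None:
                raise SensorError(f"unknown output symbol in pair {key!r}")
            self._sub_cache[key] = np.asarray(
                self.A[np.ix_(rows, cols)].todense()
            )
            if y2 != y1:
                # off-class blocks must not carry diagonal entries
                pass
        return self._sub_cache[key]

    def indices(self, y) -> np.ndarray:
        try:
            return self.class_index[y]
        except KeyError:
            raise SensorError(f"unknown output symbol {y!r}") from None


def split_generator(A: sp.spmatrix, model, space: StateSpace) -> SplitGenerator:
    """Split ``A`` into the output-pair blocks of a deterministic sensor."""
    if not isinstance(model, DeterministicPartition):
        raise SensorError(
            "continual observation requires a deterministic partition sensor"
        )
    return SplitGenerator(A, model.assign(space))


def sample_output(model, x: np.ndarray, space: StateSpace, rng=None):
    """Simulate the sensor on state ``x``: g(x), or a draw from b(.|x)."""
    if isinstance(model, DeterministicPartition):
        return model.output_of(x, space)
    if isinstance(model, GaussianEmission):
        if rng is None:
            raise SensorError("noisy sensor sampling requires an rng")
        j = space.species_names.index(model.species)
        return float(rng.normal(model.gain * x[j], model.sd))
    raise SensorError(f"unsupported sensor type {type(model).__name__}")


def three_band_partition(species: str = "X", thresholds=(6, 13),
                         labels=("LOW", "MEDIUM", "HIGH")) -> DeterministicPartition:
    """The coarse three-band sensor used in the single-species example."""
    return DeterministicPartition(
        species=species, mode="bands",
        thresholds=tuple(thresholds), labels=tuple(labels),
    )


def count_partition(species: str) -> DeterministicPartition:
    """Noise-free integer read-out: every copy number is its own symbol."""
    return DeterministicPartition(species=species, mode="count")
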