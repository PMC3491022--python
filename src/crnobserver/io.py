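"""Configuration and tabular I/O: JSON model/sensor files, CSV tables.

Model schema (JSON)::

    {
      "name": "tvo_m1",
      "species": [
        {"name": "D", "cap": 1, "division": "replicate", "fixed": 1},
        {"name": "M", "cap": 20, "division": "binomial"}
      ],
      "reactions": [
        {"name": "transcription", "changes": {"M": 1},
         "rate": 0.05, "reactants": {"D": 1}},
        {"name": "translation", "changes": {"P": 1}, "expression": "0.05*M"}
      ],
      "initial_condition": {"kind": "point", "state": {"M": 0, "P": 0}}
    }

Sensor schema (JSON)::

    {"kind": "partition", "species": "X", "thresholds": [6, 13],
     "labels": ["LOW", "MEDIUM", "HIGH"]}
    {"kind": "partition", "species": "P", "mode": "count"}
    {"kind": "gaussian", "species": "P", "gain": 1.0, "sd": 5.0}

Observation CSV columns: ``cell_id, time, output``.  Lineage CSV columns:
``cell_id, parent_id, birth_time, end_time`` (empty parent for the root).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .lineage import Cell, LineageTree
from .network import InitialCondition, Reaction, ReactionNetwork, Species
from .observers import ObservationSequence, PosteriorSeries
from .sensing import DeterministicPartition, GaussianEmission

__all__ = [
    "load_model",
    "model_to_dict",
    "save_model",
    "load_sensor",
    "sensor_to_dict",
    "save_sensor",
    "read_observations",
    "write_observations",
    "read_lineage",
    "write_lineage",
    "attach_observations",
    "write_posterior",
]


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return d[key]


# -- models -----------------------------------------------------------------
def load_model(source) -> ReactionNetwork:
    """Load a reaction network from a JSON file path or a parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
        where = str(source)
    else:
        doc, where = dict(source), "/"
    species = []
    for i, s in enumerate(_require(doc, "species", where)):
        loc = f"{where}/species/{i}"
        species.append(
            Species(
                name=_require(s, "name", loc),
                cap=int(_require(s, "cap", loc)),
                division=s.get("division", "binomial"),
                fixed=s.get("fixed"),
            )
        )
    reactions = []
    for i, r in enumerate(_require(doc, "reactions", where)):
        loc = f"{where}/reactions/{i}"
        reactions.append(
            Reaction(
                name=r.get("name", f"r{i}"),
                changes={k: int(v) for k, v in _require(r, "changes", loc).items()},
                rate=r.get("rate"),
                reactants=r.get("reactants"),
                expression=r.get("expression"),
            )
        )
    ic = doc.get("initial_condition")
    initial = None
    if ic is not None:
        initial = InitialCondition(
            kind=ic.get("kind", "point"),
            state=ic.get("state"),
            means=ic.get("means"),
        )
    return ReactionNetwork(
        species=species, reactions=reactions,
        initial_condition=initial, name=doc.get("name", ""),
    )


def model_to_dict(network: ReactionNetwork) -> dict:
    doc = {"name": network.name, "species": [], "reactions": []}
    for s in network.species:
        entry = {"name": s.name, "cap": int(s.cap), "division": s.division}
        if s.fixed is not None:
            entry["fixed"] = int(s.fixed)
        doc["species"].append(entry)
    for r in network.reactions:
        entry = {"name": r.name, "changes": dict(r.changes)}
        if r.rate is not None:
            entry["rate"] = r.rate
            if r.reactants is not None:
                entry["reactants"] = dict(r.reactants)
        elif r.expression is not None:
            entry["expression"] = r.expression
        else:
            raise SchemaError(
                f"reaction {r.name!r}: python-callable propensities are not serializable"
            )
        doc["reactions"].append(entry)
    ic = network.initial_condition
    if ic is not None:
        entry = {"kind": ic.kind}
        if ic.state is not None:
            entry["state"] = {k: int(v) for k, v in ic.state.items()}
        if ic.means is not None:
            entry["means"] = {k: float(v) for k, v in ic.means.items()}
        doc["initial_condition"] = entry
    return doc


def save_model(network: ReactionNetwork, path):
    with open(path, "w") as fh:
        json.dump(model_to_dict(network), fh, indent=2)


# -- sensors ----------------------------------------------------------------
def load_sensor(source):
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
        where = str(source)
    else:
        doc, where = dict(source), "/"
    kind = _require(doc, "kind", where)
    if kind == "partition":
        if doc.get("mode", "bands") == "count" or "thresholds" not in doc:
            return DeterministicPartition(
                species=_require(doc, "species", where), mode="count"
            )
        return DeterministicPartition(
            species=_require(doc, "species", where),
            mode="bands",
            thresholds=tuple(int(t) for t in doc["thresholds"]),
            labels=tuple(_require(doc, "labels", where)),
        )
    if kind == "gaussian":
        return GaussianEmission(
            species=_require(doc, "species", where),
            gain=float(doc.get("gain", 1.0)),
            sd=float(_require(doc, "sd", where)),
        )
    raise SchemaError(f"{where}: unknown sensor kind {kind!r}")


def sensor_to_dict(model) -> dict:
    if isinstance(model, DeterministicPartition):
        doc = {"kind": "partition", "species": model.species, "mode": model.mode}
        if model.mode == "bands":
            doc["thresholds"] = list(model.thresholds)
            doc["labels"] = list(model.labels)
        return doc
    if isinstance(model, GaussianEmission):
        return {"kind": "gaussian", "species": model.species,
                "gain": model.gain, "sd": model.sd}
    raise SchemaError(f"unsupported sensor type {type(model).__name__}")


def save_sensor(model, path):
    with open(path, "w") as fh:
        json.dump(sensor_to_dict(model), fh, indent=2)


# -- observations -----------------------------------------------------------
def _parse_output(val):
    """CSV output cells: keep integers as int, otherwise float, else str."""
    s = str(val).strip()
    try:
        return int(s)
    except ValueError:
        try:
            return float(s)
        except ValueError:
            return s


def read_observations(path) -> dict[str, ObservationSequence]:
    """Per-cell observation sequences from a cell_id,time,output CSV."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    for col in ("cell_id", "time", "output"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        times = grp["time"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(times) <= 0)
        if len(dup):
            row = grp.index[dup[0] + 1]
            raise SchemaError(
                f"{path}: duplicate/non-increasing time for cell {cid!r} at row {row}"
            )
        out[str(cid)] = ObservationSequence(
            times, [_parse_output(v) for v in grp["output"]]
        )
    return out


def write_observations(obs_map: dict[str, ObservationSequence], path):
    rows = []
    for cid, seq in obs_map.items():
        for t, y in zip(seq.times, seq.outputs):
            rows.append({"cell_id": cid, "time": t, "output": y})
    pd.DataFrame(rows, columns=["cell_id", "time", "output"]).to_csv(path, index=False)


# -- lineages ---------------------------------------------------------------
def read_lineage(path) -> LineageTree:
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    for col in ("cell_id", "parent_id", "birth_time", "end_time"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    cells = []
    for _, row in df.iterrows():
        parent = row["parent_id"]
        parent = None if (pd.isna(parent) or str(parent) == "") else str(parent)
        cells.append(
            Cell(
                id=str(row["cell_id"]), parent=parent,
                birth=float(row["birth_time"]), end=float(row["end_time"]),
            )
        )
    return LineageTree(cells)


def write_lineage(tree: LineageTree, path):
    rows = [
        {"cell_id": c.id, "parent_id": c.parent or "", "birth_time": c.birth,
         "end_time": c.end}
        for c in tree.topological()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def attach_observations(tree: LineageTree, obs_map: dict[str, ObservationSequence]):
    """Restrict each cell's observations to its lifetime and attach them.

    An observation exactly at a division time belongs to the mother cell.
    """
    for cid, cell in tree.cells.items():
        seq = obs_map.get(cid)
        if seq is None:
            cell.obs = None
            continue
        lo = cell.birth if cell.parent is None else cell.birth
        m = (seq.times >= lo - 1e-9) & (seq.times <= cell.end + 1e-9)
        if cell.parent is not None:
            m &= seq.times > cell.birth + 1e-9  # birth-time obs went to the mother
        cell.obs = ObservationSequence(
            seq.times[m], [seq.outputs[i] for i in np.flatnonzero(m)],
            t_start=cell.birth, t_end=cell.end,
        )
    return tree


# -- posteriors -------------------------------------------------------------
def write_posterior(
    results: dict[str, PosteriorSeries] | PosteriorSeries,
    space,
    path,
    full_threshold: int = 100,
    sidecar: dict | None = None,
):
    """Write posterior series to CSV (plus a JSON reproducibility sidecar).

    Small state spaces (``n <= full_threshold``) get one probability column
    per state (labelled by species counts); larger ones get per-species
    posterior mean and sd columns.
    """
    if isinstance(results, PosteriorSeries):
        results = {"c": results}
    names = space.species_names
    full = space.n <= full_threshold
    rows = []
    for cid, series in results.items():
        counts = space.counts.astype(float)
        for k in range(len(series.times)):
            row = {
                "cell_id": cid,
                "time": series.times[k],
                "boundary_side": series.sides[k],
            }
            p = series.values[k]
            if full:
                for i in range(space.n):
                    lab = "p_" + "_".join(
                        f"{nm}{int(space.counts[i, j])}" for j, nm in enumerate(names)
                    )
                    row[lab] = p[i]
            else:
                for j, nm in enumerate(names):
                    mean = float(p @ counts[:, j])
                    second = float(p @ counts[:, j] ** 2)
                    row[f"{nm}_mean"] = mean
                    row[f"{nm}_sd"] = float(np.sqrt(max(second - mean**2, 0.0)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {"package_version": __version__}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
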