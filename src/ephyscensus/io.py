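"""Serialization of recordings and feature tables.

HDF5 layout for trace containers::

    /cells/<cell_id>/<protocol>/sweeps    (n_sweeps, n_samples) float32
    /cells/<cell_id>/<protocol>.attrs     stimulus (JSON), fs, stage_group,
                                          condition, seal-test values

Feature matrices are CSV (cells x variables, NaN for missing) with a JSON
sidecar recording units and group labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import VARIABLES
from .model import Condition, Protocol, Recording, StageGroup


def save_recordings(path, cells: dict[str, dict[Protocol, Recording]]) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("cells")
        for cell_id, recs in cells.items():
            g = root.create_group(cell_id)
            for proto, rec in recs.items():
                d = g.create_dataset(Protocol(proto).value, data=rec.sweeps,
                                     dtype="float32", compression="gzip")
                d.attrs["stimulus"] = json.dumps(rec.stimulus)
                d.attrs["fs"] = rec.fs
                d.attrs["stage_group"] = rec.stage_group.value
                d.attrs["condition"] = rec.condition.value
                d.attrs["meta"] = json.dumps(rec.meta)


def load_recordings(path) -> dict[str, dict[Protocol, Recording]]:
    out: dict[str, dict[Protocol, Recording]] = {}
    with h5py.File(path, "r") as f:
        for cell_id, g in f["cells"].items():
            recs = {}
            for name, d in g.items():
                proto = Protocol(name)
                recs[proto] = Recording(
                    protocol=proto,
                    sweeps=np.asarray(d, dtype=float),
                    stimulus=json.loads(d.attrs["stimulus"]),
                    cell_id=cell_id,
                    stage_group=StageGroup(d.attrs["stage_group"]),
                    condition=Condition(d.attrs["condition"]),
                    fs=float(d.attrs["fs"]),
                    meta=json.loads(d.attrs["meta"]),
                )
            out[cell_id] = recs
    return out


def save_feature_matrix(path, matrix: pd.DataFrame,
                        labels: pd.DataFrame | None = None) -> None:
    """Write the feature CSV plus a JSON schema sidecar (units, labels)."""
    path = Path(path)
    matrix.to_csv(path, index_label="cell_id")
    sidecar = {
        "variables": [{"index": i, "name": n, "unit": u} for i, n, u in VARIABLES
                      if n in matrix.columns],
        "n_cells": int(matrix.shape[0]),
    }
    if labels is not None:
        sidecar["labels"] = labels.to_dict(orient="index")
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")
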