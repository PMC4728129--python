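"""Cost-based spike-train similarity across cells, with 2D embedding.

The Victor-Purpura metric treats one spike train as editable into another:
inserting or deleting a spike costs 1, and moving a spike by dt ms costs
q * |dt|, capped at 2 by the delete-plus-insert alternative. With
q = 0.1 / ms the metric is sensitive to both spike counts and latencies on
a ~20 ms timescale. Distances between the concatenated step-protocol
responses of all cells are embedded into 2D with classical (Torgerson)
multidimensional scaling, and similar-spiking groups are pulled as nearest
neighbors of reference cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Protocol, Recording
from .spikes import SpikeTrain

DEFAULT_Q_PER_MS = 0.1


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "vp_q0.1"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def concat_step_trains(rec_or_trains, sweep_length_ms: float | None = None) -> np.ndarray:
    """Combine step-protocol responses of all amplitudes into one long train.

    Sweeps are laid end to end in ascending order of injected current; spike
    times get the cumulative sweep offset. Accepts a step Recording with
    per-sweep SpikeTrains, or a bare list of trains plus a sweep length.
    """
    if isinstance(rec_or_trains, tuple) and isinstance(rec_or_trains[0], Recording):
        rec, trains = rec_or_trains
        if rec.protocol != Protocol.CURRENT_STEPS:
            raise ValueError("expected a current-step recording")
        sweep_length_ms = rec.sweeps.shape[1] * 1000.0 / rec.fs
        order = np.argsort([s["current_pa"] for s in rec.stimulus])
        trains = [trains[k] for k in order]
    else:
        trains = rec_or_trains
        if sweep_length_ms is None:
            raise ValueError("sweep_length_ms required for a bare train list")
        trains = sorted(trains, key=lambda tr: getattr(tr, "sweep_id", 0)) \
            if all(isinstance(tr, SpikeTrain) for tr in trains) else list(trains)
    parts = []
    for k, tr in enumerate(trains):
        t = tr.spike_times if isinstance(tr, SpikeTrain) else np.asarray(tr, dtype=float)
        parts.append(t + k * sweep_length_ms)
    return np.concatenate(parts) if parts else np.empty(0)


def vp_distance(train_a, train_b, q: float = DEFAULT_Q_PER_MS) -> float:
    """Victor-Purpura spike-train distance (dynamic programming).

    Insert/delete cost 1; moving a spike by dt costs min(q*|dt|, 2).
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        return float(na + nb)
    prev = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur = np.empty(nb + 1)
        cur[0] = i
        shift = np.minimum(q * np.abs(a[i - 1] - b), 2.0)
        for j in range(1, nb + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0,
                         prev[j - 1] + shift[j - 1])
        prev = cur
    return float(prev[nb])


def distance_matrix(trains: dict[str, np.ndarray] | list,
                    q: float = DEFAULT_Q_PER_MS) -> DistanceMatrix:
    """All pairwise VP distances between cells' concatenated trains."""
    if isinstance(trains, dict):
        ids = list(trains.keys())
        data = [np.asarray(trains[i], dtype=float) for i in ids]
    else:
        ids = [f"cell{k:03d}" for k in range(len(trains))]
        data = [np.asarray(t, dtype=float) for t in trains]
    if len(ids) < 2:
        raise ValueError("need at least 2 cells")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vp_distance(data[i], data[j], q)
    return DistanceMatrix(ids=ids, matrix=d, metric=f"vp_q{q:g}")


def classical_mds(dist: DistanceMatrix | np.ndarray, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-`dims` coordinates. Sign convention: within each dimension the
    largest-magnitude coordinate is positive. Negative eigenvalues (non-
    Euclidean metrics) are truncated at zero.
    """
    if isinstance(dist, DistanceMatrix):
        ids, d = dist.ids, dist.matrix
    else:
        d = np.asarray(dist, dtype=float)
        ids = [f"cell{k:03d}" for k in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return pd.DataFrame(coords, index=ids,
                        columns=[f"dim{k + 1}" for k in range(coords.shape[1])])


def nearest_neighbor_group(coords: pd.DataFrame, reference_id: str, k: int = 5) -> list[str]:
    """Reference cell plus its k nearest neighbors in the 2D embedding.

    Ties are broken by id order. Raises when k >= number of cells.
    """
    if k >= len(coords):
        raise ValueError("k must be smaller than the number of cells")
    xy = coords.to_numpy(dtype=float)
    ref = coords.loc[reference_id].to_numpy(dtype=float)
    dist = np.linalg.norm(xy - ref, axis=1)
    order = sorted(range(len(coords)),
                   key=lambda i: (dist[i], str(coords.index[i])))
    group = [str(coords.index[i]) for i in order if coords.index[i] != reference_id]
    return [reference_id] + group[:k]
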