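"""Spatial habitat network per epoch and pond closeness centrality.

The network is the complete graph on all extant ponds with Euclidean edge
weights in km. The closeness index of a pond is its mean shortest-path
distance to every other pond (farness / (n-1)); on a complete Euclidean
graph the direct edge is always a shortest path, so this is simply the mean
pairwise distance. Lower index = more central (better connected); a temporal
increase means the pond became more peripheral. The mean (rather than the
sum or its reciprocal) keeps the index comparable between networks of
different size, e.g. the full 116-pond epoch-1 network vs. the 30 surviving
ponds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import DataError, PondTable


@dataclass
class HabitatNetwork:
    epoch: str
    node_ids: list[str]
    coords: np.ndarray  # (n, 2) metres
    distances: np.ndarray  # (n, n) km, symmetric, zero diagonal

    @property
    def n(self) -> int:
        return len(self.node_ids)


def build_network(ponds: PondTable, epoch: str) -> HabitatNetwork:
    """Complete Euclidean network on the ponds extant in ``epoch``."""
    sub = ponds.extant(epoch)
    if len(sub) < 2:
        raise DataError(f"need at least 2 extant ponds in epoch {epoch}")
    coords = sub[["x", "y"]].to_numpy(float)
    if np.isnan(coords).any():
        bad = sub.index[np.isnan(coords).any(axis=1)][0]
        raise DataError(f"pond {bad!r} has missing coordinates")
    dist_km = squareform(pdist(coords)) / 1000.0
    return HabitatNetwork(epoch, list(sub.index), coords, dist_km)


def closeness_index(net: HabitatNetwork) -> pd.Series:
    """Mean distance (km) from each pond to all other ponds."""
    idx = net.distances.sum(axis=1) / (net.n - 1)
    return pd.Series(idx, index=pd.Index(net.node_ids, name="pond_id"), name="closeness_km")


def delta_closeness(
    net_a: HabitatNetwork,
    net_b: HabitatNetwork,
    shared_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-pond change in closeness index, ``net_b`` minus ``net_a`` (km).

    Positive = the pond became more isolated between the two epochs.
    """
    if shared_ids is None:
        in_b = set(net_b.node_ids)
        shared_ids = [s for s in net_a.node_ids if s in in_b]
    ia, ib = closeness_index(net_a), closeness_index(net_b)
    missing = [s for s in shared_ids if s not in ia.index or s not in ib.index]
    if missing:
        raise DataError(f"ids missing from a network: {missing}")
    out = ib.loc[list(shared_ids)] - ia.loc[list(shared_ids)]
    out.name = "d_closeness_km"
    return out


def to_graphml(net: HabitatNetwork, path: str | Path) -> None:
    """Export the complete weighted network (GraphML, via networkx)."""
    import networkx as nx

    g = nx.Graph()
    close = closeness_index(net)
    for i, v in enumerate(net.node_ids):
        g.add_node(v, x=float(net.coords[i, 0]), y=float(net.coords[i, 1]),
                   closeness_km=float(close.iloc[i]))
    for i in range(net.n):
        for j in range(i + 1, net.n):
            g.add_edge(net.node_ids[i], net.node_ids[j],
                       weight=float(net.distances[i, j]))
    nx.write_graphml(g, str(path))
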