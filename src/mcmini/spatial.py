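"""Spatial single-cell analysis: cell-type clustering and recurrent neighborhoods.

Two stages operate on the Spatial Feature Table:

1. *Expression clustering* assigns cells to types from their marker mean
   intensities (z-scored), via seeded k-means or k-nearest-neighbour-graph
   community detection (Leiden- or Louvain-style modularity optimisation).
2. *Neighborhood analysis* summarises each cell's local micro-environment as
   a composition vector — the fraction of each cell type among its spatial
   neighbours (fixed radius or k nearest) — and clusters those vectors with
   seeded k-means into recurrent cellular neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterAssignment",
    "NeighborhoodProfile",
    "cluster_expression",
    "neighborhood_composition",
    "recurrent_neighborhoods",
    "write_annotations",
]


@dataclass
class ClusterAssignment:
    """CellID -> contiguous integer cluster label, with method provenance."""

    cell_ids: np.ndarray
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("one label per cell required")
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = np.array([remap[v] for v in self.labels])

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.cell_ids, name="CellID"))


@dataclass
class NeighborhoodProfile:
    """Per-cell composition over cell-type clusters among spatial neighbours."""

    cell_ids: np.ndarray
    composition: np.ndarray  # (n_cells, n_types), rows sum to 1 (or all-zero)
    isolated: np.ndarray  # bool flags for cells with no neighbour in radius
    mode: str
    radius_or_k: float


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def cluster_expression(
    table: pd.DataFrame,
    markers: list[str],
    method: str = "kmeans",
    params: dict | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster cells in marker-expression space.

    ``method='kmeans'`` (params: ``n_clusters``, default 8; ``n_init`` fixed
    at 10) or ``method='knn-graph-community'`` (params: ``k`` neighbours,
    default 30 capped at n-1; ``flavor`` ``leiden``/``louvain``).  Features
    are z-scored before clustering, so the result is invariant to affine
    intensity rescaling.
    """
    params = dict(params or {})
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ValueError(f"markers not in table: {missing}")
    x = _zscore(table[markers].to_numpy(dtype=float))
    n = len(x)
    cell_ids = table["CellID"].to_numpy()

    if method == "kmeans":
        k = int(params.get("n_clusters", 8))
        if n < k:
            raise ValueError(f"{n} cells cannot form {k} clusters")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(x)
    elif method == "knn-graph-community":
        import igraph
        import leidenalg

        k = int(params.get("k", 30))
        k = min(k, n - 1)
        if k < 1:
            raise ValueError("need at least 2 cells for a kNN graph")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, idx = nn.kneighbors(x)
        edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
        g = igraph.Graph(n=n, edges=sorted(edges))
        flavor = params.get("flavor", "leiden")
        if flavor == "leiden":
            part = leidenalg.find_partition(
                g, leidenalg.ModularityVertexPartition, seed=seed
            )
            labels = np.array(part.membership)
        elif flavor == "louvain":
            labels = np.array(
                g.community_multilevel().membership
            )
        else:
            raise ValueError(f"unknown community flavor {flavor!r}")
    else:
        raise ValueError(f"unknown method {method!r}")
    return ClusterAssignment(cell_ids, np.asarray(labels), method, params, seed)


def default_radius(table: pd.DataFrame) -> float:
    """3 x the median nearest-neighbour distance between cell centroids."""
    pts = table[["centroid_y", "centroid_x"]].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=2).fit(pts)
    d, _ = nn.kneighbors(pts)
    return 3.0 * float(np.median(d[:, 1]))


def neighborhood_composition(
    table: pd.DataFrame,
    assignment: ClusterAssignment,
    mode: str = "radius",
    radius_or_k: float | None = None,
) -> NeighborhoodProfile:
    """Per-cell cell-type composition of the spatial neighbourhood.

    ``mode='radius'`` counts all cells within the radius (excluding the cell
    itself; cells with no neighbour get an all-zero vector and an isolation
    flag); ``mode='knn'`` uses the k nearest cells.  Vectors are normalised
    to the probability simplex.
    """
    pts = table[["centroid_y", "centroid_x"]].to_numpy(dtype=float)
    types = assignment.as_series().reindex(table["CellID"]).to_numpy()
    if np.any(pd.isna(types)):
        raise ValueError("assignment is missing some CellIDs from the table")
    types = types.astype(int)
    n_types = int(types.max()) + 1
    n = len(pts)
    comp = np.zeros((n, n_types))
    isolated = np.zeros(n, dtype=bool)

    if mode == "radius":
        r = default_radius(table) if radius_or_k is None else float(radius_or_k)
        if r <= 0:
            raise ValueError("radius must be > 0")
        nn = NearestNeighbors(radius=r).fit(pts)
        _, idx = nn.radius_neighbors(pts)
        for i, nbrs in enumerate(idx):
            nbrs = nbrs[nbrs != i]
            if len(nbrs) == 0:
                isolated[i] = True
                continue
            counts = np.bincount(types[nbrs], minlength=n_types)
            comp[i] = counts / counts.sum()
    elif mode == "knn":
        if radius_or_k is None or int(radius_or_k) < 1:
            raise ValueError("k must be >= 1")
        k = min(int(radius_or_k), n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, idx = nn.kneighbors(pts)
        for i, row in enumerate(idx):
            nbrs = row[row != i][:k]
            counts = np.bincount(types[nbrs], minlength=n_types)
            comp[i] = counts / counts.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NeighborhoodProfile(
        table["CellID"].to_numpy(), comp, isolated, mode,
        float(radius_or_k) if radius_or_k is not None else -1.0,
    )


def recurrent_neighborhoods(
    profiles: NeighborhoodProfile, n_neighborhoods: int = 4, seed: int = 0
) -> ClusterAssignment:
    """Cluster composition vectors into recurrent cellular neighborhoods (k-means)."""
    if n_neighborhoods < 1:
        raise ValueError("n_neighborhoods must be >= 1")
    x = profiles.composition
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < n_neighborhoods:
        raise ValueError(
            f"only {n_distinct} distinct composition profiles for "
            f"{n_neighborhoods} requested neighborhoods"
        )
    km = KMeans(n_clusters=n_neighborhoods, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterAssignment(
        profiles.cell_ids, labels, "recurrent-neighborhoods",
        {"n_neighborhoods": n_neighborhoods, "mode": profiles.mode}, seed,
    )


def write_annotations(
    table: pd.DataFrame,
    cell_types: ClusterAssignment,
    neighborhoods: ClusterAssignment | None,
    path: str | Path,
) -> Path:
    """Write CSV of CellID, cell_type_cluster and neighborhood_cluster.

    Every CellID in the feature table must be present in the assignments;
    a missing id raises with the offending id named.
    """
    out = pd.DataFrame({"CellID": table["CellID"]})
    for name, asn in (("cell_type_cluster", cell_types), ("neighborhood_cluster", neighborhoods)):
        if asn is None:
            continue
        s = asn.as_series()
        missing = set(out["CellID"]) - set(s.index)
        if missing:
            raise ValueError(f"assignment {name} missing CellID {sorted(missing)[0]}")
        out[name] = s.reindex(out["CellID"]).to_numpy()
    path = Path(path)
    out.to_csv(path, index=False)
    return path
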