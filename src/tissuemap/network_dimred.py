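"""Region interaction networks and dimensionality-reduction views.

The region network summarizes which tissue regions border one another: for
every ordered region pair (i, j) it records the percentage of region-i
neighborhoods that are directly in contact with (within ``contact_radius``
of) at least one region-j neighborhood.  Regions become graph nodes sized
by neighborhood count; an edge is kept when the contact percentage exceeds
a threshold (0.005% by default — deliberately permissive, so nearly any
physical contact qualifies).

Contact is evaluated between neighborhoods of the same sample.  The default
contact radius is ``1.1 * sqrt(2) * grid_spacing``, which captures the full
8-neighborhood of the raster grid while tolerating float error.

Dimensionality reductions (t-SNE, PCA, UMAP) are thin seeded wrappers over
scikit-learn / umap-learn; t-SNE defaults are fixed to Euclidean distance,
perplexity 30, Barnes-Hut angle 0.5, exaggeration 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .neighborhoods import NeighborhoodSet
from .regions import FeatureMatrix, RegionAssignment

__all__ = [
    "RegionGraph",
    "Embedding",
    "default_contact_radius",
    "region_contact_matrix",
    "build_network",
    "reduce_dimensions",
]

EDGE_THRESHOLD_PCT = 0.005

TSNE_DEFAULTS = {"perplexity": 30.0, "angle": 0.5, "early_exaggeration": 4.0}


@dataclass
class RegionGraph:
    """Directed region-contact graph.

    Node attribute ``n_neighborhoods`` carries the region size; edge
    attribute ``contact_pct`` the directed contact percentage.  The
    undirected view (edge weight = max of the two directions) is what a
    force-directed rendering would use.
    """

    graph: nx.DiGraph
    threshold_pct: float

    def undirected(self) -> nx.Graph:
        und = nx.Graph()
        und.add_nodes_from(self.graph.nodes(data=True))
        for u, v, data in self.graph.edges(data=True):
            w = data["contact_pct"]
            if und.has_edge(u, v):
                und[u][v]["contact_pct"] = max(und[u][v]["contact_pct"], w)
            else:
                und.add_edge(u, v, contact_pct=w)
        return und

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["contact_pct"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "contact_pct"])

    def node_table(self) -> pd.DataFrame:
        rows = [(n, d["n_neighborhoods"]) for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows, columns=["region", "n_neighborhoods"])


@dataclass
class Embedding:
    """A 2-D embedding of neighborhoods with its method, parameters, seed."""

    method: str
    coordinates: np.ndarray
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def default_contact_radius(nbhd: NeighborhoodSet) -> float:
    """1.1 x sqrt(2) x raster grid spacing: the grid's 8-neighborhood."""
    return 1.1 * np.sqrt(2.0) * nbhd.grid_spacing()


def region_contact_matrix(
    nbhd: NeighborhoodSet,
    assignment: RegionAssignment,
    contact_radius: float | None = None,
) -> pd.DataFrame:
    """Directed contact percentages between regions.

    Entry (i, j) is ``100 * (#region-i neighborhoods with >= 1 region-j
    neighborhood at center distance <= contact_radius, the neighborhood
    itself excluded) / (#region-i neighborhoods)``.  Self-contact (i, i) is
    defined the same way.  A region with zero neighborhoods yields a row of
    NaN.  Contacts never cross samples.
    """
    if len(assignment.region) != nbhd.n:
        if assignment.neighborhood_ids is not None:
            # the assignment covers a clustered subset (e.g. empty
            # neighborhoods dropped); restrict to the rows it labels
            nbhd = nbhd.for_mask(assignment.neighborhood_ids)
        else:
            raise ValueError("assignment must cover all neighborhoods")
    if contact_radius is None:
        contact_radius = default_contact_radius(nbhd)
    if contact_radius <= 0:
        raise ValueError("contact_radius must be > 0")

    regions = sorted(set(assignment.regions.tolist()) | set(assignment.annotations))
    reg_index = {r: i for i, r in enumerate(regions)}
    labels = np.array([reg_index[int(r)] for r in assignment.region])
    k = len(regions)

    # touching[i, j] True if neighborhood i touches >= 1 neighborhood of region j
    touching = np.zeros((nbhd.n, k), dtype=bool)
    pos = nbhd.center_positions()
    sample_ids = nbhd.sample_ids
    for sample in pd.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == sample)
        tree = cKDTree(pos[idx])
        for a, b in tree.query_pairs(r=contact_radius):
            touching[idx[a], labels[idx[b]]] = True
            touching[idx[b], labels[idx[a]]] = True

    matrix = np.full((k, k), np.nan)
    for r, i in reg_index.items():
        members = labels == i
        total = members.sum()
        if total:
            matrix[i] = 100.0 * touching[members].sum(axis=0) / total
    return pd.DataFrame(matrix, index=regions, columns=regions)


def build_network(
    contact: pd.DataFrame,
    region_sizes: dict[int, int] | pd.Series,
    threshold_pct: float = EDGE_THRESHOLD_PCT,
) -> RegionGraph:
    """Graph from a contact matrix: edge iff contact % strictly exceeds the
    threshold (default 0.005%); node size = neighborhood count."""
    g = nx.DiGraph()
    sizes = dict(region_sizes)
    for region in contact.index:
        g.add_node(region, n_neighborhoods=int(sizes.get(region, 0)))
    for i in contact.index:
        for j in contact.columns:
            pct = contact.loc[i, j]
            if np.isfinite(pct) and pct > threshold_pct:
                g.add_edge(i, j, contact_pct=float(pct))
    return RegionGraph(graph=g, threshold_pct=float(threshold_pct))


def region_sizes(assignment: RegionAssignment) -> pd.Series:
    vals, counts = np.unique(assignment.region, return_counts=True)
    return pd.Series(counts, index=vals)


def reduce_dimensions(
    features: FeatureMatrix | np.ndarray,
    method: str = "tsne",
    seed: int = 0,
    **params,
) -> Embedding:
    """Seeded 2-D embedding of neighborhood features.

    ``tsne``: Barnes-Hut with Euclidean distance, perplexity 30, angle 0.5,
    exaggeration 4 (overridable via keyword arguments); requires at least
    ``3 * perplexity + 1`` rows.  ``pca``: deterministic top-2 components.
    ``umap``: seeded with default umap-learn parameters.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    method = method.lower()
    if method == "pca":
        from sklearn.decomposition import PCA

        model = PCA(n_components=2, svd_solver="full")
        coords = model.fit_transform(X)
        used = {"n_components": 2}
    elif method == "tsne":
        from sklearn.manifold import TSNE

        opts = {**TSNE_DEFAULTS, **params}
        if len(X) < 3 * opts["perplexity"] + 1:
            raise ValueError(
                f"t-SNE with perplexity {opts['perplexity']} needs >= "
                f"{int(3 * opts['perplexity'] + 1)} rows, got {len(X)}"
            )
        model = TSNE(
            n_components=2,
            metric="euclidean",
            perplexity=opts["perplexity"],
            angle=opts["angle"],
            early_exaggeration=opts["early_exaggeration"],
            init="pca",
            random_state=seed,
        )
        coords = model.fit_transform(X)
        used = opts
    elif method == "umap":
        import umap

        opts = dict(params)
        model = umap.UMAP(n_components=2, random_state=seed, **opts)
        coords = model.fit_transform(X)
        used = opts
    else:
        raise ValueError(f"unsupported method {method!r}; choose tsne, pca, or umap")
    return Embedding(method=method, coordinates=np.asarray(coords, dtype=float), parameters=used, seed=seed)
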