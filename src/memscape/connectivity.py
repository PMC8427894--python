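"""A-priori connectivity hypotheses as planar graphs, and spatial weight matrices.

Four graph families express decreasing connectivity density over the same
sites: Delaunay triangulation (relatively unrestricted), the Gabriel graph,
and lune-based beta-skeletons (relative neighbour graphs, increasingly
restricted as beta grows). Each graph converts to a symmetric spatial
weighting matrix (SWM) for the Moran eigenvector analysis.

Boundary convention: a third site lying exactly on the exclusion disc/lune
boundary counts as a blocker (closed-region rule), with coordinates compared
at a relative tolerance of 1e-9 of the extent diagonal. This makes beta=1
coincide exactly with the Gabriel graph, including degenerate co-circular
layouts, and keeps behaviour deterministic on gridded inputs. Collinear or
otherwise degenerate inputs are never jittered silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, distance_matrix

from .datamodel import SiteTable, ValidationError

__all__ = [
    "ConnectivityGraph",
    "SpatialWeightMatrix",
    "delaunay_graph",
    "gabriel_graph",
    "relative_neighbour_graph",
    "to_weight_matrix",
    "pairwise_distances",
    "GRAPH_BUILDERS",
    "build_graph",
]

#: relative boundary tolerance, as a fraction of the extent diagonal
BOUNDARY_RTOL = 1e-9


class DegeneracyError(ValueError):
    """Point configuration unsuitable for the requested graph (e.g. collinear)."""


class DisconnectedError(ValueError):
    """Graph is not connected; names the components."""


@dataclass(frozen=True)
class ConnectivityGraph:
    """Undirected planar graph over the sites of a :class:`SiteTable`."""

    sites: SiteTable
    edges: frozenset[tuple[int, int]]  # (i, j) with i < j, site-order indices
    kind: str
    beta: float | None = None

    def __post_init__(self) -> None:
        n = self.sites.n_sites
        for i, j in self.edges:
            if not (0 <= i < j < n):
                raise ValidationError(f"bad edge ({i}, {j}) for n={n}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        n = self.sites.n_sites
        a = np.zeros((n, n))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def components(self) -> list[set[int]]:
        """Connected components by union-find."""
        parent = list(range(self.sites.n_sites))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in self.edges:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        comps: dict[int, set[int]] = {}
        for i in range(self.sites.n_sites):
            comps.setdefault(find(i), set()).add(i)
        return list(comps.values())

    @property
    def is_connected(self) -> bool:
        return len(self.components()) == 1

    def edge_frame(self):
        import pandas as pd

        ids = self.sites.site_ids
        rows = sorted(self.edges)
        return pd.DataFrame(
            {"site_a": [ids[i] for i, _ in rows], "site_b": [ids[j] for _, j in rows]}
        )


@dataclass(frozen=True)
class SpatialWeightMatrix:
    """Symmetric non-negative site-by-site weights with zero diagonal."""

    sites: SiteTable
    weights: np.ndarray
    style: str
    graph_kind: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = self.sites.n_sites
        if w.shape != (n, n):
            raise ValidationError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if np.any(np.diag(w) != 0):
            raise ValidationError("nonzero diagonal in weight matrix")
        if np.max(np.abs(w - w.T)) > 1e-12:
            raise ValidationError("weight matrix not symmetric")
        if np.any(w < 0):
            raise ValidationError("negative weights")
        if w.sum() <= 0:
            raise ValidationError("total weight must be positive")

    @property
    def total_weight(self) -> float:
        """W = sum over all ordered pairs (both triangles)."""
        return float(self.weights.sum())


def _boundary_tol(coords: np.ndarray) -> float:
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.hypot(*span))
    return BOUNDARY_RTOL * (diag if diag > 0 else 1.0)


def pairwise_distances(sites: SiteTable) -> np.ndarray:
    """Euclidean distances between all site pairs on the planar coordinates."""
    return distance_matrix(sites.coords, sites.coords)


def delaunay_graph(sites: SiteTable) -> ConnectivityGraph:
    """Edges of the Delaunay triangulation of the site coordinates."""
    coords = sites.coords
    # collinearity check: rank of centred coordinates
    centred = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=_boundary_tol(coords)) < 2:
        raise DegeneracyError("all sites are collinear; Delaunay triangulation undefined")
    tri = Delaunay(coords)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return ConnectivityGraph(sites=sites, edges=frozenset(edges), kind="delaunay")


def relative_neighbour_graph(sites: SiteTable, beta: float) -> ConnectivityGraph:
    """Lune-based beta-skeleton over the sites (beta >= 1).

    Edge (a, b) is present iff no third site falls in the closed beta-lune:
    the intersection of the two discs of radius beta*d/2 centred at
    (1 - beta/2)a + (beta/2)b and (beta/2)a + (1 - beta/2)b. beta=1 is the
    Gabriel graph; beta=2 the classical relative neighbourhood graph.
    """
    if beta < 1:
        raise ValidationError(f"beta must be >= 1, got {beta}")
    coords = sites.coords
    n = sites.n_sites
    tol = _boundary_tol(coords)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = coords[i], coords[j]
            d = float(np.hypot(*(a - b)))
            r = beta * d / 2.0
            c1 = (1 - beta / 2.0) * a + (beta / 2.0) * b
            c2 = (beta / 2.0) * a + (1 - beta / 2.0) * b
            blocked = False
            for k in range(n):
                if k in (i, j):
                    continue
                p = coords[k]
                if (
                    np.hypot(*(p - c1)) <= r + tol
                    and np.hypot(*(p - c2)) <= r + tol
                ):
                    blocked = True
                    break
            if not blocked:
                edges.add((i, j))
    kind = "gabriel" if beta == 1 else "relative_neighbour"
    return ConnectivityGraph(sites=sites, edges=frozenset(edges), kind=kind, beta=beta)


def gabriel_graph(sites: SiteTable) -> ConnectivityGraph:
    """Gabriel graph: edge (a, b) iff the closed disc with diameter ab is empty."""
    g = relative_neighbour_graph(sites, beta=1.0)
    return ConnectivityGraph(sites=g.sites, edges=g.edges, kind="gabriel", beta=1.0)


def to_weight_matrix(graph: ConnectivityGraph, style: str = "binary") -> SpatialWeightMatrix:
    """Convert a connected graph to a spatial weighting matrix.

    ``binary``: w_ij = 1 iff edge. ``row_standardised``: binary rows divided
    by their row sums, then symmetrised as (M + M^T)/2.
    """
    comps = graph.components()
    if len(comps) > 1:
        ids = graph.sites.site_ids
        named = [sorted(ids[i] for i in c) for c in comps]
        raise DisconnectedError(f"graph has {len(comps)} components: {named}")
    a = graph.adjacency()
    if style == "binary":
        w = a
    elif style == "row_standardised":
        m = a / a.sum(axis=1, keepdims=True)
        w = (m + m.T) / 2.0
    else:
        raise ValidationError(f"unknown weight style {style!r}")
    return SpatialWeightMatrix(sites=graph.sites, weights=w, style=style, graph_kind=graph.kind)


def build_graph(sites: SiteTable, kind: str, rng_betas: dict[str, float] | None = None) -> ConnectivityGraph:
    """Build one of the four study graphs by name (delaunay, gabriel, rng1, rng2)."""
    betas = {"rng1": 2.0, "rng2": 3.0}
    if rng_betas:
        betas.update(rng_betas)
    if kind == "delaunay":
        return delaunay_graph(sites)
    if kind == "gabriel":
        return gabriel_graph(sites)
    if kind in betas:
        return relative_neighbour_graph(sites, beta=betas[kind])
    raise ValidationError(f"unknown graph kind {kind!r}")


GRAPH_BUILDERS = ("delaunay", "gabriel", "rng1", "rng2")
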