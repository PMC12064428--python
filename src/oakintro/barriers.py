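"""Monmonier maximum-difference barrier detection.

Populations are joined by a Delaunay triangulation; each Delaunay edge is
crossed by one edge of the Voronoi dual, annotated with the genetic distance
of the population pair it separates. A barrier starts at the dual edge with
the maximal distance and grows from both ends, always crossing the adjacent
pair with the largest distance, until it reaches the outer boundary or
closes a loop. Support comes from locus bootstrap of the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from oakintro.diversity import pairwise_fst_nei
from oakintro.genotype_io import GenotypeMatrix, PopulationTable

__all__ = [
    "BarrierGraph",
    "Barrier",
    "build_graph",
    "monmonier",
    "extract_barriers",
    "bootstrap_support",
]


@dataclass
class RidgeEdge:
    """One Voronoi dual edge, crossing the Delaunay edge (pop_i, pop_j)."""

    v1: int
    v2: int
    pair: tuple[int, int]  # indices into pop_ids, sorted


@dataclass
class BarrierGraph:
    pop_ids: list[str]
    points: np.ndarray
    vertices: np.ndarray
    boundary: np.ndarray  # bool per vertex: on/beyond the clipping box
    ridges: list[RidgeEdge]
    D: np.ndarray
    incident: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.incident:
            for e, r in enumerate(self.ridges):
                self.incident.setdefault(r.v1, []).append(e)
                self.incident.setdefault(r.v2, []).append(e)

    def distance(self, ridge_index: int) -> float:
        i, j = self.ridges[ridge_index].pair
        return float(self.D[i, j])

    @property
    def delaunay_edges(self) -> list[tuple[int, int]]:
        return [r.pair for r in self.ridges]


def build_graph(pop_table: PopulationTable, D: np.ndarray) -> BarrierGraph:
    """Delaunay/Voronoi dual graph with genetic distances on the dual edges.

    Voronoi edges extending to infinity are clipped to a bounding box at
    3x the point-set diameter; their synthetic endpoints are flagged as
    boundary vertices, as are finite vertices that fall outside the box.
    """
    D = np.asarray(D, float)
    pts = pop_table.coords()
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 populations")
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError(
            "populations are collinear; Delaunay triangulation is degenerate "
            "(jitter the coordinates slightly to proceed)"
        )

    vor = Voronoi(pts)
    center = pts.mean(axis=0)
    diameter = float(np.ptp(pts, axis=0).max())
    reach = 3.0 * max(diameter, 1e-9)
    lo, hi = center - reach, center + reach

    verts = [np.asarray(v, float) for v in vor.vertices]
    boundary = [bool((v < lo).any() or (v > hi).any()) for v in verts]

    ridges: list[RidgeEdge] = []
    for (p1, p2), (u, w) in zip(vor.ridge_points, vor.ridge_vertices):
        pair = (int(min(p1, p2)), int(max(p1, p2)))
        if u == -1 or w == -1:
            finite = w if u == -1 else u
            # outward direction: normal of the Delaunay edge, oriented away
            # from the point-set centre (standard Voronoi clipping recipe)
            t = pts[p2] - pts[p1]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = (pts[p1] + pts[p2]) / 2
            direction = np.sign(np.dot(midpoint - center, normal)) * normal
            if not direction.any():
                direction = normal
            far = vor.vertices[finite] + direction * reach * 2
            verts.append(far)
            boundary.append(True)
            ridges.append(RidgeEdge(finite, len(verts) - 1, pair))
        else:
            ridges.append(RidgeEdge(u, w, pair))

    return BarrierGraph(
        pop_ids=list(pop_table.pop_ids),
        points=pts,
        vertices=np.asarray(verts),
        boundary=np.asarray(boundary, bool),
        ridges=ridges,
        D=D,
    )


@dataclass
class Barrier:
    """Ordered dual-edge path. ``pairs`` lists the separated population
    pairs; ``support`` (if set) is per-segment bootstrap percentage."""

    ridge_indices: list[int]
    pairs: list[tuple[int, int]]
    distances: list[float]
    non_informative: bool = False
    support: list[float] | None = None


def _best(graph: BarrierGraph, candidates) -> int | None:
    """Deterministic pick: max distance, ties by ascending pop pair."""
    best, key = None, None
    for e in candidates:
        k = (-graph.distance(e), graph.ridges[e].pair)
        if key is None or k < key:
            best, key = e, k
    return best


def monmonier(graph: BarrierGraph, excluded: frozenset[int] = frozenset()) -> Barrier:
    """Trace one maximum-difference barrier.

    Starts at the unused dual edge with the largest distance; each end then
    repeatedly crosses the adjacent unused dual edge with the largest
    distance, never revisiting a vertex except to close a loop; an end stops
    at the outer boundary or on loop closure.
    """
    available = [e for e in range(len(graph.ridges)) if e not in excluded]
    if not available:
        raise ValueError("no dual edges available")
    start = _best(graph, available)
    dists = [graph.distance(e) for e in available]
    non_informative = bool(np.isclose(min(dists), max(dists)))

    used = {start}
    r = graph.ridges[start]
    path_front: list[int] = []  # grown from v1, reversed at the end
    path_back: list[int] = [start]
    visited = {r.v1, r.v2}

    for end_vertex, store in ((r.v1, path_front), (r.v2, path_back)):
        v = end_vertex
        if graph.boundary[v]:
            continue
        while True:
            candidates = [
                e for e in graph.incident.get(v, [])
                if e not in used and e not in excluded
            ]
            if not candidates:
                break
            e = _best(graph, candidates)
            used.add(e)
            store.append(e)
            other = graph.ridges[e].v2 if graph.ridges[e].v1 == v else graph.ridges[e].v1
            if graph.boundary[other] or other in visited:
                break  # reached outer boundary or closed a loop
            visited.add(other)
            v = other

    ridge_indices = path_front[::-1] + path_back
    return Barrier(
        ridge_indices=ridge_indices,
        pairs=[graph.ridges[e].pair for e in ridge_indices],
        distances=[graph.distance(e) for e in ridge_indices],
        non_informative=non_informative,
    )


def extract_barriers(graph: BarrierGraph, m: int) -> list[Barrier]:
    """m successive barriers; each barrier's edges are masked before rerun."""
    if m < 1:
        raise ValueError("m must be >= 1")
    barriers: list[Barrier] = []
    masked: set[int] = set()
    for _ in range(m):
        if len(masked) == len(graph.ridges):
            break
        b = monmonier(graph, excluded=frozenset(masked))
        barriers.append(b)
        masked.update(b.ridge_indices)
    return barriers


def bootstrap_support(
    G: GenotypeMatrix,
    graph: BarrierGraph,
    n_boot: int = 100,
    seed: int = 0,
    n_barriers: int = 1,
    distance_fn=None,
) -> pd.DataFrame:
    """Per-dual-edge support: percentage of locus-bootstrap replicates whose
    barrier(s) cross that edge.

    Each replicate resamples loci with replacement, recomputes the distance
    matrix with the same estimator as the observed analysis (pairwise Nei
    FST by default) and reruns barrier extraction.
    """
    if distance_fn is None:
        def distance_fn(g):
            return pairwise_fst_nei(g).to_numpy()

    order = {p: i for i, p in enumerate(G.by_population())}
    perm = [order[p] for p in graph.pop_ids]

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(graph.ridges))
    for _ in range(n_boot):
        loci = rng.integers(0, G.n_loci, size=G.n_loci)
        Gb = GenotypeMatrix(
            list(G.individual_ids),
            list(G.pop_ids),
            [f"{G.loci[l]}_b{i}" for i, l in enumerate(loci)],
            G.calls[:, loci, :],
            G.missing,
        )
        Db = distance_fn(Gb)[np.ix_(perm, perm)]
        gb = BarrierGraph(
            graph.pop_ids, graph.points, graph.vertices, graph.boundary,
            graph.ridges, Db, dict(graph.incident),
        )
        edges: set[int] = set()
        for b in extract_barriers(gb, n_barriers):
            edges.update(b.ridge_indices)
        for e in edges:
            hits[e] += 1

    support = 100.0 * hits / n_boot
    return pd.DataFrame(
        {
            "ridge": np.arange(len(graph.ridges)),
            "pop_a": [graph.pop_ids[r.pair[0]] for r in graph.ridges],
            "pop_b": [graph.pop_ids[r.pair[1]] for r in graph.ridges],
            "distance": [graph.distance(e) for e in range(len(graph.ridges))],
            "support": support,
        }
    )
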