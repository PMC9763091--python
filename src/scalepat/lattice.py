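"""Polygonal scale lattices and per-pattern neighborhood bookkeeping.

A lizard's dorsal skin is a tessellation of polygonal scales; every model in
this package (cellular automaton, Lenz-Ising, discrete reaction-diffusion)
lives on such a lattice.  A :class:`ScaleLattice` stores the scale centers,
cell polygons, the symmetric adjacency relation, per-cell areas ``A_i``,
shared-edge lengths ``L_ij``, the interscale boundary width ``epsilon`` and
the mean edge length ``S`` (the hexagon edge length for a regular lattice,
which is also the quantity the logistic growth law tracks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, Voronoi
from shapely.geometry import Polygon
from shapely.ops import voronoi_diagram
from shapely import points as shapely_points

GREEN = 1
BLACK = 0

__all__ = [
    "GREEN",
    "BLACK",
    "ScaleLattice",
    "PatternState",
    "ColorState",
    "build_hex_lattice",
    "build_voronoi_lattice",
    "neighbor_stats",
    "flips_between",
    "lattice_to_json",
    "lattice_from_json",
]


@dataclass
class PatternState:
    """Per-scale binary color labels (``GREEN``/``BLACK``) at one time point."""

    states: np.ndarray  # int8, values in {GREEN, BLACK}
    time: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (GREEN, BLACK)).all():
            raise ValueError("pattern states must be GREEN (1) or BLACK (0)")

    @property
    def n_scales(self) -> int:
        return self.states.size


@dataclass
class ColorState:
    """Per-scale continuous CIELAB color (L*, a*, b*) at one time point."""

    colors: np.ndarray  # (n, 3) float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.colors = np.atleast_2d(np.asarray(self.colors, dtype=float))
        if self.colors.shape[1] != 3:
            raise ValueError("colors must be (n, 3) CIELAB triples")

    @property
    def n_scales(self) -> int:
        return self.colors.shape[0]


@dataclass
class ScaleLattice:
    """Polygonal tessellation of skin scales with geometry bookkeeping.

    ``adjacency`` is symmetric and irreflexive; ``edges`` lists each adjacent
    pair once as ``(i, j)`` with ``i < j`` and ``edge_lengths[k]`` the length
    of the shared Voronoi/hexagon edge of ``edges[k]``.
    """

    centers: np.ndarray              # (n, 2)
    polygons: list                   # list of (k, 2) vertex loops
    edges: np.ndarray                # (m, 2) int, i < j
    edge_lengths: np.ndarray         # (m,) > 0
    areas: np.ndarray                # (n,) > 0
    epsilon: float = 1.0             # interscale boundary width
    boundary: np.ndarray | None = None  # (n,) bool, True for rim scales
    _nbrs: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.edge_lengths <= 0).any():
            raise ValueError("all shared-edge lengths must be positive")
        if (self.areas <= 0).any():
            raise ValueError("all cell areas must be positive")
        if self.boundary is None:
            self.boundary = np.zeros(self.n_scales, dtype=bool)
        self._nbrs = None

    @property
    def n_scales(self) -> int:
        return self.centers.shape[0]

    @property
    def neighbors(self) -> list:
        """Neighbor index lists (sorted), built lazily from ``edges``."""
        if self._nbrs is None:
            nbrs = [[] for _ in range(self.n_scales)]
            for i, j in self.edges:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self._nbrs = [sorted(v) for v in nbrs]
        return self._nbrs

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(v) for v in self.neighbors])

    @property
    def S(self) -> float:
        """Mean shared-edge length (the hexagon edge length on a regular lattice)."""
        return float(self.edge_lengths.mean()) if self.edge_lengths.size else np.nan

    @property
    def mean_center_distance(self) -> float:
        """Mean distance between adjacent scale centers (used by scale matching)."""
        if self.edges.size == 0:
            return np.nan
        d = self.centers[self.edges[:, 0]] - self.centers[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    def laplacian_weights(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge arrays ``(i, j, L_ij)`` with both orientations, for flux sums."""
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        w = np.concatenate([self.edge_lengths, self.edge_lengths])
        return i, j, w


def build_hex_lattice(nx: int, ny: int, S: float, epsilon: float = 1.0) -> ScaleLattice:
    """Regular pointy-top hexagonal tessellation with edge length ``S``.

    Interior scales have 6 neighbors; cell areas are exactly 3√3/2 S² and all
    shared edges have length S.  Centers sit on a triangular lattice with
    neighbor-center spacing √3 S.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if S <= 0:
        raise ValueError("S must be positive")
    w = np.sqrt(3.0) * S
    centers = np.array(
        [[w * (i + 0.5 * (j % 2)), 1.5 * S * j] for j in range(ny) for i in range(nx)]
    )
    ang = np.deg2rad(90 + 60 * np.arange(6))
    hexv = S * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    polygons = [c + hexv for c in centers]
    edges, lengths = _shared_edges(polygons, scale=S)
    areas = np.full(len(centers), 1.5 * np.sqrt(3.0) * S * S)
    lat = ScaleLattice(centers, polygons, edges, lengths, areas, epsilon)
    lat.boundary = lat.degrees < 6
    return lat


def _shared_edges(polygons: list, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency via exactly shared polygon edges (vertices snapped to 1e-6·scale)."""
    seen: dict = {}
    edges, lengths = [], []
    for ci, poly in enumerate(polygons):
        k = len(poly)
        for a in range(k):
            p, q = poly[a], poly[(a + 1) % k]
            key = tuple(sorted((tuple(np.round(p / scale, 6)), tuple(np.round(q / scale, 6)))))
            if key in seen:
                cj = seen[key]
                if cj != ci:
                    edges.append((min(ci, cj), max(ci, cj)))
                    lengths.append(float(np.linalg.norm(p - q)))
            else:
                seen[key] = ci
    return np.asarray(edges, dtype=int).reshape(-1, 2), np.asarray(lengths)


def build_ring_lattice(n: int, S: float = 1.0, epsilon: float = 1.0) -> ScaleLattice:
    """Cycle of ``n`` scales (each with exactly 2 neighbors).

    A minimal topology used to validate stochastic dynamics against exact
    enumeration; cells are unit-area squares strung around a circle, edge
    lengths all equal to ``S``.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 scales")
    R = n * S / (2 * np.pi)
    ang = 2 * np.pi * np.arange(n) / n
    centers = R * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    h = 0.5 * np.sqrt(S)
    polygons = [c + np.array([[-h, -h], [h, -h], [h, h], [-h, h]]) for c in centers]
    edges = np.array([(i, (i + 1) % n) for i in range(n)])
    edges = np.sort(edges, axis=1)
    return ScaleLattice(
        centers, polygons, edges, np.full(n, float(S)), np.full(n, float(S)), epsilon
    )


def build_voronoi_lattice(
    centers: np.ndarray,
    clip_region: np.ndarray | Polygon | None = None,
    epsilon: float = 1.0,
    min_edge: float = 1e-9,
) -> ScaleLattice:
    """Voronoi tessellation of ``centers`` clipped to ``clip_region``.

    Adjacency is the Delaunay dual restricted to pairs whose clipped cells
    share a boundary segment of positive length.  ``clip_region`` defaults to
    the bounding box of the centers padded by half the median neighbor
    spacing.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape[0] < 3:
        raise ValueError("need at least 3 centers")
    uniq = np.unique(np.round(centers, 9), axis=0)
    if uniq.shape[0] != centers.shape[0]:
        raise ValueError("duplicate centers")
    if np.linalg.matrix_rank(centers - centers.mean(0)) < 2:
        raise ValueError("degenerate (collinear) centers")

    if clip_region is None:
        lo, hi = centers.min(0), centers.max(0)
        try:
            vor = Voronoi(centers)
            d = np.linalg.norm(
                centers[vor.ridge_points[:, 0]] - centers[vor.ridge_points[:, 1]], axis=1
            )
            pad = 0.5 * np.median(d)
        except Exception:
            pad = 0.05 * max(hi - lo)
        region = Polygon(
            [(lo[0] - pad, lo[1] - pad), (hi[0] + pad, lo[1] - pad),
             (hi[0] + pad, hi[1] + pad), (lo[0] - pad, hi[1] + pad)]
        )
    elif isinstance(clip_region, Polygon):
        region = clip_region
    else:
        region = Polygon(np.asarray(clip_region, dtype=float))

    from shapely.geometry import MultiPoint
    from shapely.strtree import STRtree

    cells_raw = voronoi_diagram(MultiPoint(centers), envelope=region)
    # voronoi_diagram returns cells in arbitrary order: each cell covers its generator
    cells = [None] * len(centers)
    tree = STRtree([Polygon(g) for g in cells_raw.geoms])
    pts = shapely_points(centers)
    for i in range(len(centers)):
        hits = tree.query(pts[i], predicate="intersects")
        if len(hits) == 0:
            hits = [int(tree.nearest(pts[i]))]
        cells[i] = cells_raw.geoms[int(hits[0])]
    clipped = []
    bmask = np.zeros(len(centers), dtype=bool)
    for i, cell in enumerate(cells):
        if cell is None:
            raise ValueError(f"no Voronoi cell found for center {i}")
        inter = cell.intersection(region)
        if inter.is_empty or inter.area <= 0:
            raise ValueError(f"center {i} has empty clipped cell")
        if inter.geom_type != "Polygon":
            inter = max(inter.geoms, key=lambda g: g.area)
        bmask[i] = abs(cell.area - inter.area) > 1e-12 * max(cell.area, 1.0) or \
            inter.exterior.distance(region.exterior) < 1e-9
        clipped.append(inter)

    tri = Delaunay(centers)
    cand = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            cand.add((min(i, j), max(i, j)))
    scale = np.sqrt(region.area / len(centers))
    edges, lengths = [], []
    for i, j in sorted(cand):
        shared = clipped[i].intersection(clipped[j])
        L = shared.length
        if L > min_edge * scale:
            edges.append((i, j))
            lengths.append(L)
    polygons = [np.asarray(c.exterior.coords[:-1]) for c in clipped]
    areas = np.array([c.area for c in clipped])
    return ScaleLattice(
        centers, polygons, np.asarray(edges), np.asarray(lengths), areas, epsilon, bmask
    )


def neighbor_stats(
    lattice: ScaleLattice, pattern: PatternState, include_boundary: bool = True
) -> np.ndarray:
    """Counts ``n(S, i)`` of scales in each nearest-neighbor configuration.

    Returns a (2, 8) table: row index is the scale state (``BLACK`` = 0,
    ``GREEN`` = 1), column ``i`` the number of isochromatic neighbors, capped
    at 7 so that irregular lattices with 8+ neighbors still fall in the 16
    configurations.  With ``include_boundary=False``, rim scales are dropped
    from the counts (their reduced neighborhoods are otherwise used as-is).
    """
    s = pattern.states
    if s.size != lattice.n_scales:
        raise ValueError("pattern size does not match lattice")
    counts = np.zeros((2, 8), dtype=int)
    nbrs = lattice.neighbors
    for idx in range(lattice.n_scales):
        if not include_boundary and lattice.boundary[idx]:
            continue
        iso = int(sum(s[j] == s[idx] for j in nbrs[idx]))
        counts[s[idx], min(iso, 7)] += 1
    return counts


def flips_between(p1: PatternState, p2: PatternState) -> int:
    """Number of scales whose binary label differs between two patterns."""
    if p1.n_scales != p2.n_scales:
        raise ValueError("patterns live on different lattices")
    return int(np.count_nonzero(p1.states != p2.states))


def lattice_to_json(lattice: ScaleLattice, path: str | None = None) -> str:
    """Serialize a lattice (geometry is unit-agnostic; units documented per file)."""
    obj = {
        "centers": lattice.centers.tolist(),
        "polygons": [np.asarray(p).tolist() for p in lattice.polygons],
        "edges": lattice.edges.tolist(),
        "edge_lengths": lattice.edge_lengths.tolist(),
        "areas": lattice.areas.tolist(),
        "epsilon": lattice.epsilon,
        "boundary": lattice.boundary.astype(int).tolist(),
    }
    text = json.dumps(obj)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def lattice_from_json(source: str) -> ScaleLattice:
    """Inverse of :func:`lattice_to_json`; accepts a path or a JSON string."""
    if source.lstrip().startswith("{"):
        obj = json.loads(source)
    else:
        with open(source) as fh:
            obj = json.load(fh)
    return ScaleLattice(
        np.asarray(obj["centers"]),
        [np.asarray(p) for p in obj["polygons"]],
        np.asarray(obj["edges"]),
        np.asarray(obj["edge_lengths"]),
        np.asarray(obj["areas"]),
        float(obj["epsilon"]),
        np.asarray(obj["boundary"], dtype=bool),
    )
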