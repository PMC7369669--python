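"""Perforated square domain and its triangulation.

The computational domain is a square sheet of homogenized cortical tissue
perforated by small circular holes standing for the arteriolar ends
("inlets", oxygen supply) and venular ends ("outlets", drainage) of the
capillary network.  Hole coordinates are generated deterministically: the
default layout places them on a checkerboard grid whose spacing (0.225 mm
for the default 1.8 mm square with 64 holes) matches the physiological mean
inlet-outlet separation of ~0.25 mm.

Meshing strategy: a structured grid of points at the edge-segment spacing is
combined with the polygonalized hole boundaries, triangulated with Delaunay,
and the triangles falling inside holes are discarded.  Each hole is an
n-gon whose vertices sit at the *area-preserving* radius
``r*sqrt(2*pi/(n*sin(2*pi/n)))`` by default, so the triangulated area equals
the true domain area ``side**2 - sum(pi*r**2)`` to rounding; an "inscribed"
mode (vertices exactly on the circle) is available for convergence studies
of the polygonalization error.

Boundary edges are tagged ``1`` (outer edge), ``2`` (inlet), ``3`` (outlet).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely import contains_xy
from shapely.geometry import Polygon

__all__ = [
    "GeometryError",
    "Hole",
    "PerforatedDomain",
    "Mesh",
    "build_domain",
    "triangulate",
    "TAG_EDGE",
    "TAG_INLET",
    "TAG_OUTLET",
]

TAG_EDGE = 1
TAG_INLET = 2
TAG_OUTLET = 3
TAG_BY_CLASS = {"edge": TAG_EDGE, "inlet": TAG_INLET, "outlet": TAG_OUTLET}


class GeometryError(RuntimeError):
    """Invalid or degenerate geometry (overlapping holes, failed meshing)."""


@dataclass(frozen=True)
class Hole:
    x: float
    y: float
    radius: float
    kind: str  # "inlet" or "outlet"

    def __post_init__(self) -> None:
        if self.kind not in ("inlet", "outlet"):
            raise GeometryError(f"unknown hole kind {self.kind!r}")
        if self.radius <= 0:
            raise GeometryError("hole radius must be > 0")


@dataclass(frozen=True)
class PerforatedDomain:
    """A square of side ``side`` mm with circular holes.

    ``area`` is the fluid/tissue area: ``side**2 - sum(pi r**2)``.
    """

    side: float
    holes: tuple[Hole, ...]

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise GeometryError("side must be > 0")
        for i, h in enumerate(self.holes):
            # strictly inside with clearance of one radius to the outer edge
            if (h.x - 2 * h.radius < 0 or h.x + 2 * h.radius > self.side
                    or h.y - 2 * h.radius < 0 or h.y + 2 * h.radius > self.side):
                raise GeometryError(
                    f"hole {i} too close to the square boundary")
        for i, hi in enumerate(self.holes):
            for j in range(i + 1, len(self.holes)):
                hj = self.holes[j]
                d = math.hypot(hi.x - hj.x, hi.y - hj.y)
                # disjoint with clearance of one radius between rims
                if d < hi.radius + hj.radius + max(hi.radius, hj.radius):
                    raise GeometryError(f"holes {i} and {j} overlap or touch")

    @property
    def area(self) -> float:
        return self.side ** 2 - sum(math.pi * h.radius ** 2 for h in self.holes)

    def counts(self) -> dict[str, int]:
        return {k: sum(1 for h in self.holes if h.kind == k)
                for k in ("inlet", "outlet")}

    def summary_json(self) -> str:
        """Domain summary (hole table) as a JSON string."""
        return json.dumps({
            "side_mm": self.side,
            "area_mm2": self.area,
            "counts": self.counts(),
            "holes": [{"x": h.x, "y": h.y, "radius": h.radius, "kind": h.kind}
                      for h in self.holes],
        }, indent=2)


def build_domain(side: float = 1.8, n_inlets: int = 32, n_outlets: int = 32,
                 hole_radius: float = 0.03, layout: str = "checkerboard",
                 seed: int = 0, jitter: float = 0.25) -> PerforatedDomain:
    """Deterministically place inlets and outlets on the square.

    ``checkerboard`` puts the ``n_inlets + n_outlets`` holes on a uniform
    k-by-k grid (centers at ``((i+1/2)*side/k, (j+1/2)*side/k)``) with the
    class alternating by parity, so nearest neighbours always pair an inlet
    with an outlet.  ``jittered`` perturbs each center by up to
    ``jitter * spacing/2`` with a seeded RNG, to probe layout sensitivity.
    """
    n_total = n_inlets + n_outlets
    if n_total == 0:
        return PerforatedDomain(side=side, holes=())
    k = round(math.sqrt(n_total))
    if k * k != n_total:
        raise GeometryError(
            f"grid layouts need a square hole count, got {n_total}")
    if layout not in ("checkerboard", "jittered"):
        raise GeometryError(f"unknown layout {layout!r}")
    spacing = side / k
    centers = []
    kinds = []
    for j in range(k):
        for i in range(k):
            centers.append(((i + 0.5) * spacing, (j + 0.5) * spacing))
            kinds.append("inlet" if (i + j) % 2 == 0 else "outlet")
    got_in = kinds.count("inlet")
    if got_in != n_inlets or n_total - got_in != n_outlets:
        raise GeometryError(
            f"checkerboard grid yields {got_in} inlets, {n_total - got_in} "
            f"outlets; cannot honor {n_inlets}+{n_outlets}")
    if layout == "jittered":
        rng = np.random.default_rng(seed)
        amp = jitter * spacing / 2.0
        centers = [(x + rng.uniform(-amp, amp), y + rng.uniform(-amp, amp))
                   for x, y in centers]
    holes = tuple(Hole(x, y, hole_radius, kind)
                  for (x, y), kind in zip(centers, kinds))
    return PerforatedDomain(side=side, holes=holes)


@dataclass
class Mesh:
    """Conforming triangulation with tagged boundary edges.

    ``vertices``: (N, 2) coordinates in mm; ``triangles``: (M, 3) vertex
    indices with positive orientation; ``boundary_edges``: (B, 2) vertex
    index pairs; ``boundary_tags``: (B,) integer tags (1 edge, 2 inlet,
    3 outlet).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_tags: np.ndarray
    domain: PerforatedDomain | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def triangle_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            p = self.vertices[self.triangles]
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            self._cache["areas"] = 0.5 * (d1[:, 0] * d2[:, 1]
                                          - d1[:, 1] * d2[:, 0])
        return self._cache["areas"]

    def boundary_lengths(self) -> np.ndarray:
        e = self.vertices[self.boundary_edges]
        return np.linalg.norm(e[:, 1] - e[:, 0], axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())


def _polygon_radius(radius: float, n: int, mode: str) -> float:
    if mode == "inscribed":
        return radius
    if mode == "area":
        return radius * math.sqrt(2 * math.pi / (n * math.sin(2 * math.pi / n)))
    raise GeometryError(f"unknown polygon mode {mode!r}")


def _hole_polygon(h: Hole, n: int, mode: str) -> np.ndarray:
    rp = _polygon_radius(h.radius, n, mode)
    # half-step angular offset: generic position w.r.t. the structured grid
    ang = math.pi / n + 2 * math.pi * np.arange(n) / n
    return np.column_stack([h.x + rp * np.cos(ang), h.y + rp * np.sin(ang)])


def triangulate(d: PerforatedDomain, n_edge_segments: int = 60,
                n_hole_segments: int = 8,
                polygon_mode: str = "area") -> Mesh:
    """Triangulate the perforated square.

    The outer boundary is split into ``n_edge_segments`` per side and every
    hole into ``n_hole_segments``; the interior is filled with a structured
    point cloud at the edge spacing and Delaunay-triangulated.  Raises
    :class:`GeometryError` if the triangulation does not conform to the
    requested boundary partition.
    """
    if n_edge_segments < 1:
        raise GeometryError("n_edge_segments must be >= 1")
    if n_hole_segments < 3:
        raise GeometryError("n_hole_segments must be >= 3")
    side = d.side
    h = side / n_edge_segments

    ax = np.linspace(0.0, side, n_edge_segments + 1)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    polys = [_hole_polygon(hole, n_hole_segments, polygon_mode)
             for hole in d.holes]
    if polys:
        centers = np.array([[hole.x, hole.y] for hole in d.holes])
        rp = np.array([_polygon_radius(hole.radius, n_hole_segments,
                                       polygon_mode) for hole in d.holes])
        s_poly = 2 * rp * np.sin(math.pi / n_hole_segments)
        clear = rp + 0.45 * np.minimum(h, s_poly)
        dist = np.linalg.norm(grid[:, None, :] - centers[None, :, :], axis=2)
        keep = np.all(dist > clear[None, :], axis=1)
        grid = grid[keep]
        hole_pts = np.vstack(polys + [centers])
        points = np.vstack([grid, hole_pts])
    else:
        points = grid

    tri = Delaunay(points)
    simplices = tri.simplices
    cent = points[simplices].mean(axis=1)

    inside = np.zeros(len(simplices), dtype=bool)
    for hole, poly in zip(d.holes, polys):
        near = (np.linalg.norm(cent - [hole.x, hole.y], axis=1)
                <= 1.2 * max(np.linalg.norm(poly - [hole.x, hole.y], axis=1)))
        if near.any():
            inside[near] |= contains_xy(Polygon(poly), cent[near, 0],
                                        cent[near, 1])
    simplices = simplices[~inside]

    # drop degenerate slivers (qhull can emit zero-area triangles on the
    # collinear outer boundary); tolerance is far below any real element
    p = points[simplices]
    areas2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    simplices = simplices[np.abs(areas2) > 1e-12 * h * h]

    # consistent positive orientation
    p = points[simplices]
    areas2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = areas2 < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    # remove unused vertices (hole centers) and reindex
    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    vertices = points[used]
    triangles = remap[simplices]

    edges, tags = _extract_boundary(vertices, triangles, d, polys,
                                    n_edge_segments, n_hole_segments)
    return Mesh(vertices=vertices, triangles=triangles, boundary_edges=edges,
                boundary_tags=tags, domain=d)


def _extract_boundary(vertices, triangles, d, polys, n_edge_segments,
                      n_hole_segments):
    all_edges = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                           triangles[:, [2, 0]]])
    key = np.sort(all_edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if (counts > 2).any():
        raise GeometryError("non-manifold edge in triangulation")

    tol = 1e-9 * d.side
    mids = vertices[bedges].mean(axis=1)
    tags = np.zeros(len(bedges), dtype=np.int64)
    on_square = ((np.abs(mids[:, 0]) < tol)
                 | (np.abs(mids[:, 0] - d.side) < tol)
                 | (np.abs(mids[:, 1]) < tol)
                 | (np.abs(mids[:, 1] - d.side) < tol))
    tags[on_square] = TAG_EDGE
    for idx, (hole, poly) in enumerate(zip(d.holes, polys)):
        rmax = np.max(np.linalg.norm(poly - [hole.x, hole.y], axis=1))
        near = np.linalg.norm(mids - [hole.x, hole.y], axis=1) <= rmax + tol
        near &= ~on_square
        if near.sum() != n_hole_segments:
            raise GeometryError(
                f"hole {idx}: expected {n_hole_segments} boundary segments, "
                f"found {int(near.sum())} (degenerate triangulation)")
        if (tags[near] != 0).any():
            raise GeometryError(f"hole {idx}: boundary tags overlap")
        tags[near] = TAG_BY_CLASS[hole.kind]
    if (tags == 0).any():
        raise GeometryError("untagged boundary edges remain")
    n_square = int(on_square.sum())
    if n_square != 4 * n_edge_segments:
        raise GeometryError(
            f"outer boundary has {n_square} segments, expected "
            f"{4 * n_edge_segments}")
    return bedges, tags
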