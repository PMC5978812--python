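"""Initial network generation.

Disordered monolayers start from a Matérn type-II hard-core point process
(so no two seed points are closer than a hardcore radius under the periodic
metric) tessellated by a periodic Voronoi diagram.  Regular fixtures — exact
N-gons and periodic honeycomb lattices — support the closed-form results and
the property tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .geometry import TissueNetwork, _as_box, polygon_area, validate_network

__all__ = [
    "SeedPointSet",
    "matern_ii_points",
    "voronoi_network",
    "network_from_polygons",
    "hexagonal_lattice",
    "regular_ngon",
    "default_hardcore_radius",
]


@dataclass(frozen=True)
class SeedPointSet:
    """Hard-core seed points for the Voronoi initial condition."""

    points: np.ndarray          # (N,2) in [0, box)
    box: np.ndarray
    hardcore_radius: float
    seed: int


def default_hardcore_radius(box, n_target: int) -> float:
    """Default inhibition radius: 60% of the mean point spacing scale
    sqrt(box_area / (pi n)).  Strong enough to suppress sliver cells,
    weak enough that Matérn-II thinning stays feasible."""
    b = _as_box(box)
    return 0.6 * np.sqrt(b[0] * b[1] / (np.pi * n_target))


def matern_ii_points(box, n_target: int, hardcore_radius: float | None = None,
                     seed: int = 0) -> SeedPointSet:
    """Matérn type-II hard-core sample of exactly ``n_target`` points.

    A Poisson number of proposal points is scattered uniformly; each carries
    a uniform mark, and a point is deleted if any other proposal within the
    hardcore radius (periodic metric) has a smaller mark.  The proposal
    intensity is raised until at least ``n_target`` points survive, then a
    random subset of exactly ``n_target`` survivors is kept.
    """
    b = _as_box(box)
    area = b[0] * b[1]
    if hardcore_radius is None:
        hardcore_radius = default_hardcore_radius(b, n_target)
    r = float(hardcore_radius)
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target * np.pi * r**2 > 0.5 * area:
        raise ValueError(
            f"infeasible packing: n*pi*r^2 = {n_target * np.pi * r**2:.3g} "
            f"exceeds half the box area {0.5 * area:.3g}"
        )
    rng = np.random.default_rng(seed)
    intensity = 2.0 * n_target / area
    for _ in range(40):
        n_prop = rng.poisson(intensity * area)
        pts = rng.uniform(0.0, 1.0, size=(n_prop, 2)) * b
        marks = rng.uniform(size=n_prop)
        if n_prop == 0:
            intensity *= 2.0
            continue
        tree = cKDTree(pts, boxsize=b)
        keep = np.ones(n_prop, dtype=bool)
        for i, k in tree.query_pairs(r):
            # delete the point whose neighbour carries the smaller mark
            if marks[i] < marks[k]:
                keep[k] = False
            else:
                keep[i] = False
        survivors = pts[keep]
        if survivors.shape[0] >= n_target:
            idx = rng.choice(survivors.shape[0], size=n_target, replace=False)
            chosen = survivors[np.sort(idx)]
            return SeedPointSet(points=chosen, box=b, hardcore_radius=r,
                                seed=seed)
        intensity *= 2.0
    raise RuntimeError(
        "Matérn-II thinning failed to reach the target count; the hardcore "
        "radius is too large for this box"
    )


# ---------------------------------------------------------------------------
# polygon soup -> periodic network
# ---------------------------------------------------------------------------

def network_from_polygons(polygons: list[np.ndarray], box,
                          merge_tol: float | None = None) -> TissueNetwork:
    """Assemble a periodic :class:`TissueNetwork` from unwrapped polygons.

    Vertices are canonicalised modulo the box and merged when closer than
    ``merge_tol`` under the periodic metric (union-find over KD-tree pairs).
    """
    b = _as_box(box)
    if merge_tol is None:
        merge_tol = 1e-9 * float(min(b))
    coords = np.concatenate([np.asarray(p, dtype=float) for p in polygons])
    offsets = np.floor(coords / b).astype(np.intp)
    canon = coords - offsets * b
    # guard against canon == box from floating roundoff
    over = canon >= b
    canon[over] -= np.broadcast_to(b, canon.shape)[over]
    offsets[over] += 1
    canon = np.clip(canon, 0.0, np.nextafter(b, 0.0))

    tree = cKDTree(canon, boxsize=b)
    parent = np.arange(canon.shape[0])

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, k in tree.query_pairs(merge_tol):
        ri, rk = find(i), find(k)
        if ri != rk:
            parent[max(ri, rk)] = min(ri, rk)
    roots = np.array([find(i) for i in range(canon.shape[0])])
    uniq, inv = np.unique(roots, return_inverse=True)
    vertices = canon[uniq]

    cell_vertices, cell_offsets = [], []
    pos = 0
    for p in polygons:
        z = np.asarray(p).shape[0]
        ids = inv[pos:pos + z]
        # recompute offsets against the representative canonical position
        off = np.rint((coords[pos:pos + z] - vertices[ids]) / b).astype(np.intp)
        cell_vertices.append(ids.astype(np.intp))
        cell_offsets.append(off)
        pos += z
    return TissueNetwork(box=b, vertices=vertices,
                         cell_vertices=cell_vertices,
                         cell_offsets=cell_offsets,
                         periodic=True).normalize_orientation()


def voronoi_network(points: SeedPointSet | np.ndarray, box=None,
                    max_retries: int = 3) -> TissueNetwork:
    """Periodic Voronoi tessellation of seed points.

    The point set is tiled 3x3, the planar Voronoi diagram is computed, the
    central-copy cells are extracted, and their vertices are re-identified
    across the periodic boundary.  Cocircular degeneracies (vertices of
    valence > 3) are resolved by a tiny position perturbation and retry.
    """
    if isinstance(points, SeedPointSet):
        pts = points.points
        b = points.box if box is None else _as_box(box)
    else:
        pts = np.asarray(points, dtype=float)
        if box is None:
            raise ValueError("box required when passing a bare point array")
        b = _as_box(box)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")

    rng = np.random.default_rng(12345)
    work = pts.copy()
    for attempt in range(max_retries + 1):
        shifts = np.array([[ox, oy] for ox in (-1, 0, 1) for oy in (-1, 0, 1)])
        tiled = np.concatenate([work + s * b for s in shifts])
        central0 = 4 * n  # shift (0,0) block starts at index 4*n
        vor = Voronoi(tiled)
        polygons = []
        open_region = False
        for i in range(central0, central0 + n):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 3:
                open_region = True
                break
            poly = vor.vertices[region]
            if polygon_area(poly) < 0:
                poly = poly[::-1]
            polygons.append(poly)
        if not open_region:
            net = network_from_polygons(polygons, b)
            report = validate_network(net)
            if report.ok:
                net.meta["voronoi_retries"] = attempt
                return net
        # degeneracy (or open central region): nudge and retry, escalating
        # the perturbation well past the vertex-merge tolerance
        warnings.warn(
            "degenerate Voronoi configuration; perturbing points and retrying",
            stacklevel=2,
        )
        scale = 10.0 ** attempt * 1e-6 * float(min(b))
        work = (pts + rng.normal(scale=scale, size=pts.shape)) % b
    raise RuntimeError("could not build a valid periodic Voronoi network")


# ---------------------------------------------------------------------------
# regular fixtures
# ---------------------------------------------------------------------------

def regular_ngon(n: int, area: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """Anticlockwise regular N-gon of given area centred at the origin.

    A regular N-gon with circumradius r has area (N/2) r^2 sin(2 pi / N);
    the perimeter then satisfies L = mu_N sqrt(A) with
    mu_N = 2 (N tan(pi/N))^{1/2}.
    """
    if n < 3:
        raise ValueError("polygon needs n >= 3")
    if area <= 0:
        raise ValueError("area must be positive")
    r = np.sqrt(2.0 * area / (n * np.sin(2.0 * np.pi / n)))
    theta = phase + 2.0 * np.pi * np.arange(n) / n
    return r * np.column_stack([np.cos(theta), np.sin(theta)])


def hexagonal_lattice(a_cell: float = 1.0, n_x: int = 4, n_y: int = 4) -> TissueNetwork:
    """Periodic honeycomb of identical regular hexagons of area ``a_cell``.

    ``n_y`` must be even for the staggered rows to close periodically.  The
    box is rectangular: (n_x * sqrt(3) s, n_y * 1.5 s) for side length s.
    """
    if n_y % 2:
        raise ValueError("n_y must be even for periodic closure")
    if n_x < 2 or n_y < 2:
        raise ValueError("need at least 2x2 hexagons")
    s = np.sqrt(2.0 * a_cell / (3.0 * np.sqrt(3.0)))
    dx = np.sqrt(3.0) * s
    dy = 1.5 * s
    box = np.array([n_x * dx, n_y * dy])
    # pointy-top hexagon template (anticlockwise, starting at the top vertex)
    ang = np.deg2rad([90, 150, 210, 270, 330, 30])
    template = s * np.column_stack([np.cos(ang), np.sin(ang)])
    polygons = []
    for jy in range(n_y):
        for jx in range(n_x):
            c = np.array([jx * dx + (jy % 2) * dx / 2.0, jy * dy])
            polygons.append(c + template)
    net = network_from_polygons(polygons, box, merge_tol=1e-6 * s)
    return net
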