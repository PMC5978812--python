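"""Polygonal cell-network geometry.

An epithelial monolayer is represented as a planar network of vertices joined
by straight edges bounding polygonal cells.  In periodic mode the network
lives on a torus: vertex positions are stored canonically inside the box and
each (cell, vertex) incidence carries an integer image offset so that every
cell unwraps to a contiguous simple polygon.  Per-cell geometry (area,
perimeter, centroid, shape tensor, circularity) is always computed on the
unwrapped polygon.

Conventions
-----------
* Cell cycles are anticlockwise, so the shoelace signed area is positive.
* The cell "centroid" is the arithmetic mean of its vertices (not the area
  centroid), so centred vertex vectors sum to zero; the shape tensor is the
  second moment of those centred vectors.
* In periodic mode every vertex is a trijunction: it appears in exactly
  three cell cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueNetwork",
    "CellGeometry",
    "FlatTopology",
    "polygon_area",
    "polygon_perimeter",
    "cell_shape",
    "build_incidence",
    "validate_network",
    "network_edges",
]

#: Relative eigenvalue gap below which a shape/stress tensor is treated as
#: isotropic (principal axis undefined).
ISOTROPY_RTOL = 1e-6


class DegeneratePolygonError(ValueError):
    """Raised for polygons with fewer than 3 vertices."""


class TopologyError(ValueError):
    """Raised when a network violates the trijunction/closure structure."""


# ---------------------------------------------------------------------------
# plain-polygon operations
# ---------------------------------------------------------------------------

def polygon_area(vertices: np.ndarray) -> float:
    """Signed (shoelace) area of a polygon.

    Positive for anticlockwise traversal; a negative value signals an
    orientation violation rather than being silently corrected.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise DegeneratePolygonError(
            f"polygon needs >=3 planar vertices, got shape {v.shape}"
        )
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


def polygon_perimeter(vertices: np.ndarray) -> tuple[np.ndarray, float]:
    """Edge lengths ``l^i`` and perimeter ``L`` of a polygon.

    Tangents are ``t^i = R^{i+1} - R^i`` with cyclic closure.  Coincident
    consecutive vertices produce a zero-length-edge warning (unit tangents
    for such edges are undefined downstream).
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        raise DegeneratePolygonError("polygon needs >=3 vertices")
    t = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(t[:, 0], t[:, 1])
    if np.any(lengths == 0.0):
        warnings.warn("polygon has zero-length edge(s)", stacklevel=2)
    return lengths, float(lengths.sum())


@dataclass(frozen=True)
class CellGeometry:
    """Geometric state of one polygonal cell.

    ``shape_tensor`` is S = (1/Z) sum_i R^i (x) R^i over vertex vectors R^i
    measured from the vertex mean; its ordered eigenvalues (lambda1 >=
    lambda2) define the principal axes of shape and the circularity
    C = lambda2/lambda1 in (0, 1].
    """

    vertices: np.ndarray          # (Z,2) unwrapped, as passed in
    area: float
    edge_lengths: np.ndarray
    perimeter: float
    centroid: np.ndarray          # arithmetic mean of vertices
    shape_tensor: np.ndarray      # (2,2) symmetric
    eigenvalues: tuple[float, float]   # (lambda1, lambda2), lambda1 >= lambda2
    major_axis: np.ndarray        # unit eigenvector of lambda1
    circularity: float
    n_sides: int
    degenerate: bool = False      # collinear polygon (lambda2 == 0)

    @property
    def polygonal_class(self) -> int:
        return self.n_sides

    @property
    def centered_vertices(self) -> np.ndarray:
        return self.vertices - self.centroid

    @property
    def is_isotropic(self) -> bool:
        l1, l2 = self.eigenvalues
        return (l1 - l2) <= ISOTROPY_RTOL * max(l1, 1e-300)

    @property
    def major_axis_angle(self) -> float:
        """Orientation of the shape major axis in [0, pi)."""
        return float(np.arctan2(self.major_axis[1], self.major_axis[0]) % np.pi)


def cell_shape(vertices: np.ndarray) -> CellGeometry:
    """Full geometric characterisation of a single (simple) polygon."""
    v = np.asarray(vertices, dtype=float)
    area = polygon_area(v)
    lengths, perim = polygon_perimeter(v)
    centroid = v.mean(axis=0)
    r = v - centroid
    s = (r.T @ r) / v.shape[0]
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)   # ascending
    l1, l2 = float(evals[1]), float(evals[0])
    major = evecs[:, 1]
    degenerate = l2 <= 0.0 or not np.isfinite(l2)
    circ = 0.0 if (degenerate or l1 <= 0.0) else l2 / l1
    return CellGeometry(
        vertices=v,
        area=area,
        edge_lengths=lengths,
        perimeter=perim,
        centroid=centroid,
        shape_tensor=s,
        eigenvalues=(l1, l2),
        major_axis=major,
        circularity=float(circ),
        n_sides=v.shape[0],
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# the tissue network
# ---------------------------------------------------------------------------

def _as_box(box) -> np.ndarray:
    b = np.atleast_1d(np.asarray(box, dtype=float))
    if b.size == 1:
        b = np.array([b[0], b[0]])
    if b.size != 2 or np.any(b <= 0):
        raise ValueError("box must be a positive scalar or pair of lengths")
    return b


@dataclass
class TissueNetwork:
    """Periodic (or finite-patch) polygonal cell network.

    Parameters
    ----------
    box : (2,) array
        Side lengths of the periodic domain (a square box is the common
        case; the honeycomb fixture and shear experiments use a rectangle).
    vertices : (Nv, 2) array
        Canonical vertex positions, each in ``[0, box)`` in periodic mode.
    cell_vertices, cell_offsets : lists
        Per cell, an anticlockwise cycle of vertex ids and the matching
        integer image offsets; vertex i of cell alpha unwraps to
        ``vertices[id] + offset * box``.
    """

    box: np.ndarray
    vertices: np.ndarray
    cell_vertices: list[np.ndarray]
    cell_offsets: list[np.ndarray]
    periodic: bool = True
    peripheral_vertices: frozenset = field(default_factory=frozenset)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.box = _as_box(self.box)
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.cell_vertices = [np.asarray(c, dtype=np.intp).ravel()
                              for c in self.cell_vertices]
        self.cell_offsets = [np.asarray(o, dtype=np.intp).reshape(-1, 2)
                             for o in self.cell_offsets]
        for c, o in zip(self.cell_vertices, self.cell_offsets):
            if c.size < 3:
                raise DegeneratePolygonError("cell cycle with <3 vertices")
            if c.size != o.shape[0]:
                raise ValueError("cell vertex/offset length mismatch")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_vertices)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def box_length(self) -> float:
        """Side of the box; raises if the box is not square."""
        if not np.isclose(self.box[0], self.box[1]):
            raise ValueError("box is not square; use .box")
        return float(self.box[0])

    @property
    def box_area(self) -> float:
        return float(self.box[0] * self.box[1])

    def cell_polygon(self, alpha: int) -> np.ndarray:
        """Unwrapped (contiguous) polygon of cell ``alpha``."""
        return (self.vertices[self.cell_vertices[alpha]]
                + self.cell_offsets[alpha] * self.box)

    def cell_geometry(self, alpha: int) -> CellGeometry:
        return cell_shape(self.cell_polygon(alpha))

    def cell_geometries(self) -> list[CellGeometry]:
        return [self.cell_geometry(a) for a in range(self.n_cells)]

    def polygonal_classes(self) -> np.ndarray:
        return np.array([c.size for c in self.cell_vertices])

    def normalize_orientation(self) -> "TissueNetwork":
        """Reverse any clockwise cell cycles (warns; used at construction
        from external data, never during relaxation where a transiently
        inverted cell must keep its cycle for the T2 machinery)."""
        flipped = 0
        for a in range(self.n_cells):
            if polygon_area(self.cell_polygon(a)) < 0:
                self.cell_vertices[a] = self.cell_vertices[a][::-1].copy()
                self.cell_offsets[a] = self.cell_offsets[a][::-1].copy()
                flipped += 1
        if flipped:
            warnings.warn(f"reversed {flipped} clockwise cell cycle(s)",
                          stacklevel=2)
        return self

    def copy(self) -> "TissueNetwork":
        return TissueNetwork(
            box=self.box.copy(),
            vertices=self.vertices.copy(),
            cell_vertices=[c.copy() for c in self.cell_vertices],
            cell_offsets=[o.copy() for o in self.cell_offsets],
            periodic=self.periodic,
            peripheral_vertices=self.peripheral_vertices,
            meta=dict(self.meta),
        )

    def with_positions(self, vertices: np.ndarray,
                       box: np.ndarray | None = None) -> "TissueNetwork":
        net = self.copy()
        net.vertices = np.asarray(vertices, dtype=float).reshape(-1, 2)
        if box is not None:
            net.box = _as_box(box)
        return net

    def canonicalize(self) -> "TissueNetwork":
        """Wrap vertex positions into [0, box), adjusting cell offsets."""
        if not self.periodic:
            return self
        shift = np.floor(self.vertices / self.box).astype(np.intp)
        if not shift.any():
            return self
        self.vertices = self.vertices - shift * self.box
        for a in range(self.n_cells):
            self.cell_offsets[a] = self.cell_offsets[a] + shift[self.cell_vertices[a]]
        return self


# ---------------------------------------------------------------------------
# incidence / flat topology
# ---------------------------------------------------------------------------

def build_incidence(network: TissueNetwork) -> dict[int, list[tuple[int, int]]]:
    """Map each global vertex j to its incidences [(cell alpha, local i), ...].

    This realises the sparse cell-vertex incidence indicator: entry (alpha, i)
    is present exactly when local vertex i of cell alpha is global vertex j.
    In a periodic network every vertex must be a trijunction (3 entries).
    """
    inc: dict[int, list[tuple[int, int]]] = {j: [] for j in range(network.n_vertices)}
    for a, cyc in enumerate(network.cell_vertices):
        for i, j in enumerate(cyc):
            inc[int(j)].append((a, i))
    if network.periodic:
        bad = [j for j, lst in inc.items() if len(lst) != 3]
        if bad:
            raise TopologyError(
                f"{len(bad)} vertex(es) are not trijunctions, e.g. vertex "
                f"{bad[0]} with {len(inc[bad[0]])} incident cells"
            )
    return inc


def network_edges(network: TissueNetwork) -> dict:
    """Enumerate undirected edges.

    Returns a dict keyed by an edge key ``(j_min, j_max, wrap)`` (``wrap``
    disambiguates distinct periodic images joining the same vertex pair),
    with values ``[(cell, local_index), ...]`` — the directed half-edges.
    In a periodic trijunction network every edge has exactly two half-edges.
    """
    edges: dict = {}
    for a, (cyc, off) in enumerate(zip(network.cell_vertices, network.cell_offsets)):
        z = cyc.size
        for i in range(z):
            j1, j2 = int(cyc[i]), int(cyc[(i + 1) % z])
            d = off[(i + 1) % z] - off[i]
            if (j1, tuple(d)) < (j2, tuple(-d)):
                key = (j1, j2, tuple(d))
            else:
                key = (j2, j1, tuple(-d))
            edges.setdefault(key, []).append((a, i))
    return edges


@dataclass(frozen=True)
class FlatTopology:
    """Flattened corner arrays for vectorised geometry/mechanics.

    One "corner" is one (cell, local vertex) incidence.  ``nxt``/``prv``
    index the cyclic successor and predecessor corner within the same cell.
    """

    corner_cell: np.ndarray     # (M,) cell id per corner
    corner_vertex: np.ndarray   # (M,) global vertex id per corner
    corner_offset: np.ndarray   # (M,2) integer image offset per corner
    nxt: np.ndarray             # (M,)
    prv: np.ndarray             # (M,)
    n_cells: int
    n_vertices: int
    cell_sizes: np.ndarray      # (Nc,)
    cell_start: np.ndarray      # (Nc,) first corner index of each cell

    @classmethod
    def from_network(cls, network: TissueNetwork) -> "FlatTopology":
        cc, cv, co, nxt, prv, starts = [], [], [], [], [], []
        pos = 0
        for a, (cyc, off) in enumerate(
                zip(network.cell_vertices, network.cell_offsets)):
            z = cyc.size
            idx = np.arange(pos, pos + z)
            cc.append(np.full(z, a))
            cv.append(cyc)
            co.append(off)
            nxt.append(np.roll(idx, -1))
            prv.append(np.roll(idx, 1))
            starts.append(pos)
            pos += z
        return cls(
            corner_cell=np.concatenate(cc),
            corner_vertex=np.concatenate(cv),
            corner_offset=np.concatenate(co),
            nxt=np.concatenate(nxt),
            prv=np.concatenate(prv),
            n_cells=network.n_cells,
            n_vertices=network.n_vertices,
            cell_sizes=network.polygonal_classes(),
            cell_start=np.asarray(starts, dtype=np.intp),
        )

    def unwrap(self, vertices: np.ndarray, box: np.ndarray) -> np.ndarray:
        """Unwrapped corner positions (M,2)."""
        return vertices[self.corner_vertex] + self.corner_offset * box


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]
    warnings: list[str]

    def __bool__(self) -> bool:
        return self.ok


def validate_network(network: TissueNetwork) -> ValidationReport:
    """Structural diagnostics: orientation, simplicity, trijunctions,
    periodic cycle closure, concavity, minimum-image size.

    Reports rather than repairs; concavity is a warning (relaxation can
    transiently produce mildly concave cells), everything else a violation.
    """
    violations: list[str] = []
    warns: list[str] = []

    # orientation + simplicity + concavity + diameter
    for a in range(network.n_cells):
        poly = network.cell_polygon(a)
        area = polygon_area(poly)
        if area <= 0:
            violations.append(f"cell {a}: non-positive signed area {area:.3g}")
            continue
        z = poly.shape[0]
        t = np.roll(poly, -1, axis=0) - poly
        tn = np.roll(t, -1, axis=0)
        crosses = t[:, 0] * tn[:, 1] - t[:, 1] * tn[:, 0]
        if np.any(crosses < -1e-12 * max(area, 1e-30)):
            warns.append(f"cell {a}: concave polygon")
        if z <= 12:
            # simplicity by brute force only for small polygons
            segs_bad = False
            for i in range(z):
                p1, p2 = poly[i], poly[(i + 1) % z]
                for k in range(i + 2, z):
                    if i == 0 and k == z - 1:
                        continue
                    q1, q2 = poly[k], poly[(k + 1) % z]
                    def _xz(u, v):
                        return u[0] * v[1] - u[1] * v[0]
                    d1 = _xz(p2 - p1, q1 - p1)
                    d2 = _xz(p2 - p1, q2 - p1)
                    d3 = _xz(q2 - q1, p1 - q1)
                    d4 = _xz(q2 - q1, p2 - q1)
                    if (d1 * d2 < 0) and (d3 * d4 < 0):
                        segs_bad = True
            if segs_bad:
                violations.append(f"cell {a}: self-intersecting polygon")
        if network.periodic:
            diam = np.ptp(poly, axis=0)
            if np.any(diam >= network.box / 2):
                warns.append(
                    f"cell {a}: diameter {diam.max():.3g} exceeds half-box "
                    "(minimum-image ambiguity)"
                )

    # trijunction property
    if network.periodic:
        try:
            build_incidence(network)
        except TopologyError as exc:
            violations.append(str(exc))

    # canonical-position closure (per-corner offsets make cycle closure
    # automatic; what can break is the canonical-range convention)
    if network.periodic:
        out = np.any((network.vertices < 0) | (network.vertices >= network.box))
        if out:
            violations.append("vertex positions outside canonical box [0, box)")

    # each undirected edge borders exactly two cells (periodic mode)
    if network.periodic:
        for key, halves in network_edges(network).items():
            if len(halves) != 2:
                violations.append(
                    f"edge {key} bounded by {len(halves)} cell(s), expected 2"
                )

    return ValidationReport(ok=not violations, violations=violations,
                            warnings=warns)
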