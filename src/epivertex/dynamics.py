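"""Relaxation dynamics, topological transitions and load control.

The monolayer evolves down gradients of the total energy.  Equilibria are
found by gradient-based minimisation using the analytic vertex forces,
converged on the maximum force residual (the physically meaningful
criterion f^j = 0).  During relaxation the network topology is updated
intermittently:

* **T1 (intercalation)** — an edge shorter than ``0.1 sqrt(A_6*)`` is
  rotated 90 degrees about its midpoint and reconnected, exchanging the
  neighbour relationships of the four surrounding cells;
* **T2 (extrusion)** — a triangular cell whose area falls below
  ``0.3 A_6*`` is collapsed to a single trijunction.

``A_6*`` is the zero-load equilibrium area of a regular hexagon at the
given parameters (the larger root in the bistable region IIb).

An unloaded monolayer must satisfy the global constraint that the
area-weighted mean effective cell pressure equals the imposed boundary
pressure; this fixes the equilibrium cell density and is enforced by a
secant iteration on a uniform rescaling of the box and all vertices,
re-relaxing after each rescale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import (FlatTopology, TissueNetwork, build_incidence,
                       network_edges)
from .mechanics import ModelParams, energy_and_forces_flat
from .tessellation import matern_ii_points, voronoi_network
from .theory import classify_region, equilibrium_areas

__all__ = [
    "RelaxationSettings",
    "relax",
    "attempt_t1",
    "attempt_t2",
    "enforce_isotropic_load",
    "step_overdamped",
    "generate_monolayer",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelaxationSettings:
    """Knobs of the relaxation / transition / load-control loop.

    The T1 and T2 thresholds (0.1 sqrt(A_6*) and 0.3 A_6*) follow the
    simulation protocol of the model; the post-T1 edge length (1.5x the
    threshold, to avoid immediate re-triggering), the load tolerance and
    the transition ordering are configuration decisions.
    """

    force_tolerance: float = 1e-6
    t1_length_factor: float = 0.1
    t2_area_factor: float = 0.3
    t1_post_factor: float = 1.5
    max_outer_iterations: int = 500
    load_tolerance: float = 1e-3
    max_minimizer_iterations: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.t1_post_factor <= 1.0:
            raise ValueError("t1_post_factor must exceed 1")
        for name in ("force_tolerance", "t1_length_factor", "t2_area_factor",
                     "load_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _reference_hex_area(params: ModelParams) -> float:
    """A_6* used for transition thresholds and box sizing (larger root in
    region IIb).  Under an external load the equilibrium hexagon area at
    that load is used, so a loaded run scales its thresholds the same way
    the dagger symmetry scales its cells."""
    roots = equilibrium_areas(6, params, p_ext=params.p_ext)
    if roots.size == 0:
        raise ValueError(
            f"no equilibrium hexagon area at (Lambda, Gamma, P_ext) = "
            f"({params.lam}, {params.gam}, {params.p_ext})"
        )
    return float(roots[0])


# ---------------------------------------------------------------------------
# energy minimisation
# ---------------------------------------------------------------------------

def _watched_corner_mask(network: TissueNetwork, flat: FlatTopology,
                         blocked: set) -> np.ndarray:
    """Boolean mask over corners whose edge may trigger a T1 interrupt
    (all edges except those whose T1 was refused)."""
    mask = np.ones(flat.corner_vertex.size, dtype=bool)
    if blocked:
        edges = network_edges(network)
        for key in blocked:
            for (a, i) in edges.get(key, ()):
                mask[flat.cell_start[a] + i] = False
    return mask


def _minimize_positions(network: TissueNetwork, params: ModelParams,
                        settings: RelaxationSettings,
                        t1_threshold: float | None = None,
                        watched: np.ndarray | None = None,
                        ) -> tuple[TissueNetwork, float, bool]:
    """Local energy minimisation at fixed topology.

    If ``t1_threshold`` is given, minimisation is interrupted as soon as
    any watched edge drops below it, so the outer loop can intercalate the
    edge before it collapses.  Returns ``(network, max |f^j|,
    interrupted)``.
    """
    flat = FlatTopology.from_network(network)
    box = network.box
    shape = network.vertices.shape

    def fun(xflat):
        u, f = energy_and_forces_flat(flat, xflat.reshape(shape), box, params)
        return u, -f.ravel()

    interrupted = [False]
    callback = None
    if t1_threshold is not None:
        w = watched if watched is not None else np.ones(
            flat.corner_vertex.size, dtype=bool)

        def callback(xk):
            x = flat.unwrap(xk.reshape(shape), box)
            tang = x[flat.nxt] - x
            ell = np.hypot(tang[:, 0], tang[:, 1])
            if np.any(ell[w] < t1_threshold):
                interrupted[0] = True
                raise StopIteration

    res = optimize.minimize(
        fun, network.vertices.ravel(), jac=True, method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": settings.max_minimizer_iterations,
            "gtol": 0.2 * settings.force_tolerance,
            "ftol": 1e-18,
            "maxcor": 20,
        },
    )
    pos = res.x.reshape(shape)
    _, forces = energy_and_forces_flat(flat, pos, box, params)
    fmax = float(np.abs(forces).max())
    out = network.with_positions(pos)
    out.canonicalize()
    return out, fmax, interrupted[0]


# ---------------------------------------------------------------------------
# topological transitions
# ---------------------------------------------------------------------------

def _edge_geometry(network: TissueNetwork, halves):
    """Unwrapped endpoints of an edge, as seen from its first half-edge."""
    (a, i) = halves[0]
    cyc, off = network.cell_vertices[a], network.cell_offsets[a]
    z = cyc.size
    j1, j2 = int(cyc[i]), int(cyc[(i + 1) % z])
    p1 = network.vertices[j1] + off[i] * network.box
    p2 = network.vertices[j2] + off[(i + 1) % z] * network.box
    return j1, j2, p1, p2


def _shortest_edge(network: TissueNetwork, exclude: set = frozenset()):
    """(length, key) of the shortest edge not in ``exclude``."""
    best = None
    for key, halves in network_edges(network).items():
        if key in exclude:
            continue
        _, _, p1, p2 = _edge_geometry(network, halves)
        length = float(np.hypot(*(p2 - p1)))
        if best is None or length < best[0]:
            best = (length, key)
    return best


def _remove_vertex_from_cell(net: TissueNetwork, a: int, j: int):
    cyc, off = net.cell_vertices[a], net.cell_offsets[a]
    keep = cyc != j
    if keep.sum() != cyc.size - 1:
        raise RuntimeError("vertex appears multiple times in cell cycle")
    net.cell_vertices[a] = cyc[keep]
    net.cell_offsets[a] = off[keep]


def _insert_vertex_into_cell(net: TissueNetwork, a: int, j_new: int,
                             j_anchor: int, before: bool):
    cyc, off = net.cell_vertices[a], net.cell_offsets[a]
    k = int(np.nonzero(cyc == j_anchor)[0][0])
    # offset of the new corner: minimum image relative to the anchor corner
    anchor_pos = net.vertices[j_anchor] + off[k] * net.box
    d = net.vertices[j_new] - anchor_pos
    o_new = -np.rint(d / net.box).astype(np.intp)
    pos = k if before else k + 1
    net.cell_vertices[a] = np.insert(cyc, pos, j_new)
    net.cell_offsets[a] = np.insert(off, pos, o_new, axis=0)


def attempt_t1(network: TissueNetwork, edge_key, params: ModelParams,
               settings: RelaxationSettings) -> tuple[TissueNetwork, bool]:
    """Apply a T1 transition to the given edge if it is below threshold.

    The edge is rotated 90 degrees about its midpoint and reconnected: the
    two cells sharing it lose one vertex each, the two flanking cells gain
    one, and the new edge is placed just above the trigger length.  Returns
    ``(network, fired)``; the input network is never mutated.
    """
    a6 = _reference_hex_area(params)
    threshold = settings.t1_length_factor * np.sqrt(a6)
    edges = network_edges(network)
    halves = edges[edge_key]
    if len(halves) != 2:
        raise ValueError("T1 needs an edge shared by exactly two cells")
    j1, j2, p1, p2 = _edge_geometry(network, halves)
    length = float(np.hypot(*(p2 - p1)))
    if length >= threshold:
        return network, False

    (a, ia), (b, ib) = halves
    # orient so that in cell `a` the edge runs j1 -> j2 anticlockwise
    if int(network.cell_vertices[a][ia]) != j1:
        (a, ia), (b, ib) = (b, ib), (a, ia)
        j1, j2 = j2, j1
    if network.cell_vertices[a].size <= 3 or network.cell_vertices[b].size <= 3:
        return network, False  # would create a 2-gon; leave for T2

    inc = build_incidence(network)
    third = {}
    for j in (j1, j2):
        cells_at_j = {alpha for alpha, _ in inc[j]}
        others = cells_at_j - {a, b}
        if len(others) != 1:
            raise ValueError("T1 endpoints must be trijunctions")
        third[j] = others.pop()
    c, d = third[j1], third[j2]   # c flanks j1, d flanks j2
    if c == d:
        return network, False     # pathological small-network case

    net = network.copy()
    # work in cell a's unwrapped frame
    za = network.cell_vertices[a].size
    o_ref = {j1: network.cell_offsets[a][ia],
             j2: network.cell_offsets[a][(ia + 1) % za]}
    p1 = network.vertices[j1] + o_ref[j1] * network.box
    p2 = network.vertices[j2] + o_ref[j2] * network.box
    mid = 0.5 * (p1 + p2)
    u = (p2 - p1) / length
    n_left = np.array([-u[1], u[0]])   # interior of cell `a` lies this way
    half = 0.5 * settings.t1_post_factor * threshold
    new_pos = {j1: mid + half * n_left,   # -> junction of cells a, c, d
               j2: mid - half * n_left}   # -> junction of cells b, c, d
    # rewrite canonical positions; every referencing corner keeps its own
    # periodic image, so its offset changes by (shift - old frame offset)
    for j, pos in new_pos.items():
        shift = np.floor(pos / net.box).astype(np.intp)
        net.vertices[j] = pos - shift * net.box
        delta = shift - o_ref[j]
        if delta.any():
            for alpha in {x for x, _ in inc[j]}:
                cyc, off = net.cell_vertices[alpha], net.cell_offsets[alpha]
                off[cyc == j] += delta

    # reconnect: a loses j2, b loses j1, d gains j1 (next to j2), c gains
    # j2 (next to j1).  The insertion side is fixed by which neighbouring
    # cell each anchor edge borders: the flanking cell's edge that used to
    # border cell `a` must now terminate at the new a-c-d junction (j1),
    # and likewise the edge bordering `b` at the new b-c-d junction (j2).
    partner = {}
    for halves_ in edges.values():
        if len(halves_) == 2:
            (x1, k1), (x2, k2) = halves_
            partner[(x1, k1)] = x2
            partner[(x2, k2)] = x1

    def _insertion_side(cell: int, j_anchor: int, redirected: int) -> bool:
        cyc = network.cell_vertices[cell]
        k = int(np.nonzero(cyc == j_anchor)[0][0])
        incoming = partner.get((cell, (k - 1) % cyc.size))
        outgoing = partner.get((cell, k))
        if incoming == redirected:
            return True    # insert before the anchor
        if outgoing == redirected:
            return False   # insert after the anchor
        raise RuntimeError("T1 flanking cell does not border the expected "
                           "neighbour")

    before_d = _insertion_side(d, j2, a)
    before_c = _insertion_side(c, j1, b)
    _remove_vertex_from_cell(net, a, j2)
    _remove_vertex_from_cell(net, b, j1)
    _insert_vertex_into_cell(net, d, j1, j2, before_d)
    _insert_vertex_into_cell(net, c, j2, j1, before_c)
    net.canonicalize()
    return net, True


def attempt_t2(network: TissueNetwork, cell: int, params: ModelParams,
               settings: RelaxationSettings) -> tuple[TissueNetwork, bool]:
    """Extrude a small triangular cell: its three vertices merge into a
    single trijunction at their mean; each neighbour loses one vertex."""
    cyc = network.cell_vertices[cell]
    if cyc.size != 3:
        warnings.warn("T2 attempted on a non-triangular cell; skipped",
                      stacklevel=2)
        return network, False
    a6 = _reference_hex_area(params)
    geo = network.cell_geometry(cell)
    if geo.area >= settings.t2_area_factor * a6:
        return network, False

    net = network.copy()
    tri_poly = net.cell_polygon(cell)
    centre = tri_poly.mean(axis=0)
    keep = int(cyc[0])
    drop = [int(cyc[1]), int(cyc[2])]
    # canonical position of the merged vertex
    shift = np.floor(centre / net.box).astype(np.intp)
    net.vertices[keep] = centre - shift * net.box

    inc = build_incidence(net)
    # remap every corner referencing a dropped vertex onto `keep`
    for j_old in drop:
        for alpha, i in inc[j_old]:
            if alpha == cell:
                continue
            net.cell_vertices[alpha][i] = keep
    # rebuild offsets for all corners now referencing `keep` using minimum
    # image relative to the pre-merge polygon, then collapse duplicates
    for alpha in range(net.n_cells):
        if alpha == cell:
            continue
        cyc_a = net.cell_vertices[alpha]
        if not np.any(np.isin(cyc_a, [keep])):
            continue
        poly_ref = network.cell_polygon(alpha)  # pre-merge unwrapped polygon
        off_a = net.cell_offsets[alpha]
        for i, j in enumerate(cyc_a):
            if int(j) == keep:
                d = net.vertices[keep] - poly_ref[i]
                off_a[i] = -np.rint(d / net.box).astype(np.intp)
        # collapse consecutive duplicate corners (same vertex, same offset)
        dup = np.zeros(cyc_a.size, dtype=bool)
        for i in range(cyc_a.size):
            k = (i + 1) % cyc_a.size
            if cyc_a[i] == cyc_a[k] and np.all(off_a[i] == off_a[k]):
                dup[k] = True
        net.cell_vertices[alpha] = cyc_a[~dup]
        net.cell_offsets[alpha] = off_a[~dup]

    # delete the triangle and the dropped vertices, compacting indices
    net.cell_vertices.pop(cell)
    net.cell_offsets.pop(cell)
    keep_mask = np.ones(net.n_vertices, dtype=bool)
    keep_mask[drop] = False
    remap = -np.ones(net.n_vertices, dtype=np.intp)
    remap[keep_mask] = np.arange(keep_mask.sum())
    net.vertices = net.vertices[keep_mask]
    net.cell_vertices = [remap[c] for c in net.cell_vertices]
    net.canonicalize()
    return net, True


def _find_t2_candidate(network: TissueNetwork, params: ModelParams,
                       settings: RelaxationSettings):
    a6 = _reference_hex_area(params)
    best = None
    for alpha, cyc in enumerate(network.cell_vertices):
        if cyc.size != 3:
            continue
        area = network.cell_geometry(alpha).area
        if area < settings.t2_area_factor * a6:
            if best is None or area < best[1]:
                best = (alpha, area)
    return None if best is None else best[0]


# ---------------------------------------------------------------------------
# outer relaxation loop
# ---------------------------------------------------------------------------

def relax(network: TissueNetwork, params: ModelParams,
          settings: RelaxationSettings | None = None) -> TissueNetwork:
    """Relax to the nearest energy minimum, applying T1/T2 transitions.

    The outer loop alternates minimisation with topology checks; one
    transition (the most urgent: smallest triangle first, else shortest
    sub-threshold edge) fires per iteration, followed by re-relaxation.
    Terminates when no transition fires and max |f^j| < force_tolerance.
    """
    settings = settings or RelaxationSettings()
    a6 = _reference_hex_area(params)
    t1_threshold = settings.t1_length_factor * np.sqrt(a6)
    net = network
    n_t1 = n_t2 = 0
    blocked: set = set()   # edges whose T1 was refused (triangle adjacency)
    prev_fmax = None
    for outer in range(settings.max_outer_iterations):
        flat = FlatTopology.from_network(net)
        watched = _watched_corner_mask(net, flat, blocked)
        net, fmax, interrupted = _minimize_positions(
            net, params, settings, t1_threshold=t1_threshold, watched=watched)
        tri = _find_t2_candidate(net, params, settings)
        if tri is not None:
            net, fired = attempt_t2(net, tri, params, settings)
            if fired:
                n_t2 += 1
                blocked.clear()
                log.info("T2 extrusion of cell %d (outer %d)", tri, outer)
                continue
        shortest = _shortest_edge(net, exclude=blocked)
        if shortest is not None and shortest[0] < t1_threshold:
            net, fired = attempt_t1(net, shortest[1], params, settings)
            if fired:
                n_t1 += 1
                blocked.clear()
                log.info("T1 on edge %s, length %.3g (outer %d)",
                         shortest[1], shortest[0], outer)
            else:
                blocked.add(shortest[1])
            continue
        if not interrupted:
            if fmax < settings.force_tolerance:
                break
            if prev_fmax is not None and fmax > 0.9 * prev_fmax:
                # minimiser stalled (tolerance below double-precision reach)
                warnings.warn(
                    f"relaxation stalled at max |f| = {fmax:.3g} above the "
                    f"requested tolerance {settings.force_tolerance:.3g}",
                    stacklevel=2)
                break
            prev_fmax = fmax
    else:
        warnings.warn(
            f"relaxation hit max_outer_iterations={settings.max_outer_iterations} "
            f"(max |f| = {fmax:.3g}); returning partial result", stacklevel=2)
    net.meta.update(n_t1=net.meta.get("n_t1", 0) + n_t1,
                    n_t2=net.meta.get("n_t2", 0) + n_t2,
                    max_force=fmax)
    return net


# ---------------------------------------------------------------------------
# load control
# ---------------------------------------------------------------------------

def _mean_effective_pressure(network: TissueNetwork, params: ModelParams) -> float:
    """Area-weighted mean of P_eff over all cells."""
    flat = FlatTopology.from_network(network)
    from .mechanics import _flat_terms
    _, _, _, _, _, area, perim = _flat_terms(flat, network.vertices, network.box)
    p = area - 1.0
    t = params.gam * (perim - params.l0)
    peff = p + t * perim / (2.0 * area)
    return float(np.sum(area * peff) / np.sum(area))


def _rescaled(network: TissueNetwork, scale: float) -> TissueNetwork:
    net = network.copy()
    net.box = network.box * scale
    net.vertices = network.vertices * scale
    return net


def enforce_isotropic_load(network: TissueNetwork, params: ModelParams,
                           settings: RelaxationSettings | None = None,
                           ) -> TissueNetwork:
    """Drive the monolayer to the prescribed isotropic load.

    Secant iteration on a uniform scale factor applied to the box and all
    vertex positions, re-relaxing after every rescale, until the
    area-weighted mean effective pressure matches P_ext within the load
    tolerance.  The cumulative scale is confined to [0.5, 2.0]; leaving
    that bracket suggests parameters without an equilibrium density.
    """
    settings = settings or RelaxationSettings()
    target = params.p_ext

    net = relax(network, params, settings)
    s_cur = 1.0
    g_cur = _mean_effective_pressure(net, params) - target
    if abs(g_cur) < settings.load_tolerance:
        net.meta["mean_peff_residual"] = g_cur
        return net
    # second point: mean P_eff increases with box size, so nudge accordingly
    s_prev, g_prev = s_cur, g_cur
    s_cur = s_cur * (1.02 if g_cur < 0 else 1.0 / 1.02)
    for _ in range(60):
        if not (0.5 <= s_cur <= 2.0):
            raise RuntimeError(
                f"no load-balancing rescale found in [0.5, 2.0] "
                f"(requested cumulative scale {s_cur:.3g}); parameters may "
                "admit no equilibrium at this load")
        net = relax(_rescaled(net, s_cur / s_prev), params, settings)
        g_cur = _mean_effective_pressure(net, params) - target
        if abs(g_cur) < settings.load_tolerance:
            net.meta["mean_peff_residual"] = g_cur
            net.meta["load_scale"] = s_cur
            return net
        if g_cur == g_prev:
            s_next = s_cur * (1.02 if g_cur < 0 else 1.0 / 1.02)
        else:
            s_next = s_cur - g_cur * (s_cur - s_prev) / (g_cur - g_prev)
            # damp wild secant extrapolations
            s_next = float(np.clip(s_next, 0.7 * s_cur, 1.4 * s_cur))
        s_prev, g_prev = s_cur, g_cur
        s_cur = s_next
    raise RuntimeError("load enforcement failed to converge in 60 rescales")


# ---------------------------------------------------------------------------
# explicit overdamped stepping
# ---------------------------------------------------------------------------

def step_overdamped(network: TissueNetwork, params: ModelParams, dt: float,
                    max_halvings: int = 20,
                    ) -> tuple[TissueNetwork, np.ndarray]:
    """Advance one explicit overdamped step.

    Force balance with substrate drag sets the vertex velocity
    ``v^j = f^j / sum_{cells at j} (A/Z)`` (the drag on a vertex has a
    contribution A/Z from each incident cell, so that a cell's total drag
    scales with its area).  If the trial step raises the energy, dt is
    halved (logged) until it does not.  Returns the advanced network and
    the vertex velocities, which can be fed to the dissipative stress term.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    flat = FlatTopology.from_network(network)
    u0, forces = energy_and_forces_flat(flat, network.vertices, network.box,
                                        params)
    from .mechanics import _flat_terms
    _, _, _, _, _, area, _ = _flat_terms(flat, network.vertices, network.box)
    drag_per_corner = area[flat.corner_cell] / flat.cell_sizes[flat.corner_cell]
    drag = np.bincount(flat.corner_vertex, weights=drag_per_corner,
                       minlength=flat.n_vertices)
    vel = forces / drag[:, None]
    step = dt
    for _ in range(max_halvings):
        trial = network.vertices + step * vel
        u1, _ = energy_and_forces_flat(flat, trial, network.box, params)
        if u1 <= u0 or np.abs(vel).max() * step < 1e-15:
            out = network.with_positions(trial)
            out.canonicalize()
            return out, vel
        step *= 0.5
        log.info("overdamped step rejected (energy rise); dt halved to %.3g",
                 step)
    raise RuntimeError("overdamped step failed even after halving dt")


# ---------------------------------------------------------------------------
# full monolayer pipeline
# ---------------------------------------------------------------------------

def generate_monolayer(params: ModelParams, n_cells: int, seed: int = 0,
                       settings: RelaxationSettings | None = None,
                       ) -> TissueNetwork:
    """Simulate an equilibrium monolayer at the prescribed isotropic load.

    Pipeline: Matérn-II seed points -> periodic Voronoi tessellation ->
    relaxation with T1/T2 transitions -> isotropic load enforcement.  The
    box is sized so the initial mean cell area is A_6* (larger root in
    region IIb); everything is deterministic given the seed.
    """
    settings = settings or RelaxationSettings(seed=seed)
    from .theory import dagger_transform
    region = classify_region(dagger_transform(params)[0] if params.p_ext
                             else params)
    if region.label == "III":
        raise ValueError(
            f"(Lambda, Gamma) = ({params.lam}, {params.gam}) lies in region "
            "III (network collapse); no monolayer can be generated")
    a6 = _reference_hex_area(params)
    box = float(np.sqrt(n_cells * a6))
    points = matern_ii_points(box, n_cells, seed=seed)
    net = voronoi_network(points)
    net = enforce_isotropic_load(net, params, settings)
    net.meta.update(
        params=dict(lam=params.lam, gam=params.gam, p_ext=params.p_ext),
        n_cells_initial=n_cells, seed=seed, region=region.label,
        settings=dict(
            force_tolerance=settings.force_tolerance,
            t1_length_factor=settings.t1_length_factor,
            t2_area_factor=settings.t2_area_factor,
            t1_post_factor=settings.t1_post_factor,
            load_tolerance=settings.load_tolerance,
        ),
    )
    return net
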