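"""Energy, forces and stress tensors of the vertex model.

Each cell alpha carries the dimensionless mechanical energy

    U_alpha = 1/2 (A_alpha - 1)^2 + 1/2 Gamma (L_alpha - L_0)^2,

where areas are measured in units of the preferred area, Gamma is the
cortical contractility, and L_0 = -Lambda/(2 Gamma) is the preferred
perimeter set by the line tension Lambda.  (The constant -Lambda^2/(4
Gamma^2) completing the square is dropped; it does not affect forces.)

Associated per-cell quantities:

* pressure  P = A - 1 and tension T = Gamma (L - L_0);
* vertex force f^i = -P p^i + T q^i with p^i = 1/2 (R^{i+1} - R^{i-1}) x z,
  q^i = t_hat^i - t_hat^{i-1} — exactly minus the energy gradient;
* cell stress sigma = -P_eff I + T J - 1/2 dS/dt, with effective pressure
  P_eff = P + T L / (2A) (a Young-Laplace-like cortical correction with
  effective radius 2A/L) and traceless deviator
  J = (1/A) (L/2 I - sum_i l^i t_hat^i (x) t_hat^i);
* tissue stress over a region = area-weighted mean of the cell stresses.

At equilibrium the principal axes of a cell's stress and shape tensors
closely align, so an elongated cell's local stress is oriented along its
elongation (see docs/methods.md for the measured accuracy of this
alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (CellGeometry, FlatTopology, TissueNetwork,
                       ISOTROPY_RTOL, cell_shape)

__all__ = [
    "ModelParams",
    "CellMechanics",
    "pressure_tension",
    "cell_vertex_forces",
    "net_vertex_forces",
    "total_energy",
    "energy_and_forces_flat",
    "cell_stress",
    "tissue_stress",
    "stress_shape_alignment",
    "classify_cell_stress",
    "network_cell_mechanics",
]

_I2 = np.eye(2)


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless model parameters.

    lam : line tension Lambda (negative favours long junctions).
    gam : cortical contractility Gamma (> 0 wherever L_0 is used).
    p_ext : imposed isotropic boundary pressure (0 for a free monolayer).
    """

    lam: float
    gam: float
    p_ext: float = 0.0

    @property
    def l0(self) -> float:
        """Preferred perimeter L_0 = -Lambda / (2 Gamma)."""
        if self.gam <= 0:
            raise ValueError("L_0 requires Gamma > 0")
        return -self.lam / (2.0 * self.gam)

    @property
    def region(self) -> str:
        from .theory import classify_region
        return classify_region(self).label


def pressure_tension(cell: CellGeometry, params: ModelParams) -> tuple[float, float]:
    """Cell pressure P = A - 1 and cortical tension T = Gamma (L - L_0)."""
    return cell.area - 1.0, params.gam * (cell.perimeter - params.l0)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _cross_z(v: np.ndarray) -> np.ndarray:
    """v x z_hat for stacked 2-vectors: (x, y) -> (y, -x)."""
    return np.column_stack([v[..., 1], -v[..., 0]])


def cell_vertex_forces(cell: CellGeometry | np.ndarray,
                       params: ModelParams) -> np.ndarray:
    """Restoring force of one cell at each of its vertices.

    Returns the (Z, 2) array f^i = -P p^i + T q^i, equal to minus the
    gradient of this cell's energy with respect to each vertex position.
    """
    geo = cell if isinstance(cell, CellGeometry) else cell_shape(cell)
    v = geo.vertices
    if np.any(geo.edge_lengths == 0.0):
        raise ValueError("zero-length edge: unit tangent undefined")
    p_, t_ = pressure_tension(geo, params)
    vn = np.roll(v, -1, axis=0)
    vp = np.roll(v, 1, axis=0)
    pvec = 0.5 * _cross_z(vn - vp)
    tang = vn - v
    that = tang / geo.edge_lengths[:, None]
    qvec = that - np.roll(that, 1, axis=0)
    return -p_ * pvec + t_ * qvec


def _flat_terms(flat: FlatTopology, vertices: np.ndarray, box: np.ndarray):
    """Vectorised per-corner geometry shared by energy/force/stress code."""
    x = flat.unwrap(vertices, box)
    xn = x[flat.nxt]
    xp = x[flat.prv]
    cc = flat.corner_cell
    area = np.bincount(cc, weights=0.5 * (x[:, 0] * xn[:, 1] - xn[:, 0] * x[:, 1]),
                       minlength=flat.n_cells)
    tang = xn - x
    ell = np.hypot(tang[:, 0], tang[:, 1])
    perim = np.bincount(cc, weights=ell, minlength=flat.n_cells)
    return x, xn, xp, tang, ell, area, perim


def energy_and_forces_flat(flat: FlatTopology, vertices: np.ndarray,
                           box: np.ndarray, params: ModelParams):
    """Total energy and net per-vertex force for a periodic network.

    The workhorse of relaxation: returns ``(U, F)`` with ``F`` of shape
    (Nv, 2) and ``F = -dU/dR`` exactly (offsets are constant, so gradients
    pass straight through the unwrap map).
    """
    x, xn, xp, tang, ell, area, perim = _flat_terms(flat, vertices, box)
    cc = flat.corner_cell
    l0 = params.l0
    p_cell = area - 1.0
    t_cell = params.gam * (perim - l0)
    energy = float(np.sum(0.5 * p_cell**2 + 0.5 * params.gam * (perim - l0)**2))

    pvec = 0.5 * _cross_z(xn - xp)
    # clamp: a (transient) zero-length edge must not poison the line search
    # with NaNs; the relaxation loop removes such edges by T1/T2
    that = tang / np.maximum(ell, 1e-30)[:, None]
    qvec = that - that[flat.prv]
    f_corner = -p_cell[cc, None] * pvec + t_cell[cc, None] * qvec
    fx = np.bincount(flat.corner_vertex, weights=f_corner[:, 0],
                     minlength=flat.n_vertices)
    fy = np.bincount(flat.corner_vertex, weights=f_corner[:, 1],
                     minlength=flat.n_vertices)
    return energy, np.column_stack([fx, fy])


def total_energy(network: TissueNetwork, params: ModelParams) -> float:
    """Sum over cells of 1/2 (A-1)^2 + 1/2 Gamma (L-L_0)^2."""
    flat = FlatTopology.from_network(network)
    u, _ = energy_and_forces_flat(flat, network.vertices, network.box, params)
    return u


def net_vertex_forces(network: TissueNetwork, params: ModelParams) -> np.ndarray:
    """Net force on every vertex: the sum of the incident cells' vertex
    forces, plus the boundary-pressure terms on peripheral vertices of a
    finite patch (the surrounding medium acts as a tensionless cell at
    pressure P_ext)."""
    flat = FlatTopology.from_network(network)
    _, forces = energy_and_forces_flat(flat, network.vertices, network.box, params)
    if not network.periodic and network.peripheral_vertices:
        forces = forces + _peripheral_pressure_forces(network, params)
    return forces


def _peripheral_pressure_forces(network: TissueNetwork,
                                params: ModelParams) -> np.ndarray:
    """External-pressure force on the periphery of a finite patch.

    The outside is treated as a cell of pressure P_ext and zero tension
    whose boundary is the tissue periphery traversed clockwise; its force
    contribution at peripheral vertex k is -P_ext p_out^k, which for the
    anticlockwise peripheral cycle equals +P_ext * 1/2 (R^{k+1}-R^{k-1}) x z.
    """
    forces = np.zeros_like(network.vertices)
    if params.p_ext == 0.0:
        return forces
    cycle = _peripheral_cycle(network)
    v = network.vertices[cycle]
    vn = np.roll(v, -1, axis=0)
    vp = np.roll(v, 1, axis=0)
    forces[cycle] = params.p_ext * 0.5 * _cross_z(vn - vp)
    return forces


def _peripheral_cycle(network: TissueNetwork) -> np.ndarray:
    """Ordered peripheral vertex cycle (anticlockwise) of a finite patch."""
    from .geometry import network_edges
    succ = {}
    for key, halves in network_edges(network).items():
        if len(halves) == 1:
            (a, i) = halves[0]
            cyc = network.cell_vertices[a]
            j1, j2 = int(cyc[i]), int(cyc[(i + 1) % cyc.size])
            # boundary half-edge j1->j2 is anticlockwise in its cell; the
            # peripheral cycle traverses the tissue boundary anticlockwise
            succ[j1] = j2
    if not succ:
        raise ValueError("network has no boundary")
    start = next(iter(succ))
    cycle = [start]
    while True:
        nxt = succ[cycle[-1]]
        if nxt == start:
            break
        cycle.append(nxt)
    return np.asarray(cycle, dtype=np.intp)


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMechanics:
    """Mechanical state of one cell (stress in units of K A_0)."""

    pressure: float
    tension: float
    p_eff: float
    stress: np.ndarray            # (2,2) symmetric
    deviator: np.ndarray          # (2,2) traceless, the J tensor
    eigenvalues: tuple[float, float]   # ordered |sigma_1| >= |sigma_2|
    principal_axis: np.ndarray    # eigenvector of the larger-|.| eigenvalue
    tensile_axis: np.ndarray      # eigenvector of the smaller (most
                                  # tensile) eigenvalue; aligns with the
                                  # shape major axis at equilibrium
    isotropic: bool               # degenerate principal axis

    @property
    def stress_class(self) -> str:
        return classify_cell_stress(self)


def cell_stress(cell: CellGeometry | np.ndarray, params: ModelParams,
                vertex_velocities: np.ndarray | None = None) -> CellMechanics:
    """Stress tensor of a single cell.

    sigma = -P_eff I + T J - 1/2 dS/dt.  The viscous rate-of-shape term is
    included only when explicit vertex velocities are supplied; at an
    equilibrium it vanishes.
    """
    geo = cell if isinstance(cell, CellGeometry) else cell_shape(cell)
    if geo.area <= 0:
        raise ValueError("cell stress requires positive area")
    p_, t_ = pressure_tension(geo, params)
    a, ell, perim = geo.area, geo.edge_lengths, geo.perimeter
    p_eff = p_ + t_ * perim / (2.0 * a)
    v = geo.vertices
    tang = np.roll(v, -1, axis=0) - v
    that = tang / ell[:, None]
    dyad = np.einsum("i,ij,ik->jk", ell, that, that)
    deviator = (0.5 * perim * _I2 - dyad) / a
    sigma = -p_eff * _I2 + t_ * deviator
    if vertex_velocities is not None:
        vel = np.asarray(vertex_velocities, dtype=float)
        rv = v - v.mean(axis=0)
        vv = vel - vel.mean(axis=0)
        sdot = (rv.T @ vv + vv.T @ rv) / v.shape[0]
        sigma = sigma - 0.5 * sdot
    sigma = 0.5 * (sigma + sigma.T)
    evals_asc, evecs = np.linalg.eigh(sigma)   # ascending
    order = np.argsort(-np.abs(evals_asc))
    evals = evals_asc[order]
    scale = np.max(np.abs(evals))
    iso = np.abs(evals_asc[1] - evals_asc[0]) <= ISOTROPY_RTOL * max(scale, 1e-300)
    return CellMechanics(
        pressure=float(p_), tension=float(t_), p_eff=float(p_eff),
        stress=sigma, deviator=deviator,
        eigenvalues=(float(evals[0]), float(evals[1])),
        principal_axis=evecs[:, order[0]],
        tensile_axis=evecs[:, 0],
        isotropic=bool(iso),
    )


def network_cell_mechanics(network: TissueNetwork, params: ModelParams,
                           ) -> list[CellMechanics]:
    return [cell_stress(network.cell_geometry(a), params)
            for a in range(network.n_cells)]


def tissue_stress(network: TissueNetwork, params: ModelParams,
                  cell_subset=None) -> np.ndarray:
    """Area-weighted mean cell stress over a (sub)region of the monolayer."""
    cells = range(network.n_cells) if cell_subset is None else list(cell_subset)
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell subset")
    total = np.zeros((2, 2))
    atot = 0.0
    for a in cells:
        geo = network.cell_geometry(a)
        mech = cell_stress(geo, params)
        total += geo.area * mech.stress
        atot += geo.area
    return total / atot


def stress_shape_alignment(geometry: CellGeometry,
                           mechanics: CellMechanics) -> float:
    """Acute angle (radians) between the principal axes of shape and stress.

    The shape and stress tensors of an equilibrium cell commute, so their
    eigenbases coincide; concretely the shape *major* axis carries the most
    tensile (algebraically smallest) stress eigenvalue whenever the cortex
    is under tension, and that is the pairing measured here.  (The
    larger-*magnitude* stress eigenvector — the classification convention —
    is perpendicular to the major axis for a net-compressed round cell, so
    it is not a misalignment measure.)  Returns ``nan`` for isotropic
    (degenerate) cells.
    """
    if geometry.is_isotropic or mechanics.isotropic:
        return float("nan")
    c = abs(float(np.dot(geometry.major_axis, mechanics.tensile_axis)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def classify_cell_stress(mech: CellMechanics) -> str:
    """Four-way stress classification.

    A cell is under net tension iff P_eff > 0 (trace of sigma negative);
    it is "round" if both stress eigenvalues share the sign of -P_eff and
    "elongated" if the signs are mixed.  The traceless boundary case
    (P_eff = 0) is assigned "elongated".
    """
    s1, s2 = mech.eigenvalues
    if mech.p_eff > 0:
        kind = "tension"
        same = (s1 <= 0) and (s2 <= 0)
    elif mech.p_eff < 0:
        kind = "compression"
        same = (s1 >= 0) and (s2 >= 0)
    else:
        return "elongated (zero effective pressure)"
    return f"{kind}-{'round' if same else 'elongated'}"
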