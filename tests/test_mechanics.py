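import numpy as np
import pytest

from epivertex.geometry import (TissueNetwork, build_incidence, cell_shape,
                                network_edges)
from epivertex.mechanics import (ModelParams, cell_stress, cell_vertex_forces,
                                 classify_cell_stress, net_vertex_forces,
                                 pressure_tension, stress_shape_alignment,
                                 tissue_stress, total_energy)
from epivertex.fixtures import perturbed_lattice
from epivertex.tessellation import hexagonal_lattice, regular_ngon
from epivertex.theory import equilibrium_areas

from conftest import random_simple_polygon

# 2x1 rectangle, anticlockwise
RECT = np.array([[1.0, -0.5], [1.0, 0.5], [-1.0, 0.5], [-1.0, -0.5]])


def _energy(vertices, params):
    g = cell_shape(vertices)
    return (0.5 * (g.area - 1) ** 2
            + 0.5 * params.gam * (g.perimeter - params.l0) ** 2)


class TestPressureTension:
    def test_preferred_area_gives_zero_pressure(self, params_iia):
        geo = cell_shape(regular_ngon(6, area=1.0))
        p, _ = pressure_tension(geo, params_iia)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_preferred_perimeter_gives_zero_tension(self):
        params = ModelParams(lam=-0.2, gam=0.1)  # L_0 = 1
        # polygon with perimeter exactly 1
        geo = cell_shape(regular_ngon(6, area=1.0) / 3.72242)
        _, t = pressure_tension(geo, params)
        assert t == pytest.approx(0.0, abs=1e-5)

    def test_unit_side_hexagon(self):
        # side-1 hexagon: L = 6, L_0 = 1 -> T = 0.1 * 5 = 0.5
        hexagon = regular_ngon(6, area=3 * np.sqrt(3) / 2)
        _, t = pressure_tension(cell_shape(hexagon), ModelParams(-0.2, 0.1))
        assert t == pytest.approx(0.5, abs=1e-12)


class TestCellForces:
    def test_forces_sum_to_zero(self, rng, params_iia):
        for _ in range(5):
            f = cell_vertex_forces(random_simple_polygon(rng), params_iia)
            assert np.abs(f.sum(axis=0)).max() < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_force_is_minus_energy_gradient(self, seed, params_iia):
        rng = np.random.default_rng(seed)
        poly = random_simple_polygon(rng)
        f = cell_vertex_forces(poly, params_iia)
        h = 1e-6
        for i in range(poly.shape[0]):
            for k in range(2):
                up = poly.copy()
                up[i, k] += h
                dn = poly.copy()
                dn[i, k] -= h
                fd = -(_energy(up, params_iia) - _energy(dn, params_iia)) / (2 * h)
                assert f[i, k] == pytest.approx(fd, abs=1e-7)

    def test_regular_polygon_forces_radial(self, params_iia):
        poly = regular_ngon(6, area=2.0)
        f = cell_vertex_forces(poly, params_iia)
        mags = np.linalg.norm(f, axis=1)
        assert np.allclose(mags, mags[0])
        # each force parallel to the vertex radius
        for v, fi in zip(poly, f):
            cosang = abs(v @ fi) / (np.linalg.norm(v) * np.linalg.norm(fi))
            assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_zero_length_edge_rejected(self, params_iia):
        poly = np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero-length"):
                cell_vertex_forces(poly, params_iia)


class TestGeometricIdentities:
    """Identities behind the stress derivation:
    sum_i R^i (x) p^i = A I  and  sum_i R^i (x) q^i = - sum_i t_hat^i (x) t^i."""

    @pytest.mark.parametrize("seed", range(5))
    def test_identities_hold_for_random_polygons(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_simple_polygon(rng)
        geo = cell_shape(poly)
        r = geo.centered_vertices
        rn, rp = np.roll(r, -1, axis=0), np.roll(r, 1, axis=0)
        pvec = 0.5 * np.column_stack([(rn - rp)[:, 1], -(rn - rp)[:, 0]])
        t = rn - r
        that = t / np.linalg.norm(t, axis=1)[:, None]
        qvec = that - np.roll(that, 1, axis=0)
        id1 = np.einsum("ij,ik->jk", r, pvec)
        id2 = np.einsum("ij,ik->jk", r, qvec)
        rhs2 = -np.einsum("ij,ik->jk", that, t)
        assert np.abs(id1 - geo.area * np.eye(2)).max() < 1e-10
        assert np.abs(id2 - rhs2).max() < 1e-10
        assert np.abs(id2 - id2.T).max() < 1e-10


class TestNetForces:
    def test_hex_lattice_at_equilibrium_area(self, params_iia):
        a6 = equilibrium_areas(6, params_iia)[0]
        lattice = hexagonal_lattice(a6, 4, 4)
        f = net_vertex_forces(lattice, params_iia)
        assert np.abs(f).max() < 1e-12

    def test_relaxed_monolayer_force_free(self, relaxed_monolayer, params_iia):
        f = net_vertex_forces(relaxed_monolayer, params_iia)
        assert np.abs(f).max() < 1e-6

    def test_trijunction_decomposition(self, params_iia):
        """Net vertex force equals the edge-wise composite-tension /
        pressure-difference decomposition at a trijunction."""
        net = perturbed_lattice(1.0, 4, 4, 0.05, seed=3)
        inc = build_incidence(net)
        fnet = net_vertex_forces(net, params_iia)
        pt = {a: pressure_tension(net.cell_geometry(a), params_iia)
              for a in range(net.n_cells)}
        partner = {}
        for halves in network_edges(net).values():
            (a1, i1), (a2, i2) = halves
            partner[(a1, i1)] = a2
            partner[(a2, i2)] = a1
        for j in [0, 7, 15]:
            f_oracle = np.zeros(2)
            for (a, i) in inc[j]:
                poly = net.cell_polygon(a)
                z = poly.shape[0]
                t = poly[(i + 1) % z] - poly[i]       # edge leaving j in cell a
                that = t / np.hypot(*t)
                n = np.array([t[1], -t[0]])           # t x z_hat
                b = partner[(a, i)]
                f_oracle += (that * (pt[a][1] + pt[b][1])
                             - 0.5 * n * (pt[a][0] - pt[b][0]))
            assert np.abs(f_oracle - fnet[j]).max() < 1e-12

    def test_finite_patch_pressure_balance(self):
        """Single square cell with P = P_ext and T = 0 is in equilibrium
        under the boundary-pressure terms."""
        side = 1.3
        gam = 0.1
        params = ModelParams(lam=-2 * gam * 4 * side, gam=gam,
                             p_ext=side**2 - 1.0)
        square = TissueNetwork(
            box=10.0,
            vertices=np.array([[1, 1], [1 + side, 1],
                               [1 + side, 1 + side], [1, 1 + side]]),
            cell_vertices=[np.arange(4)],
            cell_offsets=[np.zeros((4, 2), dtype=int)],
            periodic=False, peripheral_vertices=frozenset(range(4)))
        f = net_vertex_forces(square, params)
        assert np.abs(f).max() < 1e-12


class TestEnergy:
    def test_relaxed_cell_zero_energy(self):
        params = ModelParams(lam=-2 * 0.1 * 3.72242, gam=0.1)  # L_0 = mu_6
        net = hexagonal_lattice(1.0, 4, 4)
        assert total_energy(net, params) == pytest.approx(0.0, abs=1e-9)

    def test_energy_positive_off_equilibrium(self, small_voronoi, params_iia):
        assert total_energy(small_voronoi, params_iia) > 0


class TestCellStress:
    def test_trace_identities(self, rng, params_iia):
        for _ in range(5):
            geo = cell_shape(random_simple_polygon(rng))
            m = cell_stress(geo, params_iia)
            assert np.trace(m.stress) == pytest.approx(-2 * m.p_eff,
                                                       abs=1e-10)
            assert np.trace(m.deviator) == pytest.approx(0.0, abs=1e-10)
            assert np.abs(m.stress - m.stress.T).max() < 1e-10

    def test_regular_polygon_isotropic_stress(self, params_iia):
        m = cell_stress(cell_shape(regular_ngon(6, area=1.0)), params_iia)
        assert np.abs(m.deviator).max() < 1e-12
        assert np.allclose(m.stress, -m.p_eff * np.eye(2))

    def test_hexagon_effective_pressure_value(self):
        m = cell_stress(cell_shape(regular_ngon(6, area=1.0)),
                        ModelParams(-0.1, 0.1))
        assert m.p_eff == pytest.approx(0.59976, abs=1e-5)

    def test_rectangle_deviator(self, params_iia):
        m = cell_stress(cell_shape(RECT), params_iia)
        assert np.allclose(m.deviator, np.diag([-0.5, 0.5]), atol=1e-12)

    def test_dissipative_term_symmetric(self, rng, params_iia):
        poly = random_simple_polygon(rng)
        vel = rng.normal(size=poly.shape)
        m = cell_stress(cell_shape(poly), params_iia, vertex_velocities=vel)
        assert np.abs(m.stress - m.stress.T).max() < 1e-12

    def test_negative_area_rejected(self, params_iia):
        with pytest.raises(ValueError):
            cell_stress(cell_shape(RECT[::-1]), params_iia)


class TestTissueStress:
    def test_single_cell_subset(self, relaxed_monolayer, params_iia):
        m0 = cell_stress(relaxed_monolayer.cell_geometry(0), params_iia)
        ts = tissue_stress(relaxed_monolayer, params_iia, cell_subset=[0])
        assert np.allclose(ts, m0.stress)

    def test_zero_load_isotropic_part_vanishes(self, relaxed_monolayer,
                                               params_iia):
        ts = tissue_stress(relaxed_monolayer, params_iia)
        # trace part is controlled by the load condition
        assert abs(np.trace(ts) / 2) < 2e-3

    def test_empty_subset_rejected(self, relaxed_monolayer, params_iia):
        with pytest.raises(ValueError):
            tissue_stress(relaxed_monolayer, params_iia, cell_subset=[])


class TestAlignmentAndClassification:
    def test_rectangle_alignment_exact(self, params_iia):
        geo = cell_shape(RECT)
        m = cell_stress(geo, params_iia)
        assert stress_shape_alignment(geo, m) == pytest.approx(0.0, abs=1e-12)

    def test_regular_polygon_flagged_isotropic(self, params_iia):
        geo = cell_shape(regular_ngon(6, area=1.0))
        m = cell_stress(geo, params_iia)
        assert np.isnan(stress_shape_alignment(geo, m))

    def test_relaxed_monolayer_aligns(self, relaxed_monolayer, params_iia):
        """Stress-shape alignment across an equilibrium monolayer: strong in
        the median, looser for nearly round cells whose axes are poorly
        conditioned."""
        angles = []
        for a in range(relaxed_monolayer.n_cells):
            geo = relaxed_monolayer.cell_geometry(a)
            m = cell_stress(geo, params_iia)
            ang = stress_shape_alignment(geo, m)
            if np.isfinite(ang):
                angles.append(ang)
        angles = np.array(angles)
        assert np.median(angles) < 0.02
        assert np.quantile(angles, 0.9) < 0.1

    def test_tension_round_classification(self):
        # A > 1 with cortical tension: P_eff > 0, both eigenvalues negative
        m = cell_stress(cell_shape(regular_ngon(6, area=1.2)),
                        ModelParams(-0.1, 0.1))
        assert m.p_eff > 0
        assert classify_cell_stress(m) == "tension-round"

    def test_compression_round_classification(self):
        m = cell_stress(cell_shape(regular_ngon(6, area=0.2)),
                        ModelParams(-0.1, 0.1))
        assert m.p_eff < 0
        assert classify_cell_stress(m) == "compression-round"

    def test_elongated_mixed_signs(self):
        # thin sliver: the deviatoric part dominates the isotropic part
        rect = np.array([[1.0, -0.05], [1.0, 0.05],
                         [-1.0, 0.05], [-1.0, -0.05]])
        m = cell_stress(cell_shape(rect), ModelParams(-0.1, 0.1))
        s1, s2 = m.eigenvalues
        assert s1 * s2 < 0
        assert "elongated" in classify_cell_stress(m)
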