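import collections

import numpy as np
import pytest

from epivertex.dynamics import (RelaxationSettings, attempt_t1, attempt_t2,
                                enforce_isotropic_load, generate_monolayer,
                                relax, step_overdamped,
                                _mean_effective_pressure)
from epivertex.geometry import (build_incidence, network_edges,
                                validate_network)
from epivertex.mechanics import (ModelParams, cell_stress, net_vertex_forces,
                                 total_energy)
from epivertex.tessellation import (hexagonal_lattice, matern_ii_points,
                                    voronoi_network)
from epivertex.theory import equilibrium_areas


def triangle_fixture():
    """Periodic Voronoi network whose cell 0 is a triangle (deterministic)."""
    c = np.array([2.5, 2.5])
    ring = c + 0.8 * np.column_stack([
        np.cos(np.deg2rad([90, 210, 330])),
        np.sin(np.deg2rad([90, 210, 330]))])
    bg = matern_ii_points(5.0, 30, seed=8).points
    bg = bg[np.linalg.norm(bg - c, axis=1) > 1.6]
    net = voronoi_network(np.vstack([c, ring, bg]), 5.0)
    assert net.cell_vertices[0].size == 3
    return net


class TestRelax:
    def test_converges_from_voronoi(self, small_voronoi, params_iia):
        settings = RelaxationSettings(force_tolerance=1e-6)
        relaxed = relax(small_voronoi, params_iia, settings)
        assert relaxed.meta["max_force"] < 1e-6
        assert validate_network(relaxed).ok
        assert total_energy(relaxed, params_iia) < total_energy(
            small_voronoi, params_iia)

    def test_idempotent_on_equilibrium(self, relaxed_monolayer, params_iia):
        settings = RelaxationSettings()
        again = relax(relaxed_monolayer, params_iia, settings)
        assert again.meta.get("n_t1", 0) == relaxed_monolayer.meta.get("n_t1", 0)
        assert total_energy(again, params_iia) == pytest.approx(
            total_energy(relaxed_monolayer, params_iia), abs=1e-10)

    def test_no_short_edges_survive(self, relaxed_monolayer, params_iia):
        a6 = equilibrium_areas(6, params_iia)[0]
        threshold = 0.1 * np.sqrt(a6)
        for halves in network_edges(relaxed_monolayer).values():
            (a, i) = halves[0]
            poly = relaxed_monolayer.cell_polygon(a)
            z = poly.shape[0]
            length = np.hypot(*(poly[(i + 1) % z] - poly[i]))
            assert length >= threshold * 0.999


class TestT1:
    def test_fires_and_reassigns_classes(self, params_iia):
        lattice = hexagonal_lattice(1.0, 4, 4)
        settings = RelaxationSettings(t1_length_factor=2.0,
                                      t1_post_factor=1.001)
        key = next(iter(network_edges(lattice)))
        out, fired = attempt_t1(lattice, key, params_iia, settings)
        assert fired
        counts = collections.Counter(c.size for c in out.cell_vertices)
        assert counts == {6: 12, 5: 2, 7: 2}
        assert validate_network(out).ok
        assert all(len(v) == 3 for v in build_incidence(out).values())

    def test_above_threshold_is_noop(self, params_iia):
        lattice = hexagonal_lattice(1.0, 4, 4)
        settings = RelaxationSettings()  # threshold ~ 0.075 << edge ~ 0.62
        key = next(iter(network_edges(lattice)))
        out, fired = attempt_t1(lattice, key, params_iia, settings)
        assert not fired
        assert out is lattice


class TestT2:
    def test_extrusion_bookkeeping(self, params_iia):
        net = triangle_fixture()
        inc = build_incidence(net)
        neighbours = set()
        for j in net.cell_vertices[0]:
            neighbours |= {a for a, _ in inc[int(j)]}
        neighbours -= {0}
        before = {a: net.cell_vertices[a].size for a in neighbours}
        settings = RelaxationSettings(t2_area_factor=100.0)  # force firing
        out, fired = attempt_t2(net, 0, params_iia, settings)
        assert fired
        assert out.n_cells == net.n_cells - 1
        assert validate_network(out).ok
        for a in neighbours:
            assert out.cell_vertices[a - 1].size == before[a] - 1
        total = sum(out.cell_geometry(a).area for a in range(out.n_cells))
        assert total == pytest.approx(out.box_area, rel=1e-9)

    def test_above_threshold_is_noop(self, params_iia):
        net = triangle_fixture()
        out, fired = attempt_t2(net, 0, params_iia,
                                RelaxationSettings(t2_area_factor=1e-6))
        assert not fired

    def test_non_triangle_warns(self, params_iia, small_voronoi):
        cell = next(a for a, c in enumerate(small_voronoi.cell_vertices)
                    if c.size > 3)
        with pytest.warns(UserWarning, match="non-triangular"):
            _, fired = attempt_t2(small_voronoi, cell, params_iia,
                                  RelaxationSettings())
        assert not fired


class TestLoadControl:
    def test_hex_lattice_reaches_equilibrium_area(self, params_iia):
        a6 = equilibrium_areas(6, params_iia)[0]
        lattice = hexagonal_lattice(0.8 * a6, 4, 4)  # start compressed
        settings = RelaxationSettings(load_tolerance=1e-6)
        out = enforce_isotropic_load(lattice, params_iia, settings)
        areas = [out.cell_geometry(a).area for a in range(out.n_cells)]
        assert np.mean(areas) == pytest.approx(a6, rel=1e-4)

    def test_mean_peff_matches_pext(self):
        params = ModelParams(-0.2, 0.1, p_ext=0.2)
        net = generate_monolayer(params, 60, seed=4)
        assert abs(_mean_effective_pressure(net, params) - 0.2) < 1e-3


class TestOverdamped:
    def test_equilibrium_is_stationary(self, relaxed_monolayer, params_iia):
        out, vel = step_overdamped(relaxed_monolayer, params_iia, dt=0.01)
        assert np.abs(vel).max() < 1e-4
        assert np.abs(out.vertices - relaxed_monolayer.vertices).max() < 1e-6

    def test_energy_decreases_from_perturbation(self, relaxed_monolayer,
                                                params_iia):
        rng = np.random.default_rng(0)
        net = relaxed_monolayer.copy()
        net.vertices = net.vertices + rng.normal(scale=0.01,
                                                 size=net.vertices.shape)
        net.canonicalize()
        u0 = total_energy(net, params_iia)
        for _ in range(5):
            net, vel = step_overdamped(net, params_iia, dt=0.05)
        u1 = total_energy(net, params_iia)
        assert u1 < u0

    def test_velocities_feed_dissipative_stress(self, relaxed_monolayer,
                                                params_iia):
        rng = np.random.default_rng(0)
        net = relaxed_monolayer.copy()
        net.vertices = net.vertices + rng.normal(scale=0.01,
                                                 size=net.vertices.shape)
        net.canonicalize()
        _, vel = step_overdamped(net, params_iia, dt=0.01)
        geo = net.cell_geometry(0)
        cyc = net.cell_vertices[0]
        m = cell_stress(geo, params_iia, vertex_velocities=vel[cyc])
        assert np.abs(m.stress - m.stress.T).max() < 1e-12


class TestGenerateMonolayer:
    def test_seed_reproducibility(self, params_iia):
        a = generate_monolayer(params_iia, 40, seed=6)
        b = generate_monolayer(params_iia, 40, seed=6)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.box, b.box)

    def test_region_iii_refused(self):
        with pytest.raises(ValueError, match="region"):
            generate_monolayer(ModelParams(0.2, 0.2), 40, seed=0)

    def test_equilibrium_invariants(self, relaxed_monolayer, params_iia):
        assert validate_network(relaxed_monolayer).ok
        f = net_vertex_forces(relaxed_monolayer, params_iia)
        assert np.abs(f).max() < 1e-6
        assert abs(_mean_effective_pressure(relaxed_monolayer,
                                            params_iia)) < 1e-3

    def test_torus_euler_characteristic(self, relaxed_monolayer):
        net = relaxed_monolayer
        n_e = sum(c.size for c in net.cell_vertices) / 2
        assert n_e == int(n_e)
        assert net.n_vertices - n_e + net.n_cells == 0
        # all-trijunction torus: mean polygonal class exactly 6
        assert np.mean([c.size for c in net.cell_vertices]) == pytest.approx(6.0)

    def test_provenance_metadata(self, relaxed_monolayer):
        meta = relaxed_monolayer.meta
        assert meta["params"]["lam"] == -0.2
        assert meta["seed"] == 2
        assert "force_tolerance" in meta["settings"]
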