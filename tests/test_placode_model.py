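"""Wetting algebra, spring network, calibration, extrinsic force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placode.placode_model as pm
import placode.synthetic_data as sd
import placode.tissue_geometry as tg
import placode.vertex_dynamics as vd

finite = st.floats(-10, 10, allow_nan=False)
positive = st.floats(0.1, 10, allow_nan=False)


class TestWettingAlgebra:
    def test_basal_reference_self_normalizes_to_one(self):
        sigma_bb, K, S0b = 1.0, 1.0, 5.4
        denom = sigma_bb - 2 * K * S0b
        assert pm.wetting_coefficient(sigma_bb, K, S0b, (False, False),
                                      0.0, denom) == pytest.approx(1.0)

    def test_zero_numerator_gives_zero(self):
        K, S0 = 1.0, 3.0
        denom = -10.0
        assert pm.wetting_coefficient(2 * K * S0, K, S0, (False, False),
                                      0.0, denom) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(tg.ConfigurationError):
            pm.wetting_coefficient(1.0, 1.0, 1.0, (False, False), 0.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(sig=finite, K=positive, S0=positive, sk=finite,
           denom=st.floats(0.5, 20).map(lambda x: -x),
           fi=st.booleans(), fj=st.booleans())
    def test_roundtrip_is_exact_inverse(self, sig, K, S0, sk, denom, fi, fj):
        w = pm.wetting_coefficient(sig, K, S0, (fi, fj), sk, denom)
        back = pm.tension_from_wetting(w, K, S0, (fi, fj), sk, denom)
        assert back == pytest.approx(sig, abs=1e-12, rel=1e-12)

    def test_membrane_flags_add_spring_tension(self):
        base = pm.wetting_coefficient(0.0, 1.0, 3.0, (False, False), 2.0, -10.0)
        one = pm.wetting_coefficient(0.0, 1.0, 3.0, (True, False), 2.0, -10.0)
        two = pm.wetting_coefficient(0.0, 1.0, 3.0, (True, True), 2.0, -10.0)
        assert one - base == pytest.approx(-0.2)
        assert two - base == pytest.approx(-0.4)


class TestSpringNetwork:
    def test_no_membrane_cells_gives_empty_network(self, random_voronoi_mesh):
        net = pm.build_spring_network(random_voronoi_mesh, k_m=1.0)
        assert len(net.edges) == 0

    def test_single_basal_column_on_membrane_has_four_springs(self):
        mesh, _ = sd.make_flat_tissue(3, 3, (1.0, 1.0, 1.0), jitter=0)
        mesh = tg.assign_cell_types(mesh, (1.0, 1.0, 1.0), 0.0, (0.0, 0.0))
        net = pm.build_spring_network(mesh, k_m=1.0)
        # every basal cell contributes its shared square's 4 edges; edges
        # are shared between neighbouring squares -> 2 per cell on a 3x3 torus
        assert len(net.edges) == 2 * 9
        # each edge belongs to a {membrane, basal} face
        t = mesh.cell_types
        for e in map(tuple, net.edges):
            found = False
            for fid in pm.membrane_interface_faces(mesh):
                f = [int(v) for v in mesh.faces[fid]]
                if e[0] in f and e[1] in f:
                    found = True
            assert found

    def test_edge_set_matches_bruteforce_scan(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=1.0)
        expect = set()
        t = layered_mesh.cell_types
        for fid, o in enumerate(layered_mesh.face_owners):
            pair = {int(t[o[0]]), int(t[o[1]])}
            if pair in ({tg.MEMBRANE, tg.BASAL}, {tg.MEMBRANE, tg.PLACODE}):
                f = layered_mesh.faces[fid]
                for i in range(len(f)):
                    expect.add(tuple(sorted((int(f[i]), int(f[(i + 1) % len(f)])))))
        assert set(map(tuple, net.edges)) == expect

    def test_rest_springs_zero_energy_zero_force(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=4.0, rest_fraction=1.0)
        e, F = pm.spring_energy_forces(layered_mesh, net)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.abs(F).max() < 1e-12

    def test_single_stretched_spring_closed_form(self):
        mesh, _ = sd.make_flat_tissue(3, 3, sd.DEFAULT_LAYERS, jitter=0, seed=0)
        mesh = tg.assign_cell_types(mesh, sd.DEFAULT_LAYERS, 0.0, (0, 0))
        net = pm.build_spring_network(mesh, k_m=2.0, rest_fraction=1.0)
        d = 0.25
        net.l0 = net.l0.copy()
        net.l0[0] -= d  # one spring now stretched by d
        e, F = pm.spring_energy_forces(mesh, net)
        assert e == pytest.approx(0.5 * 2.0 * d ** 2)
        a, b = net.edges[0]
        assert np.linalg.norm(F[a]) == pytest.approx(2.0 * d, rel=1e-9)
        assert np.allclose(F[a], -F[b])

    def test_forces_match_finite_differences(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=3.0, rest_fraction=0.8)
        _, F = pm.spring_energy_forces(layered_mesh, net)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(12):
            v = int(rng.choice(net.edges.ravel()))
            ax = int(rng.integers(3))
            x0 = layered_mesh.X[v, ax]
            layered_mesh.X[v, ax] = x0 + h
            ep = vd.spring_energy(layered_mesh, net)
            layered_mesh.X[v, ax] = x0 - h
            em = vd.spring_energy(layered_mesh, net)
            layered_mesh.X[v, ax] = x0
            assert -(ep - em) / (2 * h) == pytest.approx(F[v, ax], abs=1e-5)


class TestMembraneCalibration:
    def test_zero_stiffness_zero_tension(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=0.0, rest_fraction=0.8)
        assert pm.calibrate_membrane_tension(layered_mesh, net) == pytest.approx(0.0)

    def test_too_few_strain_points_rejected(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=1.0, rest_fraction=0.8)
        with pytest.raises(tg.ConfigurationError):
            pm.calibrate_membrane_tension(layered_mesh, net, strains=(0.01, -0.01))

    def test_rest_network_has_negligible_tension(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=10.0, rest_fraction=1.0)
        sk = pm.calibrate_membrane_tension(layered_mesh, net)
        taut = pm.calibrate_membrane_tension(
            layered_mesh, pm.build_spring_network(layered_mesh, k_m=10.0,
                                                  rest_fraction=0.7))
        assert abs(sk) < 0.05 * abs(taut)

    def test_tension_invariant_to_strain_magnitude(self, layered_mesh):
        net = pm.build_spring_network(layered_mesh, k_m=20.0, rest_fraction=0.8)
        s1 = pm.calibrate_membrane_tension(layered_mesh, net)
        halved = tuple(0.5 * np.asarray(pm.DEFAULT_STRAINS))
        s2 = pm.calibrate_membrane_tension(layered_mesh, net, strains=halved)
        assert s2 == pytest.approx(s1, rel=0.05)

    def test_tension_monotone_in_prestrain(self, layered_mesh):
        vals = [pm.calibrate_membrane_tension(
            layered_mesh, pm.build_spring_network(layered_mesh, k_m=20.0,
                                                  rest_fraction=f))
            for f in (0.95, 0.8, 0.6)]
        assert vals[0] < vals[1] < vals[2]

    def test_choose_rest_length_trivial_target(self, layered_mesh):
        # target ratio 1 needs no spring tension -> mean edge length
        net = pm.build_spring_network(layered_mesh, k_m=5.0, rest_fraction=1.0)
        d = layered_mesh.box.min_image(
            layered_mesh.X[net.edges[:, 1]] - layered_mesh.X[net.edges[:, 0]])
        lbar = float(np.mean(np.linalg.norm(d, axis=1)))
        l0 = pm.choose_rest_length(layered_mesh, 5.0, 1.0, 3.0, 3.0)
        assert l0 == pytest.approx(lbar)

    def test_choose_rest_length_achieves_target_ratio(self, layered_mesh):
        lat = base = 5.0
        target = 2.0
        l0 = pm.choose_rest_length(layered_mesh, 60.0, target, lat, base)
        net = pm.build_spring_network(layered_mesh, k_m=60.0, rest_fraction=1.0)
        d = layered_mesh.box.min_image(
            layered_mesh.X[net.edges[:, 1]] - layered_mesh.X[net.edges[:, 0]])
        lbar = float(np.mean(np.linalg.norm(d, axis=1)))
        frac = l0 / lbar
        sk = pm.calibrate_membrane_tension(
            layered_mesh, pm.build_spring_network(layered_mesh, k_m=60.0,
                                                  rest_fraction=frac))
        assert (base + sk) / lat == pytest.approx(target, rel=0.02)


class TestExtrinsicForce:
    @pytest.fixture()
    def field(self):
        return pm.ExtrinsicForceField(f_r=2.0, center=np.array([5.0, 5.0, 0.0]),
                                      r_plac=1.5, decay=1.0)

    def test_magnitude_at_placode_edge(self, field):
        f = pm.extrinsic_force(np.array([5.0 + 1.5, 5.0, 0.3]), field)
        assert np.linalg.norm(f) == pytest.approx(2.0)

    def test_one_decay_length_reduces_by_e(self, field):
        f = pm.extrinsic_force(np.array([5.0 + 2.5, 5.0, 0.3]), field)
        assert np.linalg.norm(f) == pytest.approx(2.0 / np.e)

    def test_successive_decay_ratio_is_e(self, field):
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.uniform(1.6, 4.0)
            f1 = np.linalg.norm(pm.extrinsic_force(np.array([5 + d, 5, 0]), field))
            f2 = np.linalg.norm(pm.extrinsic_force(np.array([5 + d + 1, 5, 0]), field))
            assert f1 / f2 == pytest.approx(np.e, rel=1e-9)

    def test_points_inward_in_plane(self, field):
        p = np.array([7.0, 6.5, 0.4])
        f = pm.extrinsic_force(p, field)
        assert f[2] == 0.0
        assert np.dot(f[:2], p[:2] - field.center[:2]) < 0

    def test_center_singularity_returns_zero(self, field):
        assert np.allclose(pm.extrinsic_force(np.array([5.0, 5.0, 0.1]), field), 0)

    def test_only_basal_cell_vertices_feel_force(self, layered_mesh, field):
        F = field.vertex_forces(layered_mesh)
        arr = layered_mesh.compiled()
        t = layered_mesh.cell_types
        for v in range(0, len(layered_mesh.X), 13):
            owners = arr.vert_cells[arr.vert_off[v]:arr.vert_off[v + 1]]
            if not any(t[c] == tg.BASAL for c in owners):
                assert np.allclose(F[v], 0.0)


class TestScenarioSetup:
    def test_model1_dial_enters_lateral_tension(self):
        rng = np.random.default_rng(0)
        scn = pm.Scenario(kind="model1_intrinsic", sigma_pp_t=1.4, nx=4, ny=4,
                          placode_radius=1.0, relax_steps=20, n_steps=10)
        mesh, params, springs, noise, center = pm.setup_tissue(scn, rng)
        # raised lateral wetting -> placode-placode contact favoured
        assert params.sigma[tg.PLACODE, tg.PLACODE] < 0
        # neutral scenarios leave it at zero
        scn0 = pm.Scenario(kind="model2_extrinsic", nx=4, ny=4,
                           placode_radius=1.0, relax_steps=20, n_steps=10)
        _, p0, *_ = pm.setup_tissue(scn0, np.random.default_rng(0))
        assert p0.sigma[tg.PLACODE, tg.PLACODE] == 0.0

    def test_membrane_wetting_bias_raises_basal_apical_ratio(self):
        """More placode-membrane wetting expands the basal contact of the
        placode cells relative to their apical contact."""
        out = {}
        for ratio in (1.0, 2.5):
            scn = pm.Scenario(kind="model2_extrinsic", f_r=0.0,
                              ratio_pm_ps=ratio, sigma_ps_t=1.0, nx=4, ny=4,
                              placode_radius=1.0, n_steps=1000,
                              relax_steps=300, record_every=1000, seed=3)
            res = pm.run_scenario(scn)
            assert res.integrity
            out[ratio] = res.summary.basal_apical_ratio
        assert out[2.5] > out[1.0]


class TestPhaseDiagram:
    def test_row_count_and_roundtrip(self, tmp_path):
        scn = pm.Scenario(kind="model2_extrinsic", nx=4, ny=4, placode_radius=1.0,
                          n_steps=50, relax_steps=30, record_every=50)
        df = pm.phase_diagram({"f_r": [0.0, 0.5]}, "model2_extrinsic",
                              replicates=2, rng_seed=3, base=scn)
        assert len(df) == 4
        p = tmp_path / "pd.csv"
        df.to_csv(p, index=False)
        import pandas as pd
        back = pd.read_csv(p)
        assert np.allclose(back["curvature"], df["curvature"], equal_nan=True)
        assert list(back.columns) == list(df.columns)
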