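"""Measurement estimators against closed forms and brute-force oracles."""

import numpy as np
import pytest

import placode.morphometrics as mm
import placode.synthetic_data as sd
import placode.tissue_geometry as tg


class TestParaboloidFit:
    def test_plane_gives_zero_curvature(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-1, 1, 50), rng.uniform(-1, 1, 50),
                               np.zeros(50)])
        fit = mm.fit_paraboloid(pts)
        assert fit.a == pytest.approx(0, abs=1e-10)
        assert mm.gaussian_curvature_at_deepest(fit) == pytest.approx(0, abs=1e-10)

    @pytest.mark.parametrize("R", [2.0, 5.0, -3.0])
    def test_exact_quadratic_recovery(self, R):
        pts, _ = sd.make_paraboloid_cloud(R, n=120, noise_sd=0.0, seed=1)
        fit = mm.fit_paraboloid(pts)
        assert fit.a == pytest.approx(1 / (2 * R), abs=1e-8)
        assert fit.b == pytest.approx(1 / (2 * R), abs=1e-8)
        assert fit.c == pytest.approx(0, abs=1e-8)
        K = mm.gaussian_curvature_at_deepest(fit)
        assert abs(K) == pytest.approx(1 / R ** 2, rel=1e-6)
        assert np.sign(K) == np.sign(R)  # bowls positive, domes negative

    def test_noisy_recovery_within_five_percent_median(self):
        R = 3.0
        errs = []
        for seed in range(100):
            pts, _ = sd.make_paraboloid_cloud(R, n=200, noise_sd=0.01 * R,
                                              seed=seed)
            fit = mm.fit_paraboloid(pts)
            errs.append(abs(fit.a - 1 / (2 * R)) / (1 / (2 * R)))
        assert np.median(errs) < 0.05

    def test_axisymmetric_mode_from_cross_section(self):
        R = 4.0
        rho = np.linspace(-2, 2, 41)
        pts = np.column_stack([rho, rho ** 2 / (2 * R)])
        fit = mm.fit_paraboloid(pts, "axisymmetric_from_2d")
        assert fit.a == fit.b == pytest.approx(1 / (2 * R), abs=1e-10)
        assert fit.c == fit.d == fit.e == 0.0

    def test_rank_deficient_design_raises(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10)  # collinear
        with pytest.raises(mm.FitError):
            mm.fit_paraboloid(pts)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_curvature_matches_formula_for_random_quadric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0.2, 1, 2)
        c = rng.uniform(-0.2, 0.2)  # keep 4ab - c^2 > 0 (bowl, not saddle)
        x, y = rng.uniform(-1, 1, (2, 80))
        z = a * x ** 2 + b * y ** 2 + c * x * y + 0.3 * x - 0.1 * y + 2
        fit = mm.fit_paraboloid(np.column_stack([x, y, z]))
        assert mm.gaussian_curvature_at_deepest(fit) == pytest.approx(
            4 * a * b - c ** 2, rel=1e-6)

    def test_rotation_invariance_about_z(self):
        pts, _ = sd.make_paraboloid_cloud(3.0, n=150, noise_sd=0.0, seed=4)
        th = 0.7
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        K1 = mm.gaussian_curvature_at_deepest(mm.fit_paraboloid(pts))
        K2 = mm.gaussian_curvature_at_deepest(mm.fit_paraboloid(pts @ Rz.T))
        assert K1 == pytest.approx(K2, rel=1e-8)


class TestElongation:
    def test_flat_fit_returns_mean_height(self):
        pts = np.column_stack([np.random.default_rng(0).uniform(-1, 1, (30, 2)),
                               np.zeros(30)])
        fit = mm.fit_paraboloid(pts)
        assert mm.placode_elongation(fit, [1.0, 1.2, 0.8]) == pytest.approx(1.0)

    def test_bowl_depth_adds_to_height(self):
        # bowl of known apex-to-rim depth D over footprint radius 2
        R, r_max = 2.0, 2.0
        pts, _ = sd.make_paraboloid_cloud(R, n=4000, noise_sd=0.0, seed=0,
                                          extent=r_max)
        fit = mm.fit_paraboloid(pts)
        # rim = outermost 10% by radius; expected depth ~ mean rim z
        r = np.hypot(pts[:, 0], pts[:, 1])
        rim = np.sort(r)[int(np.ceil(0.9 * len(r))) - 1:]
        D = float(np.mean(rim ** 2 / (2 * R)))
        e = mm.placode_elongation(fit, [0.5])
        assert e == pytest.approx(D + 0.5, rel=0.05)


class TestBasalApicalRatio:
    def test_prism_column_is_unity(self):
        mesh, _ = sd.make_flat_tissue(3, 3, sd.DEFAULT_LAYERS, jitter=0)
        mesh = tg.assign_cell_types(mesh, sd.DEFAULT_LAYERS, 0.9, (1.5, 1.5))
        basal = np.flatnonzero(mesh.cell_types == tg.BASAL)[0]
        assert mm.basal_apical_ratio(mesh, basal) == pytest.approx(1.0)

    def test_matches_bruteforce_face_scan(self, layered_mesh):
        from placode.vertex_dynamics import _face_area

        mesh = layered_mesh
        cid = int(np.flatnonzero(mesh.cell_types == tg.PLACODE)[0])
        basal = apical = 0.0
        for fid in mesh.cells[cid]:
            o = mesh.face_owners[fid]
            other = o[1] if o[0] == cid else o[0]
            t = mesh.cell_types[other]
            if t == tg.MEMBRANE:
                basal += _face_area(mesh, fid)
            elif t == tg.SUPRABASAL:
                apical += _face_area(mesh, fid)
        assert mm.basal_apical_ratio(mesh, cid) == pytest.approx(basal / apical)

    def test_no_apical_contact_raises(self):
        # a basal cell sandwiched between membrane layers never touches
        # suprabasal cells, so its basal/apical ratio is undefined
        mesh, _ = sd.make_flat_tissue(3, 3, (1.0, 1.0, 1.0), jitter=0)
        layer = tg.layer_of_seeds((1.0, 1.0, 1.0), mesh.seed_points[:, 2])
        mesh.cell_types[:] = tg.MEMBRANE
        mesh.cell_types[layer == 1] = tg.BASAL
        basal = int(np.flatnonzero(mesh.cell_types == tg.BASAL)[0])
        with pytest.raises(mm.UndefinedRatioError):
            mm.basal_apical_ratio(mesh, basal)


class TestDivergence:
    def test_uniform_translation_zero_divergence(self):
        fld, _ = sd.make_flow_field("uniform", n=32)
        assert np.allclose(mm.divergence_map(fld), 0.0, atol=1e-12)

    def test_radial_sink_gives_minus_two_k(self):
        k = 0.37
        fld, _ = sd.make_flow_field("radial_sink", n=32, k=k)
        div = mm.divergence_map(fld)
        assert np.allclose(div[1:-1, 1:-1], -2 * k, atol=1e-10)

    def test_matches_dense_stencil_oracle_on_smooth_field(self):
        n, h = 48, 0.5
        x = h * np.arange(n)
        X, Y = np.meshgrid(x, x)
        u = np.sin(0.2 * X) * np.cos(0.1 * Y)
        v = np.cos(0.15 * X) * Y * 0.05
        fld = mm.VectorField2D(np.zeros(2), h, np.stack([u, v], axis=-1))
        div = mm.divergence_map(fld)
        # independent explicit central stencil
        oracle = ((np.roll(u, -1, 1) - np.roll(u, 1, 1))
                  + (np.roll(v, -1, 0) - np.roll(v, 1, 0))) / (2 * h)
        assert np.allclose(div[1:-1, 1:-1], oracle[1:-1, 1:-1], atol=1e-10)

    def test_divergence_linear_in_field(self):
        f1, _ = sd.make_flow_field("radial_sink", n=24, k=0.2)
        f2, _ = sd.make_flow_field("rotational", n=24, omega=0.3)
        comb = mm.VectorField2D(f1.origin, f1.spacing, 2 * f1.vec + 3 * f2.vec)
        d = mm.divergence_map(comb)
        expect = 2 * mm.divergence_map(f1) + 3 * mm.divergence_map(f2)
        assert np.allclose(d, expect, atol=1e-10)

    def test_masked_nodes_propagate(self):
        fld, _ = sd.make_flow_field("radial_sink", n=16, k=0.1)
        fld.vec[8, 8] = np.nan
        div = mm.divergence_map(fld)
        assert np.isnan(div[8, 7]) and np.isnan(div[7, 8]) and np.isnan(div[8, 8])


class TestRoiMean:
    def test_constant_divergence_any_roi(self):
        div = np.full((20, 20), 1.7)
        roi = np.zeros((20, 20), bool)
        roi[3:9, 4:12] = True
        assert mm.roi_mean_divergence(div, roi) == pytest.approx(1.7)

    def test_fully_invalid_roi_raises(self):
        div = np.full((10, 10), np.nan)
        roi = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            mm.roi_mean_divergence(div, roi)

    def test_half_and_half_straddle(self):
        div = np.zeros((40, 40))
        div[:, :20] = 1.0
        div[:, 20:] = 3.0
        roi = np.zeros((40, 40), bool)
        roi[10:30, 12:28] = True
        assert mm.roi_mean_divergence(div, roi) == pytest.approx(2.0)


class TestTraceAlignment:
    def test_identical_traces_zero_sem(self):
        tr = np.sin(np.linspace(0, 6, 60)) - 0.5
        off, mean, sem, _ = mm.align_divergence_traces([tr, tr, tr])
        assert np.allclose(sem, 0.0)
        i0 = np.flatnonzero(off == 0)[0]
        assert mean[i0] == pytest.approx(tr.min())

    def test_known_lags_recovered(self):
        base = np.zeros(80)
        base[40] = -5.0  # sharp negative peak
        traces, lags = [], [0, 7, 13]
        for lag in lags:
            traces.append(np.roll(base, lag))
        _, _, _, peaks = mm.align_divergence_traces(traces)
        assert [p - peaks[0] for p in peaks] == [0, 7, 13]

    def test_positive_trace_excluded_with_warning(self):
        good = np.zeros(50)
        good[25] = -3.0
        bad = np.abs(np.sin(np.linspace(0, 3, 50))) + 0.1
        with pytest.warns(UserWarning):
            off, mean, sem, peaks = mm.align_divergence_traces([good, bad])
        assert len(peaks) == 1


class TestInsilicoFlow:
    def _frames(self, disp, n=64, seed=0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 8, (n, 2))
        ids = np.arange(n)
        plac = np.zeros(n, bool)
        plac[:10] = True
        f1 = {"ids": ids, "xy": xy, "placode": plac}
        f2 = {"ids": ids, "xy": xy + disp(xy), "placode": plac}
        return f1, f2

    def test_static_tissue_zero_field(self):
        box = tg.PeriodicBox((8.0, 8.0, 1.0))
        f1, f2 = self._frames(lambda xy: 0.0 * xy)
        fld = mm.insilico_flow(f1, f2, box, spacing=2.0)
        v = fld.vec[np.isfinite(fld.vec)]
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_rigid_translation_without_drift_removal(self):
        box = tg.PeriodicBox((8.0, 8.0, 1.0))
        f1, f2 = self._frames(lambda xy: np.broadcast_to([0.3, -0.1], xy.shape))
        fld = mm.insilico_flow(f1, f2, box, spacing=2.0, drift_removal=False)
        u = fld.vec[..., 0][np.isfinite(fld.vec[..., 0])]
        v = fld.vec[..., 1][np.isfinite(fld.vec[..., 1])]
        assert np.allclose(u, 0.3) and np.allclose(v, -0.1)

    def test_radial_contraction_gives_minus_two_k(self):
        box = tg.PeriodicBox((8.0, 8.0, 1.0))
        k, c = 0.05, np.array([4.0, 4.0])
        f1, f2 = self._frames(lambda xy: -k * (xy - c), n=4000)
        fld = mm.insilico_flow(f1, f2, box, spacing=1.0, drift_removal=False)
        div = mm.divergence_map(fld)
        roi = mm.circular_roi(fld, c, 2.5)
        assert mm.roi_mean_divergence(div, roi) == pytest.approx(-2 * k, rel=0.2)


class TestRecoil:
    def test_zero_field_zero_profile(self):
        fld, cut, _, _ = sd.make_ablation_field("line_cut", A=0.0, n=64)
        centers, prof, total = mm.recoil_profile(fld, cut)
        assert total == 0.0
        assert np.allclose(prof[np.isfinite(prof)], 0.0, atol=1e-12)

    def test_step_recoil_total_is_twice_amplitude(self):
        u = 0.8
        fld, cut, _, _ = sd.make_ablation_field("line_cut", A=u, lam=1e9,
                                                inward_fraction=1.0, n=64)
        _, _, total = mm.recoil_profile(fld, cut)
        assert total == pytest.approx(2 * u, rel=0.05)

    def test_exponential_profile_recovered(self):
        A, lam = 1.0, 8.0
        fld, cut, _, _ = sd.make_ablation_field("line_cut", A=A, lam=lam, n=128)
        centers, prof, _ = mm.recoil_profile(fld, cut, n_bins=40)
        sel = (centers > 2) & (centers < 30) & np.isfinite(prof)
        assert np.allclose(prof[sel], A * np.exp(-centers[sel] / lam), atol=0.06)

    def test_direction_conventions_on_straight_cut(self):
        n = 96
        cut = np.zeros((n, n), bool)
        cut[:, 46:50] = True
        comp = np.zeros((n, n), bool)
        comp[:, 60:] = True  # compartment right of the cut
        away = np.zeros((n, n, 2))
        away[..., 0] = 1.0  # uniform displacement away from the cut
        fld = mm.VectorField2D(np.zeros(2), 1.0, away)
        ang = mm.recoil_direction(fld, comp, cut, dilate_px=30,
                                  convention="fibroblast")
        assert ang == pytest.approx(90.0, abs=1e-6)
        toward = mm.VectorField2D(np.zeros(2), 1.0, -away)
        assert mm.recoil_direction(toward, comp, cut, dilate_px=30) == \
            pytest.approx(-90.0, abs=1e-6)
        par = np.zeros((n, n, 2))
        par[..., 1] = 1.0
        fld_par = mm.VectorField2D(np.zeros(2), 1.0, par)
        ang_par = mm.recoil_direction(fld_par, comp, cut, dilate_px=30)
        assert abs(ang_par) == pytest.approx(0.0, abs=1e-6) or \
            abs(ang_par) == pytest.approx(180.0, abs=1e-6)
        # placode convention: 0 toward, 180 away
        assert abs(mm.recoil_direction(toward, comp, cut, dilate_px=30,
                                       convention="placode")) == pytest.approx(0.0, abs=1e-6)
        assert abs(mm.recoil_direction(fld, comp, cut, dilate_px=30,
                                       convention="placode")) == pytest.approx(180.0, abs=1e-6)

    def test_mean_direction_matches_bruteforce_average(self):
        rng = np.random.default_rng(3)
        n = 96
        cut = np.zeros((n, n), bool)
        cut[:, 46:50] = True
        comp = np.zeros((n, n), bool)
        comp[:, 55:] = True
        vec = rng.standard_normal((n, n, 2))
        fld = mm.VectorField2D(np.zeros(2), 1.0, vec)
        from scipy import ndimage
        roi = ndimage.binary_dilation(cut, iterations=20) & comp
        vbar = vec[roi].mean(axis=0)
        ang = mm.recoil_direction(fld, comp, cut, dilate_px=20)
        # reconstruct from the same mean vector: chat=(0,1), nhat=(1,0)
        assert ang == pytest.approx(
            float(np.degrees(np.arctan2(vbar[0], vbar[1]))), abs=1e-6) or \
            ang == pytest.approx(
            float(np.degrees(np.arctan2(vbar[0], -vbar[1]))), abs=1e-6)


class TestSox9Stats:
    def test_three_point_closed_form(self):
        pat = mm.PointPattern2D(points=[[0, 0], [10, 0], [0, 10]],
                                center=[0, 0])
        st = mm.sox9_stats(pat)
        assert st.count == 3
        assert st.mean_distance == pytest.approx(20 / 3)
        assert st.hull_area == pytest.approx(50.0)
        # boundary-inclusive closed disk: all three points inside
        assert st.local_density == pytest.approx(3 / (np.pi * 100))

    def test_single_point_degenerate_hull(self):
        st = mm.sox9_stats(mm.PointPattern2D(points=[[5, 5]], center=[5, 5]))
        assert st.count == 1 and st.mean_distance == 0
        assert st.hull_area == 0.0 and st.hull_degenerate

    def test_uniform_disk_mean_distance_two_thirds_R(self):
        R = 30.0
        vals = []
        for seed in range(20):
            pat, _ = sd.make_point_pattern(200, "uniform_disk", R=R, seed=seed)
            vals.append(mm.sox9_stats(pat).mean_distance)
        assert np.mean(vals) == pytest.approx(2 * R / 3, rel=0.02)

    def test_rigid_motion_invariance(self):
        pat, _ = sd.make_point_pattern(60, "ring", r0=15, sigma=2, seed=7)
        st = mm.sox9_stats(pat)
        th = 1.1
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = mm.PointPattern2D(points=pat.points @ Rm.T + [3, -4],
                                  center=Rm @ pat.center + [3, -4])
        st2 = mm.sox9_stats(moved)
        assert st2.count == st.count
        assert st2.mean_distance == pytest.approx(st.mean_distance, rel=1e-9)
        assert st2.hull_area == pytest.approx(st.hull_area, rel=1e-9)
        assert st2.local_density == pytest.approx(st.local_density)

    def test_hull_invariant_under_permutation(self):
        pat, _ = sd.make_point_pattern(40, "uniform_disk", R=10, seed=9)
        perm = np.random.default_rng(0).permutation(40)
        st1 = mm.sox9_stats(pat)
        st2 = mm.sox9_stats(mm.PointPattern2D(points=pat.points[perm],
                                              center=pat.center))
        assert st1.hull_area == pytest.approx(st2.hull_area)
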