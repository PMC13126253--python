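"""Generator correctness: geometry rasterization, step statistics,
confinement, rendering, and nucleoid images."""

import numpy as np
import pytest
from scipy import stats

from nucleotrack.models import MobilityStateModel
from nucleotrack.synthetic import (
    CONDITION_PRESETS,
    SimulatedDataset,
    build_transition_matrix,
    make_condition_model,
    make_geometry,
    render_frames,
    simulate_confined_trajectories,
    simulate_nucleoid_image,
    simulate_steps,
)


class TestGeometry:
    def test_feret_length_matches_request(self):
        from nucleotrack.morphology import feret_diameters

        g = make_geometry(3.76, 1.0, 49.0)
        fmax, _ = feret_diameters(g.mask)
        assert abs(fmax * 0.049 - 3.76) <= 0.049  # within one pixel

    def test_disk_degenerates_to_point_midline(self):
        g = make_geometry(1.0, 1.0, 49.0)
        assert len(g.midline) == 1
        assert g.length == g.width == 1.0

    def test_rasterized_area_matches_analytic(self):
        g = make_geometry(3.76, 1.0, 49.0)
        raster = g.mask.sum() * 0.049**2
        analytic = (3.76 - 1.0) * 1.0 + np.pi * 0.5**2
        assert analytic == pytest.approx(g.area)
        assert raster == pytest.approx(analytic, rel=0.02)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            make_geometry(-1.0, 1.0)
        with pytest.raises(ValueError):
            make_geometry(2.0, 0.0)


class TestTransitionMatrix:
    @pytest.mark.parametrize("name", sorted(CONDITION_PRESETS))
    def test_presets_are_stationary_and_stochastic(self, name):
        m = make_condition_model(name)
        assert np.allclose(m.T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m.T >= 0)
        assert np.allclose(m.stationary_distribution(), m.pi, atol=1e-6)

    def test_detailed_balance_reverse_entry(self):
        pi = np.array([0.3, 0.7])
        T = build_transition_matrix(pi, {(0, 1): 0.1})
        assert T[1, 0] == pytest.approx(0.3 * 0.1 / 0.7)

    def test_overfull_row_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(np.array([0.9, 0.1]), {(0, 1): 0.2})


class TestSimulateSteps:
    def test_mean_squared_displacement_matches_analytic(self, one_state_model):
        n = 100_000
        s = simulate_steps(one_state_model, n, seed=11)
        sq = s.squared_displacements
        expect = 4 * 0.1 * 0.04  # 0.016 um^2
        se = sq.std() / np.sqrt(n)
        assert abs(sq.mean() - expect) < 3 * se

    def test_identity_transitions_freeze_labels(self):
        m = MobilityStateModel(D=[0.01, 1.0], pi=[0.4, 0.6],
                               T=np.eye(2), tau=0.04)
        s = simulate_steps(m, 5000, seed=3, steps_per_track=10)
        lab = s.labels.reshape(-1, 10)
        assert np.all(lab == lab[:, :1])

    def test_stationary_occupancy_recovered(self):
        m = make_condition_model("wt-stationary")
        n = 100_000
        s = simulate_steps(m, n, seed=4)
        freq = np.bincount(s.labels, minlength=3) / n
        for k in range(3):
            se = np.sqrt(m.pi[k] * (1 - m.pi[k]) / n)
            # steps within a trajectory are correlated; allow 6 binomial SEs
            assert abs(freq[k] - m.pi[k]) < 6 * se

    def test_step_components_have_zero_mean(self, two_state_model):
        s = simulate_steps(two_state_model, 50_000, seed=5)
        for axis in range(2):
            comp = s.dxy[:, axis]
            assert abs(comp.mean()) < 3 * comp.std() / np.sqrt(len(comp))

    def test_seed_determinism(self, two_state_model):
        a = simulate_steps(two_state_model, 2000, seed=9)
        b = simulate_steps(two_state_model, 2000, seed=9)
        assert np.array_equal(a.dxy, b.dxy) and np.array_equal(a.labels, b.labels)

    def test_rejects_zero_steps(self, one_state_model):
        with pytest.raises(ValueError):
            simulate_steps(one_state_model, 0, seed=0)


class TestConfined:
    def test_zero_diffusion_is_static(self, std_geometry):
        m = MobilityStateModel(D=[0.0], pi=[1.0], T=[[1.0]], tau=0.04)
        ds = simulate_confined_trajectories(m, std_geometry, 20, 100, seed=6)
        for pos in ds.positions:
            assert np.allclose(pos, pos[0])

    def test_positions_stay_inside_mask(self, std_geometry, one_state_model):
        ds = simulate_confined_trajectories(one_state_model, std_geometry,
                                            50, 300, seed=7)
        from nucleotrack.synthetic import _axis_endpoints, _dist_to_axis

        px = std_geometry.pixel_size / 1000.0
        ny, nx = std_geometry.mask.shape
        a, b, rad = _axis_endpoints(std_geometry)
        pts = np.concatenate(ds.positions)
        d, _ = _dist_to_axis(pts, a, b)
        assert np.all(d <= rad + 1e-9)  # inside the continuous cell wall
        # the rasterized mask can exclude a thin boundary rim
        c = np.clip((pts[:, 0] / px).astype(int), 0, nx - 1)
        r = np.clip((pts[:, 1] / px).astype(int), 0, ny - 1)
        assert std_geometry.mask[r, c].mean() > 0.95

    def test_long_run_is_uniform_over_cell(self, std_geometry):
        # the uniform law is stationary for reflected Brownian motion, so
        # any single time slice is uniform; one point per molecule keeps
        # the chi-square samples independent
        m = MobilityStateModel(D=[0.15], pi=[1.0], T=[[1.0]], tau=0.04)
        ds = simulate_confined_trajectories(
            m, std_geometry, 3000, 60, seed=8,
            mean_activation_frame=1.0, mean_on_frames=40.0)
        pts = np.stack([pos[min(20, len(pos) - 1)] for pos in ds.positions])
        # coarse 4x8 bins over the bounding box, masked to the cell
        from nucleotrack.synthetic import _axis_endpoints, _dist_to_axis
        a, b, r = _axis_endpoints(std_geometry)
        xlo, xhi = a[0] - r, b[0] + r
        ylo, yhi = a[1] - r, a[1] + r
        H, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=[8, 4],
                                   range=[[xlo, xhi], [ylo, yhi]])
        # expected mass per bin from fine numeric integration of the shape
        gx = np.linspace(xlo, xhi, 400)
        gy = np.linspace(ylo, yhi, 200)
        GX, GY = np.meshgrid(gx, gy)
        inside = _dist_to_axis(np.stack([GX.ravel(), GY.ravel()], 1), a, b)[0] <= r
        W = inside.reshape(GY.shape).astype(float)
        exp_mass = np.array([
            [W[(gy >= ye[j]) & (gy < ye[j + 1])][:, (gx >= xe[i]) & (gx < xe[i + 1])].sum()
             for j in range(4)] for i in range(8)])
        exp_mass = exp_mass / exp_mass.sum() * H.sum()
        sel = exp_mass > 30
        chi2 = ((H[sel] - exp_mass[sel]) ** 2 / exp_mass[sel]).sum()
        pval = stats.chi2.sf(chi2, df=sel.sum() - 1)
        assert pval > 0.01


class TestRender:
    def _single_emitter(self, geometry, xy):
        m = MobilityStateModel(D=[0.0], pi=[1.0], T=[[1.0]], tau=0.04)
        return SimulatedDataset(
            positions=[np.array([xy])], frames_idx=[np.array([0])],
            states=[np.empty(0, int)], geometry=geometry, model=m, seed=0)

    def test_peak_at_emitter_pixel(self, std_geometry):
        ds = self._single_emitter(std_geometry, (1.503, 0.677))
        fr = render_frames(ds, photon_count=5000, background=0, noise=False)[0]
        r, c = np.unravel_index(fr.argmax(), fr.shape)
        assert (c, r) == (int(1.503 / 0.049), int(0.677 / 0.049))

    def test_noiseless_photon_conservation(self, std_geometry):
        ds = self._single_emitter(std_geometry, (1.9, 0.7))
        bg, n_photons = 3.0, 8000.0
        fr = render_frames(ds, photon_count=n_photons, background=bg,
                           noise=False)[0].astype(float)
        expect = n_photons + bg * fr.size
        assert fr.sum() == pytest.approx(expect, rel=2e-3)

    def test_localization_round_trip(self, std_geometry):
        from nucleotrack.detect import find_candidates, fit_spot

        ds = self._single_emitter(std_geometry, (1.503, 0.677))
        fr = render_frames(ds, psf_sigma=150, photon_count=50_000,
                           background=2, noise=False)[0].astype(float)
        (peak,) = find_candidates(fr)
        loc = fit_spot(fr, peak, pixel_size=49.0)
        assert abs(loc.x - 1503.0) < 0.05 * 49
        assert abs(loc.y - 677.0) < 0.05 * 49
        assert loc.sigma_fit == pytest.approx(150.0, rel=0.02)

    def test_rejects_bad_psf(self, std_geometry):
        ds = self._single_emitter(std_geometry, (1.9, 0.7))
        with pytest.raises(ValueError):
            render_frames(ds, psf_sigma=0.0)


class TestNucleoidImage:
    def test_true_mask_pixel_count(self, std_geometry):
        img, nuc = simulate_nucleoid_image(std_geometry, 0.5, 100, 1000,
                                           (30, 50), seed=1)
        assert abs(nuc.sum() - round(0.5 * std_geometry.mask.sum())) <= 1

    def test_equal_means_flagged_degenerate_downstream(self, std_geometry):
        from nucleotrack.morphology import compute_occupancy

        img, _ = simulate_nucleoid_image(std_geometry, 0.5, 200, 200,
                                         (30, 30), seed=2)
        occ = compute_occupancy(img, std_geometry.mask)
        assert occ.degenerate and occ.occupancy is None

    def test_rejects_bad_fraction(self, std_geometry):
        with pytest.raises(ValueError):
            simulate_nucleoid_image(std_geometry, 1.5, 0, 1, (1, 1), seed=0)
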