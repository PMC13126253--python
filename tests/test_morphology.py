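"""PALM rendering, nucleoid occupancy, and mask metrics."""

import numpy as np
import pytest

from nucleotrack.models import Localization
from nucleotrack.morphology import (cell_metrics, compute_occupancy,
                                    feret_diameters, render_palm)
from nucleotrack.synthetic import make_geometry, simulate_nucleoid_image


def _loc(x_nm, y_nm, ci95):
    return Localization(frame=0, x=x_nm, y=y_nm, sigma_fit=150.0,
                        amplitude=10.0, background=1.0, ci95=ci95,
                        fit_error=0.01)


class TestRenderPalm:
    def test_imprecise_localization_excluded(self):
        locs = [_loc(500, 500, 40.0), _loc(700, 700, 100.0)]
        palm = render_palm(locs, shape=(40, 40), ci_max=80.0)
        assert palm.n_localizations == 1

    def test_unit_mass_kernel(self):
        palm = render_palm([_loc(980, 980, 40.0)], shape=(40, 40))
        assert palm.intensity.sum() == pytest.approx(1.0, abs=1e-6)

    def test_linearity_of_identical_localizations(self):
        one = render_palm([_loc(980, 980, 40.0)], shape=(40, 40))
        two = render_palm([_loc(980, 980, 40.0)] * 2, shape=(40, 40))
        assert np.allclose(two.intensity, 2 * one.intensity)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            render_palm([_loc(500, 500, 120.0)], shape=(40, 40))


@pytest.fixture(scope="module")
def geometry():
    return make_geometry(3.76, 1.0, 49.0)


class TestOccupancy:

    def test_recovers_known_fraction(self, geometry):
        img, nuc = simulate_nucleoid_image(geometry, 0.5, 100, 1000,
                                           (30, 50), seed=1)
        occ = compute_occupancy(img, geometry.mask)
        truth = nuc.sum() / geometry.mask.sum()
        assert not occ.degenerate
        assert occ.occupancy == pytest.approx(truth, abs=0.03)
        assert occ.threshold == pytest.approx(0.5 * occ.mu2)

    def test_monotone_in_true_fraction(self, geometry):
        est = []
        for frac in (0.3, 0.5, 0.7):
            img, _ = simulate_nucleoid_image(geometry, frac, 100, 1000,
                                             (30, 50), seed=2)
            occ = compute_occupancy(img, geometry.mask)
            assert occ.occupancy == pytest.approx(frac, abs=0.03)
            est.append(occ.occupancy)
        assert est[0] < est[1] < est[2]

    def test_occupancy_one_when_all_above_threshold(self, geometry):
        # modes at 600 and 1000: the threshold 500 sits below both
        img, _ = simulate_nucleoid_image(geometry, 0.5, 600, 1000,
                                         (15, 15), seed=3)
        occ = compute_occupancy(img, geometry.mask)
        assert not occ.degenerate
        assert occ.occupancy == 1.0

    def test_uniform_image_degenerate(self, geometry):
        occ = compute_occupancy(np.full(geometry.mask.shape, 5.0),
                                geometry.mask)
        assert occ.degenerate and occ.occupancy is None

    def test_affine_intensity_invariance(self, geometry):
        img, _ = simulate_nucleoid_image(geometry, 0.4, 100, 1000,
                                         (30, 50), seed=4)
        a = compute_occupancy(img, geometry.mask)
        b = compute_occupancy(3.5 * img, geometry.mask)
        assert a.occupancy == pytest.approx(b.occupancy, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_occupancy(np.zeros((10, 10)),
                              np.zeros((10, 10), dtype=bool))


class TestCellMetrics:
    def test_rectangle_geometry(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[10:30, 10:90] = True  # 20 x 80 px
        m = cell_metrics(mask, 49.0)
        assert m["area"] == pytest.approx(1600 * 0.049**2)
        assert m["length"] == pytest.approx(np.hypot(80, 20) * 0.049, abs=0.049)
        assert m["width"] == pytest.approx(20 * 0.049, abs=0.049)

    def test_disk_feret_is_diameter(self):
        yy, xx = np.mgrid[:41, :41]
        mask = (xx - 20.0) ** 2 + (yy - 20.0) ** 2 <= 15.0**2
        fmax, fmin = feret_diameters(mask)
        assert fmax == pytest.approx(30.0, abs=1.5)
        assert fmin == pytest.approx(30.0, abs=1.5)

    def test_spherocylinder_round_trip(self):
        g = make_geometry(3.76, 1.0, 49.0)
        m = cell_metrics(g.mask, 49.0)
        assert m["length"] == pytest.approx(3.76, rel=0.02)
        assert m["width"] == pytest.approx(1.0, rel=0.06)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[12:15, 12:15] = True
        with pytest.raises(ValueError):
            cell_metrics(mask)
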