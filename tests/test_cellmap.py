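"""Cell coordinate system, density maps, and the mobility split."""

import numpy as np
import pytest

from nucleotrack.cellmap import (build_density_map, skeleton_midline,
                                 split_by_mobility, symmetrize_fourfold,
                                 to_cell_coords)
from nucleotrack.models import Trajectory
from nucleotrack.synthetic import (_axis_endpoints, _dist_to_axis,
                                   make_geometry)


def _uniform_points(geometry, n, rng):
    """Uniform over the mask support: random pixel + within-pixel offset."""
    rows, cols = np.nonzero(geometry.mask)
    pick = rng.integers(0, len(rows), n)
    px = geometry.pixel_size / 1000.0
    return (np.stack([cols[pick], rows[pick]], axis=1)
            + rng.random((n, 2))) * px


@pytest.fixture(scope="module")
def geometry():
    return make_geometry(3.76, 1.0, 49.0)


@pytest.fixture(scope="module")
def midline(geometry):
    return skeleton_midline(geometry.mask, 49.0)


class TestMidline:
    def test_on_axis_within_one_pixel(self, geometry, midline):
        true_y = geometry.midline[0][1]
        assert np.all(np.abs(midline[:, 1] - true_y) <= 0.049)

    def test_rectangle_center_line(self):
        mask = np.zeros((21, 80), dtype=bool)
        mask[6:15, 5:75] = True  # rows 6..14, center row 10
        mid = skeleton_midline(mask, 49.0)
        assert np.all(np.abs(mid[:, 1] / 0.049 - 10.5) <= 1.0)

    def test_disk_collapses_to_point(self):
        g = make_geometry(1.0, 1.0, 49.0)
        mid = skeleton_midline(g.mask, 49.0)
        assert len(mid) == 1


class TestCellCoords:
    def test_midcell_point(self, geometry, midline):
        a, b, _ = _axis_endpoints(geometry)
        center = 0.5 * (a + b)
        cc = to_cell_coords(center[None], midline, geometry.width,
                            geometry.length)
        assert abs(cc.r[0]) < 0.049
        assert cc.l_rel[0] == pytest.approx(0.5, abs=0.02)
        assert not cc.in_pole[0]

    def test_pole_tip(self, geometry, midline):
        a, b, r = _axis_endpoints(geometry)
        tip = b + np.array([r * 0.98, 0.0])
        cc = to_cell_coords(tip[None], midline, geometry.width,
                            geometry.length)
        assert cc.in_pole[0]
        assert cc.l_rel[0] > 0.95
        assert abs(cc.phi[0]) < 0.35  # aligned with the outward axis

    def test_uniform_points_give_flat_l_histogram(self, geometry, midline):
        rng = np.random.default_rng(5)
        pts = _uniform_points(geometry, 30_000, rng)
        cc = to_cell_coords(pts, midline, geometry.width, geometry.length)
        body = cc.l_rel[~cc.in_pole]
        h, _ = np.histogram(body, bins=10, range=(0.2, 0.8))
        expect = h.mean()
        assert np.all(np.abs(h - expect) < 4 * np.sqrt(expect))


class TestDensityMap:
    def _cells(self, geometry, midline, pts):
        return [dict(mask=geometry.mask, pixel_size=49.0, midline=midline,
                     width=geometry.width, length=geometry.length,
                     points=pts)]

    def test_bin_areas_cover_mask(self, geometry, midline):
        dm = build_density_map(self._cells(geometry, midline,
                                           np.empty((0, 2))))
        total = dm.body_areas.sum() + dm.pole_areas.sum()
        mask_area = geometry.mask.sum() * 0.049**2
        assert total == pytest.approx(mask_area, rel=0.01)

    def test_uniform_localizations_flat_map(self, geometry, midline):
        rng = np.random.default_rng(6)
        pts = _uniform_points(geometry, 200_000, rng)
        dm = build_density_map(self._cells(geometry, midline, pts))
        avg = dm.total_counts / (dm.body_areas.sum() + dm.pole_areas.sum())
        for dens, counts in ((dm.body_density, dm.body_counts),
                             (dm.pole_density, dm.pole_counts)):
            lam = np.where(counts > 0, counts, np.nan)
            rel_err = np.abs(dens - 1.0)
            bound = 3.0 / np.sqrt(lam)
            ok = np.isnan(lam) | (rel_err <= bound)
            assert ok.all()

    def test_symmetrization_idempotent(self):
        rng = np.random.default_rng(7)
        body = rng.poisson(50, (5, 20)).astype(float)
        poles = rng.poisson(50, (2, 3)).astype(float)
        b1, p1 = symmetrize_fourfold(body, poles)
        b2, p2 = symmetrize_fourfold(b1, p1)
        assert np.allclose(b1, b2) and np.allclose(p1, p2)

    def test_symmetrization_conserves_totals(self):
        rng = np.random.default_rng(8)
        body = rng.poisson(50, (5, 20)).astype(float)
        poles = rng.poisson(50, (2, 3)).astype(float)
        b, p = symmetrize_fourfold(body, poles)
        assert b.sum() == pytest.approx(body.sum())
        assert p.sum() == pytest.approx(poles.sum())

    def test_pole_localizations_spread_to_both_poles(self, geometry, midline):
        a, b_end, r = _axis_endpoints(geometry)
        pts = np.tile(b_end + [0.9 * r, 0.0], (50, 1))
        dm = build_density_map(self._cells(geometry, midline, pts))
        assert np.allclose(dm.pole_counts[0], dm.pole_counts[1])
        assert dm.total_counts == 50


class TestMobilitySplit:
    def _tr(self, i):
        return Trajectory(id=i, frames=np.arange(3), xy=np.zeros((3, 2)))

    def test_threshold_assignment(self):
        trs = [self._tr(0), self._tr(1), self._tr(2)]
        dapp = {0: 0.10, 1: 0.20, 2: 0.50}
        slow, fast = split_by_mobility(trs, dapp)
        assert [t.id for t in slow] == [0]
        assert [t.id for t in fast] == [2]

    def test_sets_disjoint(self):
        trs = [self._tr(i) for i in range(20)]
        dapp = {i: 0.05 * i for i in range(20)}
        slow, fast = split_by_mobility(trs, dapp)
        assert not ({t.id for t in slow} & {t.id for t in fast})
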