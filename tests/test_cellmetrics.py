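"""Per-cell area, shape, region binning, and orientation distributions."""

import numpy as np
import pytest

from follimetrics.cellmetrics import (
    assign_region,
    cell_area,
    cell_shape,
    measure_cells,
    orientation_distribution,
)
from follimetrics.lattice import segment_cells
from follimetrics.surface import Pullback, surface_area


def flat_pullback(shape, pixel=0.5):
    """Chart with identity-scaled metric: pixel area = pixel² μm²."""
    H, W = shape
    z = np.zeros(shape)
    return Pullback(
        image=z, s_map=z, phi_map=z,
        g11=np.full(shape, pixel**2), g12=z.copy(), g22=np.full(shape, pixel**2),
        chart="cylinder", pixel_size=pixel, valid=np.ones(shape, bool),
        wraps_phi=False,
    )


def ellipse_mask(shape, ry, rx, angle_deg=0.0):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    yy = yy - H / 2
    xx = xx - W / 2
    th = np.deg2rad(angle_deg)
    u = yy * np.cos(th) + xx * np.sin(th)
    v = -yy * np.sin(th) + xx * np.cos(th)
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


class TestCellArea:
    def test_flat_square(self):
        pb = flat_pullback((40, 40), pixel=0.5)
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True  # 10x10 pixels at 0.5 μm
        assert cell_area(mask, pb) == pytest.approx(25.0)

    def test_zero_pixel_face(self):
        pb = flat_pullback((10, 10))
        with pytest.raises(ValueError, match="zero-pixel"):
            cell_area(np.zeros((10, 10), bool), pb)

    def test_area_conservation_closed_follicle(self, sphere_epithelium,
                                               segmented_sphere):
        seg, lat = segmented_sphere
        cells = measure_cells(seg, sphere_epithelium.pullback,
                              sphere_epithelium.param, lattice=lat)
        total = surface_area(sphere_epithelium.param)
        assert cells["area"].sum() == pytest.approx(total, rel=0.01)


class TestCellShape:
    def test_disk_orientation_undefined(self):
        pb = flat_pullback((200, 200))
        e, ori = cell_shape(ellipse_mask((200, 200), 60, 60), pb)
        assert e < 0.05 and np.isnan(ori)

    def test_two_to_one_ellipse_eccentricity(self):
        pb = flat_pullback((240, 240))
        e, _ = cell_shape(ellipse_mask((240, 240), 100, 50), pb)
        assert e == pytest.approx(np.sqrt(1 - 0.25), abs=0.005)

    def test_meridional_ellipse_orientation_90(self):
        pb = flat_pullback((240, 240))
        # long axis along rows = the s (meridional) direction
        _, ori = cell_shape(ellipse_mask((240, 240), 100, 40), pb)
        assert ori == pytest.approx(90.0, abs=0.5)

    def test_latitudinal_ellipse_orientation_0(self):
        pb = flat_pullback((240, 240))
        _, ori = cell_shape(ellipse_mask((240, 240), 40, 100), pb)
        assert ori == pytest.approx(0.0, abs=0.5)

    def test_tiny_face_rejected(self):
        pb = flat_pullback((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[4, 4:7] = True
        with pytest.raises(ValueError, match="pixels"):
            cell_shape(mask, pb)

    def test_eccentricity_invariant_under_seam_rotation(self, sphere_epithelium):
        """Relocating the phi seam by pi leaves per-cell eccentricity alone."""
        pb = sphere_epithelium.pullback
        W = pb.image.shape[1]
        rolled = Pullback(
            image=np.roll(pb.image, W // 2, axis=1),
            s_map=pb.s_map, phi_map=pb.phi_map,
            g11=np.roll(pb.g11, W // 2, axis=1),
            g12=np.roll(pb.g12, W // 2, axis=1),
            g22=np.roll(pb.g22, W // 2, axis=1),
            chart=pb.chart, pixel_size=pb.pixel_size,
            valid=np.roll(pb.valid, W // 2, axis=1), wraps_phi=True,
        )
        lab = sphere_epithelium.labels
        lab_r = np.roll(lab, W // 2, axis=1)
        for cell in (5, 42, 137):
            e1, _ = cell_shape(lab == cell, pb)
            e2, _ = cell_shape(lab_r == cell, rolled)
            assert abs(e1 - e2) < 1e-3


class TestRegions:
    @pytest.mark.parametrize("s_frac,expected", [
        (0.0, "A-1/3"), (0.2, "A-1/3"), (0.5, "M-1/3"), (0.9, "P-1/3"),
        (1.0, "P-1/3"),
    ])
    def test_thirds(self, s_frac, expected):
        L = 31.4
        assert assign_region(s_frac * L, L) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_region(-1.0, 30.0)
        with pytest.raises(ValueError):
            assign_region(31.0, 30.0)


class TestOrientationDistribution:
    def test_peak_and_mean_at_45(self):
        rng = np.random.default_rng(3)
        ang = 45.0 + rng.normal(0, 1.0, 200)
        out = orientation_distribution(ang)
        assert out["grid"][np.argmax(out["density"])] == pytest.approx(45.0, abs=2.0)
        assert out["mean"] == pytest.approx(45.0, abs=0.5)

    def test_density_normalized(self):
        rng = np.random.default_rng(4)
        out = orientation_distribution(rng.uniform(0, 90, 500))
        assert np.trapezoid(out["density"], out["grid"]) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_recovery_ks(self):
        """KDE of uniform orientations stays close to uniform (KS < 0.05)."""
        rng = np.random.default_rng(5)
        out = orientation_distribution(rng.uniform(0, 90, 500))
        cdf = np.cumsum(out["density"])
        cdf /= cdf[-1]
        uniform_cdf = out["grid"] / 90.0
        assert np.abs(cdf - uniform_cdf).max() < 0.05

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match=">= 20"):
            orientation_distribution(np.arange(10.0))


class TestOrientationRecovery:
    def test_recovered_vs_true(self, aniso_epithelium):
        """Segmentation + metric moments recover per-cell orientation within
        5° on average, with regression slope in [0.9, 1.1]."""
        from .conftest import match_segmentation_to_truth

        epi = aniso_epithelium
        seg = segment_cells(epi.pullback, expected_cells=len(epi.truth.cells))
        cells = measure_cells(seg, epi.pullback, epi.param)
        match = match_segmentation_to_truth(seg.labels, epi.labels)
        truth = epi.truth.cells.set_index("cell")
        rec, tru = [], []
        for _, row in cells.iterrows():
            t = match.get(int(row["cell"]))
            if t is None or not np.isfinite(row["orientation_deg"]):
                continue
            t_ori = truth.loc[t, "orientation_deg"]
            if np.isfinite(t_ori):
                rec.append(row["orientation_deg"])
                tru.append(t_ori)
        rec, tru = np.array(rec), np.array(tru)
        assert len(rec) >= 200
        err = np.abs(rec - tru)
        err = np.minimum(err, 180 - err)
        assert err.mean() <= 5.0
        slope = np.polyfit(tru, rec, 1)[0]
        assert 0.9 <= slope <= 1.1
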