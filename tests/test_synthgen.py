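"""Generator ground truth: organ closed forms, tessellation topology,
determinism, division-event and FRAP-trace construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from follimetrics.division import division_angle
from follimetrics.frap import normalize_trace
from follimetrics.surface import spheroid_param
from follimetrics.synthgen import (
    SynthParams,
    fold_angle,
    make_division_events,
    make_epithelium,
    make_frap_trace,
    make_spheroid,
    spheroid_truth,
)


def ellipse_meridian_oracle(a, b):
    """Independent quadrature of the generating-ellipse arc length."""
    val, _ = integrate.quad(
        lambda t: np.sqrt(a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2), 0, np.pi
    )
    return val


class TestSynthParams:
    @pytest.mark.parametrize("bad", [
        dict(semi_axis_ap=-1.0),
        dict(n_cells=5),
        dict(target_eccentricity=1.0),
        dict(concentration=-2.0),
        dict(voxel_size=(0.2, 0.0, 0.2)),
        dict(orientation_bias="radial"),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SynthParams(**bad)


class TestSpheroid:
    def test_sphere_closed_forms(self):
        truth = spheroid_truth(10.0, 10.0)
        assert truth["volume"] == pytest.approx(4188.7902, abs=1e-3)
        assert truth["surface_area"] == pytest.approx(1256.6371, abs=1e-3)

    def test_prolate_meridian_matches_quadrature_oracle(self):
        truth = spheroid_truth(20.0, 10.0)
        assert truth["meridian_length"] == pytest.approx(
            ellipse_meridian_oracle(20.0, 10.0), rel=1e-9
        )
        assert truth["meridian_length"] == pytest.approx(48.442, abs=2e-3)

    @pytest.mark.parametrize("a,b", [(10.0, 10.0), (20.0, 10.0)])
    def test_voxelized_volume_within_one_percent(self, a, b):
        params = SynthParams(semi_axis_ap=a, semi_axis_eq=b,
                             voxel_size=(0.2, 0.2, 0.2), seed=3)
        mask, membrane, truth = make_spheroid(params)
        vox = mask.sum() * np.prod(params.voxel_size)
        assert vox == pytest.approx(truth["volume"], rel=0.01)
        assert membrane.shape == mask.shape

    def test_too_small_grid_rejected(self):
        params = SynthParams(semi_axis_ap=10.0, semi_axis_eq=10.0)
        with pytest.raises(ValueError, match="margin"):
            make_spheroid(params, shape=(40, 40, 40))


class TestEpithelium:
    def test_topology_euler_consequence(self, sphere_epithelium):
        """Closed 3-regular genus-0 tessellation: mean neighbors = 6 - 12/F."""
        cells = sphere_epithelium.truth.cells
        F = len(cells)
        assert F == 200
        assert cells["n_neighbors"].mean() == pytest.approx(6 - 12 / F, abs=1e-9)

    def test_neighbor_symmetry(self, sphere_epithelium):
        for pair in sphere_epithelium.truth.neighbors:
            assert len(pair) == 2

    def test_isotropic_generating_truth(self, sphere_epithelium):
        """At target 0 the generating anisotropy is exactly zero; the
        realized tessellation carries the documented Voronoi packing floor
        (well below fully random packing)."""
        cells = sphere_epithelium.truth.cells
        assert (cells["eccentricity_target"] == 0.0).all()
        assert cells["eccentricity"].mean() < 0.45

    def test_anisotropy_raises_measured_eccentricity(self, sphere_epithelium,
                                                     aniso_epithelium):
        iso = sphere_epithelium.truth.cells["eccentricity"].mean()
        aniso = aniso_epithelium.truth.cells["eccentricity"].mean()
        assert aniso > iso + 0.15
        assert aniso == pytest.approx(0.7, abs=0.08)

    def test_latitudinal_bias_mean_orientation_below_10deg(self):
        epi = make_epithelium(SynthParams(
            semi_axis_ap=10.0, semi_axis_eq=10.0, n_cells=150,
            target_eccentricity=0.7, orientation_bias="latitudinal",
            concentration=50.0, seed=13,
        ))
        ori = epi.truth.cells["orientation_deg"].dropna()
        # circular mean of the axis (pi-periodic) angles
        two = np.deg2rad(2 * ori.to_numpy())
        mean_axis = np.rad2deg(np.arctan2(np.sin(two).mean(), np.cos(two).mean()) / 2)
        assert abs(fold_angle(mean_axis)) < 10.0

    def test_deterministic_given_seed(self):
        p = SynthParams(semi_axis_ap=10.0, semi_axis_eq=10.0, n_cells=60, seed=21)
        e1 = make_epithelium(p, pixel_size=0.3)
        e2 = make_epithelium(p, pixel_size=0.3)
        assert np.array_equal(e1.labels, e2.labels)
        assert np.array_equal(e1.image, e2.image)
        pd.testing.assert_frame_equal(e1.truth.cells, e2.truth.cells)


class TestDivisionEvents:
    def test_degenerate_vonmises_all_90(self):
        sp = spheroid_param(20.0, 20.0)
        events = make_division_events(5, "vonmises", mu_deg=90.0,
                                      kappa=np.inf, seed=2, param=sp)
        for ev in events:
            assert division_angle(ev, sp) == pytest.approx(90.0, abs=0.5)

    def test_uniform_mean_45(self):
        sp = spheroid_param(20.0, 20.0)
        events = make_division_events(10_000, "uniform", seed=5, param=sp)
        angles = np.array([division_angle(ev, sp) for ev in events])
        assert angles.mean() == pytest.approx(45.0, abs=1.0)

    def test_single_event(self):
        events = make_division_events(1, "uniform", seed=0)
        assert len(events) == 1

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            make_division_events(3, "vonmises", mu_deg=0.0, kappa=-1.0)


class TestFrapTraceGeneration:
    def test_half_recovery_time(self):
        tr = make_frap_trace(0.2, 0.8, 0.0231, noise_sd=0.0)
        y = normalize_trace(tr)
        t_half = np.log(2) / 0.0231
        # value at the half-time is midway between Y0 and the plateau
        y_at = np.interp(t_half, tr.t, y)
        assert y_at == pytest.approx(0.5, abs=1e-3)
        assert t_half == pytest.approx(30.0, abs=0.1)

    def test_photobleach_cancellation_exact(self):
        tr = make_frap_trace(0.3, 0.9, 0.05, noise_sd=0.0, ref_bleach_rate=0.004)
        y = normalize_trace(tr)
        f = 0.3 + 0.6 * (1 - np.exp(-0.05 * tr.t))
        assert np.abs(y - f).max() < 1e-12

    def test_generated_mobile_fraction(self):
        # K = 0.05/s over 300 s: the plateau is reached to within e^-15
        tr = make_frap_trace(0.3, 0.8, 0.05, noise_sd=0.0)
        y = normalize_trace(tr)
        assert y[-1] - y[0] == pytest.approx(0.5, abs=1e-3)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            make_frap_trace(0.9, 0.5, 0.02)
        with pytest.raises(ValueError):
            make_frap_trace(0.2, 0.8, -1.0)
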