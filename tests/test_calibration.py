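"""Calibration factors from uniform-cylinder reconstructions."""

import numpy as np
import pytest

from spectpareto import Grid, SystemModel, calibrate_all, compute_calibration_factor
from spectpareto.calibration import calibration_voi_mask, factor_lookup
from spectpareto.osem import ReconScheme


class TestComputeFactor:
    def test_identity_when_image_equals_reference(self):
        img = np.full((4, 4, 4), 0.5)
        mask = np.ones_like(img, dtype=bool)
        assert compute_calibration_factor(img, mask, 0.5) == pytest.approx(1.0)

    def test_half_when_image_doubles_reference(self):
        img = np.full((4, 4, 4), 1.0)
        mask = np.ones_like(img, dtype=bool)
        assert compute_calibration_factor(img, mask, 0.5) == pytest.approx(0.5)

    def test_zero_signal_rejected(self):
        img = np.zeros((4, 4, 4))
        mask = np.ones_like(img, dtype=bool)
        with pytest.raises(ValueError, match="zero"):
            compute_calibration_factor(img, mask, 0.5)

    def test_empty_mask_rejected(self):
        img = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            compute_calibration_factor(img, np.zeros_like(img, dtype=bool), 0.5)


@pytest.fixture(scope="module")
def small_calibration():
    """Desk-scale cylinder calibration over a few schemes."""
    grid = Grid((32, 32, 24), 4.42)
    system = SystemModel(
        pixel_size_mm=4.42, num_pixels=32, sensitivity_cps_per_MBq=50.0
    )
    schemes = [ReconScheme(20, s, it) for s in (2, 4) for it in (1, 2, 3)]
    table = calibrate_all(
        schemes, grid, system,
        voi_volume_mL=50.0, radius_mm=50.0, length_mm=80.0, concentration=0.0228,
    )
    return grid, system, schemes, table


class TestCalibrateAll:
    def test_one_row_per_scheme(self, small_calibration):
        _, _, schemes, table = small_calibration
        assert len(table) == len(schemes)
        keys = factor_lookup(table)
        for s in schemes:
            assert (s.num_projections, s.num_subsets, s.num_iterations) in keys

    def test_factors_positive_and_finite(self, small_calibration):
        _, _, _, table = small_calibration
        assert np.all(np.isfinite(table["factor"]))
        assert np.all(table["factor"] > 0)

    def test_factors_vary_smoothly(self, small_calibration):
        _, _, _, table = small_calibration
        med = table["factor"].median()
        assert np.all(np.abs(table["factor"] / med - 1.0) < 0.5)

    def test_idempotent_on_calibration_data(self, small_calibration):
        """Applying a factor to the image it came from reproduces the reference."""
        from spectpareto.acquisition import ProjectionSet, scatter_component, uniform_angles
        from spectpareto.osem import OSEMModel
        from spectpareto.phantoms import make_cylinder_phantom
        from spectpareto.projector import forward_project

        grid, system, _, _ = small_calibration
        activity, attenuation = make_cylinder_phantom(
            grid, radius_mm=50.0, length_mm=80.0, concentration=0.0228
        )
        angles = uniform_angles(20)
        primary = forward_project(activity, attenuation, system, angles)
        scat = scatter_component(primary, system)
        pset = ProjectionSet(primary + scat, angles, 1.0)
        res = OSEMModel(pset, attenuation, system, scatter_rate=scat).fit(
            ReconScheme(20, 2, 3)
        )
        voi = calibration_voi_mask(grid, 50.0, phantom_radius_mm=50.0)
        factor = compute_calibration_factor(res.image, voi, 0.0228)
        assert (res.image * factor)[voi].mean() == pytest.approx(0.0228, rel=1e-12)

    def test_scale_equivariance(self, small_calibration):
        """Scaling the cylinder concentration (and the matching start image)
        scales the reconstruction identically, leaving the factor invariant."""
        from spectpareto.acquisition import ProjectionSet, scatter_component, uniform_angles
        from spectpareto.osem import OSEMModel
        from spectpareto.phantoms import make_cylinder_phantom
        from spectpareto.projector import forward_project

        grid, system, _, _ = small_calibration
        voi = calibration_voi_mask(grid, 50.0, phantom_radius_mm=50.0)
        factors = []
        alpha = 3.0
        for conc, init in ((0.0228, 1.0), (alpha * 0.0228, alpha)):
            activity, attenuation = make_cylinder_phantom(
                grid, radius_mm=50.0, length_mm=80.0, concentration=conc
            )
            angles = uniform_angles(20)
            primary = forward_project(activity, attenuation, system, angles)
            scat = scatter_component(primary, system)
            pset = ProjectionSet(primary + scat, angles, 1.0)
            model = OSEMModel(pset, attenuation, system, scatter_rate=scat)
            res = model.fit(
                ReconScheme(20, 2, 2), initial=np.where(attenuation.mu > 0, init, 0.0)
            )
            factors.append(compute_calibration_factor(res.image, voi, conc))
        assert factors[0] == pytest.approx(factors[1], rel=1e-9)
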