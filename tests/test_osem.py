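"""OS-EM: scheme enumeration, subsets, likelihood, update properties."""

import numpy as np
import pytest

from spectpareto import (
    Grid,
    OSEMModel,
    ProjectionSet,
    Projector,
    ReconScheme,
    SystemModel,
    enumerate_recon_schemes,
    make_subsets,
    osem_reconstruct,
    poisson_loglik,
    uniform_angles,
)

# subset lists and maximum iterations per projection count, as enumerated by
# the even-divisor rule with the 2400 iteration x projection budget
TABLE = {
    120: ([2, 4, 6, 8, 10, 12, 20, 24, 30, 40, 60], 20),
    60: ([2, 4, 6, 10, 12, 20, 30], 40),
    40: ([2, 4, 8, 10, 20], 60),
    30: ([2, 6, 10], 80),
    24: ([2, 4, 6, 8, 12], 100),
    20: ([2, 4, 10], 120),
}


class TestSchemeEnumeration:
    @pytest.mark.parametrize("n", sorted(TABLE))
    def test_subset_lists_and_max_iterations(self, n):
        schemes = enumerate_recon_schemes(n)
        subsets = sorted({s.num_subsets for s in schemes})
        expected_subsets, expected_max_iter = TABLE[n]
        assert subsets == expected_subsets
        assert max(s.num_iterations for s in schemes) == expected_max_iter
        assert all(s.num_iterations * n <= 2400 for s in schemes)

    def test_total_setting_count(self):
        total = sum(len(enumerate_recon_schemes(n)) for n in TABLE)
        assert total == sum(len(subs) * mi for subs, mi in TABLE.values()) == 1900

    def test_sixty_projection_updates_range(self):
        schemes = enumerate_recon_schemes(60)
        updates = [s.updates for s in schemes if s.num_iterations == 40]
        assert min(updates) == 80 and max(updates) == 1200

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ReconScheme(60, 3, 1)  # odd subsets
        with pytest.raises(ValueError):
            ReconScheme(60, 60, 1)  # one angle per subset
        with pytest.raises(ValueError):
            ReconScheme(60, 2, 41)  # budget exceeded
        with pytest.raises(ValueError):
            ReconScheme(60, 7, 1)  # non-divisor


class TestMakeSubsets:
    def test_two_subsets_are_evens_and_odds(self):
        subs = make_subsets(np.arange(60), 2)
        assert np.array_equal(subs[0], np.arange(0, 60, 2))
        assert np.array_equal(subs[1], np.arange(1, 60, 2))

    def test_24_angles_8_subsets(self):
        subs = make_subsets(np.arange(24), 8)
        assert len(subs) == 8
        assert all(len(s) == 3 for s in subs)

    def test_partition_property(self):
        subs = make_subsets(np.arange(40), 10)
        merged = np.sort(np.concatenate(subs))
        assert np.array_equal(merged, np.arange(40))


class TestPoissonLoglik:
    def test_three_pixel_hand_sum(self):
        p = np.array([2.0, 0.0, 5.0])
        lam = np.array([1.5, 0.7, 4.0])
        by_hand = 2.0 * np.log(1.5) + 5.0 * np.log(4.0) - (1.5 + 0.7 + 4.0)
        assert poisson_loglik(p, lam) == pytest.approx(by_hand, rel=1e-12)

    def test_maximal_at_matching_scale(self):
        p = np.array([3.0, 7.0, 1.0])
        base = poisson_loglik(p, p)
        for alpha in (0.5, 0.9, 1.1, 2.0):
            assert poisson_loglik(p, alpha * p) < base

    def test_zero_counts(self):
        lam = np.array([2.0, 3.0])
        assert poisson_loglik(np.zeros(2), lam) == pytest.approx(-5.0)

    def test_zero_expectation_with_counts_is_minus_inf(self):
        assert poisson_loglik(np.array([1.0]), np.array([0.0])) == -np.inf


@pytest.fixture(scope="module")
def disk_case():
    """Uniform disk, no attenuation, delta PSF, 8 angles."""
    grid = Grid((16, 16, 8), 4.42)
    system = SystemModel(
        pixel_size_mm=4.42, num_pixels=16, sigma0_mm=0.0, blur_slope=0.0,
        scatter_fraction=0.0, sensitivity_cps_per_MBq=5.0,
    )
    xs, ys, _ = grid.axis_centers()
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    f = np.zeros(grid.shape)
    f[(xx**2 + yy**2 <= 20.0**2)] = 1.0
    angles = uniform_angles(8)
    projector = Projector(grid, system, angles)
    rate = projector.forward(f)
    return grid, system, f, angles, projector, rate


class TestOSEMUpdates:
    def test_mlem_loglikelihood_nondecreasing(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        rng = np.random.default_rng(13)
        pset = ProjectionSet(rng.poisson(rate * 12.0).astype(float), angles, 12.0)
        res = OSEMModel(pset, None, system, grid=grid).fit(
            ReconScheme(8, 1, 40), track_loglik=True
        )
        ll = np.array(res.loglik)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_fixed_point_when_model_reproduces_data(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        pset = ProjectionSet(rate * 10.0, angles, 10.0)  # noise-free
        res = OSEMModel(pset, None, system, grid=grid).fit(
            ReconScheme(8, 2, 1), initial=f
        )
        scale = np.abs(f[f > 0])
        assert np.max(np.abs(res.image - f)[f > 0] / scale) < 1e-8

    def test_count_consistency_at_mlem_convergence(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        pset = ProjectionSet(rate * 10.0, angles, 10.0)
        res = OSEMModel(pset, None, system, grid=grid).fit(ReconScheme(8, 1, 200))
        modeled = projector.forward(res.image)
        assert abs(modeled.sum() / rate.sum() - 1.0) < 1e-3

    def test_snapshots_nonnegative_and_one_per_iteration(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        rng = np.random.default_rng(14)
        pset = ProjectionSet(rng.poisson(rate * 5.0).astype(float), angles, 5.0)
        res = OSEMModel(pset, None, system, grid=grid).fit(ReconScheme(8, 4, 6))
        assert len(res.iterates) == 6
        for img in res.iterates:
            assert np.all(img >= 0)

    def test_all_zero_projections_returns_zero_image_with_warning(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        pset = ProjectionSet(np.zeros_like(rate), angles, 10.0)
        with pytest.warns(UserWarning, match="all-zero"):
            res = OSEMModel(pset, None, system, grid=grid).fit(ReconScheme(8, 2, 3))
        assert np.all(res.image == 0)

    def test_deterministic_reconstruction(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        rng = np.random.default_rng(15)
        pset = ProjectionSet(rng.poisson(rate * 8.0).astype(float), angles, 8.0)
        scheme = ReconScheme(8, 2, 4)
        r1 = OSEMModel(pset, None, system, grid=grid).fit(scheme)
        r2 = osem_reconstruct(pset, None, system, scheme, grid=grid)
        assert np.array_equal(r1.image, r2.image)

    def test_scheme_data_mismatch_rejected(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        pset = ProjectionSet(rate, angles, 1.0)
        with pytest.raises(ValueError, match="projections"):
            OSEMModel(pset, None, system, grid=grid).fit(ReconScheme(20, 2, 1))

    def test_summary_reports_scheme(self, disk_case):
        grid, system, f, angles, projector, rate = disk_case
        pset = ProjectionSet(rate * 2.0, angles, 2.0)
        res = OSEMModel(pset, None, system, grid=grid).fit(ReconScheme(8, 2, 2))
        text = res.summary()
        assert "subsets:          2" in text
        assert "updates:          4" in text
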