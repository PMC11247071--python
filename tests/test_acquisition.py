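"""Scatter model, Poisson acquisition simulation, time binning."""

import numpy as np
import pytest

from spectpareto import (
    ActivityMap,
    Grid,
    ProjectionSet,
    SystemModel,
    add_scatter,
    simulate_acquisition,
    simulate_time_binned,
    uniform_angles,
)
from spectpareto.acquisition import scatter_component


@pytest.fixture(scope="module")
def small_phantom():
    grid = Grid((16, 16, 12), 4.42)
    values = np.zeros(grid.shape)
    values[5:11, 5:11, 4:8] = 2.0
    return ActivityMap(grid, values)


@pytest.fixture(scope="module")
def small_system():
    return SystemModel(
        pixel_size_mm=4.42, num_pixels=16, sensitivity_cps_per_MBq=20.0,
        scatter_fraction=0.2,
    )


class TestScatter:
    def test_zero_fraction_is_identity(self, small_system):
        primary = np.random.default_rng(0).uniform(0, 5, (3, 16, 12))
        system = small_system.with_(scatter_fraction=0.0)
        assert np.array_equal(add_scatter(primary, system), primary)

    def test_uniform_plane_scales_by_inverse_one_minus_fraction(self, small_system):
        primary = np.ones((1, 64, 64))
        total = add_scatter(primary, small_system)
        # away from edges the convolution preserves the uniform level
        inner = total[0, 28:36, 28:36]
        assert np.allclose(inner, 1.0 / 0.8, rtol=1e-3)

    def test_scatter_to_total_ratio_near_configured_fraction(self):
        from spectpareto import forward_project

        grid = Grid((48, 48, 32), 4.42)
        values = np.zeros(grid.shape)
        values[20:28, 20:28, 12:20] = 2.0
        phantom = ActivityMap(grid, values)
        system = SystemModel(
            pixel_size_mm=4.42, num_pixels=48, sensitivity_cps_per_MBq=20.0,
            scatter_fraction=0.2, scatter_kernel_mm=20.0,
        )
        primary = forward_project(phantom, None, system, uniform_angles(4))
        scat = scatter_component(primary, system)
        ratio = scat.sum() / (primary + scat).sum()
        assert ratio == pytest.approx(0.2, abs=0.02)  # edge losses only


class TestSimulateAcquisition:
    def test_expected_counts_scale_linearly_with_time(self, small_phantom, small_system):
        sets = [
            simulate_acquisition(small_phantom, None, small_system, 4, t, rng_seed=1)
            for t in (50.0, 100.0)
        ]
        # same seed, doubled time: Poisson means double
        lam_ratio = sets[1].counts.sum() / max(sets[0].counts.sum(), 1.0)
        assert lam_ratio == pytest.approx(2.0, rel=0.1)

    def test_nonpositive_time_rejected(self, small_phantom, small_system):
        with pytest.raises(ValueError):
            simulate_acquisition(small_phantom, None, small_system, 4, 0.0, rng_seed=1)

    def test_seed_determinism_bit_identical(self, small_phantom, small_system):
        a = simulate_acquisition(small_phantom, None, small_system, 6, 60.0, rng_seed=9)
        b = simulate_acquisition(small_phantom, None, small_system, 6, 60.0, rng_seed=9)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_acquisition(small_phantom, None, small_system, 6, 60.0, rng_seed=10)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_variance_to_mean_near_unity(self, small_phantom, small_system):
        from spectpareto import forward_project

        angles = uniform_angles(2)
        rate = add_scatter(
            forward_project(small_phantom, None, small_system, angles), small_system
        )
        counts = np.stack(
            [
                simulate_acquisition(
                    small_phantom, None, small_system, 2, 20.0, rng_seed=s, rate=rate
                ).counts
                for s in range(500)
            ]
        )
        mean = counts.mean(axis=0)
        var = counts.var(axis=0, ddof=1)
        sel = mean >= 20
        assert sel.any()
        assert np.all(var[sel] / mean[sel] > 0.8)
        assert np.all(var[sel] / mean[sel] < 1.2)


class TestTimeBinned:
    def test_default_protocol_has_180_bins(self, small_phantom, small_system):
        tb = simulate_time_binned(
            small_phantom, None, small_system, num_projections=4,
            time_per_projection_s=180, rng_seed=0,
        )
        assert tb.num_bins == 180
        assert tb.bins.shape[0] == 4

    def test_zero_activity_gives_zero_bins(self, small_system):
        grid = Grid((16, 16, 12), 4.42)
        empty = ActivityMap(grid, np.zeros(grid.shape))
        tb = simulate_time_binned(empty, None, small_system, 4, 10, rng_seed=0)
        assert np.all(tb.bins == 0)

    def test_non_integer_seconds_rejected(self, small_phantom, small_system):
        with pytest.raises(ValueError, match="integer"):
            simulate_time_binned(small_phantom, None, small_system, 4, 12.5, rng_seed=0)

    def test_bin_sums_match_full_time_poisson_mean(self, small_phantom, small_system):
        from spectpareto import forward_project

        angles = uniform_angles(2)
        rate = add_scatter(
            forward_project(small_phantom, None, small_system, angles), small_system
        )
        t = 20
        totals = []
        for s in range(50):
            tb = simulate_time_binned(
                small_phantom, None, small_system, 2, t, rng_seed=s
            )
            assert tb.to_projection_set().time_per_projection_s == t
            totals.append(tb.bins.sum())
        lam = rate.sum() * t
        se = np.sqrt(lam / 50)
        assert abs(np.mean(totals) - lam) < 3 * se


def test_projection_set_validates_angles():
    with pytest.raises(ValueError, match="uniform"):
        ProjectionSet(np.zeros((3, 4, 4)), [0.0, 10.0, 300.0], 1.0)
    with pytest.raises(ValueError, match="nonnegative"):
        ProjectionSet(-np.ones((2, 4, 4)), [0.0, 180.0], 1.0)
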