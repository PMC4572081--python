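"""Architecture: connectivity geometry, inhibition, contrast enhancement."""

import numpy as np
import pytest

from tracenet.network import (
    ConnectivityMap,
    LayerSpec,
    contrast_enhance,
    full_profile,
    get_profile,
    inhibition_kernel,
    lateral_inhibit,
    population_sparseness,
    propagate,
    sample_connectivity,
    scaled_profile,
)


class TestLayerSpec:
    def test_full_profile_matches_published_dimensions(self):
        prof = full_profile()
        assert [l.grid_dims for l in prof.layers] == [128] * 4
        assert [l.fan_in for l in prof.layers] == [100, 400, 400, 400]
        assert [l.conn_radius for l in prof.layers] == [24, 24, 36, 48]
        assert [l.inhib_sigma for l in prof.layers] == [1.38, 2.7, 4.0, 6.0]
        assert [l.inhib_delta for l in prof.layers] == [1.5, 1.5, 1.6, 1.4]
        assert [l.sigmoid_beta for l in prof.layers] == [190, 40, 75, 26]
        assert [l.learning_rate for l in prof.layers] == [0.05, 0.03, 0.005, 0.005]
        assert [l.rule for l in prof.layers] == ["hebb", "trace", "trace", "trace"]
        assert [l.trace_eta for l in prof.layers] == [0.0, 0.6, 0.8, 0.8]
        assert prof.input_dims == (256, 256)
        assert prof.n_neurons == 4 * 128 * 128

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fan_in": 0},
            {"conn_radius": -1.0},
            {"trace_eta": 1.0},
            {"sigmoid_percentile": 0.0},
            {"sigmoid_percentile": 100.0},
            {"rule": "oja"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(grid_dims=8, fan_in=10, conn_radius=3.0, inhib_sigma=1.0,
                    inhib_delta=1.0, sigmoid_percentile=95.0, sigmoid_beta=10.0,
                    learning_rate=0.01)
        base.update(kwargs)
        with pytest.raises(ValueError):
            LayerSpec(**base)

    def test_unknown_profile_name(self):
        with pytest.raises(ValueError):
            get_profile("nope")


class TestConnectivity:
    def test_exact_fan_in_and_no_duplicates(self, rng):
        spec = scaled_profile().layers[1]
        cmap = sample_connectivity((32, 32), spec, rng)
        assert cmap.indices.shape == (spec.n_neurons, spec.fan_in)
        for row in cmap.indices:
            assert len(set(row.tolist())) == spec.fan_in

    def test_within_radius_fraction_near_67_percent(self, rng):
        """The nominal radius contains ~67% of connections (interior
        neurons, where the radial profile is untruncated)."""
        spec = full_profile().layers[1]
        cmap = sample_connectivity((128, 128), spec, rng)
        interior = cmap.interior_mask(2.5 * spec.conn_sigma)
        rr, cc = cmap.spatial_coords()
        d2 = (rr - cmap.focal_points[:, [0]]) ** 2 + (cc - cmap.focal_points[:, [1]]) ** 2
        within = (d2 <= spec.conn_radius**2)[interior]
        assert within.size >= 10_000
        assert abs(within.mean() - 0.67) <= 0.02

    def test_degenerate_width_collapses_to_focal_point(self, rng):
        spec = LayerSpec(4, 5, 0.05, 1.0, 1.0, 95.0, 10.0, 0.01)
        cmap = sample_connectivity((16, 16), spec, rng)
        rr, cc = cmap.spatial_coords()
        d = np.hypot(rr - cmap.focal_points[:, [0]], cc - cmap.focal_points[:, [1]])
        # the no-duplicate rule forces the 5 distinct sites nearest the
        # (fractional) focal point: 4 at sqrt(0.5), the 5th at sqrt(2.5)
        assert d.max() <= np.sqrt(2.5) + 1e-9

    def test_topographic_focal_points(self, rng):
        spec = scaled_profile().layers[0]
        cmap = sample_connectivity((32, 64, 64), spec, rng,
                                   freq_groups=[np.arange(8 * i, 8 * (i + 1)) for i in range(4)])
        fp = cmap.focal_points.reshape(32, 32, 2)
        steps = np.diff(fp[:, 0, 0])
        np.testing.assert_allclose(steps, 64 / 32)  # grid scale ratio, exact

    def test_layer1_samples_every_frequency(self, rng):
        spec = scaled_profile().layers[0]
        groups = [np.arange(8 * i, 8 * (i + 1)) for i in range(4)]
        cmap = sample_connectivity((32, 64, 64), spec, rng, freq_groups=groups)
        sheet = cmap.indices // (64 * 64)
        for grp in groups:
            counts = np.isin(sheet, grp).sum(axis=1)
            assert np.all(counts == 25)  # 100 connections split 25 per frequency

    def test_fan_in_exceeding_support_is_an_error(self, rng):
        spec = LayerSpec(2, 200, 0.5, 1.0, 1.0, 95.0, 10.0, 0.01)
        with pytest.raises(ValueError):
            sample_connectivity((8, 8), spec, rng)


class TestPropagate:
    def test_zero_input_zero_activation(self, rng):
        spec = LayerSpec(4, 6, 2.0, 1.0, 1.0, 95.0, 10.0, 0.01)
        cmap = sample_connectivity((8, 8), spec, rng)
        assert np.all(propagate(np.zeros(64), cmap) == 0)

    def test_matches_bruteforce_dot_products(self, rng):
        spec = LayerSpec(3, 5, 2.0, 1.0, 1.0, 95.0, 10.0, 0.01)
        cmap = sample_connectivity((6, 6), spec, rng)
        x = rng.uniform(size=36)
        r = propagate(x, cmap)
        for i in range(9):
            expected = sum(w * x[j] for w, j in zip(cmap.weights[i], cmap.indices[i]))
            assert abs(r[i] - expected) < 1e-12

    def test_own_weight_vector_is_optimal_unit_input(self, rng):
        spec = LayerSpec(2, 8, 2.0, 1.0, 1.0, 95.0, 10.0, 0.01)
        cmap = sample_connectivity((6, 6), spec, rng)
        x = np.zeros(36)
        x[cmap.indices[0]] = cmap.weights[0]
        r = propagate(x, cmap)
        assert abs(r[0] - 1.0) < 1e-12  # Cauchy-Schwarz: max over unit inputs

    def test_dimension_mismatch(self, rng):
        spec = LayerSpec(2, 4, 2.0, 1.0, 1.0, 95.0, 10.0, 0.01)
        cmap = sample_connectivity((6, 6), spec, rng)
        with pytest.raises(ValueError):
            propagate(np.zeros(10), cmap)


class TestInhibition:
    @pytest.mark.parametrize("delta,sigma", [(1.5, 1.38), (1.5, 2.7), (1.6, 4.0), (1.4, 6.0)])
    def test_kernel_dc_gain_is_one(self, delta, sigma):
        assert abs(inhibition_kernel(delta, sigma).sum() - 1.0) < 1e-12

    def test_uniform_field_unchanged_in_interior(self):
        field = np.full((40, 40), 3.7)
        out = lateral_inhibit(field, 1.5, 1.38)
        half = inhibition_kernel(1.5, 1.38).shape[0] // 2
        np.testing.assert_allclose(out[half:-half, half:-half], 3.7, rtol=1e-12)

    def test_single_impulse_amplified_neighbours_negative(self):
        delta, sigma = 1.5, 1.38
        grid = np.zeros((21, 21))
        grid[10, 10] = 1.0
        out = lateral_inhibit(grid, delta, sigma)
        kern = inhibition_kernel(delta, sigma)
        centre_gain = kern[kern.shape[0] // 2, kern.shape[1] // 2]
        assert abs(out[10, 10] - centre_gain) < 1e-12
        assert centre_gain > 1.0  # 1 + delta * sum(exp(...))
        assert out[10, 11] < 0 and out[11, 10] < 0

    def test_two_impulses_mutually_suppressed(self):
        delta, sigma = 1.5, 2.0
        a = np.zeros((31, 31)); a[15, 13] = 1.0
        b = np.zeros((31, 31)); b[15, 17] = 1.0
        iso = lateral_inhibit(a, delta, sigma)[15, 13]
        both = lateral_inhibit(a + b, delta, sigma)
        assert both[15, 13] < iso and both[15, 17] < iso
        # superposition oracle: suppression equals the kernel coefficient
        kern = inhibition_kernel(delta, sigma)
        half = kern.shape[0] // 2
        np.testing.assert_allclose(iso - both[15, 13], -kern[half, half + 4], atol=1e-12)


class TestContrastEnhance:
    def test_half_activation_at_threshold(self):
        r = np.linspace(0, 1, 101)
        y, thr = contrast_enhance(r, 50.0, 10.0)
        at = np.argmin(np.abs(r - thr))
        assert abs(y[at] - 0.5) < 1e-9

    def test_percentile_controls_fraction_above_half(self, rng):
        r = rng.normal(size=10_000)
        y, _ = contrast_enhance(r, 95.0, 26.0)
        frac = (y > 0.5).mean()
        assert abs(frac - 0.05) <= 1.0 / len(r)

    def test_large_beta_approaches_step(self, rng):
        r = rng.uniform(size=1000)
        y, _ = contrast_enhance(r, 90.0, 1e6)
        assert np.all((y < 1e-6) | (y > 1 - 1e-6))

    def test_output_strictly_bounded(self, rng):
        r = rng.normal(size=500)
        y, _ = contrast_enhance(r, 80.0, 40.0)
        assert np.all(y >= 0) and np.all(y <= 1)

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning):
            y, thr = contrast_enhance(np.full(50, 2.0), 95.0, 10.0)
        assert np.all(y == 0.5) and thr == 2.0


class TestSparseness:
    def test_uniform_rates_give_one(self):
        assert population_sparseness(np.full(64, 0.3)) == pytest.approx(1.0)

    def test_single_active_neuron_gives_one_over_n(self):
        y = np.zeros(100); y[17] = 0.8
        assert population_sparseness(y) == pytest.approx(0.01)

    def test_hand_computed_example(self):
        assert population_sparseness([1.0, 0.5, 0.0, 0.0]) == pytest.approx(0.45)

    def test_bounds_hold_for_random_vectors(self, rng):
        for _ in range(20):
            y = rng.uniform(size=50)
            a = population_sparseness(y)
            assert 1 / 50 - 1e-12 <= a <= 1 + 1e-12

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            population_sparseness(np.zeros(10))
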