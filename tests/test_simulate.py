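"""Generative model: parameter validation, tail-probability activation,
closed-form noise truths, image rendering, and transfer assay."""

import numpy as np
import pytest
from scipy import stats

from icepop.simulate import (
    SimulationParams,
    preset,
    render_images,
    simulate_dual_reporter,
    simulate_population,
    simulate_transfer_assay,
)


class TestParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_cells", 0),
            ("p_act", -0.1),
            ("p_act", 1.5),
            ("sigma_R", -1.0),
            ("sigma_E", -0.2),
            ("sigma_I", -0.2),
            ("copy_number", 0),
            ("bit_depth", 12),
        ],
    )
    def test_invalid_parameters_name_the_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimulationParams(**{field: value})

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown preset"):
            preset("nonexistent")


class TestPopulation:
    def test_no_factor_x_means_no_activation(self):
        pop = simulate_population(SimulationParams(n_cells=5000, p_act=0.0, seed=1))
        assert pop.active.sum() == 0

    def test_active_implies_permissive(self, wildtype_pop):
        assert not np.any(wildtype_pop.active & ~wildtype_pop.permissive)

    def test_wildtype_tail_gives_three_percent(self):
        # theta = mu + 1.881 sigma, p_act = 1: Phi(-1.881) ~= 0.0300
        pop = simulate_population(preset("wildtype", n_cells=100_000, seed=2))
        expected = stats.norm.sf(1.881)
        assert expected == pytest.approx(0.0300, abs=2e-4)
        assert pop.active_fraction == pytest.approx(expected, abs=0.002)

    def test_active_fraction_matches_gaussian_tail_with_partial_factor_x(self):
        params = preset("rpos_plus", n_cells=200_000, p_act=0.5, seed=3)
        pop = simulate_population(params)
        assert pop.active_fraction == pytest.approx(
            params.expected_on_fraction, abs=0.004
        )

    def test_copy_number_doubles_mean_level(self):
        one = simulate_population(SimulationParams(n_cells=50_000, seed=4))
        two = simulate_population(
            SimulationParams(n_cells=50_000, copy_number=2, seed=4)
        )
        assert two.R.mean() / one.R.mean() == pytest.approx(2.0, abs=0.05)

    def test_observed_values_respect_sensor_range(self, wildtype_pop):
        smax = wildtype_pop.params.sensor_max
        for agv in (wildtype_pop.agv_g, wildtype_pop.agv_c):
            assert agv.min() >= 0 and agv.max() <= smax
        # bright ON cells must actually hit the 8-bit ceiling
        assert wildtype_pop.saturated_g.any()

    def test_fixed_seed_reproduces_byte_identical_output(self):
        a = simulate_population(preset("wildtype", n_cells=1000, seed=9))
        b = simulate_population(preset("wildtype", n_cells=1000, seed=9))
        for name in ("R", "agv_g", "agv_c", "active"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_to_frame_has_one_row_per_cell_and_channel(self, wildtype_pop):
        frame = wildtype_pop.to_frame()
        assert len(frame) == 2 * len(wildtype_pop)
        assert set(frame["channel"]) == {"g", "c"}


class TestDualReporter:
    def test_zero_intrinsic_shape_makes_channels_identical(self):
        s = simulate_dual_reporter(100, sigma_E=0.4, sigma_I=0.0, seed=1)
        assert np.array_equal(s.g, s.c)

    def test_zero_extrinsic_shape_estimates_to_zero_extrinsic_noise(self):
        from icepop.noise import noise_decomposition

        s = simulate_dual_reporter(50_000, sigma_E=0.0, sigma_I=0.3, seed=2)
        assert s.eta_ext_true == 0.0
        est = noise_decomposition(s.g, s.c)
        assert abs(est.eta_ext) < 0.01

    def test_closed_form_truths_at_reference_shapes(self, dual_sample):
        assert dual_sample.eta_ext_true == pytest.approx(0.553, abs=0.001)
        assert dual_sample.eta_int_true == pytest.approx(0.547, abs=0.001)

    def test_sample_too_small_rejected(self):
        with pytest.raises(ValueError, match="n must be >= 2"):
            simulate_dual_reporter(1, 0.1, 0.1)


class TestRenderImages:
    def test_zero_cells_gives_pure_background_and_empty_mask(self):
        images, masks, truth = render_images(np.array([]), seed=0)
        assert len(images) == 1
        assert masks[0].max() == 0
        assert truth.empty
        assert images[0].mean() == pytest.approx(10.0, abs=0.5)

    def test_interior_mean_matches_cell_value(self):
        images, masks, truth = render_images(np.array([200.0]), seed=1)
        interior = images[0][masks[0] == 1]
        assert interior.mean() == pytest.approx(200.0, abs=1.0)

    def test_eight_bit_clipping_caps_bright_cells(self):
        images, masks, _ = render_images(np.array([300.0]), bit_depth=8, seed=2)
        assert images[0][masks[0] == 1].max() <= 255

    def test_impossible_placement_reports_achievable_count(self):
        with pytest.raises(RuntimeError, match="without overlap"):
            render_images(
                np.full(50, 100.0),
                image_shape=(40, 40),
                cells_per_image=50,
                cell_radius_range=(8.0, 9.0),
                seed=3,
                max_tries=20,
            )


class TestTransferAssay:
    def test_no_activation_means_no_transconjugants(self):
        assay = simulate_transfer_assay(10_000, 0.0, 0.5, seed=1)
        assert assay.transconjugants == 0

    def test_certain_transfer_gives_frequency_one(self):
        assay = simulate_transfer_assay(1000, 1.0, 1.0, seed=2)
        assert assay.frequency == 1.0

    def test_expected_frequency_is_product_of_probabilities(self):
        assay = simulate_transfer_assay(10**7, 0.03, 1e-3, seed=3)
        assert assay.frequency == pytest.approx(3e-5, rel=0.15)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="activation_fraction"):
            simulate_transfer_assay(100, 1.2, 0.1)
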