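"""Normalization, subpopulation gating and the intrinsic/extrinsic/total
noise decomposition with bootstrap uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icepop.noise import (
    bootstrap_noise,
    noise_decomposition,
    scale_and_normalize,
    select_active,
)
from icepop.simulate import simulate_dual_reporter


class TestScaleAndNormalize:
    def test_channel_maximum_maps_to_100(self, rng):
        g, c = scale_and_normalize(rng.uniform(1, 50, 100), rng.uniform(1, 80, 100))
        assert g.max() == 100.0 and c.max() == 100.0

    def test_background_subtraction_arithmetic(self):
        g, _ = scale_and_normalize([12, 22, 112], [1, 2, 3], background_g=12.0)
        assert np.allclose(g, [0.0, 10.0, 100.0])

    def test_joint_rescaling_cancels(self, rng):
        raw_g = rng.uniform(5, 200, 500)
        raw_c = rng.uniform(5, 200, 500)
        g1, c1 = scale_and_normalize(raw_g, raw_c)
        g2, c2 = scale_and_normalize(7.3 * raw_g, 7.3 * raw_c)
        assert np.allclose(g1, g2) and np.allclose(c1, c2)

    def test_no_signal_channel_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            scale_and_normalize([1.0, 2.0], [5.0, 6.0], background_g=10.0)


class TestSelectActive:
    def test_zero_breakpoints_retain_everything(self, rng):
        g = rng.uniform(0, 100, 50)
        c = rng.uniform(0, 100, 50)
        g_on, c_on = select_active(g, c, 0.0, 0.0)
        assert g_on.size == 50

    def test_union_falls_back_to_other_channel(self, rng):
        # c never crosses its breakpoint threshold; gate = g's ON set
        g = np.concatenate([rng.uniform(0, 10, 95), rng.uniform(90, 100, 5)])
        c = np.full(100, 5.0)
        g_on, c_on = select_active(g, c, 95.0, 100.0)
        assert np.all(g_on > 10)

    def test_union_of_correlated_bimodal_channels_bounded(self):
        s = simulate_dual_reporter(20_000, sigma_E=0.3, sigma_I=0.1, seed=8)
        on = np.zeros(20_000, dtype=bool)
        on[:600] = True  # 3% ON in both channels (correlated via shared E)
        g = np.where(on, s.g * 50, s.g)
        c = np.where(on, s.c * 50, s.c)
        g_on, _ = select_active(g, c, 97.0, 97.0)
        assert 0.03 <= g_on.size / 20_000 <= 0.06

    def test_too_few_retained_cells_error_reports_count(self):
        g = np.array([1.0, 2.0, 3.0])
        c = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="cells above the breakpoints"):
            select_active(g, c, 99.0, 99.0)

    def test_intersection_mode_is_stricter_than_union(self, rng):
        g = rng.uniform(0, 100, 1000)
        c = rng.uniform(0, 100, 1000)
        gu, _ = select_active(g, c, 90.0, 90.0, mode="union")
        gi, _ = select_active(g, c, 90.0, 90.0, mode="intersection")
        assert gi.size <= gu.size


class TestDecomposition:
    def test_identical_channels_have_zero_intrinsic_noise(self, rng):
        g = rng.uniform(1, 100, 200)
        est = noise_decomposition(g, g.copy())
        assert est.eta_int == 0.0
        assert est.eta_tot == pytest.approx(est.eta_ext, abs=1e-12)

    def test_two_cell_hand_computation(self):
        # <g>=<c>=1.5, <gc>=2, <(g-c)^2>=1, <g^2>=<c^2>=2.5
        est = noise_decomposition([1.0, 2.0], [2.0, 1.0])
        assert est.eta_int**2 == pytest.approx(0.2222, abs=1e-4)
        assert est.eta_ext_sq_signed == pytest.approx(-0.1111, abs=1e-4)
        assert est.eta_tot**2 == pytest.approx(0.1111, abs=1e-4)
        assert est.eta_ext < 0  # signed root preserves the sign

    def test_estimator_recovers_closed_form_truths(self, dual_sample):
        est = noise_decomposition(dual_sample.g, dual_sample.c)
        assert est.eta_int == pytest.approx(dual_sample.eta_int_true, abs=0.01)
        assert est.eta_ext == pytest.approx(dual_sample.eta_ext_true, abs=0.01)

    def test_common_scale_invariance(self, rng):
        g = rng.lognormal(0, 0.5, 500)
        c = rng.lognormal(0, 0.5, 500)
        a = noise_decomposition(g, c)
        b = noise_decomposition(13.7 * g, 13.7 * c)
        assert a.eta_int == pytest.approx(b.eta_int, rel=1e-12)
        assert a.eta_ext_sq_signed == pytest.approx(b.eta_ext_sq_signed, rel=1e-9)
        assert a.eta_tot == pytest.approx(b.eta_tot, rel=1e-12)

    def test_zero_mean_channel_rejected(self):
        with pytest.raises(ValueError, match="means must be positive"):
            noise_decomposition([0.0, 0.0], [1.0, 2.0])

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 1e3), st.floats(0.01, 1e3)),
            min_size=2,
            max_size=60,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_total_noise_identity_holds_for_any_sample(self, pairs):
        g, c = map(np.asarray, zip(*pairs))
        est = noise_decomposition(g, c)
        lhs = est.eta_tot**2
        rhs = est.eta_int**2 + est.eta_ext_sq_signed
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)


class TestBootstrap:
    def test_degenerate_sample_gives_boot_mean_equal_to_point(self):
        # every resample of identical cells is the original sample
        g = np.full(20, 4.0)
        c = np.full(20, 6.0)
        point = noise_decomposition(g, c)
        boot = bootstrap_noise(g, c, n_boot=5, seed=0)
        assert boot.boot_mean["eta_int"] == pytest.approx(point.eta_int)
        assert boot.boot_sd["eta_int"] == 0.0

    def test_boot_mean_consistent_with_point_estimate(self, dual_sample):
        g, c = dual_sample.g[:10_000], dual_sample.c[:10_000]
        est = bootstrap_noise(g, c, n_boot=200, seed=1)
        for comp in ("eta_int", "eta_ext", "eta_tot"):
            point = getattr(est, comp)
            assert est.boot_mean[comp] == pytest.approx(
                point, abs=4 * est.boot_sd[comp] / np.sqrt(200) + 1e-3
            )

    def test_fixed_seed_reproduces_bootstrap_exactly(self, rng):
        g = rng.lognormal(0, 0.4, 300)
        c = rng.lognormal(0, 0.4, 300)
        a = bootstrap_noise(g, c, n_boot=100, seed=42)
        b = bootstrap_noise(g, c, n_boot=100, seed=42)
        assert a.boot_sd == b.boot_sd
        assert a.boot_mean == b.boot_mean
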