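"""Multi-echo decay fitting, Ernst-equation inversion, PD calibration."""

import numpy as np
import pytest

from icedmri import (
    EchoSeries,
    MultiEchoSet,
    calibrate_pd,
    dual_flip_angle_r1,
    dual_flip_angle_r1_approx,
    ernst_signal,
    estatics_fit,
    simulate_multiecho,
)
from icedmri.signal import PROTOCOL_TE_MS, PROTOCOL_TE_PDW_MS


def _noiseless_set(intercepts=(1000.0, 800.0, 600.0), r2star=20.0):
    return simulate_multiecho(intercepts, r2star, noise_sd=0.0)


class TestEstatics:
    def test_noiseless_round_trip_is_exact(self):
        res = estatics_fit(_noiseless_set())
        assert res.r2star == pytest.approx(20.0, rel=1e-9)
        for lab, truth in zip(("T1w", "PDw", "MTw"), (1000.0, 800.0, 600.0)):
            assert res.intercepts[lab] == pytest.approx(truth, rel=1e-9)
        assert res.residual_sse == pytest.approx(0.0, abs=1e-18)

    def test_two_echo_closed_form(self):
        te1, te2, s1, s2 = 3.0, 12.0, 900.0, 500.0
        series = EchoSeries((te1, te2), (s1, s2), 6.0, 24.5)
        res = estatics_fit(MultiEchoSet({"PDw": series}))
        expected = np.log(s1 / s2) / ((te2 - te1) / 1000.0)
        assert res.r2star == pytest.approx(expected, rel=1e-12)

    def test_noisy_fit_equals_generic_ols_oracle(self):
        """statsmodels OLS on the stacked design is the independent oracle."""
        import statsmodels.api as sm

        me = simulate_multiecho((1000.0, 800.0, 600.0), 20.0, noise_sd=5.0, seed=2)
        res = estatics_fit(me)
        y, te, blocks = [], [], []
        labels = list(me.contrasts)
        for j, lab in enumerate(labels):
            ser = me.contrasts[lab]
            y.extend(np.log(ser.signals))
            te.extend(np.asarray(ser.echo_times_ms) / 1000.0)
            blocks.extend([j] * len(ser.signals))
        X = np.column_stack(
            [np.asarray(blocks) == j for j in range(3)] + [-np.asarray(te)]
        ).astype(float)
        beta = sm.OLS(np.asarray(y), X).fit().params
        assert res.r2star == pytest.approx(beta[-1], rel=1e-10)
        for j, lab in enumerate(labels):
            assert res.intercepts[lab] == pytest.approx(np.exp(beta[j]), rel=1e-10)

    def test_joint_fit_beats_averaged_separate_slopes(self):
        """Joint OLS optimality among common-slope alternatives."""
        me = simulate_multiecho((1000.0, 800.0, 600.0), 20.0, noise_sd=8.0, seed=9)
        joint = estatics_fit(me)
        slopes, fits = [], {}
        for lab, ser in me.contrasts.items():
            one = estatics_fit(MultiEchoSet({lab: ser}))
            slopes.append(one.r2star)
            fits[lab] = ser
        forced = np.mean(slopes)
        sse = 0.0
        for lab, ser in fits.items():
            te = np.asarray(ser.echo_times_ms) / 1000.0
            logs = np.log(ser.signals)
            icept = np.mean(logs + forced * te)
            sse += np.sum((logs - icept + forced * te) ** 2)
        assert joint.residual_sse <= sse + 1e-12

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            EchoSeries((2.0, 4.0), (100.0, -1.0), 6.0, 24.5)

    def test_degenerate_te_spread_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            EchoSeries((2.0, 2.0), (100.0, 90.0), 6.0, 24.5)


class TestErnstSignal:
    def test_ninety_degree_closed_form(self):
        # S = A (1 - exp(-TR*R1)) at alpha = 90
        assert ernst_signal(1000.0, 1.0, 90.0, 24.5) == pytest.approx(
            24.2024, abs=1e-4
        )

    def test_vanishes_at_zero_flip(self):
        assert ernst_signal(1000.0, 1.0, 1e-9, 24.5) == pytest.approx(0.0, abs=1e-6)

    def test_full_relaxation_limit(self):
        assert ernst_signal(1000.0, 1.0, 30.0, 1e7) == pytest.approx(
            1000.0 * np.sin(np.deg2rad(30.0)), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [dict(r1=-1), dict(flip_angle_deg=120), dict(tr_ms=0)])
    def test_domain_violations(self, bad):
        kwargs = dict(amplitude=1000.0, r1=1.0, flip_angle_deg=21.0, tr_ms=24.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ernst_signal(**kwargs)


class TestDualFlipAngleR1:
    @pytest.mark.parametrize(
        "r1", list(np.linspace(0.2, 2.0, 10)) + [0.622, 0.967]
    )
    def test_round_trip_over_physiological_grid(self, r1):
        """Forward Ernst then exact inversion recovers R1 (GM/WM levels included)."""
        amp = 2500.0
        s_low = ernst_signal(amp, r1, 6.0, 24.5)
        s_high = ernst_signal(amp, r1, 21.0, 24.5)
        est, est_amp = dual_flip_angle_r1(s_low, s_high, 6.0, 21.0, 24.5)
        assert est == pytest.approx(r1, abs=1e-6)
        assert est_amp == pytest.approx(amp, rel=1e-6)

    def test_common_scaling_leaves_r1_unchanged(self):
        s_low = ernst_signal(1000.0, 0.8, 6.0, 24.5)
        s_high = ernst_signal(1000.0, 0.8, 21.0, 24.5)
        r1_a, amp_a = dual_flip_angle_r1(s_low, s_high, 6.0, 21.0, 24.5)
        r1_b, amp_b = dual_flip_angle_r1(3 * s_low, 3 * s_high, 6.0, 21.0, 24.5)
        assert r1_b == pytest.approx(r1_a, rel=1e-9)
        assert amp_b == pytest.approx(3 * amp_a, rel=1e-9)

    def test_inconsistent_signals_rejected(self):
        with pytest.raises(ValueError, match="root"):
            dual_flip_angle_r1(1.0, 1000.0, 6.0, 21.0, 24.5)

    def test_small_angle_approximation_close_to_exact(self):
        s_low = ernst_signal(1000.0, 0.7, 6.0, 24.5)
        s_high = ernst_signal(1000.0, 0.7, 21.0, 24.5)
        approx = dual_flip_angle_r1_approx(s_low, s_high, 6.0, 21.0, 24.5)
        assert approx == pytest.approx(0.7, rel=0.05)


class TestCalibratePD:
    def test_forces_masked_mean_to_target(self):
        rng = np.random.default_rng(1)
        pd_map = rng.uniform(50, 150, (6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4] = True
        out = calibrate_pd(pd_map, mask)
        assert out[mask].mean() == pytest.approx(69.0, rel=1e-12)

    def test_scalar_example_and_idempotence(self):
        pd_map = np.full((4,), 100.0)
        mask = np.ones(4, bool)
        out = calibrate_pd(pd_map, mask)
        np.testing.assert_allclose(out, 69.0)
        np.testing.assert_allclose(calibrate_pd(out, mask), out)

    def test_commutes_with_positive_rescaling(self):
        rng = np.random.default_rng(2)
        pd_map = rng.uniform(10, 90, (5, 5))
        mask = rng.random((5, 5)) > 0.4
        np.testing.assert_allclose(
            calibrate_pd(3.3 * pd_map, mask), calibrate_pd(pd_map, mask)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_pd(np.ones(3), np.zeros(3, bool))


class TestProtocol:
    def test_pdw_has_two_extra_late_echoes(self):
        assert len(PROTOCOL_TE_PDW_MS) == 8
        assert len(PROTOCOL_TE_MS) == 6
        assert PROTOCOL_TE_PDW_MS[-2:] == (16.38, 18.72)
        assert PROTOCOL_TE_MS[0] == pytest.approx(2.34)
        assert PROTOCOL_TE_MS[-1] == pytest.approx(14.04)
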