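import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdgclamp.clamp import (
    ClampRecord,
    TracerBalance,
    egp,
    ffa_suppression,
    ifcc_to_ngsp,
    m_value,
    matsuda_isi,
    ngsp_to_ifcc,
    rd_from_tracer,
)
from fdgclamp.cohort import make_clamp_record
from fdgclamp.input_function import InputFunction


def _record(times, gir, glucose, window):
    n = len(times)
    return ClampRecord(np.asarray(times, float), np.asarray(gir, float),
                       np.asarray(glucose, float), np.zeros(n), np.zeros(n),
                       steady_state_min=window)


class TestMValue:
    def test_constant_glucose_no_urine_gives_mean_gir(self):
        rec = _record([0, 30, 60, 90, 120], [0, 40, 50, 50, 50],
                      [5.3] * 5, (60, 120))
        m, _ = m_value(rec, 80.0, 60.0)
        assert m == pytest.approx(50.0)

    def test_space_correction_hand_arithmetic(self):
        # GIR 50, glucose 5.0 -> 5.2 mmol/L over 60 min, vd 0.19 L/kg:
        # SC = 200 umol/L * 0.19 / 60 = 0.633, M = 49.37
        rec = _record([0, 30, 60], [50, 50, 50], [5.0, 5.1, 5.2], (0, 60))
        m, _ = m_value(rec, 70.0, 58.0, vd_l_per_kg=0.19)
        assert m == pytest.approx(50 - 0.2 * 1000 * 0.19 / 60, abs=1e-9)
        assert m == pytest.approx(49.37, abs=0.005)

    def test_ffm_normalization_is_weight_over_ffm(self):
        rec = _record([0, 60], [40, 40], [5.3, 5.3], (0, 60))
        m, m_ffm = m_value(rec, 70.3, 59.2)
        assert m_ffm / m == pytest.approx(70.3 / 59.2)

    def test_urinary_correction_subtracts(self):
        rec = _record([0, 60], [40, 40], [5.3, 5.3], (0, 60))
        m0, _ = m_value(rec, 70.0, 59.0)
        m1, _ = m_value(rec, 70.0, 59.0, urinary_glucose_umol=70.0 * 60.0 * 2)
        assert m0 - m1 == pytest.approx(2.0)

    def test_rising_glycemia_lowers_m(self):
        flat = _record([0, 60], [40, 40], [5.3, 5.3], (0, 60))
        rising = _record([0, 60], [40, 40], [5.3, 5.8], (0, 60))
        assert m_value(rising, 70, 59)[0] < m_value(flat, 70, 59)[0]

    def test_empty_window_rejected(self):
        rec = _record([0, 30, 60], [40] * 3, [5.3] * 3, (59.9, 60.0))
        with pytest.raises(ValueError, match="window"):
            m_value(rec, 70, 59)

    def test_noise_free_generator_round_trip(self):
        rec = make_clamp_record(47.3, 5.3, 500.0, 0.3, 0.03,
                                t_steady_min=80.0, rng=None)
        m, _ = m_value(rec, 70.0, 59.0)
        assert m == pytest.approx(47.3, abs=1e-6)

    def test_noisy_generator_unbiased(self):
        rng = np.random.default_rng(99)
        ests = []
        for _ in range(1000):
            rec = make_clamp_record(47.3, 5.3, 500.0, 0.3, 0.03,
                                    t_steady_min=80.0, rng=rng)
            ests.append(m_value(rec, 70.0, 59.0)[0])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 47.3) < 4 * se + 0.05


class TestRdFromTracer:
    def test_full_excretion_gives_zero(self):
        f = InputFunction([0.0, 10.0, 20.0, 30.0],
                          np.exp(-0.05 * np.array([0, 10, 20, 30.0])))
        tb = TracerBalance(150.0, 150.0, 70.0)
        assert rd_from_tracer(tb, f, 5.3) == 0.0

    def test_mono_exponential_closed_form(self):
        # Cp = C0*exp(-lam*t): CL = dose*lam/C0 analytically
        c0, lam, dose, weight, glucose = 40.0, 0.08, 156.0, 70.0, 5.3
        t = np.linspace(0, 60, 25)
        f = InputFunction(t, c0 * np.exp(-lam * t))
        tb = TracerBalance(dose, 0.0, weight)
        expected = (dose * 1000 * lam / c0 / 1000) * glucose * 1000 / weight
        # trapezoidal quadrature over the 25 knots carries ~0.3% error
        assert rd_from_tracer(tb, f, glucose) == pytest.approx(expected, rel=7e-3)

    def test_linear_in_glucose(self):
        t = np.linspace(0, 60, 25)
        f = InputFunction(t, 40 * np.exp(-0.08 * t))
        tb = TracerBalance(156.0, 10.0, 70.0)
        assert rd_from_tracer(tb, f, 10.6) == pytest.approx(
            2 * rd_from_tracer(tb, f, 5.3), rel=1e-12)

    def test_invariant_to_joint_rescaling(self):
        t = np.linspace(0, 60, 25)
        cp = 40 * np.exp(-0.08 * t)
        rd1 = rd_from_tracer(TracerBalance(156.0, 6.0, 70.0),
                             InputFunction(t, cp), 5.3)
        rd2 = rd_from_tracer(TracerBalance(156.0 * 3, 18.0, 70.0),
                             InputFunction(t, cp * 3), 5.3)
        assert rd1 == pytest.approx(rd2, rel=1e-10)


class TestEGP:
    def test_balance(self):
        assert egp(40.0, 40.0) == 0.0
        assert egp(40.0, 43.4) == pytest.approx(-3.4)

    @given(st.floats(-500, 500), st.floats(0, 500))
    @settings(deadline=None, max_examples=200)
    def test_identity_egp_plus_gir_is_rd(self, rd, gir):
        # identity holds to machine precision (one rounding step)
        tol = 1e-12 * max(1.0, abs(rd), abs(gir))
        assert abs(egp(rd, gir) + gir - rd) <= tol

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            egp(np.nan, 40.0)


class TestMatsuda:
    def test_hand_arithmetic(self):
        # conventional-unit inputs G0=90 mg/dL, I0=10 uU/mL, Gbar=100,
        # Ibar=50 -> 10000/sqrt(90*10*100*50) = 4.714
        isi = matsuda_isi(90 / 18.016, 10 * 6.0, 100 / 18.016, 50 * 6.0)
        assert isi == pytest.approx(10000 / np.sqrt(90 * 10 * 100 * 50),
                                    rel=1e-12)
        assert isi == pytest.approx(4.714, abs=5e-4)

    def test_doubling_insulin_halves_index(self):
        base = matsuda_isi(5.0, 40.0, 6.0, 200.0)
        assert matsuda_isi(5.0, 80.0, 6.0, 400.0) == pytest.approx(base / 2)

    def test_published_group_means_reproduce_reported_indices(self):
        # LR/HR fasting and 2-h OGTT group means land near the reported
        # group Matsuda values (11.0 and 4.9)
        lr = matsuda_isi(4.9, 38.7, (4.9 + 4.8) / 2, (38.7 + 160.7) / 2)
        hr = matsuda_isi(5.5, 61.8, (5.5 + 5.9) / 2, (61.8 + 328.2) / 2)
        assert lr == pytest.approx(11.0, abs=0.5)
        assert hr == pytest.approx(4.9, abs=0.8)
        assert hr < lr

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            matsuda_isi(0.0, 40.0, 5.0, 200.0)


class TestHbA1c:
    @pytest.mark.parametrize("ifcc,ngsp", [(29, 4.8), (32, 5.1)])
    def test_published_rows(self, ifcc, ngsp):
        assert round(ifcc_to_ngsp(ifcc), 1) == ngsp

    def test_round_trip(self):
        assert ngsp_to_ifcc(ifcc_to_ngsp(31.7)) == pytest.approx(31.7, abs=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ifcc_to_ngsp(0.0)


class TestFFASuppression:
    def test_no_suppression(self):
        assert ffa_suppression(0.3, 0.3) == 0.0

    def test_published_lr_values(self):
        assert ffa_suppression(0.3, 0.03) == pytest.approx(90.0)

    def test_negative_allowed_when_ffa_rises(self):
        assert ffa_suppression(0.3, 0.45) == pytest.approx(-50.0)

    def test_zero_fasting_rejected(self):
        with pytest.raises(ValueError):
            ffa_suppression(0.0, 0.03)
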