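import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from porocoil.metrics import (
    area_average,
    characterize_curve,
    osi,
    rfv_av,
    tawss,
)
from porocoil.reference import reference_sweep
from porocoil.solver import FlowField


def make_field(nx, ny, speed):
    """Uniform +x flow at the given speed."""
    return FlowField(
        u=np.full((nx + 1, ny), speed),
        v=np.zeros((nx, ny + 1)),
        p=np.zeros((nx, ny)),
        mu=np.full((nx, ny), 0.00345),
    )


class TestTAWSS:
    def test_constant_signal(self):
        t = np.linspace(0, 1, 16)
        series = np.full((16, 3), -2.5)
        assert np.allclose(tawss(series, t), 2.5)

    def test_rectified_sine_mean(self):
        t = np.linspace(0, 1, 400)
        series = np.sin(2 * np.pi * t)[:, None] * 1.7
        assert tawss(series, t)[0] == pytest.approx(2 * 1.7 / np.pi, rel=1e-3)

    def test_matches_dense_sampling_oracle(self):
        # the same smooth WSS-magnitude waveform sampled at 64 vs 4001
        # points: trapezoid quadrature must agree within 1 %
        signal = lambda t: 1.5 + np.sin(2 * np.pi * t / 0.8) * np.cos(6 * np.pi * t / 0.8)
        t = np.linspace(0, 0.8, 64)
        t_fine = np.linspace(0, 0.8, 4001)
        coarse = np.column_stack([signal(t), 0.5 * signal(t)])
        fine = np.column_stack([signal(t_fine), 0.5 * signal(t_fine)])
        assert np.allclose(tawss(coarse, t), tawss(fine, t_fine), rtol=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tawss(np.ones((4, 1)), np.linspace(0, 1, 4))


class TestOSI:
    def test_constant_direction_is_zero(self):
        t = np.linspace(0, 1, 32)
        series = np.ones((32, 2, 2))
        assert np.allclose(osi(series, t), 0.0)

    def test_sign_reversing_sine_is_half(self):
        t = np.linspace(0, 1, 1001)
        series = np.sin(2 * np.pi * t)[:, None, None] * np.array([[[1.0, 0.0]]])
        assert osi(series, t)[0] == pytest.approx(0.5, abs=1e-6)

    def test_asymmetric_reversal_matches_scalar_oracle(self):
        # half cycle at +tau0, half at -tau0/2:
        # |mean| integral = tau0/4, magnitude integral = 3 tau0/4 -> OSI = 1/3
        t = np.linspace(0, 1, 20001)
        signal = np.where(t < 0.5, 1.0, -0.5)
        series = signal[:, None, None] * np.array([[[1.0, 0.0]]])
        assert osi(series, t)[0] == pytest.approx(0.5 * (1 - (1 / 4) / (3 / 4)), abs=1e-3)

    def test_all_zero_face_defined_as_zero(self):
        t = np.linspace(0, 1, 16)
        assert osi(np.zeros((16, 1, 2)), t)[0] == 0.0

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_bounds_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 32)
        series = rng.normal(size=(32, 4, 2))
        o = osi(series, t)
        assert np.all((o >= 0.0) & (o <= 0.5))
        # TAWSS >= |time-averaged vector| for every face
        mean_vec = np.linalg.norm(np.trapezoid(series, t, axis=0), axis=1)
        assert np.all(tawss(series, t) + 1e-12 >= mean_vec)


class TestRFV:
    def test_uniform_speeds(self):
        mask = np.ones((8, 4), dtype=bool)
        fast = make_field(8, 4, 0.02)
        slow = make_field(8, 4, 0.005)
        assert rfv_av(fast, mask, 1.0)[2] == 100.0
        assert rfv_av(slow, mask, 1.0)[2] == 0.0

    def test_half_above_threshold(self):
        mask = np.ones((8, 4), dtype=bool)
        f = make_field(8, 4, 0.005)
        f.u[:, 2:] = 0.02  # top half moving fast
        assert rfv_av(f, mask, 1.0)[2] == pytest.approx(50.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        mask = np.ones((10, 10), dtype=bool)
        f = make_field(10, 10, 0.0)
        f.u[:] = rng.uniform(0, 0.05, size=f.u.shape)
        ratios = [rfv_av(f, mask, 1.0, threshold=th)[2] for th in np.linspace(0, 0.05, 11)]
        assert all(b <= a for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == 100.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            rfv_av(make_field(4, 4, 0.1), np.zeros((4, 4), bool), 1.0)


class TestAreaAverage:
    def test_uniform_field(self):
        assert area_average(np.full(7, 3.3)) == pytest.approx(3.3)

    def test_two_equal_faces(self):
        assert area_average([1.0, 5.0], [2.0, 2.0]) == pytest.approx(3.0)

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=30)
        areas = rng.uniform(0.1, 2.0, size=30)
        expected = sum(v * a for v, a in zip(vals, areas)) / sum(areas)
        assert area_average(vals, areas) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            area_average([])


class TestCharacterizeCurve:
    def test_logistic_steepest_at_midpoint(self):
        vpd = np.arange(0.0, 31.0)
        y = 100.0 / (1.0 + np.exp((vpd - 15.0) / 3.0))
        desc = characterize_curve(pd.DataFrame({"vpd_pct": vpd, "y": y}), "y")
        assert 14.0 <= desc.steepest_interval[0] <= 15.0
        assert desc.monotone_tail

    def test_exponential_decay_flags_asymptote(self):
        vpd = np.arange(0.0, 31.0, 5.0)
        y = 5.0 * np.exp(-vpd / 6.0)
        desc = characterize_curve(pd.DataFrame({"vpd_pct": vpd, "y": y}), "y")
        assert desc.asymptote_flag
        assert desc.asymptote_value == pytest.approx(y[-1])

    def test_noisy_tail_marks_no_asymptote(self):
        vpd = np.arange(0.0, 31.0, 5.0)
        y = np.array([10.0, 8.0, 9.5, 7.0, 9.0, 6.0, 8.5])
        desc = characterize_curve(pd.DataFrame({"vpd_pct": vpd, "y": y}), "y")
        assert not desc.asymptote_flag
        assert not desc.monotone_tail

    def test_too_few_rows_rejected(self):
        frame = pd.DataFrame({"vpd_pct": [0, 1], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            characterize_curve(frame, "y")


class TestReferenceSweepShape:
    """Qualitative claims about the published stationary sweep table."""

    def test_rfv_sigmoid_steepest_between_10_and_20(self):
        desc = characterize_curve(reference_sweep(), "rfv_av_pct")
        assert 10.0 <= desc.steepest_interval[0] and desc.steepest_interval[1] <= 20.0
        assert desc.monotone_tail and desc.tail_direction == "decreasing"
        assert desc.asymptote_flag

    def test_wss_asymptotic_decrease(self):
        desc = characterize_curve(reference_sweep(), "wss_aneurysm")
        assert desc.monotone_tail and desc.tail_direction == "decreasing"
        assert desc.asymptote_flag
        assert desc.steepest_interval == (0.0, 1.0)

    def test_pressure_extrema_locations(self):
        desc = characterize_curve(reference_sweep(), "pressure_aneurysm")
        assert desc.vpd_of_max == 10.0
        assert desc.vpd_of_min == 2.0
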