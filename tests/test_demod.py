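"""Demodulator recurrence, closed-form responses and rejection properties."""

import math

import numpy as np
import pytest
from scipy.signal import lfilter

import fluorlock as fl
from fluorlock.errors import ConfigError, CorruptInputError


class TestReferences:
    @pytest.mark.parametrize(
        "n, expected",
        [(0, (1.0, 0.0)), (122, (0.0, 1.0)), (244, (-1.0, 0.0)), (488, (1.0, 0.0))],
    )
    def test_quadrature_pair(self, n, expected):
        qx, qy = fl.references(n, 488)
        assert qx == pytest.approx(expected[0], abs=1e-12)
        assert qy == pytest.approx(expected[1], abs=1e-12)

    def test_period_m_in_n(self):
        n = np.arange(488)
        qx0, qy0 = fl.references(n, 488)
        qx1, qy1 = fl.references(n + 488 * 7, 488)
        np.testing.assert_allclose(qx0, qx1, atol=1e-9)
        np.testing.assert_allclose(qy0, qy1, atol=1e-9)


class TestStep:
    def test_zero_input_stays_zero(self, cfg):
        state = fl.DemodState.zeros(cfg.n_stages)
        for _ in range(500):
            state, r2 = fl.step(state, 0.0, cfg)
            assert r2 == 0.0
        assert state.n == 500

    def test_non_finite_sample_rejected(self, cfg):
        state = fl.DemodState.zeros(cfg.n_stages)
        with pytest.raises(CorruptInputError):
            fl.step(state, float("nan"), cfg)

    def test_stage_count_mismatch_rejected(self, cfg):
        with pytest.raises(ConfigError):
            fl.step(fl.DemodState.zeros(3), 1.0, cfg)

    def test_matches_vectorised_filter(self, cfg):
        rng = np.random.default_rng(42)
        samples = rng.integers(0, 4096, 3000).astype(float)
        state = fl.DemodState.zeros(cfg.n_stages)
        for s in samples:
            state, r2 = fl.step(state, float(s), cfg)
        x2, y2, final = fl.lockin_filter(samples, cfg)
        assert state.x2 == pytest.approx(x2[-1], rel=1e-10, abs=1e-14)
        assert state.y2 == pytest.approx(y2[-1], rel=1e-10, abs=1e-14)
        assert final.n == state.n


class TestClosedFormResponses:
    def test_dc_input_rejected(self, cfg):
        """A constant input is orthogonal to both references: the oscillating
        products average to (nearly) zero."""
        n_samples = fl.settling_samples(cfg, 10)
        trace = fl.demodulate(np.full(n_samples, 1000.0), cfg)
        assert trace.values[-1] < 1e-3 * 1000.0

    @pytest.mark.parametrize("phi", [0.0, 1.0, 2.5, 4.5])
    def test_on_frequency_tone_reads_half_amplitude(self, cfg, phi):
        """A settled tone A*cos(2*pi*n/m + phi) demodulates to A/2 for any
        phase (unit-amplitude reference convention)."""
        n = np.arange(fl.settling_samples(cfg, 12))
        tone = np.cos(2 * np.pi * n / cfg.m + phi)
        trace = fl.demodulate(tone, cfg)
        assert trace.values[-1] == pytest.approx(0.5, abs=1e-3)

    def test_second_harmonic_rejected(self, cfg):
        n = np.arange(fl.settling_samples(cfg, 12))
        tone = 1000.0 * np.cos(2 * np.pi * 2 * n / cfg.m)
        trace = fl.demodulate(tone, cfg)
        assert trace.values[-1] < 1e-3 * 1000.0

    def test_linearity_over_two_decades(self, cfg, settled_unit_tone):
        """Settled output is proportional to tone amplitude; the slope is
        constant to <0.1% from A=0.01 to A=1."""
        r_small = fl.demodulate(0.01 * settled_unit_tone, cfg).values[-1]
        r_big = fl.demodulate(settled_unit_tone, cfg).values[-1]
        assert r_big / r_small == pytest.approx(100.0, rel=1e-3)

    def test_single_stage_matches_fourier_quadrature_oracle(self):
        """With one filter stage, the settled channel means agree with the
        direct Fourier quadrature sums of the input over whole periods."""
        cfg = fl.DemodConfig(n_stages=1)
        m = cfg.m
        n = np.arange(fl.settling_samples(cfg, 14))
        # periodic input with several harmonics and a DC pedestal
        signal = (
            120.0
            + 80.0 * np.cos(2 * np.pi * n / m + 0.7)
            + 30.0 * np.cos(2 * np.pi * 3 * n / m)
            + 10.0 * np.sin(2 * np.pi * 2 * n / m)
        )
        x1, y1, _ = fl.lockin_filter(signal, cfg)
        # channel means over whole periods, so demodulation ripple cancels
        x1_mean = np.mean(x1[-10 * m :])
        y1_mean = np.mean(y1[-10 * m :])
        # oracle: quadrature sums over an integer number of periods
        period = signal[:m]
        qx, qy = fl.references(np.arange(m), m)
        ax = np.mean(period * qx)  # settled filter output equals this DC term
        ay = np.mean(period * qy)
        assert x1_mean == pytest.approx(ax, rel=1e-3)
        assert y1_mean == pytest.approx(ay, rel=1e-3)
        assert math.hypot(ax, ay) == pytest.approx(80.0 / 2, rel=1e-3)

    def test_off_frequency_tone_attenuated_by_filter_skirt(self, cfg):
        """A tone df off-frequency is suppressed by at least the two-pole
        roll-off (1 + (df/fc)^2)^(n_stages/2), within 3 dB."""
        df = 10.0
        r_on = fl.settled_tone_response(cfg.f0, cfg)
        r_off = fl.settled_tone_response(cfg.f0 + df, cfg)
        bound = (1.0 + (df / cfg.cutoff) ** 2) ** (cfg.n_stages / 2.0)
        assert r_on / r_off >= bound / 10 ** (3 / 20)


class TestDemodulate:
    def test_zeros_give_zero_trace_of_expected_length(self, cfg):
        trace = fl.demodulate(np.zeros(int(2.0 * cfg.fs)), cfg)
        assert len(trace) == 20
        assert np.all(trace.values == 0.0)
        np.testing.assert_allclose(np.diff(trace.times), 0.1, atol=1 / cfg.fs)

    def test_empty_stream_gives_empty_trace(self, cfg):
        trace = fl.demodulate(np.empty(0), cfg)
        assert len(trace) == 0

    def test_rate_mismatch_rejected(self, cfg):
        stream = fl.SampleStream(counts=np.zeros(10, dtype=int), fs=96_000.0)
        with pytest.raises(ConfigError):
            fl.demodulate(stream, cfg)

    def test_ten_second_tone_of_amplitude_two_reads_one(self, cfg):
        n = np.arange(int(10.0 * cfg.fs))
        trace = fl.demodulate(2.0 * np.cos(2 * np.pi * n / cfg.m), cfg)
        assert len(trace) == 100
        assert trace.values[-1] == pytest.approx(1.0, abs=2e-3)

    def test_dc_offset_does_not_move_settled_output(self, cfg, settled_unit_tone):
        base = fl.demodulate(settled_unit_tone, cfg).values[-1]
        shifted = fl.demodulate(settled_unit_tone + 700.0, cfg).values[-1]
        assert abs(shifted - base) < 1e-3


class TestNumericPrecision:
    def test_single_precision_accumulator_stalls(self):
        """With alpha ~ 8e-6 the per-sample increment underflows a float32
        accumulator's resolution: the filter stalls visibly short of its
        asymptote, which is why the recurrence must run in float64."""
        alpha = 7.85e-6
        n = 1_300_000  # ~10 tau
        x = np.full(n, 1000.0)
        b, a = [alpha], [1.0, -(1.0 - alpha)]
        y64 = lfilter(b, a, x.astype(np.float64))[-1]
        y32 = lfilter(
            np.asarray(b, np.float32), np.asarray(a, np.float32), x.astype(np.float32)
        )[-1]
        assert abs(y64 - 1000.0 * (1 - math.exp(-n * alpha))) < 0.05
        assert abs(y32 - y64) > 1.0  # stalled > 0.1% short


class TestLockInDemodulatorEstimator:
    def test_sklearn_params_round_trip(self):
        demod = fl.LockInDemodulator(m=488, alpha=1e-5)
        params = demod.get_params()
        clone = fl.LockInDemodulator(**params)
        assert clone.get_params() == params

    def test_transform_rows_independently(self, cfg):
        demod = fl.LockInDemodulator(output_interval=0.01)
        n = np.arange(int(0.1 * cfg.fs))
        X = np.stack([np.cos(2 * np.pi * n / 488), np.zeros_like(n, dtype=float)])
        out = demod.fit_transform(X)
        assert out.shape == (2, 10)
        assert np.all(out[1] == 0.0)
        assert np.all(out[0] >= 0.0)

    def test_one_dim_input_equals_demodulate(self, cfg):
        n = np.arange(int(0.5 * cfg.fs))
        tone = np.cos(2 * np.pi * n / cfg.m)
        demod = fl.LockInDemodulator()
        np.testing.assert_allclose(
            demod.fit(None).transform(tone), fl.demodulate(tone, cfg).values
        )
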