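"""Unit and property tests for the stimulus envelope, reuptake law and ODE core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dakinetics.model import (
    IntegrationError,
    KineticParameters,
    ResolutionError,
    StimulusProtocol,
    ValidationError,
    observable,
    reuptake_rate,
    simulate,
    state_derivative,
    stimulus_envelope,
)

from ._oracle import euler_simulate


class TestStimulusEnvelope:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, 0.0),  # before onset
            (0.999, 0.0),
            (1.0, 1.0),  # closed at onset
            (1.3, 1.0),  # inside window
            (1.6, 1.0),  # closed at offset
            (1.601, 0.0),
            (5.0, 0.0),
        ],
    )
    def test_single_burst_indicator(self, protocol, t, expected):
        assert stimulus_envelope(t, protocol) == expected

    def test_window_length_is_np_over_f(self, protocol):
        """30 pulses at 50 Hz stimulate for exactly 0.6 s."""
        t = np.arange(0, 3.0, 1e-4)
        on = stimulus_envelope(t, protocol)
        measured = (on.sum() - 1) * 1e-4  # closed window: one extra grid point
        assert measured == pytest.approx(0.6, abs=1e-9)

    def test_multi_burst_windows(self):
        prot = StimulusProtocol(
            n_pulses=10, frequency=50.0, onset=1.0, n_bursts=2, inter_burst_interval=1.0
        )
        assert stimulus_envelope(1.1, prot) == 1.0
        assert stimulus_envelope(1.5, prot) == 0.0  # between bursts
        assert stimulus_envelope(2.3, prot) == 1.0  # second burst
        assert prot.end == pytest.approx(2.4)

    def test_negative_time_rejected(self, protocol):
        with pytest.raises(ValidationError):
            stimulus_envelope(-0.1, protocol)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_pulses": 0},
            {"frequency": 0.0},
            {"current": -1.0},
            {"onset": -0.5},
            {"n_bursts": 0},
        ],
    )
    def test_invalid_protocol_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            StimulusProtocol(**kwargs)


class TestReuptakeRate:
    def test_half_saturation(self, wt_params):
        assert reuptake_rate(wt_params.km, wt_params) == pytest.approx(
            wt_params.vm / 2
        )

    def test_zero_substrate(self, wt_params):
        assert reuptake_rate(0.0, wt_params) == 0.0

    def test_near_saturation_value(self, wt_params):
        # closed form at 100·Km: Vm·100/101
        assert reuptake_rate(100 * wt_params.km, wt_params) == pytest.approx(
            7.4 * 100 / 101
        )

    def test_negative_substrate_rejected(self, wt_params):
        with pytest.raises(ValidationError):
            reuptake_rate(-0.01, wt_params)

    @given(
        da=st.floats(0.0, 1e4),
        da_hi=st.floats(0.0, 1e4),
    )
    def test_saturation_and_monotonicity(self, da, da_hi, wt_params):
        lo, hi = sorted([da, da_hi])
        r_lo = reuptake_rate(lo, wt_params)
        r_hi = reuptake_rate(hi, wt_params)
        assert 0.0 <= r_lo <= r_hi <= wt_params.vm


class TestKineticParameters:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            KineticParameters(km=0.0)
        with pytest.raises(ValidationError):
            KineticParameters(L=1.5)
        with pytest.raises(ValidationError):
            KineticParameters(vm=-1.0)
        with pytest.raises(ValidationError):
            KineticParameters(free=frozenset({"kgamma"}))  # kgamma is not fittable

    def test_fixed_values_excludes_free(self, wt_params):
        fixed = wt_params.fixed_values()
        assert "vm" not in fixed and "dap" not in fixed
        assert fixed["km"] == 0.2


class TestSimulate:
    def test_peak_without_uptake_or_transfer(self, protocol):
        """With reuptake and transfer off, [DA]_S integrates the source exactly:
        DAP·I·L·NP = 0.67·0.4·1·30 = 8.04 μM."""
        p = KineticParameters(
            vm=0.0, dap=0.67, ks=0.0, ke=0.0, k1ads=0.0, k2ads=0.0, k3ads=0.0
        )
        trace = simulate(p, protocol, duration=3.0)
        assert trace.da_s.max() == pytest.approx(8.04, rel=1e-3)

    def test_conservation_with_zero_uptake(self, protocol, wt_params):
        """Cumulative release is conserved in [DA]_S when Vm = 0 (Eq. 1 has no
        other sink), regardless of the electrode transfer parameters."""
        p = wt_params.with_values(vm=0.0)
        trace = simulate(p, protocol, duration=3.0)
        expected = 0.67 * 0.4 * 1.0 * 30
        assert trace.da_s[-1] == pytest.approx(expected, rel=1e-3)

    def test_zero_stimulation_stays_zero(self, wt_params):
        prot = StimulusProtocol(current=0.0)
        trace = simulate(wt_params, prot, duration=3.0)
        assert np.all(trace.da_s == 0) and np.all(trace.da_e == 0)
        assert np.all(trace.gamma == 0)

    def test_striatal_release_bound(self, wt_trace, protocol, wt_params):
        bound = wt_params.dap * protocol.current * wt_params.L * protocol.n_pulses
        assert wt_trace.da_s.max() <= bound * (1 + 1e-9)

    def test_states_nonnegative_and_decaying(self, wt_trace):
        for series in (wt_trace.da_s, wt_trace.da_e, wt_trace.gamma):
            assert series.min() >= -1e-9
        # all states relax toward zero well after stimulation
        tail = wt_trace.time > 10.0
        assert wt_trace.da_s[tail].max() < 1e-3 * wt_trace.da_s.max()
        assert wt_trace.da_e[tail].max() < 0.05 * wt_trace.da_e.max()

    @pytest.mark.parametrize("genotype", ["wt", "ko"])
    def test_rk4_matches_fine_euler_oracle(
        self, protocol, wt_params, ko_params, genotype
    ):
        """RK4 at 1 ms agrees with a brute-force Euler oracle at 10 μs."""
        params = wt_params if genotype == "wt" else ko_params
        trace = simulate(params, protocol, duration=4.0, dt=1e-3)
        t_o, _, da_e_o, _ = euler_simulate(params, protocol, duration=4.0, dt=1e-5)
        coarse = np.rint(trace.time / 1e-5).astype(int)
        assert np.max(np.abs(trace.da_e - da_e_o[coarse])) < 1e-3

    def test_adsorption_steady_state(self, wt_params):
        """With [DA]_E clamped, Γ_DA converges to k1·c/(k2·c + k3)."""
        c = 2.0
        p = wt_params
        g = 0.0
        dt = 1e-4
        horizon = 10.0 / (p.k2ads * c + p.k3ads)
        for _ in range(int(horizon / dt)):
            _, _, dg = state_derivative((0.0, c, g), 0.0, p)
            g += dt * dg
        expected = p.k1ads * c / (p.k2ads * c + p.k3ads)
        assert g == pytest.approx(expected, rel=1e-3)

    def test_decay_slower_for_smaller_vm(self, protocol, wt_params):
        lo = simulate(wt_params.with_values(vm=2.0), protocol, duration=8.0)
        hi = simulate(wt_params.with_values(vm=7.4), protocol, duration=8.0)
        post = lo.time > protocol.end
        assert np.all(lo.da_s[post] >= hi.da_s[post] - 1e-12)

    def test_duration_must_cover_stimulus(self, protocol, wt_params):
        with pytest.raises(ValidationError):
            simulate(wt_params, protocol, duration=1.5)
        with pytest.raises(ValidationError):
            simulate(wt_params, protocol, duration=5.0, dt=0.0)

    def test_nonfinite_state_reported_with_time(self, protocol, wt_params):
        runaway = wt_params.with_values(kgamma=1e6, k1ads=1e6)
        with pytest.raises(IntegrationError, match="t ="):
            simulate(runaway, protocol, duration=3.0)


class TestObservable:
    def test_sample_count(self, wt_params, protocol):
        trace = simulate(wt_params, protocol, duration=10.0, dt=1e-3)
        rec = observable(trace, sample_rate=10.0)
        assert len(rec.time) == 101

    def test_full_rate_is_identity(self, wt_trace):
        rec = observable(wt_trace, sample_rate=1.0 / wt_trace.dt)
        assert np.array_equal(rec.signal, wt_trace.da_e)

    def test_downsampling_preserves_constant(self, wt_trace):
        from dataclasses import replace

        const = replace(wt_trace, da_e=np.full_like(wt_trace.da_e, 1.23))
        rec = observable(const, sample_rate=7.0)
        assert np.all(rec.signal == 1.23)

    def test_rate_above_resolution_rejected(self, wt_trace):
        with pytest.raises(ResolutionError):
            observable(wt_trace, sample_rate=2000.0)
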