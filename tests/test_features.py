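import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnstephys import Sweep, SweepSet
from bnstephys.protocols import ProtocolSpec, EXCITABILITY, IH, MFR
from bnstephys.features import (
    detect_spikes, count_evoked_spikes, rebound_spikes, voltage_sag,
    ih_amplitude, ih_density, detect_block, spikes_before_block,
    max_firing_rate, isi_list, first_isi, first_spike_latency, isi_histogram,
    passive_properties, ModeError,
)
from oracles import spike_oracle


def cc_sweep(v, dt=0.1, amp=0.0, protocol=None):
    v = np.asarray(v, dtype=float)
    proto = protocol or ProtocolSpec(
        name="t", mode="current_clamp", holding=-60.0, step_onset=100.0,
        step_duration=500.0, post_window=max(v.size * dt - 600.0, 0.0),
        amplitudes=(amp,) if amp else (0.0,))
    return Sweep(dt=dt, command=np.full(v.size, amp), response=v,
                 step_amplitude=amp, mode="current_clamp", protocol=proto)


def spikes_at(times_ms, n_ms=1100.0, dt=0.1, base=-60.0, amp=10.0):
    """Synthetic trace with 1-sample spike peaks at the given times."""
    n = int(n_ms / dt)
    v = np.full(n, base)
    for t in times_ms:
        v[int(t / dt)] = 30.0
    return cc_sweep(v, dt=dt, amp=amp)


class TestDetectSpikes:
    def test_constant_trace_no_events(self):
        assert detect_spikes(cc_sweep(np.full(5000, -60.0))).size == 0

    def test_sine_10hz_five_peaks(self):
        """40 mV 10 Hz sine over 500 ms crosses 0 upward 5 times."""
        dt = 0.1
        t = np.arange(int(500 / dt)) * dt
        v = 40.0 * np.sin(2 * np.pi * 10.0 * t / 1000.0)
        times = detect_spikes(cc_sweep(v, dt=dt))
        assert len(times) == 5
        assert np.allclose(times, [25.0, 125.0, 225.0, 325.0, 425.0], atol=dt)

    def test_mode_error_on_voltage_clamp(self):
        sw = Sweep(dt=0.1, command=np.zeros(10), response=np.zeros(10),
                   step_amplitude=-100.0, mode="voltage_clamp")
        with pytest.raises(ModeError):
            detect_spikes(sw)

    def test_matches_oracle_on_simulated_sweep(self, template_runs):
        _, rec, _ = template_runs["I"]
        sw = rec.sweep_sets["excitability"].by_amplitude(60.0)
        got = detect_spikes(sw)
        exp = spike_oracle(sw.response, sw.dt)
        assert np.allclose(got, exp)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_traces(self, seed):
        from oracles import bandlimited_traces

        v = bandlimited_traces(1, 2000, seed)[0]
        sw = cc_sweep(v, dt=0.1)
        assert np.allclose(detect_spikes(sw), spike_oracle(v, 0.1))


class TestWindows:
    def test_count_restricted_to_step_window(self):
        sw = spikes_at([50.0, 200.0, 620.0])
        assert count_evoked_spikes(sw) == 1

    def test_no_spikes_zero(self):
        assert count_evoked_spikes(spikes_at([])) == 0

    def test_rebound_counts_post_offset_only(self):
        sw = spikes_at([150.0, 300.0, 550.0], amp=-80.0)
        assert rebound_spikes(sw) == 0
        sw = spikes_at([610.0, 700.0], amp=-80.0)
        assert rebound_spikes(sw) == 2

    def test_fsl_relative_to_onset(self):
        assert first_spike_latency(spikes_at([150.0])) == pytest.approx(50.0)

    def test_fsl_missing_without_spikes(self):
        assert first_spike_latency(spikes_at([])) is None


class TestSag:
    def test_analytic_drop_and_plateau(self):
        """Drop to -85 then relax to a -75 plateau during the step: 10 mV."""
        dt = 0.1
        n = int(1100 / dt)
        t = np.arange(n) * dt
        v = np.full(n, -70.0)
        onstep = (t >= 100.0) & (t < 600.0)
        ts = t[onstep] - 100.0
        v[onstep] = -75.0 - 10.0 * np.exp(-ts / 20.0)
        sw = cc_sweep(v, dt=dt, amp=-80.0)
        assert voltage_sag(sw) == pytest.approx(10.0, abs=0.05)

    def test_constant_step_zero(self):
        sw = cc_sweep(np.full(11000, -70.0), amp=-50.0)
        assert voltage_sag(sw) == 0.0

    def test_monotone_relaxation_without_undershoot_is_zero(self):
        dt = 0.1
        n = int(1100 / dt)
        t = np.arange(n) * dt
        v = np.full(n, -60.0)
        onstep = (t >= 100.0) & (t < 600.0)
        v[onstep] = -80.0 + 5.0 * np.exp(-(t[onstep] - 100.0) / 50.0)
        assert voltage_sag(cc_sweep(v, dt=dt, amp=-80.0)) == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-30.0, 30.0))
    def test_offset_invariance(self, off):
        dt = 0.1
        n = int(1100 / dt)
        t = np.arange(n) * dt
        v = np.full(n, -70.0)
        onstep = (t >= 100.0) & (t < 600.0)
        v[onstep] = -78.0 - 9.0 * np.exp(-(t[onstep] - 100.0) / 30.0)
        a = voltage_sag(cc_sweep(v, dt=dt, amp=-80.0))
        b = voltage_sag(cc_sweep(v + off, dt=dt, amp=-80.0))
        assert a == pytest.approx(b, abs=1e-9)


def vc_fixture(tau=100.0, dI=50.0, base=-100.0, dt=0.1):
    n = int(1000 / dt)
    t = np.arange(n) * dt
    i = np.full(n, -20.0)
    onstep = (t >= IH.step_onset) & (t < IH.step_offset)
    ts = t[onstep] - IH.step_onset
    i[onstep] = base - dI * (1.0 - np.exp(-ts / tau))
    cmd = IH.command_waveform(-150.0, dt)[:n]
    return Sweep(dt=dt, command=cmd, response=i, step_amplitude=-150.0,
                 mode="voltage_clamp", protocol=IH)


class TestIh:
    def test_closed_form_fixture(self):
        """Analytic clamp current -100 - 50(1-e^(-t/100)) pA: the measured
        amplitude equals 50 (1 - e^(-t/100)) evaluated at the windows."""
        sw = vc_fixture()
        inst = np.mean([50.0 * (1 - math.exp(-tt / 100.0))
                        for tt in np.arange(10.0, 30.0, 0.1)])
        steady = np.mean([50.0 * (1 - math.exp(-tt / 100.0))
                          for tt in np.arange(750.0, 800.0, 0.1)])
        assert ih_amplitude(sw) == pytest.approx(steady - inst, rel=1e-3)

    def test_density_arithmetic(self):
        assert ih_density(50.0, 50.0) == 1.0

    def test_density_missing_capacitance(self):
        assert ih_density(50.0, None) is None

    def test_gh_zero_amplitude_negligible(self, sim_config):
        import dataclasses
        from bnstephys import TEMPLATES, simulate_voltage_clamp

        p = dataclasses.replace(TEMPLATES["III"], g_h=0.0)
        ss = simulate_voltage_clamp(p, IH, sim_config)
        assert ih_amplitude(ss.by_amplitude(-150.0)) < 0.5

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-50.0, 50.0))
    def test_offset_invariance(self, off):
        sw = vc_fixture()
        sw2 = Sweep(dt=sw.dt, command=sw.command, response=sw.response + off,
                    step_amplitude=-150.0, mode="voltage_clamp", protocol=IH)
        assert ih_amplitude(sw) == pytest.approx(ih_amplitude(sw2), abs=1e-9)


class TestMfr:
    def _set(self, counts: dict, block_at: dict = {}):
        dt, sweeps = 0.5, []
        for amp, c in counts.items():
            n = int(MFR.sweep_duration / dt)
            v = np.full(n, -60.0)
            for k in range(c):
                v[int((MFR.step_onset + 10 + 25 * k) / dt)] = 30.0
            sweeps.append(Sweep(dt=dt, command=MFR.command_waveform(amp, dt),
                                response=v, step_amplitude=amp,
                                mode="current_clamp", protocol=MFR))
        return SweepSet(protocol=MFR, sweeps=sweeps)

    def test_argmax(self):
        ss = self._set({50.0: 2, 100.0: 5, 150.0: 9, 200.0: 4})
        assert max_firing_rate(ss) == (9, 150.0)

    def test_tie_breaks_to_lowest_step(self):
        ss = self._set({100.0: 7, 150.0: 7})
        assert max_firing_rate(ss) == (7, 100.0)

    def test_no_spikes_missing(self):
        ss = self._set({100.0: 0})
        assert max_firing_rate(ss) == (None, None)

    def test_block_truncates_count(self):
        """Spikes after a sustained suprathreshold plateau are not counted."""
        dt = 0.5
        n = int(MFR.sweep_duration / dt)
        v = np.full(n, -60.0)
        for k in range(5):
            v[int((150.0 + 20 * k) / dt)] = 30.0
        v[int(300 / dt):int(900 / dt)] = -10.0     # depolarized plateau
        v[int(950 / dt)] = 30.0                     # late spike: not counted
        sw = Sweep(dt=dt, command=MFR.command_waveform(300.0, dt), response=v,
                   step_amplitude=300.0, mode="current_clamp", protocol=MFR)
        assert detect_block(sw) is not None
        assert spikes_before_block(sw) == 5

    def test_no_block_on_subthreshold_plateau(self):
        dt = 0.5
        n = int(MFR.sweep_duration / dt)
        v = np.full(n, -40.0)
        sw = Sweep(dt=dt, command=MFR.command_waveform(100.0, dt), response=v,
                   step_amplitude=100.0, mode="current_clamp", protocol=MFR)
        assert detect_block(sw) is None


class TestIsi:
    def test_basic_intervals(self):
        sw = spikes_at([100.0, 112.0, 124.0])
        assert np.allclose(isi_list(sw), [12.0, 12.0])
        assert first_isi(sw) == pytest.approx(12.0)

    def test_fewer_than_two_spikes_missing(self):
        assert first_isi(spikes_at([200.0])) is None

    def test_histogram_bins_and_normalization(self):
        df = isi_histogram({"II": [12.0, 12.0, 3.0], "I": [22.0]},
                           bin_ms=5.0, n_per_type={"II": 2, "I": 1})
        # bin [10, 15) holds both 12 ms intervals, normalized by n=2
        iv = df.index[2]
        assert iv.left == 10.0 and iv.right == 15.0
        assert df.loc[iv, "II"] == 1.0
        assert df.loc[df.index[4], "I"] == 1.0

    def test_histogram_mass_conservation(self):
        rng = np.random.default_rng(0)
        isis = {"I": list(rng.uniform(1, 80, 37)), "II": list(rng.uniform(1, 80, 11))}
        n = {"I": 5, "II": 3}
        df = isi_histogram(isis, 5.0, n)
        for t in isis:
            assert df[t].sum() * n[t] == pytest.approx(len(isis[t]))


class TestPassives:
    def test_single_step_resistance(self):
        """dV = -5 mV at dI = -50 pA is 100 MOhm."""
        dt = 0.5
        proto = EXCITABILITY
        n = int(proto.sweep_duration / dt)
        sweeps = []
        for amp, dv in [(0.0, 0.0), (-50.0, -5.0)]:
            v = np.full(n, -60.0)
            t = np.arange(n) * dt
            v[(t >= proto.step_onset) & (t < proto.step_offset)] += dv
            sweeps.append(Sweep(dt=dt, command=proto.command_waveform(amp, dt),
                                response=v, step_amplitude=amp,
                                mode="current_clamp", protocol=proto))
        _, rin, _ = passive_properties(
            {"excitability": SweepSet(protocol=proto, sweeps=sweeps)},
            rin_steps=(-50.0,))
        assert rin == pytest.approx(100.0, rel=1e-6)

    def test_capacitance_from_tau_over_r(self):
        """tau = 10 ms with R_in = 100 MOhm gives 100 pF."""
        dt = 0.05
        proto = EXCITABILITY
        n = int(proto.sweep_duration / dt)
        t = np.arange(n) * dt
        sweeps = []
        for amp in (-30.0, -20.0, -10.0):
            v = np.full(n, -60.0)
            on = (t >= proto.step_onset) & (t < proto.step_offset)
            ts = t[on] - proto.step_onset
            v[on] = -60.0 + amp * 0.1 * (1 - np.exp(-ts / 10.0))
            sweeps.append(Sweep(dt=dt, command=proto.command_waveform(amp, dt),
                                response=v, step_amplitude=amp,
                                mode="current_clamp", protocol=proto))
        _, rin, cap = passive_properties(
            {"excitability": SweepSet(protocol=proto, sweeps=sweeps)})
        assert rin == pytest.approx(100.0, rel=1e-3)
        assert cap == pytest.approx(100.0, rel=0.02)

    def test_parameter_recovery_on_simulated_neuron(self, sim_config):
        """A passive 80 pF / 10 nS neuron is recovered within 10%."""
        import dataclasses
        from bnstephys import TEMPLATES, simulate_current_clamp
        from bnstephys.protocols import RMP as RMP_PROTO

        p = dataclasses.replace(TEMPLATES["III"], C_m=80.0, g_L=10.0,
                                g_h=0.0, g_D=0.0)
        sets = {
            "rmp": simulate_current_clamp(p, RMP_PROTO, sim_config),
            "excitability": simulate_current_clamp(p, EXCITABILITY, sim_config),
        }
        rmp, rin, cap = passive_properties(sets)
        assert rmp == pytest.approx(p.E_L, abs=0.5)
        assert rin == pytest.approx(100.0, rel=0.1)
        assert cap == pytest.approx(80.0, rel=0.1)
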