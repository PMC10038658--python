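"""Protocols, Gillespie state paths, trace rendering, ensemble averages."""

import numpy as np
import pytest

from mechgate.kinetic_model import (
    Conditions,
    RateLaw,
    KineticScheme,
    default_scheme,
    transient_occupancy,
    two_state_scheme,
)
from mechgate.stochastic_sim import (
    ObservationModel,
    Segment,
    StimulusProtocol,
    TraceRecording,
    ensemble_average,
    make_protocol,
    render_trace,
    simulate_state_path,
)
from mechgate.kinetic_model import Transition


class TestProtocols:
    def test_ladder_structure(self):
        p = make_protocol("ladder", pressure=-10.0)
        assert len(p.episodes) == 5
        volts = [ep[0].V for ep in p.episodes]
        assert volts == [-100.0, -80.0, -60.0, -40.0, -20.0]
        for ep in p.episodes:
            assert len(ep) == 2
            assert ep[0].P == 0.0 and ep[1].P == -10.0
            assert ep[0].duration == pytest.approx(0.2)
            assert ep[1].duration == pytest.approx(0.2)
        assert p.holding_V == -120.0

    def test_ladder_slow_gating_timing(self):
        p = make_protocol("ladder", pressure=-10.0, slow_gating=True)
        for ep in p.episodes:
            assert ep[0].duration == pytest.approx(2.0)
            assert ep[1].duration == pytest.approx(2.0)

    def test_reversibility_pressure_sandwich(self):
        p = make_protocol("reversibility", pressure=-30.0)
        assert p.interval_s == 7.5
        for ep in p.episodes:
            assert [s.P for s in ep] == [0.0, -30.0, 0.0]
            assert ep[1].duration == pytest.approx(0.5)
            assert sum(s.duration for s in ep) == pytest.approx(1.0)

    def test_positive_pressure_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("ladder", pressure=10.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("staircase")

    def test_durations_snap_to_sample_grid(self):
        p = StimulusProtocol(
            ((Segment(-60.0, 0.0, 0.100003),),), sampling_rate=20_000.0
        )
        d = p.episodes[0][0].duration
        assert (d * 20_000.0) == pytest.approx(round(d * 20_000.0), abs=1e-9)

    def test_whole_cell_voltages(self):
        p = make_protocol("whole_cell_nachbac", pressure=0.0)
        v1 = [ep[0].V for ep in p.episodes]
        assert v1[0] == -110.0 and v1[-1] == 0.0
        assert np.allclose(np.diff(v1), 10.0)
        assert p.interval_s == 4.75


class TestStatePath:
    def test_near_zero_rates_give_single_dwell(self):
        frozen = KineticScheme(
            states=("C", "O"),
            forward=(Transition("C", "O", RateLaw(1e-12)),),
            backward=(Transition("O", "C", RateLaw(1e-12)),),
        )
        ep = (Segment(-60.0, 0.0, 0.4),)
        path = simulate_state_path(frozen, ep, seed=7, initial_state=0)
        assert len(path.states) == 1
        assert path.duration == pytest.approx(0.4)

    def test_open_dwell_mean_matches_closing_rate(self, pore_scheme, rng):
        """Mean open dwell of the C5-O6 flicker = 1/k_close."""
        dwells = []
        ep = (Segment(-20.0, 0.0, 2.0),)
        while len(dwells) < 10_000:
            p = simulate_state_path(pore_scheme, ep, seed=rng, holding=Conditions(-20.0, 0.0))
            ends = np.append(p.entry_times[1:], p.duration)
            durs = ends - p.entry_times
            dwells.extend(durs[p.states == 1][:-1])  # drop edge dwell
        dwells = np.asarray(dwells[:10_000])
        mean, se = dwells.mean(), dwells.std(ddof=1) / np.sqrt(len(dwells))
        assert abs(mean - 1 / 55.0) < 3 * se

    def test_seed_determinism(self, mso):
        ep = make_protocol("ladder").episodes[2]
        a = simulate_state_path(mso, ep, seed=42, holding=Conditions(-120.0, 0.0))
        b = simulate_state_path(mso, ep, seed=42, holding=Conditions(-120.0, 0.0))
        c = simulate_state_path(mso, ep, seed=43, holding=Conditions(-120.0, 0.0))
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.entry_times, b.entry_times)
        assert len(a.states) != len(c.states) or not np.array_equal(a.states, c.states)

    def test_transitions_are_chain_adjacent(self, mso, rng):
        ep = make_protocol("ladder").episodes[3]
        for _ in range(5):
            p = simulate_state_path(mso, ep, seed=rng, holding=Conditions(-120.0, 0.0))
            if len(p.states) > 1:
                assert np.all(np.abs(np.diff(p.states)) == 1)
            assert np.all(np.diff(p.entry_times) > 0)


class TestRenderTrace:
    def test_closed_path_zero_noise_is_baseline(self, om_clean):
        from mechgate.stochastic_sim import StatePath

        path = StatePath(np.array([0]), np.array([0.0]), 0.1, open_index=1)
        tr = render_trace(path, om_clean, (Segment(-60.0, 0.0, 0.1),), 20_000.0)
        np.testing.assert_allclose(tr.current, 0.0, atol=1e-12)

    def test_open_plateau_amplitude(self, om_clean):
        from mechgate.stochastic_sim import StatePath

        path = StatePath(np.array([1]), np.array([0.0]), 0.1, open_index=1)
        tr = render_trace(path, om_clean, (Segment(-60.0, 0.0, 0.1),), 20_000.0)
        # gamma*(V - E_rev) = 6.7 pS * (-115 mV) = -0.7705 pA ("0.77 pA")
        assert tr.current[500] == pytest.approx(-0.7705, abs=1e-9)

    def test_amplitude_linear_in_driving_force(self, om_clean):
        from mechgate.stochastic_sim import StatePath

        path = StatePath(np.array([1]), np.array([0.0]), 0.05, open_index=1)
        for V in (-100.0, -80.0, -60.0, -40.0, -20.0):
            tr = render_trace(path, om_clean, (Segment(V, 0.0, 0.05),), 20_000.0)
            assert abs(tr.current[600] - 6.7e-3 * (V - 55.0)) < 1e-9

    def test_filter_rise_time(self, om_clean):
        """10-90% rise of the Bessel low-pass ~ 0.3321/cutoff (within 15%)."""
        from mechgate.stochastic_sim import lowpass

        fs = 20_000.0
        x = np.r_[np.zeros(2000), np.ones(8000)]
        for fc in (500.0, 2000.0):
            y = lowpass(x, fc, fs)
            rise = (np.argmax(y >= 0.9) - np.argmax(y >= 0.1)) / fs
            assert rise == pytest.approx(0.3321 / fc, rel=0.15)

    def test_post_filter_noise_sd_calibrated(self, mso):
        om = ObservationModel(noise_sd_pA=0.25, cutoff_hz=5000.0)
        from mechgate.stochastic_sim import StatePath

        path = StatePath(np.array([0]), np.array([0.0]), 2.0, open_index=5)
        tr = render_trace(path, om, (Segment(-100.0, 0.0, 2.0),), 20_000.0, seed=3)
        assert len(tr.current) == 40_000
        assert tr.current[2000:].std() == pytest.approx(0.25, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self, om_clean):
        from dataclasses import replace
        from mechgate.stochastic_sim import StatePath

        om = replace(om_clean, cutoff_hz=15_000.0)
        path = StatePath(np.array([0]), np.array([0.0]), 0.01, open_index=1)
        with pytest.raises(ValueError):
            render_trace(path, om, (Segment(-60.0, 0.0, 0.01),), 20_000.0)

    def test_tsv_round_trip(self, tmp_path, mso, om, rng):
        ep = make_protocol("ladder").episodes[2]
        p = simulate_state_path(mso, ep, seed=rng, holding=Conditions(-120.0, 0.0))
        tr = render_trace(p, om, ep, 20_000.0, seed=5, metadata={"cell_id": "c0"})
        f = tmp_path / "trace.tsv"
        tr.write(f)
        back = TraceRecording.read(f)
        assert back.sampling_rate == tr.sampling_rate
        assert back.bandwidth == tr.bandwidth
        assert back.metadata["cell_id"] == "c0"
        np.testing.assert_allclose(back.current, tr.current, rtol=1e-5)
        np.testing.assert_array_equal(back.voltage, tr.voltage)


class TestEnsemble:
    def test_single_sweep_equals_render(self, pore_scheme, om_clean):
        ep = (Segment(-20.0, 0.0, 0.02),)
        ea = ensemble_average(pore_scheme, ep, om_clean, 1, seed=9, holding=Conditions(-20.0, 0.0))
        path = simulate_state_path(
            pore_scheme, ep, seed=np.random.default_rng(np.random.SeedSequence(9).spawn(2)[0]),
            holding=Conditions(-20.0, 0.0),
        )
        tr = render_trace(path, om_clean, ep, 20_000.0)
        np.testing.assert_allclose(ea.current, tr.current)

    def test_monte_carlo_matches_matrix_exponential(self, pore_scheme, om_clean):
        """Gillespie ensemble open fraction vs transient occupancy, 3 MC SE."""
        n = 2000
        ep = (Segment(-20.0, 0.0, 0.02),)
        ea = ensemble_average(pore_scheme, ep, om_clean, n, seed=5, holding=Conditions(-20.0, 0.0))
        occ_frac = ea.current / om_clean.unitary_current(-20.0)
        p0 = np.array([55.0, 70.0]) / 125.0  # stationary at holding
        _, occ = transient_occupancy(pore_scheme, [(Conditions(-20.0, 0.0), 0.02)], p0, 1 / 20_000.0)
        expected = occ[1:, 1]
        for i in np.linspace(10, len(expected) - 1, 10).astype(int):
            se = np.sqrt(expected[i] * (1 - expected[i]) / n)
            assert abs(occ_frac[i] - expected[i]) < 3 * se + 1e-3

    def test_mso_pressure_step_rise_and_relaxation(self, mso, om_clean):
        """Po rises under suction and relaxes back gradually after release."""
        ep = (
            Segment(-60.0, 0.0, 0.2),
            Segment(-60.0, -50.0, 0.2),
            Segment(-60.0, 0.0, 0.2),
        )
        ea = ensemble_average(mso, ep, om_clean, 400, seed=11, rp_offset=20.0,
                              holding=Conditions(-120.0, 0.0))
        occ = ea.current / om_clean.unitary_current(-60.0)
        fs = 20_000
        pre = occ[int(0.15 * fs):int(0.2 * fs)].mean()
        during = occ[int(0.35 * fs):int(0.4 * fs)].mean()
        just_after = occ[int(0.405 * fs):int(0.42 * fs)].mean()
        late_after = occ[int(0.55 * fs):int(0.6 * fs)].mean()
        assert during > pre + 0.05
        assert just_after > late_after  # relaxation is not instantaneous
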