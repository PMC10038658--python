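"""Six-state gating model: rate laws, generator, equilibrium, transients."""

import json
import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechgate.kinetic_model import (
    Conditions,
    DEFAULT_PARAMS,
    KineticScheme,
    RateLaw,
    RestingPotentialModel,
    build_generator,
    default_scheme,
    po_pressure_curve,
    po_voltage_curve,
    rate,
    stationary_occupancy,
    stationary_open_probability,
    transient_occupancy,
    two_state_scheme,
)


class TestRateLaw:
    @pytest.mark.parametrize(
        "law, V, P, expected",
        [
            (RateLaw(800.0, 0.055, 0.0), 0.0, 0.0, 800.0),
            (RateLaw(800.0, 0.055, 0.0), -60.0, 0.0, 800.0 * np.exp(-3.3)),
            (RateLaw(70.0, 0.0, -0.05), -20.0, -10.0, 70.0 * np.exp(0.5)),
        ],
    )
    def test_rate_evaluation(self, law, V, P, expected):
        assert rate(law, Conditions(V, P)) == pytest.approx(expected, rel=1e-12)
        # the two classic worked values
        assert rate(RateLaw(800.0, 0.055, 0.0), Conditions(-60.0, 0.0)) == pytest.approx(29.51, abs=0.01)
        assert rate(RateLaw(70.0, 0.0, -0.05), Conditions(-20.0, -10.0)) == pytest.approx(115.4, abs=0.1)

    def test_invalid_k0_rejected(self):
        with pytest.raises(ValueError):
            RateLaw(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            RateLaw(-5.0, 0.0, 0.0)

    def test_overflow_saturates_finite(self, caplog):
        law = RateLaw(1e3, 1.0, 0.0)
        with caplog.at_level(logging.WARNING):
            v = rate(law, Conditions(1e4, 0.0))
        assert np.isfinite(v) and v > 0
        assert any("saturat" in r.message for r in caplog.records)

    @given(
        V=st.floats(-200, 200),
        P=st.floats(-100, 0),
        k0=st.floats(1e-3, 1e4),
        kv=st.floats(-0.2, 0.2),
        kp=st.floats(-0.2, 0.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rates_strictly_positive(self, V, P, k0, kv, kp):
        assert rate(RateLaw(k0, kv, kp), Conditions(V, P)) > 0


class TestDefaultScheme:
    def test_mso_pressure_on_pore_step_only(self, mso):
        pore_f, pore_b = mso.forward[-1].law, mso.backward[-1].law
        assert (pore_f.k0, pore_f.kv, pore_f.kp) == (70.0, 0.0, -0.05)
        assert (pore_b.k0, pore_b.kv, pore_b.kp) == (55.0, 0.0, -0.005)
        for tr in list(mso.forward[:-1]) + list(mso.backward[:-1]):
            assert tr.law.kp == 0.0
        assert mso.forward[0].law.k0 == 4 * 800.0
        assert mso.forward[0].law.kv == 0.055

    def test_msa_pressure_on_activation_steps_only(self, msa):
        assert msa.forward[-1].law.kp == 0.0 and msa.backward[-1].law.kp == 0.0
        for tr in msa.forward[:-1]:
            assert tr.law.kp == -0.05
        for tr in msa.backward[:-1]:
            assert tr.law.kp == -0.005
        assert msa.forward[0].law.kp == -0.05

    def test_forward_multiplicity_ratio(self, mso):
        # activation-path forward rates in 4:3:2:1 (so C3->C4 = 2x C4->C5)
        k = [rate(t.law, Conditions(-50.0, 0.0)) for t in mso.forward[:4]]
        assert k[2] == pytest.approx(2 * k[3], rel=1e-12)
        np.testing.assert_allclose(np.array(k) / k[3], [4, 3, 2, 1], rtol=1e-12)

    def test_pore_step_voltage_insensitive(self, mso, msa):
        for s in (mso, msa):
            assert s.forward[-1].law.kv == 0.0
            assert s.backward[-1].law.kv == 0.0

    def test_variants_identical_at_zero_pressure(self, mso, msa):
        for V in (-100.0, -60.0, -20.0, 40.0):
            qa = build_generator(msa, Conditions(V, 0.0)).Q
            qo = build_generator(mso, Conditions(V, 0.0)).Q
            np.testing.assert_allclose(qa, qo, rtol=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            default_scheme("MSX")

    def test_json_round_trip(self, tmp_path, mso, msa):
        for s in (mso, msa):
            p = tmp_path / f"{s.variant}.json"
            s.to_json(p)
            s2 = KineticScheme.from_json(p)
            assert s2.to_dict() == s.to_dict()

    def test_shipped_parameter_files_match_defaults(self):
        from importlib.resources import files

        for variant in ("mso", "msa"):
            doc = json.loads(
                files("mechgate.data").joinpath(f"default_scheme_{variant}.json").read_text()
            )
            assert KineticScheme.from_dict(doc).to_dict() == default_scheme(variant).to_dict()


class TestGenerator:
    @pytest.mark.parametrize("V,P", [(-20.0, 0.0), (-60.0, -10.0), (100.0, -50.0)])
    def test_rows_sum_to_zero_and_tridiagonal(self, mso, V, P):
        Q = build_generator(mso, Conditions(V, P)).Q
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-10 * np.abs(Q).max())
        mask = np.abs(np.subtract.outer(range(6), range(6))) > 1
        assert np.all(Q[mask] == 0.0)

    def test_pore_entries(self, mso):
        Q = build_generator(mso, Conditions(-20.0, 0.0)).Q
        assert Q[4, 5] == pytest.approx(70.0, rel=1e-12)
        assert Q[5, 4] == pytest.approx(55.0, rel=1e-12)
        Q = build_generator(mso, Conditions(-20.0, -50.0)).Q
        assert Q[4, 5] == pytest.approx(852.7, abs=0.1)
        assert Q[5, 4] == pytest.approx(70.6, abs=0.1)


class TestStationary:
    def test_saturating_open_fraction(self, mso):
        pi = stationary_occupancy(build_generator(mso, Conditions(100.0, 0.0)))
        assert pi[5] / (pi[4] + pi[5]) == pytest.approx(70.0 / 125.0, abs=1e-4)
        assert pi[:4].sum() < 1e-6

    def test_hyperpolarized_parks_in_c1(self, mso):
        pi = stationary_occupancy(build_generator(mso, Conditions(-140.0, 0.0)))
        assert pi[0] > 0.99
        assert np.argmax(pi) == 0

    def test_saturating_with_suction(self, mso):
        po = stationary_open_probability(mso, 100.0, -50.0)
        assert po == pytest.approx(852.7745 / (852.7745 + 70.6214), abs=1e-4)

    def test_detailed_balance_on_grid(self, mso, msa):
        Vg, Pg = np.meshgrid(np.linspace(-120, 40, 20), np.linspace(-50, 0, 20))
        for s in (mso, msa):
            for V, P in zip(Vg.ravel()[::13], Pg.ravel()[::13]):
                q = build_generator(s, Conditions(V, P))
                pi = stationary_occupancy(q)
                assert pi.sum() == pytest.approx(1.0, abs=1e-10)
                for i in range(5):
                    flux_f = pi[i] * q.Q[i, i + 1]
                    flux_b = pi[i + 1] * q.Q[i + 1, i]
                    assert flux_f == pytest.approx(flux_b, rel=1e-8)

    def test_pi_solves_generator(self, mso):
        q = build_generator(mso, Conditions(-40.0, -30.0))
        pi = stationary_occupancy(q)
        np.testing.assert_allclose(pi @ q.Q, 0.0, atol=1e-10 * np.abs(q.Q).max())


class TestTransient:
    def test_initial_sample_is_p0(self, mso):
        p0 = np.array([1.0, 0, 0, 0, 0, 0])
        t, occ = transient_occupancy(mso, [(Conditions(-60.0, 0.0), 0.001)], p0, 1e-4)
        np.testing.assert_allclose(occ[0], p0)
        assert t[0] == 0.0

    def test_converges_to_stationary(self, mso):
        c = Conditions(-40.0, -10.0)
        p0 = np.array([1.0, 0, 0, 0, 0, 0])
        _, occ = transient_occupancy(mso, [(c, 5.0)], p0, 0.01)
        pi = stationary_occupancy(build_generator(mso, c))
        np.testing.assert_allclose(occ[-1], pi, atol=1e-6)

    def test_two_state_closed_form(self):
        ts = two_state_scheme(70.0, 55.0, 0.0, 0.0)
        t, occ = transient_occupancy(ts, [(Conditions(0.0, 0.0), 0.05)], np.array([1.0, 0.0]), 1e-4)
        analytic = (70.0 / 125.0) * (1 - np.exp(-125.0 * t))
        np.testing.assert_allclose(occ[:, 1], analytic, atol=1e-8)

    def test_occupancy_conserved_and_bounded(self, mso):
        segs = [(Conditions(-60.0, 0.0), 0.005), (Conditions(-60.0, -30.0), 0.005)]
        p0 = stationary_occupancy(build_generator(mso, Conditions(-120.0, 0.0)))
        _, occ = transient_occupancy(mso, segs, p0, 1e-4)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(occ >= -1e-12) and np.all(occ <= 1 + 1e-12)

    def test_matches_fine_step_euler(self, mso):
        """Matrix-exponential solution vs brute-force Euler (dt=1e-6 s)."""
        segs = [(Conditions(-60.0, 0.0), 0.005), (Conditions(-60.0, -50.0), 0.005)]
        p0 = stationary_occupancy(build_generator(mso, Conditions(-120.0, 0.0)))
        t, occ = transient_occupancy(mso, segs, p0, 1e-4)
        dt = 1e-6
        p = p0.copy()
        euler = [p0]
        for c, dur in segs:
            Q = build_generator(mso, c).Q
            for _ in range(round(dur / dt)):
                p = p + dt * (p @ Q)
                euler.append(p)
        euler = np.asarray(euler)
        idx = np.round(t / dt).astype(int)
        assert np.abs(occ - euler[idx]).max() < 1e-4

    def test_invalid_p0_rejected(self, mso):
        with pytest.raises(ValueError):
            transient_occupancy(mso, [(Conditions(0, 0), 0.01)], np.array([0.5, 0.5, 0, 0, 0, 0.5]), 1e-4)


class TestPoCurves:
    def test_no_rp_equals_pointwise_stationary(self, mso):
        V = np.linspace(-100, -20, 9)
        po = po_voltage_curve(mso, V, P=-10.0, rp=None)
        ref = [stationary_open_probability(mso, v, -10.0) for v in V]
        np.testing.assert_allclose(po, ref, rtol=1e-12)

    @pytest.mark.parametrize("variant", ["MSO", "MSA"])
    @pytest.mark.parametrize("P", [0.0, -30.0])
    def test_monotone_in_voltage(self, variant, P):
        s = default_scheme(variant)
        po = po_voltage_curve(s, np.linspace(-140, 60, 81), P)
        assert np.all(np.diff(po) >= -1e-12)

    def test_rp_scatter_flattens_but_preserves_extremes(self, mso):
        V = np.linspace(-150, 100, 251)
        sharp = po_voltage_curve(mso, V, 0.0, RestingPotentialModel(0.0, 0.0))
        wide = po_voltage_curve(mso, V, 0.0, RestingPotentialModel(0.0, 12.0))
        assert wide.max() == pytest.approx(sharp.max(), abs=1e-3)
        # midpoint voltage unchanged (symmetric scatter), slope reduced
        half = sharp.max() / 2
        v_mid_sharp = np.interp(half, sharp, V)
        v_mid_wide = np.interp(half, wide, V)
        assert abs(v_mid_sharp - v_mid_wide) < 2.0
        assert np.gradient(wide, V).max() < np.gradient(sharp, V).max()

    def test_rp_mean_shifts_curve_positive(self, mso):
        """A +20 mV hyperpolarizing offset moves the apparent midpoint ~+20 mV."""
        V = np.linspace(-150, 40, 191)
        base = po_voltage_curve(mso, V, 0.0)
        shifted = po_voltage_curve(mso, V, 0.0, RestingPotentialModel(20.0, 0.0))
        vm_base = np.interp(base.max() / 2, base, V)
        vm_shift = np.interp(base.max() / 2, shifted, V)
        assert vm_shift - vm_base == pytest.approx(20.0, abs=0.5)

    def test_pressure_curve_single_point_matches_stationary(self, mso):
        po = po_pressure_curve(mso, [-30.0], V=-40.0)
        assert po[0] == pytest.approx(stationary_open_probability(mso, -40.0, -30.0), rel=1e-12)

    def test_msa_pressure_independent_maximum(self, msa):
        """MSA signature: saturating-voltage Po does not move with pressure."""
        maxima = [po_voltage_curve(msa, [100.0], P)[0] for P in (0.0, -10.0, -30.0, -50.0)]
        assert np.ptp(maxima) < 1e-6

    def test_mso_maximum_follows_closed_form(self, mso):
        """MSO signature: Po_max(P) = kO e^{kpO P} / (kO e^{kpO P} + kC e^{kpC P})."""
        for P in (0.0, -10.0, -30.0, -50.0):
            num = 70.0 * np.exp(-0.05 * P)
            den = num + 55.0 * np.exp(-0.005 * P)
            assert po_voltage_curve(mso, [100.0], P)[0] == pytest.approx(num / den, abs=1e-4)

    def test_msa_pressure_curve_flat_at_saturating_voltage(self, msa):
        po = po_pressure_curve(msa, np.linspace(-200, 0, 21), V=100.0)
        np.testing.assert_allclose(po, 70.0 / 125.0, atol=1e-4)
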