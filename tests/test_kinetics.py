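"""Unit and property tests for the neurotransmitter-kinetics stage."""

import numpy as np
import pytest

from anshrv.kinetics import (
    Branch,
    BranchKinetics,
    DepletionMode,
    DepletionSpec,
    PositivityError,
    autonomic_signal,
    branch_signal,
    build_stimulus_train,
    cross_couple,
    simulate_concentration,
)


def vagal_kin(**over):
    kw = dict(
        branch=Branch.VAGAL,
        release_quantum_q=1.0,
        junction_clearance_kJ=1.5,
        junction_to_ejs_transfer_kT=0.5,
        ejs_clearance_kE=0.5,
        junction_weight_wJ=1.0,
        ejs_weight_wE=0.2,
        gain_g=1.0,
        latency_s=0.0,
    )
    kw.update(over)
    return BranchKinetics(**kw)


class TestStimulusTrain:
    def test_vagal_band_event_count_and_intervals(self):
        tr = build_stimulus_train("vagal", 300.0, (0.25, 0.5), seed=1)
        n = len(tr.event_times_s)
        assert 75 <= n <= 150
        iv = np.diff(tr.event_times_s)
        assert np.all(iv >= 2.0 - 1e-12) and np.all(iv <= 4.0 + 1e-12)

    def test_sympathetic_band_event_count_and_intervals(self):
        tr = build_stimulus_train("sympathetic", 300.0, (0.025, 0.05), seed=1)
        assert 7 <= len(tr.event_times_s) <= 15
        iv = np.diff(tr.event_times_s)
        assert np.all(iv >= 20.0 - 1e-12) and np.all(iv <= 40.0 + 1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_degenerate_band_is_periodic(self, seed):
        tr = build_stimulus_train("vagal", 100.0, (0.5, 0.5), seed=seed)
        assert np.allclose(np.diff(tr.event_times_s), 2.0)

    def test_deterministic_under_seed(self):
        a = build_stimulus_train("vagal", 300.0, seed=7)
        b = build_stimulus_train("vagal", 300.0, seed=7)
        assert np.array_equal(a.event_times_s, b.event_times_s)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_stimulus_train("vagal", -1.0, (0.25, 0.5))
        with pytest.raises(ValueError):
            build_stimulus_train("vagal", 10.0, (0.5, 0.25))


class TestConcentration:
    def test_zero_events_zero_concentration(self):
        from anshrv.kinetics import StimulusTrain

        tr = StimulusTrain(Branch.VAGAL, np.array([]), 10.0, (0.25, 0.5), 0)
        c = simulate_concentration(tr, vagal_kin(), dt=0.01)
        assert np.all(c.C_J == 0) and np.all(c.C_E == 0)

    def test_single_impulse_closed_form(self):
        # q=1, kJ+kT=2/s: C_J(t) = exp(-2 t); at t=0.5 s -> 0.3679
        from anshrv.kinetics import StimulusTrain

        kin = vagal_kin(junction_clearance_kJ=1.5, junction_to_ejs_transfer_kT=0.5)
        tr = StimulusTrain(Branch.VAGAL, np.array([0.0]), 5.0, (0.25, 0.5), 0)
        c = simulate_concentration(tr, kin, dt=0.01)
        i = int(round(0.5 / 0.01))
        assert c.C_J[i] == pytest.approx(np.exp(-1.0), rel=1e-9)
        assert c.C_J[i] == pytest.approx(0.3679, abs=5e-5)

    def test_periodic_train_steady_state_mean(self):
        # long-run mean C_J -> q * alpha * f / (kJ + kT)
        kin = vagal_kin()
        tr = build_stimulus_train("vagal", 2000.0, (0.25, 0.25), seed=0)
        dep = DepletionSpec(alpha=0.8)
        c = simulate_concentration(tr, kin, dep, dt=0.01)
        expected = 1.0 * 0.8 * 0.25 / kin.junction_decay
        assert np.mean(c.C_J) == pytest.approx(expected, rel=0.01)

    def test_exact_updates_match_fine_euler(self):
        """Oracle: brute-force Euler at dt=1e-4 on a 30 s example."""
        from anshrv.kinetics import StimulusTrain

        kin = vagal_kin()
        tr0 = build_stimulus_train("vagal", 30.0, (0.25, 0.5), seed=3)
        # snap events to the coarse grid so both integrators inject at
        # exactly the same instants
        tr = StimulusTrain(
            Branch.VAGAL, np.round(tr0.event_times_s, 2), 30.0, (0.25, 0.5), 3
        )
        c = simulate_concentration(tr, kin, dt=0.01)

        # independent Euler integration
        dt_f = 1e-4
        n = int(30.0 / dt_f) + 1
        cj = np.zeros(n)
        ce = np.zeros(n)
        a, kT, kE = kin.junction_decay, kin.junction_to_ejs_transfer_kT, kin.ejs_clearance_kE
        events = set(np.round(tr.event_times_s / dt_f).astype(int))
        for i in range(1, n):
            cj[i] = cj[i - 1] * (1 - a * dt_f)
            ce[i] = ce[i - 1] + (kT * cj[i - 1] - kE * ce[i - 1]) * dt_f
            if i in events:
                cj[i] += kin.release_quantum_q
        idx = np.round(c.t_s / dt_f).astype(int)
        scale = max(cj.max(), 1e-12)
        assert np.max(np.abs(c.C_J - cj[idx])) / scale < 1e-3
        assert np.max(np.abs(c.C_E - ce[idx])) / max(ce.max(), 1e-12) < 1e-3

    def test_junction_integral_conservation(self):
        # time-integral of C_J ~= n_events * q * alpha / (kJ + kT) within 1%
        kin = vagal_kin()
        tr = build_stimulus_train("vagal", 400.0, (0.25, 0.5), seed=2)
        dep = DepletionSpec(alpha=0.7)
        c = simulate_concentration(tr, kin, dep, dt=0.002)
        integral = np.trapezoid(c.C_J, c.t_s)
        expected = len(tr.event_times_s) * 1.0 * 0.7 / kin.junction_decay
        assert integral == pytest.approx(expected, rel=0.01)

    def test_branch_mismatch_and_bad_dt(self):
        tr = build_stimulus_train("sympathetic", 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_concentration(tr, vagal_kin())
        tr2 = build_stimulus_train("vagal", 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_concentration(tr2, vagal_kin(), dt=0.2)


class TestBranchSignal:
    def test_linearity_in_release_quantum(self):
        """Linear transduction: scaling q by c scales the signal by exactly c."""
        tr = build_stimulus_train("vagal", 60.0, seed=4)
        c_scale = 3.7
        v1 = branch_signal(simulate_concentration(tr, vagal_kin()), vagal_kin())
        kin2 = vagal_kin(release_quantum_q=c_scale)
        v2 = branch_signal(simulate_concentration(tr, kin2), kin2)
        assert np.allclose(v2, c_scale * v1, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("gamma", [1.0, 2.0])
    def test_depletion_scaling_law(self, gamma):
        """junction_conc depletion scales the vagal signal by alpha**gamma
        (exactly alpha for the linear chain)."""
        kin = vagal_kin(ejs_weight_wE=0.0001, transduction_gamma=gamma)
        tr = build_stimulus_train("vagal", 60.0, seed=5)
        v_full = branch_signal(simulate_concentration(tr, kin, DepletionSpec(alpha=1.0)), kin)
        dep = DepletionSpec(alpha=0.7)
        v_dep = branch_signal(simulate_concentration(tr, kin, dep), kin, dep)
        assert np.allclose(v_dep, 0.7**gamma * v_full, rtol=1e-9)

    def test_depletion_mode_equivalence(self):
        """vesicle_count and junction_conc give identical V(t)."""
        kin = vagal_kin(transduction_gamma=3.0)
        tr = build_stimulus_train("vagal", 60.0, seed=6)
        traces = {
            mode: simulate_concentration(tr, kin, DepletionSpec(mode=mode, alpha=0.6))
            for mode in (DepletionMode.VESICLE_COUNT, DepletionMode.JUNCTION_CONC)
        }
        v = {
            mode: branch_signal(tr_, kin, DepletionSpec(mode=mode, alpha=0.6))
            for mode, tr_ in traces.items()
        }
        assert np.array_equal(
            v[DepletionMode.VESICLE_COUNT], v[DepletionMode.JUNCTION_CONC]
        )

    def test_signs_and_zero_input(self):
        from anshrv.kinetics import ConcentrationTrace

        t = np.arange(0, 1, 0.01)
        zero = ConcentrationTrace(t, np.zeros_like(t), np.zeros_like(t), Branch.VAGAL)
        assert np.all(branch_signal(zero, vagal_kin()) == 0)

        sk = BranchKinetics(branch=Branch.SYMPATHETIC)
        tr = build_stimulus_train("sympathetic", 100.0, seed=0)
        s = branch_signal(simulate_concentration(tr, sk), sk)
        assert np.all(s >= 0) and s.max() > 0
        vt = build_stimulus_train("vagal", 100.0, seed=0)
        v = branch_signal(simulate_concentration(vt, vagal_kin()), vagal_kin())
        assert np.all(v <= 0) and v.min() < 0

    def test_vagal_gain_mode_scales_output_only(self):
        kin = vagal_kin()
        tr = build_stimulus_train("vagal", 60.0, seed=8)
        dep = DepletionSpec(mode=DepletionMode.VAGAL_GAIN, alpha=0.5)
        trace = simulate_concentration(tr, kin, dep)
        v_dep = branch_signal(trace, kin, dep)
        v_full = branch_signal(trace, kin, DepletionSpec())
        assert np.allclose(v_dep, 0.5 * v_full, rtol=1e-12)


class TestCoupling:
    def test_identity_at_baseline_and_decoupled(self):
        rng = np.random.default_rng(0)
        S = rng.random(100)
        V = -rng.random(100)
        v_base = float(np.mean(np.abs(V)))
        S2, V2 = cross_couple(S, V, kappa_sv=0.2, v_baseline=v_base)
        assert np.allclose(S2, S)  # rho = 1
        S3, _ = cross_couple(S, 0.5 * V, kappa_sv=0.0, v_baseline=v_base)
        assert np.allclose(S3, S)

    def test_stated_attenuation_formula(self):
        # kappa=0.2, rho=0.5 -> S scaled by 0.9
        S = np.ones(10)
        V = -np.full(10, 0.5)
        S2, V2 = cross_couple(S, V, kappa_sv=0.2, v_baseline=1.0)
        assert np.allclose(S2, 0.9)
        assert np.array_equal(V2, V)

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            cross_couple(np.ones(3), -np.ones(3), 0.2, v_baseline=0.0)


class TestAutonomicSignal:
    def test_constant_m0(self):
        t = np.arange(0, 10, 0.01)
        sig = autonomic_signal(np.zeros_like(t), np.zeros_like(t), t, m0=1.0)
        assert np.all(sig.m == 1.0)

    def test_m_decomposition_recovers_V(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 10, 0.01)
        S = 0.3 * rng.random(t.size)
        V = -0.5 * rng.random(t.size)
        sig = autonomic_signal(S, V, t, m0=1.0)
        assert np.allclose(sig.m - sig.m0 - sig.S, V, atol=1e-15)

    def test_positivity_violation_reports_first_time(self):
        t = np.arange(0, 10, 0.01)
        V = np.zeros_like(t)
        V[t >= 5.0] = -2.0
        with pytest.raises(PositivityError) as err:
            autonomic_signal(np.zeros_like(t), V, t, m0=1.0)
        assert err.value.t_first == pytest.approx(5.0, abs=0.011)
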