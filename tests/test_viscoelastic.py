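"""QLV checks: reduced relaxation, step solution, integrator, ramps, rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantarvisc import (
    PronySeries,
    StressTrace,
    decay_rate,
    elastic_axial_stress,
    integrate_history,
    ramp_curve,
    reduced_relaxation,
    secant_modulus,
    step_relaxation,
)
from plantarvisc.viscoelastic import default_hold_times


@st.composite
def prony_series(draw, min_m=0, max_m=4):
    m = draw(st.integers(min_m, max_m))
    if m == 0:
        return PronySeries()
    raw = draw(
        st.lists(st.floats(0.05, 1.0), min_size=m, max_size=m)
    )
    total = draw(st.floats(0.1, 1.0))
    g = np.array(raw) / sum(raw) * total
    taus = draw(
        st.lists(st.floats(-2.0, 3.0), min_size=m, max_size=m, unique=True)
    )
    return PronySeries(zip(g, [10.0**t for t in taus]))


class TestPronySeries:
    def test_branches_sorted_by_tau(self):
        ps = PronySeries(((0.1, 10.0), (0.2, 1.0)))
        assert ps.taus.tolist() == [1.0, 10.0]
        assert ps.gammas.tolist() == [0.2, 0.1]

    @pytest.mark.parametrize(
        "branches", [((1.1, 1.0),), ((0.5, -1.0),), ((0.6, 1.0), (0.6, 2.0))]
    )
    def test_invalid_series_rejected(self, branches):
        with pytest.raises(ValueError):
            PronySeries(branches)


class TestReducedRelaxation:
    def test_unity_at_origin(self, ps3):
        assert reduced_relaxation(ps3, 0.0) == 1.0

    def test_long_time_limit_three_branch(self, ps3):
        # 1 - (0.19 + 0.11 + 0.12) = 0.58
        assert reduced_relaxation(ps3, 1e9) == pytest.approx(0.58, abs=1e-12)

    def test_value_at_240s_three_branch(self, ps3):
        expected = 0.58 + sum(
            g * np.exp(-240.0 / t) for g, t in ps3.branches
        )
        assert reduced_relaxation(ps3, 240.0) == pytest.approx(expected, rel=1e-12)
        assert reduced_relaxation(ps3, 240.0) == pytest.approx(0.5849, abs=5e-5)

    def test_one_branch_hand_value(self, ps1):
        # 1 - 0.39 (1 - e^-1)
        assert reduced_relaxation(ps1, 6.0) == pytest.approx(0.75347, abs=1e-5)

    def test_negative_time_rejected(self, ps3):
        with pytest.raises(ValueError):
            reduced_relaxation(ps3, -1.0)

    @given(prony_series())
    @settings(derandomize=True, max_examples=100)
    def test_monotone_with_correct_limits(self, ps):
        t = np.geomspace(1e-3, 1e6, 200)
        r = reduced_relaxation(ps, t)
        assert reduced_relaxation(ps, 0.0) == 1.0
        assert np.all(np.diff(r) <= 1e-15)
        assert r[-1] == pytest.approx(1.0 - ps.gamma_total, abs=1e-6)


class TestStepRelaxation:
    def test_initial_stress_is_elastic(self, hp, ps3):
        tr = step_relaxation(hp, ps3, 0.06, np.array([0.0, 1.0]))
        assert tr.stress[0] == elastic_axial_stress(hp, 1.06).nominal

    def test_no_branches_means_no_relaxation(self, hp):
        tr = step_relaxation(hp, PronySeries(), 0.06, np.linspace(0, 240, 50))
        assert np.all(tr.stress == tr.stress[0])

    def test_closed_form_product(self, hp, ps3):
        tr = step_relaxation(hp, ps3, 0.06, np.array([0.0, 240.0]))
        s_el = elastic_axial_stress(hp, 1.06).nominal
        assert tr.stress[-1] == pytest.approx(
            reduced_relaxation(ps3, 240.0) * s_el, rel=1e-12
        )

    def test_quasilinearity_of_normalized_traces(self, hp, ps3, hold_times):
        # the normalized relaxation is strain-level independent to machine precision
        norms = []
        for strain in (0.04, 0.06, 0.08):
            tr = step_relaxation(hp, ps3, strain, hold_times)
            norms.append(tr.stress / tr.stress[0])
        np.testing.assert_allclose(norms[1], norms[0], rtol=5e-16, atol=0)
        np.testing.assert_allclose(norms[2], norms[0], rtol=5e-16, atol=0)


class TestIntegrateHistory:
    def test_step_history_matches_closed_form(self, hp, ps3):
        tr = integrate_history(
            hp, ps3, lambda t: np.full_like(t, 0.06), t_end=10.0, dt=0.01
        )
        ref = step_relaxation(hp, ps3, 0.06, tr.times)
        assert np.max(np.abs(tr.stress - ref.stress) / ref.stress) < 1e-3

    def test_purely_elastic_limit(self, hp):
        history = lambda t: 0.08 * np.sin(t) ** 2
        tr = integrate_history(hp, PronySeries(), history, t_end=3.0, dt=0.01)
        expected = [
            elastic_axial_stress(hp, 1 + e).nominal for e in history(tr.times)
        ]
        np.testing.assert_allclose(tr.stress, expected, rtol=1e-12)

    def test_virgin_state_before_loading(self, hp, ps3):
        tr = integrate_history(hp, ps3, lambda t: np.zeros_like(t), t_end=1.0, dt=0.1)
        np.testing.assert_array_equal(tr.stress, 0.0)

    def test_convergence_order_on_ramp(self, hp, ps3):
        # error vs a fine-dt reference decreases at least linearly in dt
        history = lambda t: np.minimum(1.2 * t, 0.08)
        t_end = 0.2
        ref = integrate_history(hp, ps3, history, t_end, dt=t_end / 16384)
        errs = []
        for n in (64, 128, 256):
            tr = integrate_history(hp, ps3, history, t_end, dt=t_end / n)
            ref_interp = np.interp(tr.times, ref.times, ref.stress)
            errs.append(np.max(np.abs(tr.stress - ref_interp) / ref.stress[-1]))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] > 1.8
        assert errs[1] / errs[2] > 1.8

    def test_ramp_deficit_below_bound(self, hp, ps3):
        # 0.067 s ramp to 8%: viscous loss during the ramp stays below 0.85%
        ramp = integrate_history(
            hp, ps3, lambda t: np.minimum(0.08 / 0.067 * t, 0.08),
            t_end=0.067, dt=0.067 / 1000,
        )
        s_step = elastic_axial_stress(hp, 1.08).nominal
        deficit = 100 * (s_step - ramp.stress[-1]) / s_step
        assert 0 < deficit < 0.85

    def test_bad_dt_rejected(self, hp, ps3):
        with pytest.raises(ValueError):
            integrate_history(hp, ps3, lambda t: t, t_end=1.0, dt=-0.1)
        with pytest.raises(ValueError):
            integrate_history(hp, ps3, lambda t: t, t_end=1.0,
                              times=np.array([0.0, 0.5, 0.5]))


class TestRampCurve:
    def test_fast_ramp_approaches_elastic(self, hp, ps3):
        tr = ramp_curve(hp, ps3, strain_rate=10.0, target_strain=0.06)
        elastic = elastic_axial_stress(hp, 1.06).cauchy
        assert tr.stress[-1] == pytest.approx(elastic, rel=0.01)

    def test_rate_stiffening_monotone(self, hp, ps3):
        stresses = [
            ramp_curve(hp, ps3, r, 0.06).stress[-1]
            for r in (0.006, 0.012, 0.024, 0.24)
        ]
        assert np.all(np.diff(stresses) > 0)

    def test_secant_modulus_gap_slow_vs_fast(self, hp, ps3):
        slow = secant_modulus(ramp_curve(hp, ps3, 0.006, 0.06), 0.06)
        fast = secant_modulus(ramp_curve(hp, ps3, 0.24, 0.06), 0.06)
        assert 100 * (fast - slow) / slow == pytest.approx(20.0, abs=5.0)


class TestSecantModulus:
    def test_linear_material(self):
        strain = np.linspace(0.001, 0.1, 50)
        tr = StressTrace(np.linspace(0, 1, 50), 120.0 * strain, strain)
        for e in (0.01, 0.05, 0.09):
            assert secant_modulus(tr, e) == pytest.approx(120.0, rel=1e-9)

    def test_elastic_trace_closed_form(self, hp):
        tr = ramp_curve(hp, PronySeries(), 0.012, 0.06)
        expected = elastic_axial_stress(hp, 1.06).cauchy / 0.06
        assert secant_modulus(tr, 0.06) == pytest.approx(expected, rel=1e-4)

    def test_sampling_density_consistency(self, hp, ps3):
        coarse = ramp_curve(hp, ps3, 0.012, 0.06, dt=0.06 / 0.012 / 200)
        fine = ramp_curve(hp, ps3, 0.012, 0.06, dt=0.06 / 0.012 / 2000)
        a, b = secant_modulus(coarse, 0.05), secant_modulus(fine, 0.05)
        assert a == pytest.approx(b, rel=1e-3)

    def test_out_of_range(self, hp, ps3):
        tr = ramp_curve(hp, ps3, 0.012, 0.06)
        with pytest.raises(ValueError):
            secant_modulus(tr, 0.07)


class TestDecayRate:
    def test_zero_without_branches(self, hp):
        tr = step_relaxation(hp, PronySeries(), 0.06, np.linspace(0.01, 240, 100))
        assert decay_rate(tr, 120.0) == 0.0

    def test_one_branch_analytic(self, hp):
        g, tau = 0.3, 10.0
        tr = step_relaxation(
            hp, PronySeries(((g, tau),)), 0.06, np.linspace(0.0, 60.0, 6001)
        )
        t = 20.0
        expected = 100 * (g / tau) * np.exp(-t / tau)
        assert decay_rate(tr, t) == pytest.approx(expected, rel=1e-3)

    def test_terminal_decay_three_branch(self, hp, ps3):
        times = np.unique(np.concatenate([default_hold_times(), np.linspace(239, 240, 5)]))
        tr = step_relaxation(hp, ps3, 0.06, times)
        assert decay_rate(tr, 240.0) < 0.007

    def test_boundary_rejected(self, step_trace):
        with pytest.raises(ValueError):
            decay_rate(step_trace, step_trace.times[0])
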