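import numpy as np
import pytest

from methylrap.crystallites import CrystalliteSet, make_crystallites
from methylrap.redor import (
    SequenceParams,
    _delta_phase_factors,
    build_grid,
    compute_epsilon,
    load_grid,
    simulate_redor,
)
from methylrap.tensor import DipolarTensor

from ._oracles import universal_redor

MAS = 50e3
TAU_R = 1.0 / MAS


class TestEpsilon:
    def test_four_microsecond_shift_at_50khz(self):
        assert compute_epsilon(4e-6, MAS) == pytest.approx(0.4)

    def test_zero_shift(self):
        assert compute_epsilon(0.0, MAS) == 0.0

    def test_direct_ratio(self):
        assert compute_epsilon(5e-6, MAS) == pytest.approx(0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            compute_epsilon(11e-6, MAS)


class TestSequenceParams:
    def test_dephasing_times(self):
        p = SequenceParams(mas_rate=MAS, n_max=3)
        assert np.allclose(p.dephasing_times, 2 * TAU_R * np.arange(1, 5))

    def test_pulse_exceeds_slot(self):
        # a pi pulse longer than half a rotor period cannot avoid overlap
        with pytest.raises(ValueError):
            SequenceParams(mas_rate=MAS, rf_H=40e3)


class TestDeltaPulseSimulation:
    def test_zero_coupling_no_dephasing(self):
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=3, delta_pulse=True)
        c = simulate_redor(DipolarTensor(0.0, 0.7), p,
                           make_crystallites("zcw", 89, 4))
        assert np.allclose(c.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0])
    def test_matches_universal_bessel_curve(self, lam):
        # classic REDOR spacing (zeta = tau_r/4), axially symmetric tensor
        n = 11
        T = 2 * TAU_R * (n + 1)
        p = SequenceParams(mas_rate=MAS, zeta=TAU_R / 4, n_max=n,
                           delta_pulse=True)
        c = simulate_redor(DipolarTensor(-lam / T, 0.0), p,
                           make_crystallites("zcw", 987, 4))
        assert c.values[-1] == pytest.approx(universal_redor(lam), abs=0.01)

    @pytest.mark.parametrize("lam", [5.0, 8.0, 12.0])
    def test_long_time_powder_asymptote(self, lam):
        # the powder curve tracks the oracle into its long-time plateau
        # around 1 (the oracle itself oscillates within ~0.09 of 1 here)
        n = 11
        T = 2 * TAU_R * (n + 1)
        p = SequenceParams(mas_rate=MAS, zeta=TAU_R / 4, n_max=n,
                           delta_pulse=True)
        c = simulate_redor(DipolarTensor(-lam / T, 0.0), p,
                           make_crystallites("zcw", 1597, 4))
        assert c.values[-1] == pytest.approx(universal_redor(lam), abs=0.02)
        assert abs(c.values[-1] - 1.0) < 0.1

    def test_reference_phase_refocuses_exactly(self):
        # rf_H = 0: the IzSz term refocuses over full rotor periods, so the
        # toggled reference phase vanishes identically for every crystallite
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=4, rf_H=0.0,
                           delta_pulse=True)
        PhiA, PhiB = _delta_phase_factors(
            p, make_crystallites("zcw", 55, 3), p.dephasing_times
        )
        assert np.abs(PhiA).max() < 1e-12
        assert np.abs(PhiB).max() < 1e-12

    def test_gamma_angle_irrelevant_for_axial_tensor(self):
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=5, delta_pulse=True)
        base = make_crystallites("zcw", 144, 1)
        curves = []
        for gamma0 in (0.0, 1.234):
            ang = base.angles.copy()
            ang[:, 2] = gamma0
            cs = CrystalliteSet(ang, base.weights, "zcw")
            curves.append(simulate_redor(DipolarTensor(-8000, 0.0), p, cs).values)
        assert np.allclose(curves[0], curves[1], atol=1e-10)

    def test_even_in_sign_of_delta(self):
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=5, delta_pulse=True)
        cs = make_crystallites("zcw", 89, 4)
        plus = simulate_redor(DipolarTensor(8000, 0.4), p, cs).values
        minus = simulate_redor(DipolarTensor(-8000, 0.4), p, cs).values
        assert np.allclose(plus, minus, atol=1e-12)

    def test_powder_converged_against_doubling(self):
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=11, delta_pulse=True)
        a = simulate_redor(DipolarTensor(-8000, 0.3), p,
                           make_crystallites("zcw", 610, 6)).values
        b = simulate_redor(DipolarTensor(-8000, 0.3), p,
                           make_crystallites("zcw", 1220, 6)).values
        assert np.abs(a - b).max() < 1e-3


class TestFinitePulsePropagator:
    def test_hard_pulse_limit_matches_delta_pulse(self):
        cs = make_crystallites("zcw", 89, 4)
        pd = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=1, delta_pulse=True)
        pf = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=1, rf_H=5e6,
                            rf_C=5e6)
        cd = simulate_redor(DipolarTensor(-8000, 0.3), pd, cs)
        cf = simulate_redor(DipolarTensor(-8000, 0.3), pf, cs, dt=2e-8)
        assert np.allclose(cd.values, cf.values, atol=1e-3)

    def test_time_step_convergence(self):
        cs = make_crystallites("zcw", 89, 4)
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=1)
        c1 = simulate_redor(DipolarTensor(-8000, 0.3), p, cs, dt=1e-7)
        c2 = simulate_redor(DipolarTensor(-8000, 0.3), p, cs, dt=5e-8)
        assert np.abs(c1.values - c2.values).max() < 1e-4

    def test_finite_pulses_attenuate_dephasing(self):
        # finite rf scales the recoupling slightly relative to ideal pulses
        cs = make_crystallites("zcw", 89, 4)
        pd = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=3, delta_pulse=True)
        pf = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=3)
        vd = simulate_redor(DipolarTensor(-8000, 0.3), pd, cs).values
        vf = simulate_redor(DipolarTensor(-8000, 0.3), pf, cs, dt=1e-7).values
        rising = vd > 0.05
        assert np.all(vf[rising] < vd[rising] * 1.05)


class TestGrid:
    def test_axes_and_zero_slice(self, fit_grid):
        assert fit_grid.aniso_axis[1] - fit_grid.aniso_axis[0] == 100.0
        assert fit_grid.eta_axis[1] - fit_grid.eta_axis[0] == pytest.approx(0.1)
        assert np.allclose(fit_grid.curves[0], 0.0, atol=1e-12)

    def test_values_within_physical_band(self, fit_grid):
        # the axially symmetric slice is bounded by its closed-form oracle,
        # whose largest overshoot is 1.043; strongly asymmetric tensors
        # (eta -> 1) rephase more coherently and overshoot further
        assert fit_grid.curves.min() > -0.05
        assert fit_grid.curves[:, 0, :].max() < 1.05
        assert fit_grid.curves.max() < 1.15

    def test_full_axis_count(self):
        # 0..21800 Hz in 100 Hz steps and 0..1 in 0.1 steps: 219 x 11 nodes
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=0, delta_pulse=True)
        g = build_grid(p, aniso_max=21800.0,
                       crystallites=make_crystallites("zcw", 34, 2))
        assert g.curves.shape[:2] == (219, 11)

    def test_cache_round_trip(self, tmp_path):
        p = SequenceParams(mas_rate=MAS, zeta=4e-6, n_max=1, delta_pulse=True)
        cs = make_crystallites("zcw", 34, 2)
        path = tmp_path / "grid.npz"
        g1 = build_grid(p, aniso_max=500.0, crystallites=cs, cache_path=path)
        g2 = load_grid(path)
        assert np.allclose(g1.curves, g2.curves)
        # matching cache is reused silently
        g3 = build_grid(p, aniso_max=500.0, crystallites=cs, cache_path=path)
        assert np.allclose(g1.curves, g3.curves)
        # parameter mismatch regenerates with a warning
        p2 = SequenceParams(mas_rate=MAS, zeta=3e-6, n_max=1, delta_pulse=True)
        with pytest.warns(UserWarning):
            build_grid(p2, aniso_max=500.0, crystallites=cs, cache_path=path)


class TestCrystallites:
    def test_zcw_counts_and_weights(self):
        cs = make_crystallites("zcw", 144, 16)
        assert len(cs) == 2304
        assert cs.weights.sum() == pytest.approx(1.0)

    def test_single_orientation_degenerate_set(self):
        cs = CrystalliteSet(np.zeros((1, 3)), np.ones(1))
        assert len(cs) == 1

    def test_repulsion_deterministic(self):
        a = make_crystallites("repulsion", 30, 2)
        b = make_crystallites("repulsion", 30, 2)
        assert np.array_equal(a.angles, b.angles)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            make_crystallites("lebedev", 10, 2)
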