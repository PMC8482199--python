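import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpragekit import (
    SequenceParams,
    apparent_rate,
    driven_equilibrium,
    elliptical_speedup,
    ernst_angle,
    gre_steady_state_signal,
    mprage_signal,
    scale_reference_signal,
    simulate_mprage_cycle,
)
from mpragekit.signal_models import mprage_mz_at_center

from conftest import per_pulse_center


class TestApparentRate:
    @pytest.mark.parametrize("r1,alpha,tr,expected", [
        (1.0, 0.0, 0.008, 1.0),          # cos 0 = 1, log term vanishes
        (1.0, 8.0, 0.008, 2.2224),
        (0.83, 3.0, 0.008, 1.0014),
    ])
    def test_closed_form_values(self, r1, alpha, tr, expected):
        assert apparent_rate(r1, alpha, tr) == pytest.approx(expected, abs=1e-4)

    def test_rejects_angle_at_or_beyond_90(self):
        with pytest.raises(ValueError):
            apparent_rate(1.0, 90.0, 0.008)

    @given(r1=st.floats(0.1, 5.0), alpha=st.floats(0.0, 89.0),
           tr=st.floats(1e-3, 0.05))
    def test_never_below_free_rate(self, r1, alpha, tr):
        r1s = apparent_rate(r1, alpha, tr)
        assert r1s >= r1
        if alpha == 0.0:
            assert r1s == r1


class TestDrivenEquilibrium:
    def test_zero_angle_is_full_equilibrium(self):
        assert driven_equilibrium(0.83, 0.0, 0.008) == pytest.approx(1.0)

    def test_reference_value(self):
        assert driven_equilibrium(0.83, 3.0, 0.008) == pytest.approx(
            0.8294, abs=1e-4)

    @given(r1=st.floats(0.1, 5.0), alpha=st.floats(0.0, 89.0))
    def test_bounded_in_unit_interval(self, r1, alpha):
        m = driven_equilibrium(r1, alpha, 0.008)
        assert 0.0 < m <= 1.0

    def test_monotonically_decreasing_in_flip_angle(self):
        alphas = np.linspace(0.0, 89.0, 200)
        m = driven_equilibrium(0.83, alphas, 0.008)
        assert np.all(np.diff(m) < 0)


class TestGreSteadyState:
    def test_product_of_saturation_and_sine(self):
        s = gre_steady_state_signal(1.2, 3.0, 1.0, 0.008)
        assert s == pytest.approx(
            driven_equilibrium(1.0 / 1.2, 3.0, 0.008)
            * math.sin(math.radians(3.0)))
        assert s == pytest.approx(0.0434, abs=1e-4)

    def test_vanishes_at_zero_flip(self):
        assert gre_steady_state_signal(1.7, 3.0, 0.0, 0.008) == 0.0

    @pytest.mark.parametrize("t1", [1.0, 1.5, 2.0])
    def test_maximal_at_ernst_angle(self, t1):
        alphas = np.linspace(0.5, 20.0, 2000)
        s = gre_steady_state_signal(t1, alphas, 1.0, 0.008)
        peak = alphas[np.argmax(s)]
        assert peak == pytest.approx(ernst_angle(0.008, t1), abs=0.02)


class TestErnstAngle:
    def test_closed_form(self):
        assert ernst_angle(0.008, 1.0) == pytest.approx(
            math.degrees(math.acos(math.exp(-0.008))))

    def test_protocol_values_round_to_7_and_5_degrees(self):
        assert round(ernst_angle(0.008, 1.0)) == 7
        assert round(ernst_angle(0.008, 2.0)) == 5

    def test_vanishes_with_tr(self):
        assert ernst_angle(1e-9, 1.0) == pytest.approx(0.0, abs=1e-2)


def test_elliptical_speedup_is_area_ratio():
    v = elliptical_speedup()
    assert v == pytest.approx(4.0 / math.pi)
    assert round(v, 1) == 1.3
    assert v > 1.0


class TestMprageCycle:
    @pytest.mark.parametrize("t1", [1.2, 2.0, 4.0])
    def test_in_train_samples_obey_per_pulse_recursion(self, seq, t1):
        """Sampled at pulse times, the trajectory satisfies the discrete
        rotation-relaxation recursion mz' = 1 + (mz cos(a) - 1) e^{-TR/T1}."""
        traj = simulate_mprage_cycle(seq, t1=t1, f_t=1.0, dt=seq.tr)
        t_start = seq.train_start
        pulse_times = t_start + seq.tr * np.arange(seq.tf + 1)
        mz = np.interp(pulse_times, traj.times, traj.mz)
        ca = math.cos(math.radians(seq.alpha_mp))
        e_tr = math.exp(-seq.tr / t1)
        pred = 1.0 + (mz[:-1] * ca - 1.0) * e_tr
        assert np.max(np.abs(pred - mz[1:])) < 1e-9

    def test_no_excitation_fast_relaxation_recovers_equilibrium(self):
        """With zero local flip angle (no readout saturation) and T1 much
        shorter than the cycle, Mz sits at thermal equilibrium at the
        centre line and at cycle end."""
        seq = SequenceParams(f_inv=0.0)  # saturating preparation
        traj = simulate_mprage_cycle(seq, t1=0.1, f_t=0.0)
        assert traj.mz_at_center == pytest.approx(1.0, abs=1e-4)
        assert traj.mz[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(traj.mz) >= -1e-12)  # pure recovery

    def test_trajectory_is_cycle_periodic(self, seq):
        for t1 in (1.2, 1.8, 4.0):
            traj = simulate_mprage_cycle(seq, t1=t1)
            # value at cycle end equals the pre-inversion value that seeded
            # the cycle: -mz(0+)/f_inv
            mz_start = traj.mz[0]
            assert traj.mz[-1] == pytest.approx(-mz_start / seq.f_inv,
                                                abs=1e-8)

    def test_outer_loop_steady_state_reached_in_three_cycles(self, seq):
        """The cycle map converges to ~1% of its fixed point by cycle 3."""
        for t1 in (1.2, 3.0, 5.0):
            m3 = per_pulse_center(seq, t1, 1.0, n_cycles=3)
            m4 = per_pulse_center(seq, t1, 1.0, n_cycles=4)
            assert abs(m4 - m3) < 0.01

    def test_magnitude_bounded_by_equilibrium(self, seq):
        for t1 in (0.8, 1.2, 4.0):
            traj = simulate_mprage_cycle(seq, t1=t1)
            assert np.all(np.abs(traj.mz) <= 1.0 + 1e-12)

    def test_csf_near_zero_crossing_at_center(self, seq):
        """Protocol timing puts CSF Mz near its zero crossing at TI."""
        csf = simulate_mprage_cycle(seq, t1=4.0)
        wm = simulate_mprage_cycle(seq, t1=1.2)
        assert abs(csf.mz_at_center) < 0.1
        assert wm.mz_at_center > 0.25

    def test_train_must_fit_in_cycle(self):
        with pytest.raises(ValueError):
            SequenceParams(tf=500, tr=0.008, t_cycle=3.5)

    def test_matches_per_pulse_oracle(self, seq):
        t1 = np.array([0.8, 1.2, 2.0, 3.5, 5.0])
        for ft in (0.4, 1.0, 1.6):
            cont = mprage_mz_at_center(seq, t1, ft)
            disc = per_pulse_center(seq, t1, ft)
            assert np.max(np.abs(cont - disc)) < 0.01


class TestMprageSignal:
    def test_sign_follows_center_magnetization(self, seq):
        assert mprage_signal(seq, 1.2, 1.0) > 0     # WM recovered
        assert mprage_signal(seq, 1e9, 1.0) < 1e-3  # no recovery

    def test_zero_transmit_field_gives_zero_signal(self, seq):
        assert mprage_signal(seq, 1.5, 0.0) == 0.0


class TestScaleReferenceSignal:
    def test_identity_at_equal_angles(self):
        assert scale_reference_signal(3.3, 4.0, 4.0) == pytest.approx(3.3)

    def test_reference_ratio_value(self):
        # alpha_i=3, alpha_ref=6: small-angle Ernst ratio 0.7567
        out = scale_reference_signal(1.0, 3.0, 6.0, r1=0.83, tr=0.008)
        assert out == pytest.approx(1.0 / 0.7567, abs=2e-4)

    def test_zero_angle_rejected(self):
        with pytest.raises(ZeroDivisionError):
            scale_reference_signal(1.0, 0.0, 6.0)

    @pytest.mark.parametrize("t1", [1.0, 1.5, 2.0])
    @pytest.mark.parametrize("alpha_i", [1.0, 2.0, 4.0, 8.0])
    def test_small_angle_ratio_tracks_exact_ernst_ratio(self, t1, alpha_i):
        """With the scaling R1 matched to the tissue, the rational
        small-angle ratio agrees with the exact steady-state signal ratio
        within 2% for angles up to 8 deg."""
        alpha_ref = 6.0
        scaled = scale_reference_signal(
            gre_steady_state_signal(t1, alpha_i, 1.0, 0.008),
            alpha_i, alpha_ref, r1=1.0 / t1, tr=0.008)
        ref = gre_steady_state_signal(t1, alpha_ref, 1.0, 0.008)
        assert scaled == pytest.approx(ref, rel=0.02)


class TestSequenceParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"tr": -1.0},
        {"ti": 4.0},
        {"tf": 0},
        {"f_inv": 1.5},
        {"alpha_mp": 95.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SequenceParams(**kwargs)
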