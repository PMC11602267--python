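import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resl_sirs.protocol import GAMMA_HZ_PER_T, NeuronalField, ProtocolParams
from resl_sirs.bloch import (
    RunTimeSeries,
    SpinState,
    TissueParams,
    evolve_spinlock,
    resl_preparation,
    resonance_curve,
    rotate_hard_pulse,
    simulate_run,
    slice_signal,
    steady_state_mz,
)

LOCK_DOWN = np.array([0.0, -1.0, 0.0])


def deviation_from_lock(state: SpinState) -> float:
    """Angle between the magnetization and the -y lock axis."""
    return float(np.arccos(np.clip(-state.m[1] / np.linalg.norm(state.m),
                                   -1.0, 1.0)))


class TestHardPulse:
    def test_right_handed_convention(self):
        out = rotate_hard_pulse(SpinState(), (1, 0, 0), np.pi / 2)
        assert out.m == pytest.approx([0.0, -1.0, 0.0], abs=1e-12)

    def test_zero_angle_identity(self):
        m0 = np.array([0.3, -0.4, 0.5])
        out = rotate_hard_pulse(SpinState(m=m0), (0, 1, 0), 0.0)
        assert out.m == pytest.approx(m0, abs=1e-15)

    def test_inversion(self):
        out = rotate_hard_pulse(SpinState(), (1, 0, 0), np.pi)
        assert out.m == pytest.approx([0.0, 0.0, -1.0], abs=1e-12)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            rotate_hard_pulse(SpinState(), (0, 0, 0), 1.0)

    @given(mx=st.floats(-1, 1), my=st.floats(-1, 1), mz=st.floats(-1, 1),
           ax=st.floats(-1, 1), ay=st.floats(-1, 1), az=st.floats(0.1, 1),
           angle=st.floats(-6.3, 6.3))
    @settings(max_examples=100, derandomize=True)
    def test_norm_preserved(self, mx, my, mz, ax, ay, az, angle):
        m = np.array([mx, my, mz])
        out = rotate_hard_pulse(SpinState(m=m), (ax, ay, az), angle)
        assert np.linalg.norm(out.m) == pytest.approx(np.linalg.norm(m),
                                                      abs=1e-12)


class TestEvolveSpinlock:
    def test_no_field_locked_magnetization_unchanged(self, default_params):
        out = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                              NeuronalField(b_n=0.0), 0.0)
        assert out.m == pytest.approx(LOCK_DOWN, abs=1e-9)

    def test_coarse_step_matches_fine_step_oracle(self):
        """The default 0.1 ms step must agree with a 1 us integration."""
        field = NeuronalField(b_n=4e-9, f_n=8.0)
        coarse = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                                 field, 1.0, dt=1e-4)
        fine = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                               field, 1.0, dt=1e-6)
        assert coarse.m == pytest.approx(fine.m, abs=1e-6)

    def test_resonant_deviation_near_rotating_wave_value(self):
        """Phase-averaged resonant deviation over 35 ms is within 10% of the
        rotating-wave closed form gamma*b_n*t/2 (~0.0187 rad)."""
        field = NeuronalField(b_n=4e-9, f_n=8.0)
        devs = []
        for phi in np.linspace(0, 2 * np.pi, 16, endpoint=False):
            out = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                                  field, phi)
            devs.append(deviation_from_lock(out))
        expected = 2 * np.pi * GAMMA_HZ_PER_T * 4e-9 * 0.035 / 2
        assert expected == pytest.approx(0.0187, abs=3e-4)
        assert np.mean(devs) == pytest.approx(expected, rel=0.10)

    def test_far_off_resonance_deviation_small(self):
        """A field detuned by 10/TSL from the lock frequency deviates the
        magnetization < 20% as much as the resonant field."""
        res, off = [], []
        for phi in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            o1 = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                                 NeuronalField(b_n=4e-9, f_n=8.0), phi)
            o2 = evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                                 NeuronalField(b_n=4e-9, f_n=8.0 + 10 / 0.070),
                                 phi)
            res.append(deviation_from_lock(o1))
            off.append(deviation_from_lock(o2))
        assert np.mean(off) < 0.20 * np.mean(res)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            evolve_spinlock(SpinState(m=LOCK_DOWN), 0.035, 8.0, -1,
                            NeuronalField(), 0.0, dt=-1e-4)


class TestReslPreparation:
    @given(tsl=st.floats(0.01, 0.2), f_sl=st.floats(0.0, 100.0),
           mz=st.floats(0.1, 1.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_rotary_echo_refocuses_without_field(self, tsl, f_sl, mz):
        """With no oscillating field the opposite-phase halves cancel and
        the preparation is the identity on Mz, for any TSL and f_SL."""
        params = ProtocolParams(tsl=tsl, f_sl=f_sl)
        out = resl_preparation(SpinState(m=np.array([0.0, 0.0, mz])), params,
                               NeuronalField(b_n=0.0), 1.2)
        assert out == pytest.approx(mz, abs=1e-9)

    def test_zero_amplitude_at_lock_frequency(self, default_params):
        out = resl_preparation(SpinState(), default_params,
                               NeuronalField(b_n=0.0, f_n=8.0), 0.0)
        assert out == pytest.approx(1.0, abs=1e-9)

    def test_resonant_field_saturates_phase_dependently(self, default_params):
        field = NeuronalField(b_n=4e-9, f_n=8.0)
        mz = [resl_preparation(SpinState(), default_params, field, phi)
              for phi in np.linspace(0, 2 * np.pi, 16, endpoint=False)]
        mz = np.array(mz)
        assert np.all(mz <= 1.0 + 1e-12)
        assert mz.max() - mz.min() > 1e-5     # saturation varies with phase
        assert np.any(1.0 - mz > 1e-5)        # some phase saturates


class TestSliceSignal:
    def test_unprepared_steady_state(self, default_params):
        tissue = TissueParams()
        mz_ss = steady_state_mz(default_params, tissue)
        sig = slice_signal(mz_ss, 1, default_params, tissue)
        assert sig == pytest.approx(mz_ss)

    def test_infinite_t1_keeps_deviation(self, default_params):
        tissue = TissueParams(t1=1e9)
        sigs = [slice_signal(0.5, k, default_params, tissue)
                for k in range(1, 7)]
        devs = np.array(sigs) - steady_state_mz(default_params, tissue)
        assert np.allclose(devs, devs[0], atol=1e-9)

    def test_decay_matches_recursive_bookkeeping_oracle(self, default_params):
        """The prepared-unprepared signal difference per slice must follow
        the step-by-step Mz recursion: relaxation toward M0 between the
        preparation and each slice's excitation."""
        tissue = TissueParams(t1=1.3)
        mz_prep, mz_unprep = 0.4, steady_state_mz(default_params, tissue)
        tr, t1 = default_params.tr, tissue.t1
        # oracle: advance both runs slice by slice, relaxing toward M0
        diffs = []
        m_p, m_u = mz_prep, mz_unprep
        for k in range(default_params.n_slices):
            diffs.append(m_p - m_u)
            e = np.exp(-tr / t1)
            m_p = 1.0 + (m_p - 1.0) * e
            m_u = 1.0 + (m_u - 1.0) * e
        diffs = np.array(diffs)
        got = np.array([slice_signal(mz_prep, k, default_params, tissue)
                        - slice_signal(mz_unprep, k, default_params, tissue)
                        for k in range(1, default_params.n_slices + 1)])
        assert got == pytest.approx(diffs, abs=1e-9)
        ratios = got / got[0]
        k = np.arange(default_params.n_slices)
        assert ratios == pytest.approx(np.exp(-k * tr / t1), abs=1e-9)

    def test_out_of_range_slice(self, default_params):
        with pytest.raises(ValueError):
            slice_signal(0.5, 7, default_params)


class TestSimulateRun:
    def test_no_field_streams_identical(self, scaled_params):
        run = simulate_run(scaled_params, NeuronalField(b_n=0.0))
        assert np.array_equal(run.slon, run.sloff)
        assert run.slon.shape == (90, 3)

    def test_resonant_field_variance_contrast(self, default_params):
        params = default_params.replace(n_reps=60)
        run = simulate_run(params, NeuronalField(b_n=4e-9, f_n=8.0))
        v_on = run.slon[:, 0].var()
        v_off = run.sloff[:, 0].var()
        assert v_on > 10 * max(v_off, 1e-30)

    def test_prepared_deviation_decays_with_slice(self, default_params):
        params = default_params.replace(n_reps=60)
        run = simulate_run(params, NeuronalField(b_n=4e-9, f_n=8.0))
        dev_std = (run.slon - run.sloff).std(axis=0)
        assert np.all(np.diff(dev_std) < 0)
        assert dev_std[1] / dev_std[0] == pytest.approx(
            np.exp(-params.tr / 1.3), rel=1e-6)

    def test_phi0_is_cyclic_shift(self, default_params):
        """Changing the initial field phase by an integer number of
        repetition increments cyclically shifts the sampled phase sequence."""
        params = default_params.replace(n_reps=24, n_dummies=0)
        f_n = 8.0
        step = (2 * np.pi * f_n * params.tr_eff) % (2 * np.pi)
        r0 = simulate_run(params, NeuronalField(b_n=4e-9, f_n=f_n, phi0=0.0))
        r1 = simulate_run(params, NeuronalField(b_n=4e-9, f_n=f_n,
                                                phi0=step % (2 * np.pi)))
        assert r1.slon[:-1] == pytest.approx(r0.slon[1:], abs=1e-12)

    def test_dummies_discarded(self, scaled_params):
        run = simulate_run(scaled_params, NeuronalField(b_n=0.0))
        assert run.slon.shape[0] == scaled_params.n_reps
        assert run.phases.shape == (scaled_params.n_reps,)

    def test_export_table(self, scaled_params):
        run = simulate_run(scaled_params.replace(n_reps=4),
                           NeuronalField(b_n=0.0))
        df = run.to_frame()
        assert set(df.columns) == {"repetition", "slice", "slon", "sloff",
                                   "phase"}
        assert len(df) == 4 * 3


class TestResonanceCurve:
    def test_zero_amplitude_gives_zero(self, default_params):
        curve = resonance_curve(default_params, 0.0, [0.0, 4.0, 8.0],
                                n_phases=4)
        assert np.allclose(curve.saturation, 0.0, atol=1e-12)

    def test_default_params_subcycle_regime(self, default_params):
        """At the study parameters the lock completes only 0.56 cycles, so
        the quasi-static response dominates: the curve decreases from DC and
        its maximum is still within 1/TSL of the lock frequency."""
        grid = np.linspace(0.0, 24.0, 25)
        curve = resonance_curve(default_params, 4e-9, grid, n_phases=8)
        peak = curve.f_n[curve.saturation.idxmax()]
        assert peak == 0.0
        assert abs(peak - default_params.f_sl) <= 1.0 / default_params.tsl

    def test_multicycle_regime_peaks_at_lock_frequency(self):
        """With several lock cycles the rotary resonance forms and the curve
        peaks at f_SL within the 1/(2 TSL) linewidth."""
        params = ProtocolParams(f_sl=80.0)
        grid = np.linspace(40.0, 120.0, 41)
        curve = resonance_curve(params, 4e-9, grid, n_phases=8)
        peak = curve.f_n[curve.saturation.idxmax()]
        assert abs(peak - 80.0) <= 1.0 / (2 * params.tsl)

    def test_saturation_monotone_in_field_amplitude(self, default_params):
        sats = [resonance_curve(default_params, b, [8.0], n_phases=8)
                .saturation.iloc[0] for b in np.linspace(0, 10e-9, 6)]
        assert np.all(np.diff(sats) >= 0)

    def test_symmetric_near_resonance_multicycle(self):
        params = ProtocolParams(f_sl=40.0, tsl=0.5)
        half_width = 1.0 / (2 * params.tsl)
        curve = resonance_curve(params, 1e-9,
                                [40.0 - half_width, 40.0 + half_width],
                                n_phases=8)
        s = curve.saturation.to_numpy()
        assert abs(s[0] - s[1]) <= 0.05 * s.max()

    def test_empty_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            resonance_curve(default_params, 4e-9, [])
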