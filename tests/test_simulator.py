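import numpy as np
import pytest
from scipy.signal import periodogram

from fuzzytrack.motion_data import MarkerTrace
from fuzzytrack.simulator import (
    AffineCoupling,
    BreathingParams,
    DEFAULT_AFFINE,
    PiecewiseLinearCoupling,
    SigmoidCoupling,
    make_cohort,
    preset_params,
    sample_imaging,
    simulate_patient,
)


def quiet_params(**overrides):
    base = dict(
        period_jitter_s=0.0,
        amplitude_jitter_frac=0.0,
        external_noise_mm=0.0,
        internal_noise_mm=0.0,
        drift_mm_per_min=np.zeros(9),
        lag_s=0.0,
        duration_s=60.0,
        n_imaging=10,
        seed=7,
    )
    base.update(overrides)
    return BreathingParams(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p1 = simulate_patient(BreathingParams(seed=11))
        p2 = simulate_patient(BreathingParams(seed=11))
        np.testing.assert_array_equal(p1.external.values, p2.external.values)
        np.testing.assert_array_equal(p1.imaging.X, p2.imaging.X)

    def test_different_seeds_differ(self):
        p1 = simulate_patient(BreathingParams(seed=11))
        p2 = simulate_patient(BreathingParams(seed=12))
        assert not np.allclose(p1.external.values, p2.external.values)


class TestStructure:
    def test_noiseless_affine_coupling_is_exactly_affine(self):
        patient = simulate_patient(quiet_params())
        X = patient.external.values
        Y = patient.internal_truth.values
        B = np.column_stack([X, np.ones(len(X))])
        theta, *_ = np.linalg.lstsq(B, Y, rcond=None)
        resid = np.abs(B @ theta - Y).max()
        assert resid < 1e-9

    def test_lag_shifts_the_coupled_signal(self):
        # lag of exactly 5 samples at 25 Hz
        params = quiet_params(lag_s=0.2)
        patient = simulate_patient(params)
        X = patient.external.values
        Y = patient.internal_truth.values
        B = np.column_stack([X[:-5], np.ones(len(X) - 5)])
        theta, *_ = np.linalg.lstsq(B, Y[5:], rcond=None)
        assert np.abs(B @ theta - Y[5:]).max() < 1e-9

    def test_dominant_spectral_peak_at_breathing_rate(self):
        params = quiet_params(period_s=4.0, duration_s=300.0, period_jitter_s=0.05)
        patient = simulate_patient(params)
        z = patient.external.values[:, 2]
        f, pxx = periodogram(z - z.mean(), fs=params.rate_hz)
        peak = f[np.argmax(pxx)]
        assert peak == pytest.approx(0.25, abs=0.03)

    def test_amplitude_scaling_doubles_oscillation_exactly(self):
        p1 = quiet_params()
        p2 = quiet_params(amplitudes_mm=p1.amplitudes_mm * 2.0)
        x1 = simulate_patient(p1).external.values
        x2 = simulate_patient(p2).external.values
        osc1 = x1 - p1.baselines_mm
        osc2 = x2 - p2.baselines_mm
        np.testing.assert_allclose(osc2, 2.0 * osc1, atol=1e-12)

    def test_affine_coupling_functionally_identifiable_at_zero_noise(self):
        # cycle-to-cycle variability spreads the trajectory enough that a
        # global affine fit on one half predicts the other half exactly
        params = quiet_params(
            period_jitter_s=0.2, amplitude_jitter_frac=0.1, duration_s=200.0
        )
        patient = simulate_patient(params)
        X, Y = patient.external.values, patient.internal_truth.values
        half = len(X) // 2
        B = np.column_stack([X, np.ones(len(X))])
        theta, *_ = np.linalg.lstsq(B[:half], Y[:half], rcond=None)
        assert np.abs(B[half:] @ theta - Y[half:]).max() < 1e-6

    def test_sigh_cycles_deepen_breathing(self):
        deep = simulate_patient(quiet_params(sigh_prob=0.5, sigh_factor=2.0,
                                             duration_s=120.0, seed=3))
        calm = simulate_patient(quiet_params(duration_s=120.0, seed=3))
        assert deep.external.values[:, 2].max() > 1.5 * calm.external.values[:, 2].max()


class TestImaging:
    def test_uniform_schedule_gap_regularity(self):
        patient = simulate_patient(quiet_params(duration_s=100.0))
        imaging = sample_imaging(
            patient.external, patient.internal_truth, 11, "uniform", seed=1, noise_mm=0.0
        )
        gaps = np.diff(imaging.timestamps)
        span = patient.internal_truth.timestamps[-1] - patient.internal_truth.timestamps[0]
        np.testing.assert_allclose(gaps, span / 10, atol=0.05)

    def test_minimum_clinical_regime_four_points_over_58s(self):
        patient = simulate_patient(quiet_params(duration_s=58.0))
        imaging = sample_imaging(
            patient.external, patient.internal_truth, 4, "uniform", seed=1
        )
        assert imaging.n_points == 4
        assert imaging.timestamps[-1] - imaging.timestamps[0] <= 58.0

    def test_maximum_clinical_regime_27_points_over_603s(self):
        patient = simulate_patient(quiet_params(duration_s=603.0))
        imaging = sample_imaging(
            patient.external, patient.internal_truth, 27, "random", seed=1
        )
        assert imaging.n_points == 27

    def test_burst_then_sparse_front_loads_half_the_points(self):
        patient = simulate_patient(quiet_params(duration_s=100.0))
        imaging = sample_imaging(
            patient.external, patient.internal_truth, 20, "burst-then-sparse", seed=1
        )
        t0, t1 = patient.internal_truth.timestamps[[0, -1]]
        early = imaging.timestamps < t0 + 0.2 * (t1 - t0)
        assert early.sum() == 10

    def test_too_many_points_rejected(self):
        patient = simulate_patient(quiet_params(duration_s=10.0))
        with pytest.raises(ValueError):
            sample_imaging(patient.external, patient.internal_truth, 10**6, "uniform")


class TestCouplings:
    def test_piecewise_linear_is_continuous_at_the_knee(self):
        c = PiecewiseLinearCoupling(
            weights=np.full(9, 1 / 9), threshold=1.0,
            slopes_low=np.ones(3), slopes_high=np.full(3, 3.0), offset=np.zeros(3),
        )
        eps = 1e-9
        below = c.apply(np.full((1, 9), 1.0 - eps))
        above = c.apply(np.full((1, 9), 1.0 + eps))
        np.testing.assert_allclose(below, above, atol=1e-6)

    def test_sigmoid_saturates(self):
        c = SigmoidCoupling(
            weights=np.full(9, 1 / 9), center=0.0, width=1.0,
            scale=np.array([10.0, 10.0, 10.0]), offset=np.zeros(3),
        )
        hi = c.apply(np.full((1, 9), 100.0))
        np.testing.assert_allclose(hi, [[10.0, 10.0, 10.0]], atol=1e-6)


class TestCohort:
    def test_cohort_regenerates_identically(self):
        c1 = make_cohort(["control", "worst"], master_seed=5, duration_s=60.0, n_imaging=8)
        c2 = make_cohort(["control", "worst"], master_seed=5, duration_s=60.0, n_imaging=8)
        for a, b in zip(c1, c2):
            assert a.seed == b.seed and a.name == b.name
            np.testing.assert_array_equal(a.patient.external.values, b.patient.external.values)

    def test_every_patient_satisfies_trace_invariants(self):
        cohort = make_cohort(
            ["control"] * 2 + ["worst"] * 2, master_seed=9, duration_s=60.0, n_imaging=8
        )
        for member in cohort:
            ext, truth = member.patient.external, member.patient.internal_truth
            assert ext.n_channels == 9 and truth.n_channels == 3
            assert np.all(np.diff(ext.timestamps) > 0)
            img = member.patient.imaging
            assert img.timestamps[0] >= ext.timestamps[0]
            assert img.timestamps[-1] <= ext.timestamps[-1]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_params("typical", 1)
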