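"""Fourier spectra, inverse-oscillation detection, rank correlations."""

import numpy as np
import pytest

import spinegait as sg
from spinegait.coupling import (
    InsufficientSpanError,
    SpectrumAlignmentError,
    UndefinedCorrelationError,
    cosine_spectrum,
    strength_label,
)


def naive_dft_amplitudes(x):
    """O(N^2) direct-summation oracle for the cosine/sine amplitudes."""
    n = len(x)
    ks = np.arange(n // 2 + 1)
    a = np.zeros(len(ks))
    b = np.zeros(len(ks))
    t = np.arange(n)
    for k in ks:
        c = np.cos(2 * np.pi * k * t / n)
        s = np.sin(2 * np.pi * k * t / n)
        scale = 1.0 / n if k in (0, n / 2) else 2.0 / n
        a[k] = scale * np.sum(x * c)
        b[k] = scale * np.sum(x * s)
    return a, b


class TestCosineSpectrum:
    def test_pure_cosine_eigenfunction(self):
        t = np.arange(400) / 100.0  # 4 strides of 1 s
        x = 3.0 * np.cos(2 * np.pi * t)
        spec = cosine_spectrum(x, 100.0, 1.0)
        k = np.argmin(np.abs(spec.frequencies - 1.0))
        assert spec.cosine_amplitudes[k] == pytest.approx(3.0, abs=1e-9)
        assert spec.sine_amplitudes[k] == pytest.approx(0.0, abs=1e-9)
        assert spec.main_index == k
        others = np.delete(spec.cosine_amplitudes, [0, k])
        assert np.allclose(others, 0.0, atol=1e-9)

    def test_matches_direct_summation_oracle(self, rng):
        x = rng.standard_normal(200)
        spec = cosine_spectrum(x, 100.0, 1.0)  # 2 strides
        a, b = naive_dft_amplitudes(x - x.mean())
        assert np.allclose(spec.cosine_amplitudes[1:], a[1:], atol=1e-9)
        assert np.allclose(spec.sine_amplitudes[1:], b[1:], atol=1e-9)

    def test_parseval_consistency(self, rng):
        x = rng.standard_normal(300)
        spec = cosine_spectrum(x, 100.0, 1.0)
        xc = x[:300] - x[:300].mean()
        power = np.mean(xc**2)
        # even length: the Nyquist bin carries full (not half) weight
        amp_power = 0.5 * np.sum(
            spec.cosine_amplitudes[1:-1] ** 2 + spec.sine_amplitudes[1:-1] ** 2
        ) + spec.cosine_amplitudes[-1] ** 2
        assert amp_power == pytest.approx(power, abs=1e-9)

    def test_insufficient_span_rejected(self):
        with pytest.raises(InsufficientSpanError):
            cosine_spectrum(np.zeros(150), 100.0, 1.0)

    def test_truncates_to_whole_strides(self):
        t = np.arange(250) / 100.0
        x = np.cos(2 * np.pi * t)
        spec = cosine_spectrum(x, 100.0, 1.0)  # 2.5 strides -> 2 used
        k = np.argmin(np.abs(spec.frequencies - 1.0))
        assert spec.cosine_amplitudes[k] == pytest.approx(1.0, abs=1e-9)

    def test_main_frequency_matches_phase_class(self, walk_trial, trot_trial):
        # monophasic DOFs oscillate at 1 cycle/stride, biphasic at 2
        cases = [
            (walk_trial, "pelvis", "rx", 1.0),
            (walk_trial, "pelvis", "ry", 1.0),
            (walk_trial, "pelvis", "rz", 2.0),
            (trot_trial, "pelvis", "rx", 1.0),
            (trot_trial, "pelvis", "rz", 2.0),
            (trot_trial, "L7", "rz", 2.0),
        ]
        for trial, bone, dof, freq in cases:
            T = trial["preset"].stride_duration_s
            spec = cosine_spectrum(
                trial["relative"][bone][dof].to_numpy(), 100.0, T
            )
            assert spec.main_frequency == pytest.approx(freq), (bone, dof)


class TestInverseOscillation:
    def _spec(self, x):
        return cosine_spectrum(x, 100.0, 1.0)

    def test_cos_vs_minus_cos(self):
        t = np.arange(300) / 100.0
        a = self._spec(np.cos(2 * np.pi * t))
        b = self._spec(-np.cos(2 * np.pi * t))
        assert sg.inverse_oscillation(a, b) == "inverse"

    def test_identical_spectra_in_phase(self):
        t = np.arange(300) / 100.0
        a = self._spec(np.cos(2 * np.pi * t))
        assert sg.inverse_oscillation(a, a) == "in_phase"

    def test_symmetry(self, walk_trial):
        T = walk_trial["preset"].stride_duration_s
        a = cosine_spectrum(walk_trial["relative"]["pelvis"]["rx"].to_numpy(),
                            100.0, T)
        b = cosine_spectrum(walk_trial["relative"]["L7"]["rx"].to_numpy(),
                            100.0, T)
        assert sg.inverse_oscillation(a, b) == sg.inverse_oscillation(b, a)

    def test_axial_pelvis_l7_inverse_both_gaits(self, walk_trial, trot_trial):
        for trial in (walk_trial, trot_trial):
            T = trial["preset"].stride_duration_s
            a = cosine_spectrum(
                trial["relative"]["pelvis"]["rx"].to_numpy(), 100.0, T
            )
            b = cosine_spectrum(trial["relative"]["L7"]["rx"].to_numpy(),
                                100.0, T)
            assert sg.inverse_oscillation(a, b) == "inverse"

    def test_sagittal_pelvis_l7_inverse_only_at_trot(self, walk_trial,
                                                     trot_trial):
        verdicts = {}
        for name, trial in (("walk", walk_trial), ("trot", trot_trial)):
            T = trial["preset"].stride_duration_s
            a = cosine_spectrum(
                trial["relative"]["pelvis"]["rz"].to_numpy(), 100.0, T
            )
            b = cosine_spectrum(trial["relative"]["L7"]["rz"].to_numpy(),
                                100.0, T)
            verdicts[name] = sg.inverse_oscillation(a, b)
        assert verdicts["trot"] == "inverse"
        assert verdicts["walk"] != "inverse"

    def test_mismatched_grids_rejected(self):
        t = np.arange(300) / 100.0
        a = self._spec(np.cos(2 * np.pi * t))
        b = cosine_spectrum(np.cos(2 * np.pi * t[:200]), 100.0, 1.0)
        with pytest.raises(SpectrumAlignmentError):
            sg.inverse_oscillation(a, b)


class TestRankCorrelation:
    def test_monotone_pair_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert sg.rank_correlation(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(10.0)
        assert sg.rank_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        d2 = np.sum((np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))) ** 2)
        expected = 1 - 6 * d2 / (4 * 15)
        assert sg.rank_correlation(x, y) == pytest.approx(expected)
        assert expected == pytest.approx(0.8)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        rho = sg.rank_correlation(x, y)
        assert sg.rank_correlation(np.exp(x), y) == pytest.approx(rho)
        assert sg.rank_correlation(x, 5 * y + 2) == pytest.approx(rho)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            sg.rank_correlation(np.ones(5), np.arange(5.0))


class TestStrideCorrelationMatrix:
    def _stride_curves(self, presets, seed, noise=True, jitter=False):
        preset = presets["walk"]
        spec = sg.TrialSpec(
            n_strides=6, seed=seed, noise_enabled=noise, jitter_enabled=jitter
        )
        chain, events = sg.generate_trial(preset, spec)
        rel = sg.chain_to_relative(chain)
        segments = sg.segment_strides(events)
        duty = sg.duty_factor(events)
        df = rel["pelvis"]
        return {
            f"stride_{i}": sg.normalize_stride(
                df["time_s"].to_numpy(), df["rx"].to_numpy(), seg, duty
            )
            for i, seg in enumerate(segments)
        }

    def test_identical_strides_all_one(self, presets):
        curves = self._stride_curves(presets, seed=0, noise=False)
        out = sg.stride_correlation_matrix(curves)
        assert np.allclose(out.rho.to_numpy(), 1.0)
        assert out.median_abs_rho == pytest.approx(1.0)

    def test_noisy_strides_strongly_correlated(self, presets):
        medians = [
            sg.stride_correlation_matrix(
                self._stride_curves(presets, seed=s)
            ).median_abs_rho
            for s in range(20)
        ]
        assert np.median(medians) > 0.9

    def test_white_noise_uncorrelated(self, rng):
        curves = {
            f"n{i}": sg.NormalizedCurve(rng.standard_normal(101))
            for i in range(8)
        }
        out = sg.stride_correlation_matrix(curves)
        assert out.median_abs_rho < 0.2

    def test_strength_labels(self):
        assert strength_label(0.2) == "mild"
        assert strength_label(-0.55) == "moderate"
        assert strength_label(0.95) == "strong"


class TestCouplingTest:
    def test_self_coupling_strong_in_phase(self, walk_trial, mean_curve_of):
        a = mean_curve_of(walk_trial, "pelvis", "rx")
        rep = sg.coupling_test(a, a)
        assert rep.relation == "in_phase" and rep.strength == "strong"

    def test_negated_curve_strong_inverse(self, walk_trial, mean_curve_of):
        a = mean_curve_of(walk_trial, "pelvis", "rx")
        b = sg.NormalizedCurve(-a.values)
        rep = sg.coupling_test(a, b)
        assert rep.relation == "inverse" and rep.strength == "strong"

    def test_l7_translation_rotation_coupling_at_trot(self, trot_trial,
                                                      mean_curve_of):
        # craniocaudal translation of L7 is coupled to its sagittal rotation
        tx = mean_curve_of(trot_trial, "L7", "tx")
        rz = mean_curve_of(trot_trial, "L7", "rz")
        rep = sg.coupling_test(tx, rz, pair=("L7.tx", "L7.rz"))
        assert abs(rep.rho) > 0.7
        assert rep.strength == "strong"
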