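"""Phase-series analysis: size change, noise floors, pulsation detection,
harmonic decomposition, repeatability gating."""

import math

import numpy as np
import pytest
import trimesh

from aneupulse.dynamics import (
    NotEvaluable,
    PhaseSeries,
    assess_size_change,
    assess_size_change_from_summaries,
    classify_deformability,
    compute_mdc,
    detect_gvp,
    detect_swp,
    estimate_noise_sigma,
    fit_first_harmonic,
    qualify_signal,
)
from aneupulse.pipeline import vertex_areas
from aneupulse.synthetic import SignalSpec, generate_repeatability_pairs, generate_signal


def sinusoid(amplitude, n=20, level=50.0, noise_sd=0.0, seed=0):
    return generate_signal(
        SignalSpec(
            baseline_level=level, harmonic_amplitude=amplitude, noise_sd=noise_sd,
            n_phases=n, seed=seed,
        )
    ).series


class TestSizeChange:
    def test_published_enlarging_summary(self):
        # 65.05 +/- 2.41 -> 81.59 +/- 1.40: delta 16.54 clears 2*rss = 5.57
        v = assess_size_change_from_summaries(65.05, 2.41, 81.59, 1.40)
        assert v.changed and v.direction == "enlarged"
        assert v.threshold == pytest.approx(5.574, abs=0.01)

    def test_published_stable_summary(self):
        v = assess_size_change_from_summaries(31.08, 0.59, 31.01, 1.27)
        assert not v.changed and v.direction == "none"

    def test_identical_series_stable(self):
        s = sinusoid(1.0)
        v = assess_size_change(s, PhaseSeries(s.values.copy()))
        assert not v.changed
        assert v.delta == 0.0

    def test_mismatched_parameters_rejected(self):
        a = PhaseSeries(np.ones(5), parameter_name="V_sac")
        b = PhaseSeries(np.ones(5), parameter_name="S_sac")
        with pytest.raises(ValueError):
            assess_size_change(a, b)


class TestNoiseSigma:
    def test_constant_series_zero(self):
        assert estimate_noise_sigma(PhaseSeries(np.full(20, 5.0))) == 0.0

    def test_alternating_series_hand_value(self):
        # odd length -> an even number of +-1 differences, median 0
        s = PhaseSeries(np.append(np.tile([0.0, 1.0], 10), 0.0))
        # d = +-1, MAD about median 0 is 1 -> sigma = 1/(0.6745*sqrt(2))
        assert estimate_noise_sigma(s) == pytest.approx(1.0 / (0.6745 * math.sqrt(2)), abs=1e-9)
        assert estimate_noise_sigma(s, divisor="literal") == pytest.approx(
            1.0 / (0.6745 * 2.0), abs=1e-9
        )

    def test_monte_carlo_calibration(self):
        rng = np.random.default_rng(0)
        series = rng.normal(0.0, 2.0, size=(10_000, 20))
        d = np.diff(series, axis=1)
        mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
        est = mad / (0.6745 * math.sqrt(2.0))
        assert np.median(est) == pytest.approx(2.0, rel=0.10)
        # spot-check the vectorised oracle against the implementation
        assert estimate_noise_sigma(PhaseSeries(series[0])) == pytest.approx(est[0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(PhaseSeries(np.ones(4)))


class TestGvp:
    def test_noiseless_sinusoid_present(self):
        s = sinusoid(5.0)  # peak-to-peak 10 mm^3
        s = PhaseSeries(s.values + np.random.default_rng(1).normal(0, 0.05, 20))
        assert detect_gvp(s).present

    def test_constant_absent(self):
        assert not detect_gvp(PhaseSeries(np.full(20, 30.0))).present

    def test_small_amplitude_fails_resolution_floor(self):
        # peak-to-peak 2.5 mm^3 passes 3 sigma yet fails the 3 mm^3 floor
        s = sinusoid(1.25)
        s = PhaseSeries(s.values + np.random.default_rng(2).normal(0, 0.02, 20))
        r = detect_gvp(s)
        assert r.amplitude > 3.0 * r.sigma_noise
        assert r.amplitude < r.volume_floor
        assert not r.present

    def test_invariant_flag_consistency(self):
        for seed in range(20):
            s = PhaseSeries(np.random.default_rng(seed).normal(50, 1.0, 20))
            r = detect_gvp(s)
            assert r.present == (
                r.amplitude > 3.0 * r.sigma_noise and r.amplitude > r.volume_floor
            )


@pytest.fixture(scope="module")
def sphere():
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=3.0)
    return mesh, np.asarray(mesh.faces), vertex_areas(mesh), float(mesh.area)


class TestSwp:
    def _patch_amplitude(self, mesh, direction, half_angle, amp):
        v = np.asarray(mesh.vertices)
        cosang = (v / np.linalg.norm(v, axis=1, keepdims=True)) @ np.asarray(direction, float)
        out = np.zeros(len(v))
        out[cosang > math.cos(half_angle)] = amp
        return out

    def test_zero_field_none(self, sphere):
        mesh, faces, va, area = sphere
        r = detect_swp(np.zeros(len(mesh.vertices)), faces, va, area)
        assert r.classification == "none"
        assert not r.regions

    def test_single_patch_focal(self, sphere):
        mesh, faces, va, area = sphere
        # ~10% of a 113 mm^2 sphere at 0.5 mm amplitude
        amp = self._patch_amplitude(mesh, (0, 0, 1), math.acos(1 - 0.2), 0.5)
        r = detect_swp(amp, faces, va, area)
        assert r.classification == "focal"
        assert len(r.regions) == 1
        assert r.regions[0].area >= 5.0
        assert 0.05 <= r.pulsating_fraction < 0.20

    def test_two_patches_heterogeneous(self, sphere):
        mesh, faces, va, area = sphere
        amp = self._patch_amplitude(mesh, (0, 0, 1), math.acos(1 - 0.25), 0.5)
        amp += self._patch_amplitude(mesh, (0, 0, -1), math.acos(1 - 0.25), 0.4)
        r = detect_swp(amp, faces, va, area)
        assert r.classification == "heterogeneous"
        assert r.pulsating_fraction >= 0.20
        assert len(r.regions) == 2

    def test_subthreshold_amplitude_ignored(self, sphere):
        mesh, faces, va, area = sphere
        amp = np.full(len(mesh.vertices), 0.29)
        assert detect_swp(amp, faces, va, area).classification == "none"

    def test_small_region_dropped(self, sphere):
        mesh, faces, va, area = sphere
        amp = self._patch_amplitude(mesh, (0, 0, 1), 0.12, 0.6)  # ~2 mm^2
        r = detect_swp(amp, faces, va, area)
        assert r.classification == "none"
        assert not r.regions


class TestQualification:
    def test_constant_unqualified(self):
        q = qualify_signal(PhaseSeries(np.full(20, 3.0)))
        assert q.delta_x == 0.0 and not q.qualified

    def test_noiseless_sinusoid_qualifies(self):
        # a pure sinusoid leaks into the first-difference noise estimate,
        # so its SNR is large and finite; it qualifies comfortably
        q = qualify_signal(sinusoid(2.0))
        assert q.snr > 5.0
        assert q.qualified

    def test_noise_free_step_has_infinite_snr(self):
        # a signal whose inter-phase differences are mostly zero drives
        # the robust noise estimate to zero: SNR reported as +inf sentinel
        values = np.full(20, 10.0)
        values[12] = 11.0
        q = qualify_signal(PhaseSeries(values))
        assert q.sd_noise == 0.0
        assert math.isinf(q.snr)
        assert q.qualified

    def test_snr_monotone_in_amplitude(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0.0, 1.0, 20)
        snrs = []
        for amp in (0.5, 1.0, 2.0, 4.0, 8.0):
            base = sinusoid(amp).values
            snrs.append(qualify_signal(PhaseSeries(base + noise)).snr)
        assert all(b >= a for a, b in zip(snrs, snrs[1:]))


class TestFirstHarmonic:
    def test_exact_sinusoid_representation(self):
        t = np.arange(20)
        s = PhaseSeries(5.0 + 2.0 * np.sin(2 * np.pi * t / 20))
        dec = fit_first_harmonic(s)
        assert dec.mean_level == pytest.approx(5.0, abs=1e-10)
        assert dec.pulsation_amplitude == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(dec.residuals, 0.0, atol=1e-10)

    def test_second_harmonic_orthogonal(self):
        t = np.arange(20)
        dec = fit_first_harmonic(PhaseSeries(np.sin(4 * np.pi * t / 20)))
        assert dec.pulsation_amplitude == pytest.approx(0.0, abs=1e-10)

    def test_decomposition_reconstructs_input(self):
        rng = np.random.default_rng(3)
        s = PhaseSeries(rng.normal(10.0, 2.0, 20))
        dec = fit_first_harmonic(s)
        assert np.allclose(dec.fitted + dec.residuals, s.values, atol=1e-12)

    def test_monte_carlo_recovery_and_residual_sd(self):
        amps, rsds = [], []
        for seed in range(1000):
            s = generate_signal(
                SignalSpec(harmonic_amplitude=2.0, noise_sd=0.5, n_phases=20, seed=seed)
            )
            dec = fit_first_harmonic(s.series)
            amps.append(dec.pulsation_amplitude)
            rsds.append(np.std(dec.residuals, ddof=3))
        assert np.mean(amps) == pytest.approx(2.0, rel=0.05)
        assert np.mean(rsds) == pytest.approx(0.5, rel=0.10)

    def test_amplitude_monotone_in_injected_amplitude(self):
        rng = np.random.default_rng(11)
        noise = rng.normal(0.0, 0.5, 20)
        measured = []
        for amp in (0.0, 0.5, 1.0, 2.0, 4.0):
            s = PhaseSeries(sinusoid(amp).values + noise)
            measured.append(fit_first_harmonic(s).pulsation_amplitude)
        assert all(b >= a - 1e-12 for a, b in zip(measured, measured[1:]))


class TestMdc:
    def test_identical_pairs(self):
        r = compute_mdc([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert r.bias == 0.0 and r.mdc == 0.0

    def test_constant_offset(self):
        r = compute_mdc([(1.0, 2.0), (5.0, 6.0), (9.0, 10.0)])
        assert r.bias == pytest.approx(1.0)
        assert r.mdc == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_differences(self):
        pairs = generate_repeatability_pairs(10_000, 0.0, 1.0 / math.sqrt(2.0), seed=8)
        r = compute_mdc(pairs)
        assert r.mdc == pytest.approx(1.96, rel=0.03)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            compute_mdc([(1.0, 2.0)])


class TestDeformability:
    def _qualified(self, series):
        return qualify_signal(series, min_snr=0.1)

    def test_zero_residual_not_deformable(self):
        s = sinusoid(2.0)
        dec = fit_first_harmonic(s)
        assert dec.residual_mad == pytest.approx(0.0, abs=1e-10)
        assert not classify_deformability(dec, self._qualified(s), mdc=1.0)

    def test_direct_rule(self):
        s = PhaseSeries(np.tile([0.0, 6.0], 10))  # strong square wave
        dec = fit_first_harmonic(s)
        q = self._qualified(s)
        assert classify_deformability(dec, q, mdc=1.0, noise_floor=0.5)
        assert not classify_deformability(dec, q, mdc=10.0, noise_floor=0.5)

    def test_unqualified_raises_not_evaluable(self):
        s = PhaseSeries(np.full(20, 4.0))
        dec = fit_first_harmonic(s)
        with pytest.raises(NotEvaluable):
            classify_deformability(dec, qualify_signal(s), mdc=0.1)

    def test_alternating_square_component_power(self):
        # a non-harmonic (phase-alternating) square component at 3x the
        # uncertainty gate survives first-harmonic subtraction and is
        # flagged as deformability in nearly every seeded replicate
        noise_sd = 0.3
        pairs = generate_repeatability_pairs(200, 0.0, noise_sd, seed=1)
        mdc = compute_mdc(pairs).mdc
        t = np.arange(20)
        square = 3.0 * mdc * np.where(t % 2 == 0, 1.0, -1.0)
        hits = 0
        n = 500
        for seed in range(n):
            rng = np.random.default_rng(seed)
            s = PhaseSeries(50.0 + 2.0 * np.sin(2 * np.pi * t / 20) + square
                            + rng.normal(0, noise_sd, 20))
            dec = fit_first_harmonic(s)
            q = qualify_signal(s, min_snr=3.0)
            try:
                hits += classify_deformability(dec, q, mdc=mdc, noise_floor=noise_sd)
            except NotEvaluable:
                pass
        assert hits / n >= 0.95
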