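"""QC, scaling, baseline subtraction and ppm calibration."""

import numpy as np
import pytest

from nmrmet.lineshape import pseudo_voigt
from nmrmet.preprocess import (
    QCConfig,
    calibrate_ppm,
    median_reference,
    qc_spectra,
    regrid,
    scale_receiver_sensitivity,
    subtract_constant_baseline,
)
from nmrmet.simulate import (
    CohortConfig,
    SpectraConfig,
    default_ppm_grid,
    generate_cohort,
    generate_concentrations,
    render_spectra,
)
from nmrmet.types import Spectrum1D


def _spectrum(intensity, ppm=None, **kw):
    if ppm is None:
        ppm = np.linspace(9.0, 0.5, intensity.size)
    return Spectrum1D(sample_id="s", ppm=ppm, intensity=intensity, **kw)


class TestQC:
    def test_empty_input_gives_empty_table(self):
        assert qc_spectra([]).empty

    def test_water_threshold_rule(self):
        spectra = [
            _spectrum(np.zeros(32), water_intensity=w) for w in [1.0, 1.0, 1.0, 10.0]
        ]
        for i, s in enumerate(spectra):
            s.sample_id = f"s{i}"
        flags = qc_spectra(spectra, QCConfig(max_water_rel=5.0, max_shim_hz=np.inf))
        assert flags.loc["s3", "passed"] == False  # noqa: E712
        assert flags.loc["s3", "reason"] == "water"
        assert flags["passed"][:3].all()

    def test_generator_corrupted_samples_flagged(self, templates):
        cfg = CohortConfig(n_subjects=20, seed=21)
        cohort = generate_cohort(cfg)
        truth = generate_concentrations(cohort, templates, cfg)
        scfg = SpectraConfig(n_corrupted=2)
        spectra, _ = render_spectra(
            truth, templates, scfg, ppm=default_ppm_grid(6.0, 3.0, 0.001), seed=21
        )
        flags = qc_spectra(spectra, QCConfig())
        truly_bad = set(truth.sample_effects.index[truth.sample_effects.corrupted])
        assert set(flags.index[~flags.passed]) == truly_bad


class TestScaling:
    def test_identity_and_proportionality(self):
        s = _spectrum(np.ones(32), pulse_length_us=10.0)
        assert np.array_equal(
            scale_receiver_sensitivity(s, 10.0).intensity, s.intensity
        )
        assert np.allclose(
            scale_receiver_sensitivity(s, 5.0).intensity, 2.0 * s.intensity
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            scale_receiver_sensitivity(_spectrum(np.ones(32)), 0.0)

    def test_round_trip_through_simulated_sensitivity_law(self, templates, small_truth):
        """Two renders differing only in pulse length agree after scaling."""
        *_, truth = small_truth
        ppm = default_ppm_grid(6.0, 3.0, 0.001)
        base = dict(noise_sd=0.0, ppm_jitter_sd=0.0, gain_sd=0.0, baseline_sd=0.0,
                    pulse_length_sd_us=0.0)
        s1, _ = render_spectra(
            truth, templates, SpectraConfig(pulse_length_mean_us=10.0, **base),
            ppm=ppm, seed=0,
        )
        s2, _ = render_spectra(
            truth, templates, SpectraConfig(pulse_length_mean_us=14.0, **base),
            ppm=ppm, seed=0,
        )
        a = scale_receiver_sensitivity(s1[0], 10.0)
        b = scale_receiver_sensitivity(s2[0], 10.0)
        big = np.abs(a.intensity) > 1e-6
        assert np.max(np.abs(a.intensity[big] / b.intensity[big] - 1.0)) < 1e-6


class TestBaseline:
    def test_zero_baseline_unchanged(self):
        s = _spectrum(np.zeros(100))
        out, c = subtract_constant_baseline(s, [(8.0, 8.5)])
        assert c == 0.0
        assert np.array_equal(out.intensity, s.intensity)

    def test_additive_constant_recovered_exactly(self):
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(0, 1, 200))
        base[:50] = 0.0  # signal-free high-field end
        s = _spectrum(base + 3.7)
        out, c = subtract_constant_baseline(s, [(s.ppm[0], s.ppm[40])])
        assert c == pytest.approx(3.7)
        assert np.allclose(out.intensity, base)

    def test_estimated_constant_within_standard_error(self, templates, small_truth):
        # pure-Gaussian low-field metabolites, so the 8.7-9.0 window is
        # truly signal-free (accumulated Lorentzian tails would bias it)
        cfg, cohort, _ = small_truth
        from nmrmet.simulate import MetaboliteTemplate, generate_concentrations

        low_field = [
            MetaboliteTemplate(
                name=t.name,
                peaks=[(c, a, w, 1.0) for c, a, w, _ in t.peaks],
                base_concentration=t.base_concentration,
                log_sd=t.log_sd,
            )
            for t in templates
            if all(p[0] < 6.0 for p in t.peaks)
        ]
        truth = generate_concentrations(cohort, low_field, cfg)
        scfg = SpectraConfig(ppm_jitter_sd=0.0, gain_sd=0.0, water_amplitude=0.0)
        ppm = default_ppm_grid()
        spectra, _ = render_spectra(truth, low_field, scfg, ppm=ppm, seed=2)
        window = [(8.70, 9.00)]
        n_pts = int(0.3 / 0.001)
        for s in spectra[:3]:
            _, c = subtract_constant_baseline(s, window)
            true_c = truth.sample_effects.loc[s.sample_id, "baseline"]
            assert abs(c - true_c) < 3 * scfg.noise_sd / np.sqrt(n_pts) + 1e-4

    def test_empty_window_set_rejected(self):
        with pytest.raises(ValueError):
            subtract_constant_baseline(_spectrum(np.zeros(32)), [])

    def test_scaling_and_baseline_commute(self):
        rng = np.random.default_rng(3)
        s = _spectrum(rng.normal(2.0, 1.0, 300), pulse_length_us=14.0)
        w = [(s.ppm[0], s.ppm[60])]
        a = subtract_constant_baseline(scale_receiver_sensitivity(s, 7.0), w)[0]
        b = scale_receiver_sensitivity(subtract_constant_baseline(s, w)[0], 7.0)
        assert np.allclose(a.intensity, b.intensity, atol=1e-12)


def _glucose_like(apex_ppm, ppm=None):
    if ppm is None:
        ppm = default_ppm_grid(5.6, 4.9, 0.001)
    y = pseudo_voigt(ppm, apex_ppm, 10.0, 0.012, 0.6)
    return Spectrum1D(sample_id="g", ppm=ppm, intensity=y)


class TestCalibration:
    def test_off_target_apex_lands_on_target(self):
        s = _glucose_like(5.247)
        out, shift = calibrate_ppm(s, 5.23, 0.05)
        apex = out.ppm[np.argmax(out.intensity)]
        assert abs(apex - 5.23) <= 0.001  # within one grid step
        assert shift == pytest.approx(-0.017, abs=2e-4)

    def test_idempotent_when_on_target(self):
        s = _glucose_like(5.23)
        out, shift = calibrate_ppm(s, 5.23, 0.05)
        assert abs(shift) < 1e-9
        out2, shift2 = calibrate_ppm(out, 5.23, 0.05)
        assert abs(shift2) < 1e-9

    def test_injected_offset_recovered_from_generator(self, templates):
        cfg = CohortConfig(n_subjects=30, seed=22)
        cohort = generate_cohort(cfg)
        truth = generate_concentrations(cohort, templates, cfg)
        scfg = SpectraConfig(ppm_jitter_sd=0.004)
        spectra, _ = render_spectra(truth, templates, scfg, ppm=default_ppm_grid(), seed=22)
        anchor_offset = 5.23 - 5.22921  # reference shift of the rendered anomeric peak
        for s in spectra[:10]:
            _, shift = calibrate_ppm(s)
            injected = truth.sample_effects.loc[s.sample_id, "ppm_shift"]
            assert shift == pytest.approx(-injected + anchor_offset, abs=5e-4)

    def test_missing_peak_raises(self):
        ppm = default_ppm_grid(5.6, 4.9, 0.001)
        flat = Spectrum1D(sample_id="f", ppm=ppm, intensity=np.zeros(ppm.size))
        with pytest.raises(ValueError, match="calibration peak not found"):
            calibrate_ppm(flat, 5.23, 0.05)


def test_regrid_preserves_peak_shape():
    ppm = default_ppm_grid(5.6, 4.9, 0.001)
    s = _glucose_like(5.23, ppm)
    shifted = s.with_ppm(ppm + 0.0004)
    back = regrid(shifted, ppm)
    # cubic regridding keeps apex attenuation well under 1% (linear
    # interpolation loses several percent at this sampling density)
    assert np.max(back.intensity) > 0.99 * np.max(s.intensity)
    linear = np.interp(ppm[::-1], shifted.ppm[::-1], shifted.intensity[::-1])[::-1]
    assert np.max(back.intensity) > np.max(linear)


def test_median_reference_is_pointwise_median():
    specs = [_spectrum(np.full(32, v)) for v in (1.0, 2.0, 10.0)]
    ref = median_reference(specs)
    assert np.allclose(ref.intensity, 2.0)
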