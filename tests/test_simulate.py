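"""Synthetic cohort, concentration and spectrum generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrmet.lineshape import amplitude_for_area, pseudo_voigt
from nmrmet.postprocess import intraclass_correlation
from nmrmet.simulate import (
    CohortConfig,
    MetaboliteTemplate,
    SpectraConfig,
    default_ppm_grid,
    generate_cohort,
    generate_concentrations,
    measured_signal_table,
    render_spectra,
    signal_catalog,
)
from nmrmet.types import validate_cohort


class TestCohort:
    def test_catalog_matches_study_structure(self, templates, catalog):
        assert len(templates) == 49
        assert len(catalog) == 100
        assert catalog["lifetime_informative"].sum() == 6
        assert catalog["active_informative"].sum() == 22
        # every metabolite's relative areas sum to one
        sums = catalog.groupby("metabolite")["relative_area"].sum()
        assert np.allclose(sums, 1.0)

    def test_lifetime_prevalence_within_binomial_band(self):
        cfg = CohortConfig(n_subjects=1650, prevalence_lifetime=0.175, seed=1)
        cohort = generate_cohort(cfg)
        n, p = 1650, 0.175
        sd = np.sqrt(n * p * (1 - p))
        assert abs(cohort["lifetime"].sum() - n * p) < 2.58 * sd  # 99% band

    def test_active_fraction_of_lifetime(self):
        cfg = CohortConfig(n_subjects=1650, seed=2)
        cohort = generate_cohort(cfg)
        n_l = cohort["lifetime"].sum()
        frac = cohort["active"].sum() / n_l
        sd = np.sqrt(0.52 * 0.48 / n_l)
        assert abs(frac - 0.52) < 3 * sd
        validate_cohort(cohort)  # active nested in lifetime

    def test_null_covariate_effects_leave_groups_exchangeable(self):
        """With all effects zero, case/control covariate distributions
        should be indistinguishable in the vast majority of replicates."""
        nonsig = 0
        reps = 30
        for seed in range(reps):
            cfg = CohortConfig(
                n_subjects=400,
                covariate_effect_sizes={"sex": 0.0, "age": 0.0, "bmi": 0.0, "smoking": 0.0},
                seed=seed,
            )
            c = generate_cohort(cfg)
            cases, ctrl = c[c.lifetime == 1], c[c.lifetime == 0]
            p_age = stats.ttest_ind(cases.age, ctrl.age).pvalue
            p_sex = stats.chi2_contingency(
                pd.crosstab(c.lifetime, c.sex), correction=True
            )[1]
            if p_age > 0.05 and p_sex > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * reps * 0.9  # >= ~81% jointly non-significant

    def test_configured_covariate_effects_show_up(self):
        cohort = generate_cohort(CohortConfig(n_subjects=1650, seed=3))
        cases, ctrl = cohort[cohort.lifetime == 1], cohort[cohort.lifetime == 0]
        assert cases.sex.mean() > ctrl.sex.mean() + 0.1  # female excess
        assert cases.smoking.mean() > ctrl.smoking.mean()
        assert cases.age.mean() < ctrl.age.mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(prevalence_lifetime=1.2)
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CohortConfig(kinship_variance_fraction=1.0)
        with pytest.raises(ValueError):
            CohortConfig(covariate_effect_sizes={"sex": np.nan})


class TestConcentrations:
    def test_null_case_effect_means_equal(self, templates):
        cfg = CohortConfig(n_subjects=800, seed=5)
        cohort = generate_cohort(cfg)
        nulls = [
            MetaboliteTemplate(
                name=t.name,
                peaks=t.peaks,
                base_concentration=t.base_concentration,
                log_sd=t.log_sd,
            )
            for t in templates[:5]
        ]
        truth = generate_concentrations(cohort, nulls, cfg)
        logc = np.log(truth.concentrations)
        y = cohort.set_index("subject_id")["lifetime"]
        for m in logc.columns:
            p = stats.ttest_ind(logc.loc[y == 1, m], logc.loc[y == 0, m]).pvalue
            assert p > 1e-3

    def test_kinship_icc_recovered(self, templates):
        cfg = CohortConfig(n_subjects=1600, kinship_variance_fraction=0.3, seed=6)
        cohort = generate_cohort(cfg)
        truth = generate_concentrations(cohort, templates[:3], cfg)
        iccs = [
            intraclass_correlation(
                np.log(truth.concentrations[t.name]), cohort["family_id"].to_numpy()
            )
            for t in templates[:3]
        ]
        assert abs(np.mean(iccs) - 0.3) < 0.1

    def test_determinism_bit_identical(self, templates):
        cfg = CohortConfig(n_subjects=50, seed=7)
        a = generate_concentrations(generate_cohort(cfg), templates, cfg)
        b = generate_concentrations(generate_cohort(cfg), templates, cfg)
        pd.testing.assert_frame_equal(a.concentrations, b.concentrations)

    def test_empty_templates_rejected(self):
        cfg = CohortConfig(n_subjects=10, seed=0)
        with pytest.raises(ValueError):
            generate_concentrations(generate_cohort(cfg), [], cfg)


def _noiseless_config():
    return SpectraConfig(
        noise_sd=0.0,
        ppm_jitter_sd=0.0,
        gain_sd=0.0,
        baseline_sd=0.0,
        water_amplitude=0.0,
        pulse_length_sd_us=0.0,
    )


class TestRenderSpectra:
    def test_noiseless_render_matches_closed_form(self, templates, small_truth):
        cfg, cohort, truth = small_truth
        ppm = default_ppm_grid()
        spectra, projections = render_spectra(
            truth, templates, _noiseless_config(), ppm=ppm, seed=0
        )
        s = spectra[0]
        areas = truth.true_signal_areas().loc[s.sample_id]
        expected = np.zeros(ppm.size)
        for sid, row in truth.catalog.iterrows():
            amp = amplitude_for_area(areas[sid], row.width_ppm, row.eta)
            expected += pseudo_voigt(ppm, row.shift_ppm, amp, row.width_ppm, row.eta)
        assert np.allclose(s.intensity, expected, rtol=1e-10, atol=1e-12)

    def test_doubling_concentration_doubles_peaks(self, templates, small_truth):
        cfg, cohort, truth = small_truth
        ppm = default_ppm_grid(6.0, 3.0, 0.001)
        spectra1, _ = render_spectra(truth, templates, _noiseless_config(), ppm=ppm, seed=0)
        truth2 = generate_concentrations(cohort, templates, cfg)
        truth2.concentrations = truth.concentrations * 2.0
        spectra2, _ = render_spectra(truth2, templates, _noiseless_config(), ppm=ppm, seed=0)
        assert np.allclose(spectra2[0].intensity, 2.0 * spectra1[0].intensity)

    def test_jitter_sd_recovered_from_apex_positions(self, templates):
        cfg = CohortConfig(n_subjects=100, seed=8)
        cohort = generate_cohort(cfg)
        truth = generate_concentrations(cohort, templates, cfg)
        scfg = _noiseless_config()
        scfg.ppm_jitter_sd = 0.005
        ppm = default_ppm_grid(5.5, 5.0, 0.001)  # isolated glucose anomeric
        spectra, _ = render_spectra(truth, templates, scfg, ppm=ppm, seed=8)
        apexes = [s.ppm[np.argmax(s.intensity)] for s in spectra]
        sd = np.std(apexes)
        assert 0.0035 < sd < 0.0065
        assert np.allclose(
            apexes - truth.sample_effects["ppm_shift"].to_numpy() - 5.22921,
            0.0,
            atol=2e-3,
        )

    def test_nonmonotone_grid_rejected(self, templates, small_truth):
        *_, truth = small_truth
        with pytest.raises(ValueError):
            render_spectra(truth, templates, ppm=np.linspace(0.5, 9.0, 100))

    def test_render_determinism(self, templates, small_truth):
        *_, truth = small_truth
        ppm = default_ppm_grid(6.0, 5.0, 0.001)
        s1, p1 = render_spectra(truth, templates, ppm=ppm, seed=9)
        s2, p2 = render_spectra(truth, templates, ppm=ppm, seed=9)
        assert np.array_equal(s1[0].intensity, s2[0].intensity)
        assert np.array_equal(p1[-1].intensity, p2[-1].intensity)


def test_measured_signal_table_tracks_truth(templates):
    cfg = CohortConfig(n_subjects=300, seed=10)
    cohort = generate_cohort(cfg)
    truth = generate_concentrations(cohort, templates, cfg)
    table = measured_signal_table(truth, noise_cv=0.05, seed=10)
    ta = truth.true_signal_areas()
    rel = np.log(table.values / ta)
    assert abs(rel.values.std() - 0.05) < 0.01
    # same-metabolite signal pairs stay strongly correlated, cross pairs less
    cat = truth.catalog
    same, cross = [], []
    corr = np.log(table.values).corr()
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1 :]:
            r = corr.loc[a, b]
            (same if cat.loc[a, "metabolite"] == cat.loc[b, "metabolite"] else cross).append(r)
    assert min(same) >= 0.8
    assert np.mean(cross) < np.mean(same)
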