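"""Synthetic cohort generator: distribution calibration, missingness
mechanisms, derived analytes, determinism, round-trips."""

import numpy as np
import pytest
from scipy import stats

from labsieve.records import build_matrix, label_cases, parse_records
from labsieve.synthetic import (
    AnalyteSpec,
    GeneratorConfig,
    apply_missingness,
    ckdepi_egfr,
    default_panel,
    generate_cohort,
    generate_dataset,
    write_fixture,
)


class TestCkdEpi:
    def test_power_terms_cancel_for_scr_equal_kappa_age_zero(self):
        assert ckdepi_egfr(0.7, 0.0, female=True) == pytest.approx(141 * 1.018)

    def test_male_direct_evaluation(self):
        assert ckdepi_egfr(0.9, 60.0, female=False) == pytest.approx(141 * 0.993**60)

    def test_reference_female_case_by_formula(self):
        # female, 53 y, Scr 0.8 mg/dL: the formula itself gives ~84.2
        assert ckdepi_egfr(0.8, 53.0, female=True) == pytest.approx(84.17, abs=0.01)

    def test_black_factor(self):
        ratio = ckdepi_egfr(0.8, 53.0, True, black=True) / ckdepi_egfr(0.8, 53.0, True)
        assert ratio == pytest.approx(1.159)

    def test_matches_direct_evaluation_on_grid(self):
        scr = np.array([0.4, 0.7, 0.9, 1.3, 2.5])
        for age in (20.0, 53.0, 80.0):
            for female in (True, False):
                kappa, a = (0.7, -0.329) if female else (0.9, -0.411)
                direct = (
                    141.0
                    * np.minimum(scr / kappa, 1) ** a
                    * np.maximum(scr / kappa, 1) ** -1.209
                    * 0.993**age
                    * (1.018 if female else 1.0)
                )
                np.testing.assert_allclose(
                    ckdepi_egfr(scr, age, female), direct, atol=1e-10
                )

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            ckdepi_egfr(0.0, 50.0, True)


class TestGenerateCohort:
    def test_determinism_under_seed(self):
        a = generate_cohort(GeneratorConfig(seed=5, n_cases=200))
        b = generate_cohort(GeneratorConfig(seed=5, n_cases=200))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1].labels == b[1].labels

    def test_median_and_iqr_approach_targets(self):
        matrix, _, _ = generate_cohort(GeneratorConfig(seed=0, n_cases=5000))
        for name in ("troponin_t", "potassium", "urea"):
            spec = next(s for s in default_panel() if s.name == name)
            col = matrix.column(name)
            assert np.median(col) == pytest.approx(spec.median, rel=0.10)
            iqr = np.subtract(*np.percentile(col, [75, 25]))
            assert iqr == pytest.approx(spec.iqr, rel=0.15)

    def test_dominant_analyte_higher_in_cases_than_controls(self):
        matrix, labels, _ = generate_cohort(GeneratorConfig(seed=1, n_cases=5000))
        y = labels.vector(matrix.cases)
        tnt = matrix.column("troponin_t")
        assert np.median(tnt[y == 1]) > 2 * np.median(tnt[y == 0])

    def test_prevalence_calibration(self):
        matrix, labels, _ = generate_cohort(GeneratorConfig(seed=2, n_cases=8000))
        y = labels.vector(matrix.cases)
        assert y.mean() == pytest.approx(0.1, abs=0.02)

    def test_null_panel_labels_independent_of_analytes(self):
        # with all coefficients zero, analyte/label association should be
        # at chance level across seeds
        specs = [
            AnalyteSpec("a", "normal", 10.0, 2.0, coverage_target=1.0, loading=0.0),
            AnalyteSpec("b", "lognormal", 5.0, 3.0, coverage_target=1.0, loading=0.0),
        ]
        rejections = 0
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, n_cases=400, analyte_specs=specs)
            matrix, labels, _ = generate_cohort(cfg)
            y = labels.vector(matrix.cases)
            for j in range(2):
                hi = matrix.values[:, j] > np.median(matrix.values[:, j])
                table = np.array(
                    [[np.sum(hi & (y == 1)), np.sum(hi & (y == 0))],
                     [np.sum(~hi & (y == 1)), np.sum(~hi & (y == 0))]]
                )
                if stats.chi2_contingency(table)[1] < 0.01:
                    rejections += 1
        assert rejections <= 2  # ≥18/20 seeds × both analytes non-significant

    def test_derived_egfr_recomputable_bitwise(self):
        matrix, _, truth = generate_cohort(GeneratorConfig(seed=3, n_cases=300))
        crea = matrix.column("creatinine")
        expected = ckdepi_egfr(crea / 88.4, truth.age, truth.female)
        np.testing.assert_array_equal(matrix.column("egfr"), expected)

    def test_unreachable_prevalence_errors(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, n_cases=100, prevalence=1.5)


class TestApplyMissingness:
    def test_full_coverage_untouched(self):
        matrix, _, truth = generate_cohort(GeneratorConfig(seed=4, n_cases=500))
        specs = [AnalyteSpec(a, "normal", 1.0, 0.5, coverage_target=1.0)
                 for a in matrix.analytes]
        masked = apply_missingness(matrix, specs, seed=0)
        assert masked.observed_mask.all()

    def test_mcar_rate_within_binomial_tolerance(self):
        n = 10000
        spec = AnalyteSpec("a", "normal", 10.0, 2.0, coverage_target=0.7)
        cfg = GeneratorConfig(seed=5, n_cases=n, analyte_specs=[spec])
        matrix, _, _ = generate_cohort(cfg)
        masked = apply_missingness(matrix, [spec], seed=6)
        observed = masked.observed_mask.mean()
        assert 0.68 <= observed <= 0.72

    def test_troponin_analog_always_fully_observed(self):
        for seed in (0, 1, 2):
            sparse, _, _ = generate_dataset(GeneratorConfig(seed=seed, n_cases=300))
            j = sparse.analytes.index("troponin_t")
            assert sparse.observed_mask[:, j].all()

    def test_mar_shifts_severity_of_observed_cells_mcar_does_not(self):
        n = 10000
        for mech, expect_shift in (("MAR_on_severity", True), ("MCAR", False)):
            specs = [
                AnalyteSpec("tnt", "lognormal", 25.0, 78.0, true_coefficient=2.0,
                            coverage_target=1.0, loading=0.5),
                AnalyteSpec("x", "normal", 10.0, 2.0, coverage_target=0.5,
                            missingness=mech),
            ]
            cfg = GeneratorConfig(seed=7, n_cases=n, analyte_specs=specs)
            matrix, _, truth = generate_cohort(cfg)
            masked = apply_missingness(matrix, specs, seed=8,
                                       severity=truth.linear_predictor)
            obs = masked.observed_mask[:, masked.analytes.index("x")]
            _, pval = stats.ks_2samp(truth.linear_predictor[obs],
                                     truth.linear_predictor[~obs])
            if expect_shift:
                assert pval < 1e-6
            else:
                assert pval > 0.01

    def test_mar_needs_severity(self):
        spec = AnalyteSpec("a", "normal", 10.0, 2.0, coverage_target=0.5,
                           missingness="MAR_on_severity")
        matrix, _, _ = generate_cohort(
            GeneratorConfig(seed=9, n_cases=100, analyte_specs=[spec])
        )
        with pytest.raises(ValueError, match="severity"):
            apply_missingness(matrix, [spec], seed=0)


def test_fixture_round_trip_through_records_io(tmp_path):
    cfg = GeneratorConfig(seed=10, n_cases=120)
    sparse, labels, truth = generate_dataset(cfg)
    paths = write_fixture(tmp_path, sparse, truth)
    recs = parse_records(paths["records"])
    rebuilt = build_matrix(recs)
    rebuilt = rebuilt.select_analytes(sparse.analytes)
    cases_order = [rebuilt.cases.index(c) for c in sparse.cases]
    np.testing.assert_array_equal(
        rebuilt.observed_mask[cases_order], sparse.observed_mask
    )
    np.testing.assert_array_equal(
        rebuilt.values[cases_order][sparse.observed_mask],
        sparse.values[sparse.observed_mask],
    )
    from labsieve.records import read_diagnoses

    relabeled = label_cases(read_diagnoses(paths["diagnoses"]))
    assert relabeled.labels == labels.labels
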