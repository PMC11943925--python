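import numpy as np
import pytest

from uromet.io import ValidationError
from uromet.preprocess import integrate_buckets, normalize_total_intensity
from uromet.synthetic import (
    SyntheticDesign,
    build_scheme,
    estimate_power,
    estimate_type1_error,
    generate_cohort,
    generate_spectrum,
    load_metabolite_library,
)


def null_design(seed=0, **kw):
    return SyntheticDesign(
        effect_trajectory={1: 1.0, 3: 1.0, 5: 1.0, 7: 1.0}, seed=seed, **kw
    )


class TestLibraryAndScheme:
    def test_default_library_loads(self):
        lib = load_metabolite_library()
        assert len(lib) >= 25
        names = [m.name for m in lib]
        assert len(set(names)) == len(names)
        assert sum(m.affected for m in lib) == 8

    def test_scheme_has_requested_bucket_count(self, default_design):
        scheme, annotation = build_scheme(default_design)
        assert len(scheme) == 114
        # every metabolite line got an annotated bucket
        n_lines = sum(len(m.lines) for m in default_design.metabolites)
        assert len(annotation) == n_lines

    def test_annotated_buckets_sit_on_lines(self, default_design):
        scheme, annotation = build_scheme(default_design)
        centers = {b.bucket_id: b.center for b in scheme.buckets}
        positions = {
            m.name: [ppm for ppm, _ in m.lines]
            for m in default_design.metabolites
        }
        for bid, met in annotation.items():
            assert any(abs(centers[bid] - p) < 1e-9 for p in positions[met])

    def test_design_validation(self):
        with pytest.raises(ValidationError, match="group sizes"):
            SyntheticDesign(n_control=2)
        with pytest.raises(ValidationError, match="trajectory"):
            SyntheticDesign(effect_trajectory={1: 1.2})
        with pytest.raises(ValidationError, match="positive"):
            SyntheticDesign(effect_trajectory={1: 1.0, 3: -2.0, 5: 1.0, 7: 1.0})


class TestGenerateSpectrum:
    def test_zero_concentrations_give_zero_spectrum(self, default_design):
        spec = generate_spectrum({}, default_design)
        assert np.all(spec.intensity == 0.0)

    def test_bucket_integral_linear_in_concentration(self, default_design):
        scheme, annotation = build_scheme(default_design)
        one = generate_spectrum({"acetate": 1.0}, default_design)
        two = generate_spectrum({"acetate": 2.0}, default_design)
        v1 = integrate_buckets(one, scheme)
        v2 = integrate_buckets(two, scheme)
        bid = next(b for b, m in annotation.items() if m == "acetate")
        j = scheme.bucket_ids.index(bid)
        assert v1[j] > 0
        assert v2[j] == pytest.approx(2.0 * v1[j], rel=1e-9)

    def test_deterministic_given_seed(self, default_design):
        a = generate_spectrum({"lactate": 1.0}, default_design,
                              rng=np.random.default_rng(5))
        b = generate_spectrum({"lactate": 1.0}, default_design,
                              rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_coarse_grid_rejected(self):
        design = SyntheticDesign(n_grid=1024)
        with pytest.raises(ValidationError, match="coarse"):
            generate_spectrum({"lactate": 1.0}, design)


class TestGenerateCohort:
    def test_master_seed_determines_everything(self):
        t1, truth1 = generate_cohort(SyntheticDesign(seed=3))
        t2, truth2 = generate_cohort(SyntheticDesign(seed=3))
        for week in t1:
            np.testing.assert_array_equal(t1[week].values, t2[week].values)
        assert truth1.concentrations.equals(truth2.concentrations)

    def test_different_seed_differs(self):
        t1, _ = generate_cohort(SyntheticDesign(seed=3))
        t2, _ = generate_cohort(SyntheticDesign(seed=4))
        assert not np.array_equal(t1[1].values, t2[1].values)

    def test_truth_bucket_ids_follow_affected_lines(self, default_design):
        _, truth = generate_cohort(default_design)
        affected = set(truth.affected_metabolites)
        for bid in truth.affected_bucket_ids:
            assert truth.annotation[bid] in affected
        # and no affected line bucket is missing
        expected = {b for b, m in truth.annotation.items() if m in affected}
        assert set(truth.affected_bucket_ids) == expected

    def test_tables_carry_study_conditions(self, default_design):
        tables, _ = generate_cohort(default_design)
        assert sorted(tables) == [1, 3, 5, 7]
        table = tables[3]
        assert table.n_buckets == 114
        assert table.group_mask("control").sum() == 15
        assert table.group_mask("study").sum() == 15

    def test_bucket_values_track_true_concentrations(self):
        # zero noise/jitter: annotated bucket integral is linear in the
        # sample's true concentration (R^2 > 0.999)
        design = SyntheticDesign(seed=9, noise_sd=0.0, shift_jitter_sd=0.0)
        tables, truth = generate_cohort(design)
        table = tables[1]
        conc = truth.concentrations
        week1 = conc[conc["week"] == 1].set_index("sample_id")
        scheme, annotation = build_scheme(design)
        bid = next(b for b, m in annotation.items() if m == "succinate")
        j = table.bucket_ids.index(bid)
        x = week1.loc[table.sample_ids, "succinate"].to_numpy(dtype=float)
        y = table.values[:, j]
        r = np.corrcoef(x, y)[0, 1]
        assert r**2 > 0.999

    def test_minimal_design_runs_end_to_end(self):
        from uromet.pipeline import AnalysisConfig, run_timepoint

        design = SyntheticDesign(n_control=3, n_study=3, seed=2)
        tables, truth = generate_cohort(design)
        res = run_timepoint(
            tables[3],
            config=AnalysisConfig(n_folds=3, n_components=2),
            annotation=truth.annotation,
        )
        assert res.week == 3
        assert res.comparison.n_buckets_tested == 114


class TestCalibration:
    def test_type1_error_requires_null_design(self, default_design):
        with pytest.raises(ValidationError, match="null design"):
            estimate_type1_error(default_design, 10)

    def test_zero_reps_is_error(self):
        with pytest.raises(ValidationError, match="n_reps"):
            estimate_type1_error(null_design(), 0)

    def test_null_familywise_rate_is_controlled(self):
        rate, se = estimate_type1_error(null_design(seed=21), 150)
        assert rate <= 0.05 + 3 * max(se, np.sqrt(0.05 * 0.95 / 150))

    def test_power_requires_affected_metabolites(self):
        lib = [m for m in load_metabolite_library()]
        unaffected = [
            type(m)(m.name, m.lines, m.baseline_log_mean, m.baseline_log_sd,
                    False)
            for m in lib
        ]
        design = SyntheticDesign(metabolites=unaffected, seed=1)
        with pytest.raises(ValidationError, match="affected"):
            estimate_power(design, 5)

    def test_power_monotone_in_fold(self):
        rates = []
        for fold in (1.0, 1.5, 2.0, 3.0):
            design = SyntheticDesign(
                effect_trajectory={1: fold, 3: fold, 5: fold, 7: fold},
                seed=31,
            )
            rates.append(estimate_power(design, 60, week=3).mean())
        # non-decreasing within Monte-Carlo slack
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 0.05
        assert rates[0] <= 0.1      # null limit: ~Bonferroni false-positive rate
        assert rates[-1] >= 0.95    # strong-effect limit
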