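import numpy as np
import pytest

from exprpatterns import (
    SyntheticSpec,
    ValidationError,
    filter_probesets,
    generate_study,
    mask_outliers,
    standardize_by_cohort,
)

from conftest import make_study


class TestFilterProbesets:
    def _study(self, present_counts=(6, 5, 6), grades=("A", "A", "A"),
               symbols=("X", "Y", "Z")):
        n_samples = 6
        present = np.zeros((3, n_samples), dtype=bool)
        for i, c in enumerate(present_counts):
            present[i, :c] = True
        rng = np.random.default_rng(0)
        return make_study(
            rng.normal(size=(3, n_samples)), ["a"] * 3 + ["b"] * 3,
            present=present, symbols=list(symbols), grades=list(grades),
        )

    def test_presence_boundary_five_calls_removed(self):
        study = self._study(present_counts=(6, 5, 6))
        filtered, report = filter_probesets(study, min_present=6)
        assert list(filtered.genes["symbol"]) == ["X", "Z"]
        assert report.n_presence_pass == 2

    def test_gene_without_symbol_removed(self):
        study = self._study(symbols=("X", "", "Z"))
        study.genes.loc["p1", "symbol"] = None
        filtered, report = filter_probesets(study, min_present=1)
        assert "Y" not in set(filtered.genes["symbol"])
        assert report.n_symbol_pass == 2

    def test_non_a_grade_removed(self):
        study = self._study(grades=("A", "B", "A"))
        filtered, report = filter_probesets(study, min_present=1)
        assert report.n_grade_pass == 2
        assert list(filtered.genes["symbol"]) == ["X", "Z"]

    def test_identity_when_everything_passes(self):
        study = self._study(present_counts=(6, 6, 6))
        filtered, report = filter_probesets(study, min_present=6)
        assert filtered.n_genes == 3
        assert report.n_input == report.n_presence_pass == 3

    def test_idempotent(self):
        study = self._study(present_counts=(6, 5, 6))
        once, _ = filter_probesets(study, min_present=6)
        twice, report = filter_probesets(once, min_present=6)
        assert list(twice.probe_ids) == list(once.probe_ids)
        assert report.n_input == report.n_presence_pass == once.n_genes

    def test_duplicate_symbol_keeps_most_present_probe(self):
        study = self._study(present_counts=(4, 6, 6), symbols=("X", "X", "Z"))
        filtered, report = filter_probesets(study, min_present=1)
        assert report.n_symbol_pass == 2
        assert "p1" in filtered.probe_ids  # the X probe with 6 presence calls
        assert "p0" not in filtered.probe_ids

    def test_min_present_above_sample_count_rejected(self):
        with pytest.raises(ValidationError, match="min_present"):
            filter_probesets(self._study(), min_present=7)


class TestMaskOutliers:
    def test_borderline_value_not_masked(self):
        # group (0,0,0,10): mean 2.5, sample SD 5 -> |10-2.5| = 7.5 <= 10
        study = make_study([[0, 0, 0, 10]], ["g"] * 4)
        out = mask_outliers(study, k_sd=2)
        assert not out.mask.any()

    def test_extreme_value_masked(self):
        # group (0,0,0,0,0,10): mean 1.667, sample SD 4.082 -> 8.33 > 8.16
        study = make_study([[0, 0, 0, 0, 0, 10]], ["g"] * 6)
        out = mask_outliers(study, k_sd=2)
        assert out.mask[0, 5]
        assert out.mask.sum() == 1

    def test_constant_group_masks_nothing(self):
        study = make_study([[3.0, 3.0, 3.0, 3.0]], ["g"] * 4)
        out = mask_outliers(study, k_sd=2)
        assert not out.mask.any()

    def test_single_perturbed_cell_masks_at_most_one_per_group(self):
        rng = np.random.default_rng(21)
        signal = rng.normal(size=(40, 12))
        signal[:, 3] += 50  # one wild sample within group a
        study = make_study(signal, ["a"] * 6 + ["b"] * 6)
        out = mask_outliers(study, k_sd=2)
        a_cols = out.group_columns()["a"]
        assert (out.mask[:, a_cols].sum(axis=1) <= 1).all()
        assert out.mask[:, 3].all()

    def test_group_left_below_two_values_flagged(self):
        signal = [[0.0, 0.0, 0.0, 0.0, np.nan, np.nan, 5.0]]
        study = make_study(signal, ["a"] * 4 + ["b"] * 3)
        out = mask_outliers(study, k_sd=2)
        assert "p0" in out.flags.get("low_n", set())


class TestStandardizeByCohort:
    def test_unit_moments_per_gene_and_cohort(self):
        rng = np.random.default_rng(5)
        study = make_study(rng.normal(size=(10, 8)), ["a"] * 4 + ["b"] * 4,
                           cohorts=["1"] * 4 + ["2"] * 4)
        out = standardize_by_cohort(study)
        for cols in out.cohort_columns().values():
            block = out.values()[:, cols]
            np.testing.assert_allclose(np.nanmean(block, axis=1), 0, atol=1e-12)
            np.testing.assert_allclose(np.nanstd(block, axis=1, ddof=1), 1,
                                       atol=1e-12)

    def test_additive_cohort_offset_removed_contrasts_preserved(self):
        spec = SyntheticSpec(
            n_genes=300,
            frac_per_template={"sustained": 0.3},
            effect_size=2.0,
            cohort_offset=10.0,
            seed=17,
        )
        study, truth = generate_study(spec)
        out = standardize_by_cohort(study)
        c = out.cohort_columns()
        X = out.values()
        # offset eliminated: per-gene cohort means now agree
        gap = np.nanmean(X[:, c["1"]], axis=1) - np.nanmean(X[:, c["2"]], axis=1)
        np.testing.assert_allclose(gap, 0, atol=1e-12)
        # group contrast of planted genes survives standardization
        cols = out.group_columns()
        planted = (truth["status"] == "planted").to_numpy()
        up = planted & (truth["direction"] == "up").to_numpy()
        contrast = (X[np.ix_(up, cols["24SD"])].mean()
                    - X[np.ix_(up, cols["HC"])].mean())
        assert contrast > 0.5

    def test_single_cohort_is_plain_z_score(self):
        rng = np.random.default_rng(6)
        signal = rng.normal(size=(5, 6))
        study = make_study(signal, ["a"] * 3 + ["b"] * 3)
        out = standardize_by_cohort(study)
        expected = (signal - signal.mean(axis=1, keepdims=True)) / signal.std(
            axis=1, keepdims=True, ddof=1
        )
        np.testing.assert_allclose(out.values(), expected)

    def test_zero_sd_gene_flagged_and_masked(self):
        study = make_study(
            [[1.0, 1.0, 1.0, 2.0, 3.0, 4.0]],
            ["a"] * 3 + ["b"] * 3,
            cohorts=["1"] * 3 + ["2"] * 3,
        )
        out = standardize_by_cohort(study)
        assert "p0" in out.flags.get("zero_sd", set())
        assert out.mask[0, :3].all()
        assert not out.mask[0, 3:].any()

    def test_cohort_with_one_sample_rejected(self):
        study = make_study([[1.0, 2.0, 3.0]], ["a"] * 3, cohorts=["1", "1", "2"])
        with pytest.raises(ValidationError, match="cohort"):
            standardize_by_cohort(study)
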