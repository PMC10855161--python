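"""Filtering, ANOVA preselection, PCA diagnostic and [0,1] scaling."""

import numpy as np
import pytest

from trustomics import preprocess, simdata
from trustomics.simdata import OmicsMatrix, SimSpec


def make_matrix(values, name="mirna"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(values=values,
                       subject_ids=[f"s{i}" for i in range(values.shape[0])],
                       feature_names=[f"f{j}" for j in range(values.shape[1])],
                       omics_name=name)


class TestFilterLowSignal:
    def test_zero_mean_and_constant_columns_removed(self):
        x = make_matrix(np.column_stack([
            [0.0, 0.0, 0.0],      # no signal: mean exactly 0
            [5.0, 5.0, 5.0],      # constant nonzero: SD = 0 <= 0
            [1.0, 2.0, 3.0],      # kept
            [1.0, -1.0, 0.0],     # mean 0: removed even though SD > 0
        ]))
        out = preprocess.filter_low_signal(x, sd_threshold=0.0)
        assert out.feature_names == ("f2",)

    def test_planted_constants_leave_expected_count(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1.0, 1.0, size=(30, 100))
        values[:, :10] = 7.0           # 10 planted constants
        out = preprocess.filter_low_signal(make_matrix(values), 0.0)
        assert out.n_features == 90

    def test_omics_specific_default_threshold(self):
        rng = np.random.default_rng(1)
        low = rng.normal(1.0, 0.01, size=(200, 1))      # SD ~ 0.01
        high = rng.normal(1.0, 1.0, size=(200, 1))
        x = make_matrix(np.hstack([low, high]), name="mrna")
        out = preprocess.filter_low_signal(x)            # mRNA default 0.1
        assert out.feature_names == ("f1",)

    def test_everything_removed_names_the_stage(self):
        x = make_matrix(np.zeros((4, 3)), name="mrna")
        with pytest.raises(ValueError, match="low-signal"):
            preprocess.filter_low_signal(x, 0.0)


class TestAnovaPreselect:
    def test_identical_distributions_keep_order(self):
        rng = np.random.default_rng(3)
        x = make_matrix(rng.standard_normal((40, 6)))
        labels = np.repeat([0, 1], 20)
        out = preprocess.anova_preselect(x, labels, k=6)
        assert out.feature_names == x.feature_names

    def test_planted_features_selected(self):
        hits = 0
        for seed in range(20):
            spec = SimSpec(seed=seed, n_subjects=300, n_features=(50,),
                           module_sizes=((10,) * 5,),
                           informative_fraction=(0.1,), effect_size=1.5)
            (x,), labels = simdata.generate_cohort(spec)
            planted = {x.feature_names[j]
                       for j in simdata.informative_features(spec)[0]}
            out = preprocess.anova_preselect(x, labels, k=5)
            hits += set(out.feature_names) == planted
        assert hits >= 19

    def test_bad_k_and_small_class_rejected(self):
        x = make_matrix(np.random.default_rng(0).standard_normal((10, 4)))
        labels = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            preprocess.anova_preselect(x, labels, k=0)
        with pytest.raises(ValueError):
            preprocess.anova_preselect(x, [0] * 9 + [1], k=2)


class TestPcaVarianceCheck:
    def test_isotropic_noise_passes(self):
        rng = np.random.default_rng(0)
        x = make_matrix(rng.standard_normal((500, 50)))
        passed, fraction = preprocess.pca_variance_check(x)
        assert passed and fraction < 0.1

    def test_dominant_direction_fails(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((100, 1))
        values = np.repeat(base, 50, axis=1) + 1e-3 * rng.standard_normal(
            (100, 50))
        passed, fraction = preprocess.pca_variance_check(make_matrix(values))
        assert not passed and fraction > 0.5

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            preprocess.pca_variance_check(make_matrix(np.ones((5, 1))))


class TestMinMaxScale:
    def test_simple_column(self):
        x = make_matrix(np.array([[2.0], [4.0], [6.0]]))
        out, _ = preprocess.minmax_scale(x)
        np.testing.assert_allclose(out.values[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero_with_warning(self):
        x = make_matrix(np.full((4, 1), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            out, _ = preprocess.minmax_scale(x)
        assert (out.values == 0).all()

    def test_held_out_values_may_exceed_one(self):
        x = make_matrix(np.array([[0.0], [1.0], [5.0]]))
        out, scaler = preprocess.minmax_scale(x, fit_ids=["s0", "s1"])
        assert out.values[2, 0] == 5.0    # beyond training max, preserved
        np.testing.assert_allclose(out.values[:2, 0], [0, 1])
        again = scaler.transform(x)
        np.testing.assert_allclose(again.values, out.values)


class TestFittedPipeline:
    def setup_method(self):
        spec = SimSpec(seed=21, n_subjects=120, n_features=(40,),
                       module_sizes=((10,) * 4,),
                       informative_fraction=(0.2,), effect_size=1.0)
        (self.x,), self.labels = simdata.generate_cohort(spec)

    def test_idempotent_on_own_output(self):
        ids = list(self.x.subject_ids)
        out, fitted = preprocess.fit_preprocess(
            self.x, self.labels, ids, k=20)
        again = fitted.transform(out)           # re-apply selection + scaling
        # selection keeps the same features; rescaling the already scaled
        # values with the *same* fitted state is only identity if mins/ranges
        # were refit, so instead check: fitting a new pipeline on the scaled
        # output changes nothing.
        out2, _ = preprocess.fit_preprocess(out, self.labels, ids, k=20)
        np.testing.assert_allclose(out2.values, out.values, atol=1e-12)

    def test_scaled_training_features_span_unit_interval(self):
        ids = list(self.x.subject_ids)[:80]
        out, _ = preprocess.fit_preprocess(
            self.x, self.labels[:80], ids, k=20)
        train = out.subset_subjects(ids)
        np.testing.assert_allclose(train.values.min(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(train.values.max(axis=0), 1, atol=1e-12)

    def test_fitted_state_is_independent_of_test_subjects(self):
        ids = list(self.x.subject_ids)
        fit_ids = ids[:80]
        _, fitted = preprocess.fit_preprocess(
            self.x, self.labels[:80], fit_ids, k=20)
        perturbed = self.x.values.copy()
        perturbed[80:] += 100.0         # wreck the held-out subjects
        x2 = self.x.replace(values=perturbed)
        _, fitted2 = preprocess.fit_preprocess(
            x2, self.labels[:80], fit_ids, k=20)
        assert fitted.feature_names == fitted2.feature_names
        np.testing.assert_allclose(fitted.scaler.mins, fitted2.scaler.mins)
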