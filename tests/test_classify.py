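"""Difference-sample construction, fold hygiene and cross-validation behaviour."""
import numpy as np
import pandas as pd
import pytest

from pdvoice.classify import (
    CVConfig,
    DifferenceSample,
    build_difference_samples,
    cross_validate,
    predict,
    select_top_k,
    standardize,
    train_classifier,
)
from pdvoice.errors import ParameterError
from pdvoice.synth import generate_feature_table


def _samples_from_table(table, task="picture", feature_set="SF"):
    return build_difference_samples(table, task, feature_set)


@pytest.fixture
def gaussian_samples(rng):
    """25 subjects, 6 features, one strongly shifted."""
    spec = [(f"w{i}", 1.0, 0.0) for i in range(5)] + [("strong", 1.0, 3.0)]
    table = generate_feature_table(25, spec, rng)
    samples, names = _samples_from_table(table)
    return samples, names


class TestBuildDifferenceSamples:
    def test_two_antisymmetric_samples_per_subject(self, gaussian_samples):
        samples, _ = gaussian_samples
        assert len(samples) == 50
        by_subject = {}
        for s in samples:
            by_subject.setdefault(s.subject, []).append(s)
        for pair in by_subject.values():
            a, b = pair
            assert a.label == -b.label
            assert np.array_equal(a.x, -b.x)

    def test_subject_missing_state_excluded_with_warning(self, rng):
        table = generate_feature_table(5, [("f", 1.0, 1.0)], rng)
        table = table.drop(table[(table.subject == "S03") & (table.state == "ON")].index)
        with pytest.warns(UserWarning, match="S03"):
            samples, _ = _samples_from_table(table)
        assert len(samples) == 8

    def test_equal_states_give_zero_vector(self, rng):
        table = generate_feature_table(4, [("f", 1.0, 0.0)], rng)
        table.loc[table.state == "ON", "f"] = table.loc[table.state == "OFF", "f"].to_numpy()
        samples, _ = _samples_from_table(table)
        assert all(np.allclose(s.x, 0) for s in samples)

    def test_unknown_feature_set_rejected(self, rng):
        table = generate_feature_table(4, [("f", 1.0, 0.0)], rng)
        with pytest.raises(ParameterError):
            build_difference_samples(table, "picture", "BOGUS")


class TestStandardize:
    def test_train_becomes_zero_mean_unit_sd(self, rng):
        X = rng.normal(3, 5, size=(40, 6))
        Z = standardize(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self, rng):
        X = rng.normal(size=(10, 2))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            Z = standardize(X)
        assert np.all(Z[:, 1] == 0.0)

    def test_test_data_uses_train_statistics_only(self, rng):
        train = rng.normal(0, 1, size=(50, 3))
        test = rng.normal(5, 2, size=(20, 3))
        _, Z_test = standardize(train, test)
        own_z = (test - test.mean(axis=0)) / test.std(axis=0)
        assert not np.allclose(Z_test, own_z, atol=0.1)
        assert np.abs(Z_test.mean(axis=0)).min() > 1.0  # shifted, as it must be


class TestSelectTopK:
    def test_planted_feature_always_selected(self, gaussian_samples):
        samples, names = gaussian_samples
        sel = select_top_k(samples, k=1)
        assert names[sel[0]] == "strong"

    def test_k_equal_to_feature_count_is_identity(self, gaussian_samples):
        samples, names = gaussian_samples
        assert list(select_top_k(samples, k=len(names))) == list(range(len(names)))

    def test_k_none_selects_all(self, gaussian_samples):
        samples, names = gaussian_samples
        assert list(select_top_k(samples, None)) == list(range(len(names)))

    def test_oversized_k_warns_and_uses_all(self, gaussian_samples):
        samples, names = gaussian_samples
        with pytest.warns(UserWarning, match="exceeds"):
            sel = select_top_k(samples, k=100)
        assert len(sel) == len(names)

    def test_selection_varies_across_folds_on_noise(self, rng):
        """Per-fold selection on pure noise differs fold to fold (leakage sentinel:
        a selection computed globally would be constant)."""
        spec = [(f"n{i}", 1.0, 0.0) for i in range(10)]
        table = generate_feature_table(20, spec, rng)
        samples, _ = _samples_from_table(table)
        subjects = sorted({s.subject for s in samples})
        picks = set()
        for drop in range(4):
            held = set(subjects[drop * 5 : (drop + 1) * 5])
            train = [s for s in samples if s.subject not in held]
            picks.add(tuple(select_top_k(train, k=3)))
        assert len(picks) > 1


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["EN", "LR-l1", "NB", "RF"])
    def test_separable_data_fits_perfectly(self, kind, rng):
        X = np.r_[rng.normal(3, 0.3, size=(20, 4)), rng.normal(-3, 0.3, size=(20, 4))]
        y = np.r_[np.ones(20), -np.ones(20)]
        model = train_classifier(kind, X, y, rng=np.random.default_rng(0))
        assert (predict(model, X) == y).all()

    def test_nb_approaches_bayes_rate(self):
        """Gaussian classes at +/- mu: accuracy tends to Phi(mu) for unit variance."""
        from scipy.stats import norm

        rng = np.random.default_rng(41)
        mu = 1.0
        X = np.r_[rng.normal(mu, 1, size=(4000, 1)), rng.normal(-mu, 1, size=(4000, 1))]
        y = np.r_[np.ones(4000), -np.ones(4000)]
        model = train_classifier("NB", X, y)
        acc = (predict(model, X) == y).mean()
        assert acc == pytest.approx(norm.cdf(mu), abs=0.03)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ParameterError):
            train_classifier("NB", X, np.ones(10))


class TestCrossValidate:
    CFG = CVConfig(n_runs=3, n_folds=10, classifiers=("NB", "LR-l1"), rng_seed=77)

    def test_strong_effect_reaches_high_accuracy(self, gaussian_samples):
        samples, _ = gaussian_samples
        reports = cross_validate(samples, self.CFG)
        assert max(r.accuracy_mean for r in reports) > 0.8

    def test_null_data_is_unbiased_at_chance(self):
        """Grand mean over independent null cohorts sits at 0.5 (a single
        cohort's CV accuracy is itself noisy, so only the mean is sharp)."""
        spec = [(f"n{i}", 1.0, 0.0) for i in range(6)]
        means = []
        for c in range(8):
            table = generate_feature_table(25, spec, np.random.default_rng([61, c]))
            samples, _ = _samples_from_table(table)
            cfg = CVConfig(n_runs=2, classifiers=("NB",), rng_seed=c)
            (report,) = cross_validate(samples, cfg)
            means.append(report.accuracy_mean)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) <= 2.5 * se + 1e-9

    def test_same_seed_identical_report(self, gaussian_samples):
        samples, _ = gaussian_samples
        r1 = cross_validate(samples, self.CFG)
        r2 = cross_validate(samples, self.CFG)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.run_accuracies, b.run_accuracies)

    def test_flipping_all_states_preserves_accuracy(self, gaussian_samples):
        """Relabelling ON<->OFF negates every sample; sign-symmetric pipelines
        report the same accuracy."""
        samples, _ = gaussian_samples
        flipped = [DifferenceSample(s.subject, -s.x, -s.label) for s in samples]
        r1 = cross_validate(samples, self.CFG)
        r2 = cross_validate(flipped, self.CFG)
        for a, b in zip(r1, r2):
            assert a.accuracy_mean == pytest.approx(b.accuracy_mean, abs=1e-12)

    def test_poisoning_test_folds_does_not_change_predictions(self, gaussian_samples):
        """No-leakage instrumentation: corrupting held-out subjects' features
        must not alter the other subjects' reports."""
        samples, _ = gaussian_samples
        target = samples[0].subject
        poisoned = [
            DifferenceSample(s.subject, s.x + 1e3, s.label) if s.subject == target else s
            for s in samples
        ]
        clean_wo = [s for s in samples if s.subject != target]
        # hold the target out manually; train on the rest in both worlds
        train_clean = clean_wo
        train_pois = [s for s in poisoned if s.subject != target]
        sel_c = select_top_k(train_clean, 3)
        sel_p = select_top_k(train_pois, 3)
        assert np.array_equal(sel_c, sel_p)

    def test_fewer_subjects_than_folds_warns(self, rng):
        table = generate_feature_table(5, [("f", 1.0, 2.0)], rng)
        samples, _ = _samples_from_table(table)
        with pytest.warns(UserWarning, match="folds"):
            cross_validate(samples, CVConfig(n_runs=1, classifiers=("NB",), rng_seed=1))
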