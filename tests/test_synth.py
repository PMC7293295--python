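"""Synthetic cohort generator: determinism, ground truth, effect recovery."""
import numpy as np
import pytest

from pdvoice.errors import ParameterError
from pdvoice.prosody import detect_syllable_nuclei
from pdvoice.semantics import ACTION_SEEDS, NON_ACTION_SEEDS, similarity
from pdvoice.stats import paired_ttest
from pdvoice.synth import (
    ACTION_VERBS,
    NON_ACTION_VERBS,
    SyntheticCohortConfig,
    default_vocabulary,
    generate_cohort,
    generate_feature_table,
    generate_toy_embeddings,
    generate_transcript,
    synthesize_utterance,
    write_cohort,
)


class TestSynthesizeUtterance:
    def test_burst_count_is_rate_times_duration(self):
        _, truth = synthesize_utterance(
            5.0, 3.0, rng=np.random.default_rng(0), interval_jitter=0.0
        )
        assert len(truth["burst_times"]) == 15

    def test_same_seed_gives_identical_samples(self):
        r1, _ = synthesize_utterance(3.0, 4.0, rng=np.random.default_rng(9))
        r2, _ = synthesize_utterance(3.0, 4.0, rng=np.random.default_rng(9))
        assert np.array_equal(r1.samples, r2.samples)

    def test_nuclei_recover_bursts_around_inserted_pause(self):
        rec, truth = synthesize_utterance(
            6.0, 3.0, pause_spec=(10.0, 0.5), rng=np.random.default_rng(2)
        )
        track = detect_syllable_nuclei(rec)
        assert abs(track.times.size - len(truth["burst_times"])) <= 1

    @pytest.mark.parametrize("kwargs", [dict(duration_s=0.5), dict(syllable_rate=0.2),
                                        dict(syllable_rate=12.0)])
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(duration_s=5.0, syllable_rate=3.0, rng=np.random.default_rng(0))
        base.update(kwargs)
        with pytest.raises(ParameterError):
            synthesize_utterance(**base)


class TestTranscripts:
    @pytest.mark.parametrize("p,expect_all", [(1.0, True), (0.0, False)])
    def test_extreme_action_probabilities(self, p, expect_all):
        cfg = SyntheticCohortConfig(
            action_verb_prob_on=p, action_verb_prob_off=p, words_per_transcript=400
        )
        t = generate_transcript("ON", cfg, np.random.default_rng(0))
        verbs = [w for w, tag in t.tokens if tag == "verb"]
        assert verbs
        in_action = [w in ACTION_VERBS for w in verbs]
        assert all(in_action) if expect_all else not any(in_action)

    def test_action_fraction_within_binomial_error(self):
        cfg = SyntheticCohortConfig(action_verb_prob_on=0.7, words_per_transcript=4000)
        t = generate_transcript("ON", cfg, np.random.default_rng(1))
        verbs = [w for w, tag in t.tokens if tag == "verb"]
        frac = np.mean([w in ACTION_VERBS for w in verbs])
        se = np.sqrt(0.7 * 0.3 / len(verbs))
        assert abs(frac - 0.7) < 3 * se


class TestToyEmbeddings:
    def test_unit_norm_vectors(self, toy_embeddings):
        for w in toy_embeddings.vocabulary:
            assert np.linalg.norm(toy_embeddings[w]) == pytest.approx(1.0, abs=1e-9)

    def test_action_words_nearer_action_seeds(self, toy_embeddings):
        assert similarity("run", "act", toy_embeddings) > similarity(
            "run", "sleep", toy_embeddings
        )

    def test_mean_margin_toward_own_seed_is_positive(self, toy_embeddings):
        margins = [
            similarity(w, "act", toy_embeddings) - similarity(w, "rest", toy_embeddings)
            for w in ACTION_VERBS
        ]
        assert np.mean(margins) > 0

    def test_dim_below_two_rejected(self):
        with pytest.raises(ParameterError):
            generate_toy_embeddings(default_vocabulary(), 1, np.random.default_rng(0))

    def test_missing_seed_words_rejected(self):
        from pdvoice.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            generate_toy_embeddings({"boy", "run"}, 8, np.random.default_rng(0))


class TestCohort:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SyntheticCohortConfig(
            n_subjects=3, rng_seed=5, duration_s=3.0, ddk_duration_s=2.0,
            words_per_transcript=60,
        )
        return cfg, generate_cohort(cfg)

    def test_counts_subjects_states_tasks(self, small_cohort):
        cfg, cohort = small_cohort
        assert len(cohort) == 3
        for subj in cohort:
            assert len(subj.recordings) == 2 * len(cfg.task_set)
            for task in cfg.task_set:
                assert {("ON" if s == "ON" else "OFF") for (t, s) in subj.recordings if t == task} == {"ON", "OFF"}

    def test_bit_identical_under_same_seed(self, small_cohort):
        cfg, cohort = small_cohort
        again = generate_cohort(cfg)
        for a, b in zip(cohort, again):
            for key in a.recordings:
                assert np.array_equal(a.recordings[key].samples, b.recordings[key].samples)
            assert a.transcripts["ON"].tokens == b.transcripts["ON"].tokens

    def test_adding_subjects_preserves_existing_ones(self, small_cohort):
        cfg, cohort = small_cohort
        bigger = generate_cohort(
            SyntheticCohortConfig(
                n_subjects=4, rng_seed=5, duration_s=3.0, ddk_duration_s=2.0,
                words_per_transcript=60,
            )
        )
        key = ("picture", "ON")
        assert np.array_equal(
            cohort[0].recordings[key].samples, bigger[0].recordings[key].samples
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticCohortConfig(n_subjects=1)

    def test_write_cohort_layout(self, small_cohort, tmp_path):
        import pandas as pd

        cfg, cohort = small_cohort
        manifest = write_cohort(cohort, tmp_path, embeddings=None)
        frame = pd.read_csv(manifest)
        assert len(frame) == 3 * 2 * len(cfg.task_set)
        for rel in frame["wav_path"]:
            assert (tmp_path / rel).exists()


class TestFeatureTable:
    def test_same_seed_identical_table(self):
        spec = [("f1", 1.0, 0.0), ("f2", 1.0, 2.0)]
        t1 = generate_feature_table(10, spec, np.random.default_rng(4))
        t2 = generate_feature_table(10, spec, np.random.default_rng(4))
        assert t1.equals(t2)

    def test_planted_shift_recovered_by_paired_test(self):
        spec = [("null", 1.0, 0.0), ("shifted", 1.0, 5.0)]
        table = generate_feature_table(25, spec, np.random.default_rng(6))
        on = table[table.state == "ON"].sort_values("subject")
        off = table[table.state == "OFF"].sort_values("subject")
        r_null = paired_ttest(on["null"].to_numpy(), off["null"].to_numpy())
        r_shift = paired_ttest(on["shifted"].to_numpy(), off["shifted"].to_numpy())
        assert r_shift.p_value < 1e-6
        assert abs(r_null.t_statistic) < 4

    def test_five_sd_shift_ranks_first_in_most_replicates(self):
        from pdvoice.stats import rank_features

        spec = [(f"n{i}", 1.0, 0.0) for i in range(9)] + [("big", 1.0, 5.0)]
        wins = 0
        for rep in range(40):
            table = generate_feature_table(20, spec, np.random.default_rng([8, rep]))
            ranked = rank_features(table, "picture")
            wins += ranked[0].feature == "big"
        assert wins >= 38  # >= 95 % of replicates
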