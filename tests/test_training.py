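import numpy as np
import pytest

from groupdecode import (
    GeneratorConfig,
    TrainConfig,
    WaveNetConfig,
    build_model,
    embedding_ablation,
    evaluate,
    finetune,
    generate_dataset,
    holm_correction,
    loso_run,
    paired_wilcoxon,
    standardize_per_channel,
    stratified_split,
    subgroup_scaling,
    train,
)


@pytest.fixture(scope="module")
def easy_problem():
    """2 classes, 2 subjects, high SNR: small enough to memorize quickly."""
    cfg = GeneratorConfig(n_subjects=2, n_classes=2, n_trials_per_class=10,
                          C=6, T=32, t0=0.0, planted_window=(0.02, 0.1),
                          planted_channels=(0, 1, 2), evoked_amplitude=3.0,
                          subject_mixing_strength=0.2, seed=5)
    ds, _, _ = generate_dataset(cfg)
    split = stratified_split(ds, (4, 1), seed=5)
    ds, _ = standardize_per_channel(ds, split.train_indices)
    return ds, split


def small_model_config(embedding_size=4, **overrides):
    kw = dict(n_channels=6, n_timepoints=32, n_classes=2, n_conv_layers=2,
              hidden_channels=10, fc_hidden=16, embedding_size=embedding_size,
              n_subjects=2, dropout=0.1)
    kw.update(overrides)
    return WaveNetConfig(**kw)


class TestTrain:
    def test_memorizes_high_snr_toy(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(dropout=0.0), seed=0)
        cfg = TrainConfig(learning_rate=2e-3, batch_size=16, n_epochs=60,
                          seed=0, checkpoint_rule="final")
        model, history = train(model, ds, split, cfg)
        assert history.train_acc.iloc[-1] >= 0.95

    def test_reproducible_history(self, easy_problem):
        ds, split = easy_problem
        runs = []
        for _ in range(2):
            model = build_model(small_model_config(), seed=1)
            cfg = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=5, seed=3)
            _, history = train(model, ds, split, cfg)
            runs.append(history)
        assert runs[0].equals(runs[1])

    def test_zero_learning_rate_keeps_parameters(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(dropout=0.0), seed=2)
        before = {k: v.copy() for k, v in model.params.items()}
        cfg = TrainConfig(learning_rate=0.0, batch_size=16, n_epochs=3, seed=0,
                          checkpoint_rule="final")
        model, history = train(model, ds, split, cfg)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        # constant up to batch-order summation error
        np.testing.assert_allclose(history.train_loss,
                                   history.train_loss.iloc[0], rtol=1e-12)

    def test_best_val_checkpoint_recorded(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(), seed=0)
        cfg = TrainConfig(learning_rate=2e-3, batch_size=16, n_epochs=10, seed=0)
        model, history = train(model, ds, split, cfg)
        assert "best_epoch" in history.attrs
        best = history.attrs["best_epoch"]
        assert history.val_acc.iloc[best] == history.val_acc.max()


class TestEvaluate:
    def test_constant_logit_model_scores_favored_class_rate(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(embedding_size=0), seed=0)
        model.params["fc2_W"][:] = 0.0
        model.params["fc2_b"][:] = [0.0, 1.0]  # always predicts class 1
        rep = evaluate(model, ds, np.arange(ds.n_trials))
        assert rep.overall_accuracy == pytest.approx(np.mean(ds.labels == 1))

    def test_overall_is_trial_weighted_mean_of_per_subject(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(), seed=1)
        rep = evaluate(model, ds, np.arange(ds.n_trials))
        weights = [np.sum(ds.subjects == s) for s in sorted(rep.per_subject)]
        weighted = np.average([rep.per_subject[s] for s in sorted(rep.per_subject)],
                              weights=weights)
        assert rep.overall_accuracy == pytest.approx(weighted)

    def test_empty_indices_rejected(self, easy_problem):
        ds, _ = easy_problem
        model = build_model(small_model_config(), seed=1)
        with pytest.raises(ValueError):
            evaluate(model, ds, np.array([], dtype=int))


class TestFinetune:
    def test_zero_epochs_is_identity(self, easy_problem):
        ds, split = easy_problem
        group = build_model(small_model_config(), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=0, seed=0,
                          checkpoint_rule="final")
        tuned, _ = finetune(group, 0, ds, split, cfg)
        for k in group.params:
            np.testing.assert_array_equal(tuned.params[k], group.params[k])

    def test_only_target_embedding_row_moves(self, easy_problem):
        ds, split = easy_problem
        group = build_model(small_model_config(), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=3, seed=0,
                          checkpoint_rule="final")
        tuned, _ = finetune(group, 1, ds, split, cfg)
        emb0 = group.params["embedding"]
        emb1 = tuned.params["embedding"]
        np.testing.assert_array_equal(emb1[0], emb0[0])
        assert np.abs(emb1[1] - emb0[1]).max() > 0

    def test_original_model_untouched(self, easy_problem):
        ds, split = easy_problem
        group = build_model(small_model_config(), seed=0)
        snapshot = {k: v.copy() for k, v in group.params.items()}
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=2, seed=0,
                          checkpoint_rule="final")
        finetune(group, 0, ds, split, cfg)
        for k in snapshot:
            np.testing.assert_array_equal(group.params[k], snapshot[k])


class TestLoso:
    def test_fraction_sweep_structure(self, easy_problem):
        ds, split = easy_problem
        mcfg = small_model_config()
        fast = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=3, seed=0,
                           checkpoint_rule="final")
        table, group_model = loso_run(ds, left_out=1,
                                      fractions=[0.0, 0.5, 1.0],
                                      model_config=mcfg, group_config=fast,
                                      finetune_config=fast, split=split)
        assert list(table.fraction) == [0.0, 0.5, 1.0]
        counts = table.n_train_trials.to_numpy()
        assert (np.diff(counts) >= 0).all()
        assert counts[0] == 0
        assert (table.accuracy >= 0).all() and (table.accuracy <= 1).all()

    def test_untrained_scratch_baseline_is_chance(self, easy_problem):
        # zero-shot comparison baseline: a from-scratch subject model with no
        # training cannot beat chance systematically
        ds, split = easy_problem
        model = build_model(small_model_config(embedding_size=0), seed=7)
        val = split.val_indices
        rep = evaluate(model, ds, val)
        assert abs(rep.overall_accuracy - 0.5) <= 3 * np.sqrt(0.25 / val.size)

    def test_invalid_fraction_rejected(self, easy_problem):
        ds, split = easy_problem
        cfg = TrainConfig(n_epochs=1)
        with pytest.raises(ValueError):
            loso_run(ds, 0, [0.0, 1.5], small_model_config(), cfg, cfg, split=split)


class TestSubgroupScaling:
    def test_full_size_matches_direct_training(self, easy_problem):
        ds, split = easy_problem
        mcfg = small_model_config()
        tcfg = TrainConfig(learning_rate=1e-3, batch_size=16, n_epochs=4, seed=0)
        table = subgroup_scaling(ds, np.array([0, 1]), mcfg, tcfg, split=split)
        model = build_model(mcfg, seed=0)
        model, _ = train(model, ds, split, tcfg)
        direct = evaluate(model, ds, split.val_indices).overall_accuracy
        assert table.acc_trained_subjects.iloc[-1] == pytest.approx(direct)

    def test_mode_b_not_above_mode_a_when_above_chance(self, easy_problem):
        ds, split = easy_problem
        mcfg = small_model_config()
        tcfg = TrainConfig(learning_rate=2e-3, batch_size=16, n_epochs=6, seed=0)
        table = subgroup_scaling(ds, np.array([0, 1]), mcfg, tcfg, split=split)
        row = table.iloc[0]  # k=1 < total
        if row.acc_trained_subjects > 1.0 / ds.n_classes:
            assert row.acc_all_subjects <= row.acc_trained_subjects + 1e-9

    def test_bad_order_rejected(self, easy_problem):
        ds, split = easy_problem
        with pytest.raises(ValueError):
            subgroup_scaling(ds, np.array([0, 0]), small_model_config(),
                             TrainConfig(n_epochs=1), split=split)


class TestEmbeddingAblation:
    def test_zero_mode_deterministic_and_zeroed(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(), seed=0)
        a = embedding_ablation(model, ds, split.val_indices, "zero", seed=1)
        b = embedding_ablation(model, ds, split.val_indices, "zero", seed=99)
        assert a.overall_accuracy == b.overall_accuracy
        np.testing.assert_array_equal(a.correct, b.correct)

    def test_identity_shuffle_preserves_accuracy(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(), seed=0)
        # find a seed whose permutation of 2 subjects is the identity
        seed = next(s for s in range(20)
                    if (np.random.default_rng(s).permutation(2) == [0, 1]).all())
        rep = embedding_ablation(model, ds, split.val_indices, "shuffle", seed=seed)
        base = evaluate(model, ds, split.val_indices)
        assert rep.overall_accuracy == base.overall_accuracy

    def test_requires_embeddings(self, easy_problem):
        ds, split = easy_problem
        model = build_model(small_model_config(embedding_size=0), seed=0)
        with pytest.raises(ValueError):
            embedding_ablation(model, ds, split.val_indices, "zero")


class TestWilcoxon:
    def test_textbook_six_pair_vector(self):
        # differences: +1.5 -0.5 +2.0 +3.0 -1.0 +2.5 -> |d| ranks
        # 0.5->1, 1.0->2, 1.5->3, 2.0->4, 2.5->5, 3.0->6; negative-rank sum 3.
        # Exact two-sided p: 2 * 5/64 = 0.15625 (subsets of {1..6} summing <= 3).
        b = np.zeros(6)
        a = np.array([1.5, -0.5, 2.0, 3.0, -1.0, 2.5])
        res = paired_wilcoxon(a, b)
        assert res.statistic == 3.0
        assert res.pvalue == pytest.approx(0.15625)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.random(8)
        b = rng.random(8)
        assert paired_wilcoxon(a, b).pvalue == pytest.approx(
            paired_wilcoxon(b, a).pvalue)

    def test_degenerate_all_equal(self):
        x = np.full(6, 0.3)
        with pytest.raises(ValueError):
            paired_wilcoxon(x, x)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2], [2, 1])


class TestHolm:
    def test_adjustment_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.2])
        adj = holm_correction(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        # sorted p: 0.01*4=0.04, 0.03*3=0.09, 0.04*2=0.08 -> monotone 0.09, 0.2*1
        np.testing.assert_allclose(adj, [0.04, 0.09, 0.09, 0.2])
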