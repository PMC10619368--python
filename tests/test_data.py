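import h5py
import numpy as np
import pytest

from groupdecode import (
    EpochedDataset,
    load_epochs,
    make_kfold,
    save_epochs,
    split_to_csv,
    standardize_per_channel,
    stratified_split,
    whiten_channels,
)
from groupdecode.data import DegenerateInputError, FormatError, ValidationError


def _dataset(n_sub=2, n_cls=3, n_per=5, C=4, T=16, seed=0):
    rng = np.random.default_rng(seed)
    n = n_sub * n_cls * n_per
    labels = np.tile(np.repeat(np.arange(n_cls), n_per), n_sub)
    subjects = np.repeat(np.arange(n_sub), n_cls * n_per)
    trials = rng.standard_normal((n, C, T)).astype(np.float32).astype(np.float64)
    return EpochedDataset(trials=trials, labels=labels, subjects=subjects,
                          fs=100.0, t0=-0.05, balanced=True)


class TestPersistence:
    def test_roundtrip_is_identical(self, tmp_path):
        ds = _dataset()
        path = tmp_path / "epochs.h5"
        save_epochs(ds, path)
        back = load_epochs(path)
        np.testing.assert_array_equal(back.trials, ds.trials)
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_array_equal(back.subjects, ds.subjects)
        assert back.fs == ds.fs and back.t0 == ds.t0 and back.balanced

    def test_layout_roundtrip(self, tiny_dataset, tmp_path):
        ds, layout, _ = tiny_dataset
        path = tmp_path / "epochs.h5"
        save_epochs(ds, path)
        back = load_epochs(path)
        np.testing.assert_array_equal(back.layout.positions, layout.positions)
        np.testing.assert_array_equal(back.layout.location_group, layout.location_group)

    def test_overwrite_requires_flag(self, tmp_path):
        ds = _dataset()
        path = tmp_path / "epochs.h5"
        save_epochs(ds, path)
        with pytest.raises(FileExistsError):
            save_epochs(ds, path)
        save_epochs(ds, path, overwrite=True)

    def test_empty_dataset_roundtrips(self, tmp_path):
        ds = EpochedDataset(
            trials=np.empty((0, 3, 8)), labels=np.empty(0, np.int64),
            subjects=np.empty(0, np.int64), fs=100.0,
        )
        path = tmp_path / "empty.h5"
        save_epochs(ds, path)
        assert load_epochs(path).n_trials == 0

    def test_mismatched_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("trials", data=np.zeros((4, 2, 8), np.float32))
            f.create_dataset("labels", data=np.zeros(5, np.int64))
            f.create_dataset("subjects", data=np.zeros(4, np.int64))
            f.attrs["fs"] = 100.0
            f.attrs["t0"] = 0.0
        with pytest.raises(ValidationError):
            load_epochs(path)

    def test_missing_field_is_format_error(self, tmp_path):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("trials", data=np.zeros((4, 2, 8), np.float32))
        with pytest.raises(FormatError):
            load_epochs(path)


class TestDatasetInvariants:
    def test_generated_counts(self, tiny_dataset):
        ds, _, _ = tiny_dataset
        assert ds.n_trials == 2 * 3 * 4
        assert ds.balanced

    def test_nonfinite_rejected(self):
        trials = np.zeros((2, 2, 4))
        trials[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            EpochedDataset(trials=trials, labels=np.zeros(2, np.int64),
                           subjects=np.zeros(2, np.int64), fs=10.0)

    def test_unbalanced_declared_balanced_rejected(self):
        with pytest.raises(ValidationError):
            EpochedDataset(
                trials=np.zeros((3, 2, 4)), labels=np.array([0, 0, 1]),
                subjects=np.zeros(3, np.int64), fs=10.0, balanced=True,
            )

    def test_time_axis_convention(self):
        ds = _dataset(T=16)
        assert ds.times[0] == pytest.approx(-0.05)
        assert ds.time_to_sample(-0.05) == 0
        assert ds.time_to_sample(0.05) == 10  # round((0.05 - -0.05) * 100)


class TestStandardize:
    def test_fit_trials_become_zero_mean_unit_variance(self):
        ds = _dataset()
        fit = np.arange(0, ds.n_trials, 2)
        out, scaler = standardize_per_channel(ds, fit)
        m = out.trials[fit].mean(axis=(0, 2))
        v = out.trials[fit].var(axis=(0, 2))
        np.testing.assert_allclose(m, 0, atol=1e-12)
        np.testing.assert_allclose(v, 1, atol=1e-12)

    def test_hand_computed_toy(self):
        # 2 trials, 2 channels, 2 timepoints; channel 0 values {0,2,4,6}:
        # mean 3, population var 5; channel 1 values {1,1,3,3}: mean 2, var 1.
        trials = np.array([[[0.0, 2.0], [1.0, 1.0]], [[4.0, 6.0], [3.0, 3.0]]])
        ds = EpochedDataset(trials=trials, labels=np.array([0, 1]),
                            subjects=np.array([0, 0]), fs=10.0)
        out, scaler = standardize_per_channel(ds)
        np.testing.assert_allclose(scaler.mean, [3.0, 2.0])
        np.testing.assert_allclose(scaler.var, [5.0, 1.0])
        np.testing.assert_allclose(
            out.trials[0, 0], (np.array([0.0, 2.0]) - 3.0) / np.sqrt(5.0)
        )
        np.testing.assert_allclose(out.trials[0, 1], [-1.0, -1.0])

    def test_same_transform_applied_to_held_out_trials(self):
        ds = _dataset()
        fit = np.arange(10)
        out, scaler = standardize_per_channel(ds, fit)
        held = np.setdiff1d(np.arange(ds.n_trials), fit)
        np.testing.assert_allclose(out.trials[held], scaler.apply(ds.trials[held]))

    def test_constant_channel_raises(self):
        ds = _dataset()
        ds.trials[:, 1, :] = 2.5
        with pytest.raises(DegenerateInputError):
            standardize_per_channel(ds)

    def test_idempotent_on_own_output(self):
        ds = _dataset()
        once, _ = standardize_per_channel(ds)
        twice, _ = standardize_per_channel(once)
        np.testing.assert_allclose(twice.trials, once.trials, atol=1e-10)


class TestWhiten:
    def test_fit_covariance_is_identity(self):
        ds = _dataset(C=5, T=64)
        out, tf = whiten_channels(ds)
        flat = out.trials.transpose(1, 0, 2).reshape(5, -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        cov = flat @ flat.T / flat.shape[1]
        assert np.abs(cov - np.eye(5)).max() < 1e-6

    def test_keeps_all_components(self):
        ds = _dataset(C=4)
        _, tf = whiten_channels(ds)
        assert tf.projection.shape == (4, 4)
        assert np.linalg.matrix_rank(tf.projection) == 4

    def test_single_channel_is_rescaling(self):
        ds = _dataset(C=1)
        out, tf = whiten_channels(ds)
        flat = out.trials.reshape(-1)
        assert np.var(flat) == pytest.approx(1.0, rel=1e-9)

    def test_projection_reapplicable_to_held_out(self):
        ds = _dataset()
        fit = np.arange(15)
        out, tf = whiten_channels(ds, fit)
        held = np.setdiff1d(np.arange(ds.n_trials), fit)
        np.testing.assert_allclose(out.trials[held], tf.apply(ds.trials[held]))

    def test_rank_deficient_warns(self):
        ds = _dataset(C=3, T=32)
        ds.trials[:, 2, :] = ds.trials[:, 0, :]  # duplicate channel
        with pytest.warns(RuntimeWarning):
            _, tf = whiten_channels(ds)
        assert tf.rank_deficient


class TestSplits:
    def test_four_to_one_of_30_gives_6_validation(self):
        ds = _dataset(n_sub=2, n_cls=2, n_per=30)
        spec = stratified_split(ds, (4, 1), seed=0)
        for s in range(2):
            for k in range(2):
                cell_val = np.sum(
                    (ds.subjects[spec.val_indices] == s)
                    & (ds.labels[spec.val_indices] == k)
                )
                assert cell_val == 6

    def test_all_train_when_ratio_one_zero(self):
        ds = _dataset()
        spec = stratified_split(ds, (1, 0), seed=0)
        assert spec.val_indices.size == 0
        assert spec.train_indices.size == ds.n_trials

    def test_partition_and_seed_behavior(self):
        ds = _dataset(n_per=10)
        a = stratified_split(ds, (4, 1), seed=1)
        b = stratified_split(ds, (4, 1), seed=2)
        union = np.union1d(a.train_indices, a.val_indices)
        np.testing.assert_array_equal(union, np.arange(ds.n_trials))
        assert not np.array_equal(a.val_indices, b.val_indices)
        assert a.val_indices.size == b.val_indices.size

    def test_remainder_rule_floor_to_validation(self):
        ds = _dataset(n_per=7)  # 7 * 1/5 -> val gets 1, train 6
        spec = stratified_split(ds, (4, 1), seed=0)
        assert spec.val_indices.size == 1 * 2 * 3

    def test_tiny_cell_rejected(self):
        ds = _dataset(n_per=1)
        with pytest.raises(ValidationError):
            stratified_split(ds, (4, 1), seed=0)

    def test_kfold_partitions_validation(self):
        ds = _dataset(n_per=10)
        folds = make_kfold(ds, k=5, seed=0)
        vals = [f.val_indices for f in folds]
        assert sum(v.size for v in vals) == ds.n_trials
        np.testing.assert_array_equal(np.sort(np.concatenate(vals)),
                                      np.arange(ds.n_trials))
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.intersect1d(vals[i], vals[j]).size == 0

    def test_kfold_cells_balanced(self):
        ds = _dataset(n_sub=2, n_cls=2, n_per=30)
        folds = make_kfold(ds, k=5, seed=0)
        for f in folds:
            for s in range(2):
                for k in range(2):
                    n = np.sum((ds.subjects[f.val_indices] == s)
                               & (ds.labels[f.val_indices] == k))
                    assert n == 6

    def test_kfold_degenerate_k(self):
        ds = _dataset()
        with pytest.raises(ValueError):
            make_kfold(ds, k=1)

    def test_split_csv_export(self, tmp_path):
        import pandas as pd

        ds = _dataset()
        spec = stratified_split(ds, (4, 1), seed=0)
        path = tmp_path / "split.csv"
        split_to_csv(spec, ds, path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"trial_index", "role", "subject", "class"}
        assert len(df) == ds.n_trials


def test_mne_epochs_adapter():
    mne = pytest.importorskip("mne")
    from groupdecode.data import from_mne_epochs

    rng = np.random.default_rng(0)
    data = rng.standard_normal((6, 3, 20))
    info = mne.create_info(["c0", "c1", "c2"], sfreq=100.0, ch_types="mag")
    events = np.column_stack([np.arange(6) * 30, np.zeros(6, int),
                              np.array([11, 17, 11, 17, 11, 17])])
    epochs = mne.EpochsArray(data, info, events=events, tmin=-0.05, verbose=False)
    ds = from_mne_epochs(epochs, subjects=np.zeros(6, int))
    assert ds.trials.shape == (6, 3, 20)
    assert ds.fs == 100.0
    assert ds.t0 == pytest.approx(-0.05)
    np.testing.assert_array_equal(ds.labels, [0, 1, 0, 1, 0, 1])  # remapped codes
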