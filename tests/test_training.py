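"""Patient-wise splits, validation filtering, early stopping, protocol."""

import numpy as np
import pytest

import uncertram.training as training
from uncertram.data_model import Dataset
from uncertram.network import NetworkConfig
from uncertram.training import (EarlyStopper, TrainConfig, filter_validation,
                                grid_search, patient_wise_folds,
                                run_experiment, train_fold)


def small_net():
    return NetworkConfig(encoder_kind="small_cnn", embedding_dim=16)


def fast_train(**kw):
    defaults = dict(lr_encoder=1e-3, lr_rest=1e-3, batch_size=16,
                    max_epochs=2, patience=2, n_folds=2, seed_final=3)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestPatientWiseFolds:
    def _dataset(self, n_patients, per_patient=2):
        from conftest import make_set
        from uncertram.data_model import ImageRecord
        records = []
        for p in range(n_patients):
            for i in range(per_patient):
                records.append(ImageRecord(f"im{p}_{i}", f"p{p}", None,
                                           make_set([4], image_id=f"im{p}_{i}")))
        return Dataset(records=records)

    def test_nine_patients_three_folds_split_evenly(self):
        folds = patient_wise_folds(self._dataset(9), 3, seed=0)
        counts = np.bincount(list(folds.values()))
        assert counts.tolist() == [3, 3, 3]

    def test_patients_never_straddle_folds(self):
        ds = self._dataset(10, per_patient=3)
        folds = patient_wise_folds(ds, 3, seed=1)
        for r in ds.records:
            assert folds[r.patient_id] == folds[ds.records[0].patient_id] or \
                r.patient_id != ds.records[0].patient_id
        # record-level view: every record of a patient maps to one fold
        by_patient = {}
        for r in ds.records:
            by_patient.setdefault(r.patient_id, set()).add(folds[r.patient_id])
        assert all(len(v) == 1 for v in by_patient.values())

    def test_same_seed_same_assignment(self):
        ds = self._dataset(11)
        assert patient_wise_folds(ds, 3, 7) == patient_wise_folds(ds, 3, 7)

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = patient_wise_folds(self._dataset(11), 3, seed=2)
        counts = np.bincount(list(folds.values()))
        assert counts.max() - counts.min() <= 1

    def test_fewer_patients_than_folds_errors(self):
        with pytest.raises(ValueError):
            patient_wise_folds(self._dataset(2), 3, seed=0)


class TestFilterValidation:
    def _records_with_D(self, d_values):
        from conftest import make_set
        from uncertram.data_model import ImageRecord, LabelInfo
        records = []
        for i, d in enumerate(d_values):
            r = ImageRecord(f"im{i}", f"p{i}", None, make_set([4]))
            r.label = LabelInfo(y=0, mu_S=4.0, ordinal_target=4, D=d)
            records.append(r)
        return records

    def test_threshold_is_inclusive(self):
        records = self._records_with_D([0.5, 2.0, 3.1])
        kept = filter_validation(records, tau_val=2.0)
        assert [r.label.D for r in kept] == [0.5, 2.0]

    def test_infinite_threshold_keeps_all(self):
        records = self._records_with_D([0.5, 2.0, 3.9])
        assert len(filter_validation(records, tau_val=float("inf"))) == 3

    def test_zero_threshold_keeps_only_unanimous_extremes(self, tiny_dataset):
        dataset, _ = tiny_dataset
        kept = filter_validation(list(dataset.records), tau_val=0.0)
        for r in kept:
            scores = set(r.annotation_set.scores)
            assert scores in ({1.0}, {8.0})

    def test_empty_result_warns(self):
        records = self._records_with_D([2.5, 3.0])
        with pytest.warns(UserWarning, match="validation"):
            filter_validation(records, tau_val=0.0)


class TestEarlyStopper:
    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=10)
        for epoch in range(1, 41):
            assert not stopper.update(1.0 / epoch, epoch)
        assert stopper.best_epoch == 40

    def test_flat_losses_stop_after_patience(self):
        stopper = EarlyStopper(patience=10)
        stops = [stopper.update(0.7, e) for e in range(1, 12)]
        assert stops == [False] * 10 + [True]
        assert stopper.best_epoch == 1

    def test_improvement_resets_the_counter(self):
        stopper = EarlyStopper(patience=3)
        seq = [1.0, 0.9, 0.95, 0.95, 0.8, 0.85, 0.9, 0.85]
        stops = [stopper.update(v, e + 1) for e, v in enumerate(seq)]
        # the improvement at epoch 5 resets the count, so the stop only
        # fires three non-improving epochs later, at the end
        assert stops == [False] * 7 + [True]
        assert stopper.best_epoch == 5

    def test_divergent_loss_raises(self):
        with pytest.raises(FloatingPointError):
            EarlyStopper(3).update(float("nan"), 1)


class TestTrainFold:
    def test_returns_best_checkpoint_and_log(self, tiny_dataset):
        dataset, _ = tiny_dataset
        folds = patient_wise_folds(dataset, 2, seed=0)
        train = [r for r in dataset.records if folds[r.patient_id] == 0]
        val = [r for r in dataset.records if folds[r.patient_id] == 1]
        result, variant = train_fold(train, val, small_net(), fast_train(),
                                     "proposed", seed=0)
        assert len(result.log) <= 2
        assert result.best_epoch >= 1
        assert np.isfinite(result.best_validation_loss)
        logged = [e["val_loss"] for e in result.log]
        assert result.best_validation_loss == pytest.approx(min(logged))

    def test_validation_set_is_filtered_training_is_not(self, tiny_dataset,
                                                        monkeypatch):
        dataset, _ = tiny_dataset
        folds = patient_wise_folds(dataset, 2, seed=0)
        train = [r for r in dataset.records if folds[r.patient_id] == 0]
        val = [r for r in dataset.records if folds[r.patient_id] == 1]
        seen = {}
        original = training.prepare_arrays

        def spy(records, net_config):
            arrays = original(records, net_config)
            seen.setdefault("calls", []).append(arrays["D"])
            return arrays
        monkeypatch.setattr(training, "prepare_arrays", spy)
        train_fold(train, val, small_net(), fast_train(max_epochs=1,
                                                       patience=1),
                   "proposed", seed=0)
        train_D, val_D = seen["calls"][0], seen["calls"][1]
        assert np.all(val_D <= 2.0)
        assert len(train_D) == len(train)   # unfiltered


class TestGridSearch:
    def test_single_point_grid_returns_it(self, tiny_dataset):
        dataset, _ = tiny_dataset
        cfg = fast_train(max_epochs=1, patience=1,
                         lr_encoder_grid=(1e-3,), lr_rest_grid=(1e-3,))
        assert grid_search(dataset, small_net(), cfg, "linear_probe") == \
            (1e-3, 1e-3)

    def test_argmin_and_lexicographic_tie_break(self, tiny_dataset,
                                                monkeypatch):
        dataset, _ = tiny_dataset
        losses = {(1e-4, 1e-3): 0.40, (1e-4, 5e-3): 0.35,
                  (4e-4, 1e-3): 0.35, (4e-4, 5e-3): 0.50}

        class StubResult:
            def __init__(self, loss):
                self.best_validation_loss = loss

        def stub(train, val, net, cfg, variant, seed, fold_index):
            return StubResult(losses[(cfg.lr_encoder, cfg.lr_rest)]), None
        monkeypatch.setattr(training, "train_fold", stub)
        cfg = fast_train(lr_encoder_grid=(1e-4, 4e-4),
                         lr_rest_grid=(1e-3, 5e-3))
        # 0.35 twice: the smaller lr_encoder, then smaller lr_rest, wins
        assert grid_search(dataset, small_net(), cfg) == (1e-4, 5e-3)


class TrackingRecord:
    """Proxy that logs any access to a record's pixel data.

    Identifier reads (patient_id for the disjointness check) are free; the
    timeline captures when image content is actually consumed.
    """

    def __init__(self, record, timeline):
        object.__setattr__(self, "_record", record)
        object.__setattr__(self, "_timeline", timeline)

    def __getattr__(self, name):
        if name == "pixels":
            self._timeline.append("holdout_read")
        return getattr(self._record, name)

    def __setattr__(self, name, value):
        setattr(self._record, name, value)


class TestRunExperiment:
    def test_protocol_shape_and_reproducibility(self, tiny_dataset):
        dataset, _ = tiny_dataset
        holdout, _ = _make_holdout()
        cfg = fast_train()
        a = run_experiment(dataset, holdout, small_net(), cfg, "proposed")
        assert len(a["fold_metrics"]) == cfg.n_folds
        assert set(a["summary"]) == {"precision", "accuracy", "auprc",
                                     "auroc", "sensitivity", "specificity",
                                     "f1", "mcc"}
        b = run_experiment(dataset, holdout, small_net(), cfg, "proposed")
        for name, (mean_a, sd_a) in a["summary"].items():
            mean_b, sd_b = b["summary"][name]
            np.testing.assert_equal((mean_a, sd_a), (mean_b, sd_b), name)

    def test_patient_overlap_with_holdout_errors(self, tiny_dataset):
        dataset, _ = tiny_dataset
        with pytest.raises(ValueError, match="overlap"):
            run_experiment(dataset, dataset, small_net(), fast_train())

    def test_holdout_never_read_before_training_ends(self, tiny_dataset):
        dataset, _ = tiny_dataset
        holdout, _ = _make_holdout()
        timeline = []
        holdout.records = [TrackingRecord(r, timeline)
                           for r in holdout.records]
        callbacks = [lambda event, info: timeline.append(event)]
        run_experiment(dataset, holdout, small_net(), fast_train(),
                       "linear_probe", callbacks=callbacks)
        last_epoch = max(i for i, e in enumerate(timeline)
                         if e == "epoch_end")
        reads = [i for i, e in enumerate(timeline) if e == "holdout_read"]
        assert reads and min(reads) > last_epoch


def _make_holdout():
    from uncertram.synthetic import SynthConfig, generate_dataset
    from uncertram.training import annotate_labels
    config = SynthConfig(n_patients=6, images_per_patient=(2, 3),
                         image_size=16, seed=99)
    ds, latent = generate_dataset(config)
    for r in ds.records:
        r.patient_id = "holdout_" + r.patient_id
    return annotate_labels(ds), latent
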