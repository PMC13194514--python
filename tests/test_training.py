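import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mceegnet.data_io import Cue, EpochSet, Group, Sex, SubjectRecord, ValidationError
from mceegnet.evaluation import regression_metrics
from mceegnet.model import BranchConfig, MCEEGNetConfig, build_model
from mceegnet.synthetic import SimConfig, cohort_to_dataset, simulate_cohort
from mceegnet.training import (ContractError, DegenerateFoldError,
                               DegenerateRangeError, NormalizationParams,
                               SubjectDataset, TrainConfig,
                               denormalize_predictions, fit_label_normalizer,
                               make_cue_triplets, normalize_labels, run_losocv,
                               train_model)


def records(scores, groups=None):
    out = []
    for i, s in enumerate(scores):
        g = groups[i] if groups else (Group.MDD if s >= 11 else Group.HC)
        out.append(SubjectRecord(i + 1, g, Sex.M, s))
    return out


TINY_SIM = SimConfig(n_channels=4, n_trials_per_cue=6, noise=(0.3, 0.3))
TINY_MODEL = MCEEGNetConfig(branch=BranchConfig(n_channels=4, n_samples=125,
                                                f1=2, temporal_kernel=16,
                                                depth_multiplier=1, sep_kernel=4))
FAST_TRAIN = TrainConfig(epochs=2, batch_size=16, seed=0, val_fraction=0.2)


class TestLabelNormalizer:
    def test_cohort_minmax(self):
        from mceegnet.data_io import packaged_subject_table
        p = fit_label_normalizer(packaged_subject_table(), "train_minmax")
        assert (p.ymin, p.ymax) == (0.0, 24.0)

    def test_scale_bounds(self):
        p = fit_label_normalizer(records([5, 5]), "scale_bounds")
        assert (p.ymin, p.ymax) == (0.0, 27.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError, match="scale_bounds"):
            fit_label_normalizer(records([4, 4, 4]), "train_minmax")

    def test_normalize_examples(self):
        p27 = NormalizationParams(0, 27)
        assert normalize_labels(27, p27) == pytest.approx(1.0)
        assert normalize_labels(0, p27) == pytest.approx(0.0)
        assert normalize_labels(23, p27) == pytest.approx(23 / 27)
        assert denormalize_predictions(1.0, p27) == pytest.approx(27.0)
        assert denormalize_predictions(0.5, NormalizationParams(0, 24)) == pytest.approx(12.0)

    def test_round_trip_exact_on_examples(self):
        p = NormalizationParams(0, 27)
        y = np.array([0.0, 5.0, 23.0, 27.0])
        assert np.allclose(denormalize_predictions(normalize_labels(y, p), p), y,
                           atol=1e-12)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(y=st.floats(-5, 40, allow_nan=False),
           ymin=st.integers(0, 10), span=st.integers(1, 27))
    def test_round_trip_property(self, y, ymin, span):
        p = NormalizationParams(float(ymin), float(ymin + span))
        assert denormalize_predictions(normalize_labels(y, p), p) == pytest.approx(
            y, abs=1e-9)

    def test_metrics_invariant_under_normalization_round_trip(self, rng):
        """Denorm(norm(.)) is the identity, so PHQ-9-scale metrics are
        unchanged by the choice of (ymin, ymax)."""
        yt = rng.uniform(0, 27, 50)
        yp = yt + rng.normal(0, 3, 50)
        base = regression_metrics(yt, yp)
        for p in (NormalizationParams(0, 27), NormalizationParams(2, 19)):
            m = regression_metrics(yt, denormalize_predictions(
                normalize_labels(yp, p), p))
            assert m.mse == pytest.approx(base.mse, abs=1e-9)
            assert m.medae == pytest.approx(base.medae, abs=1e-9)


class TestCueTriplets:
    @staticmethod
    def _es(cue, n, sid=1, seed=0):
        rng = np.random.default_rng(seed)
        return EpochSet(rng.normal(size=(n, 2, 10)), fs=250.0, cue=cue,
                        subject_id=sid)

    def test_equal_counts(self):
        b = make_cue_triplets(self._es(Cue.hcue, 160), self._es(Cue.fcue, 160),
                              self._es(Cue.scue, 160))
        assert b.n == 160

    def test_min_count_policy_drops_excess(self):
        b = make_cue_triplets(self._es(Cue.hcue, 160), self._es(Cue.fcue, 158),
                              self._es(Cue.scue, 160))
        assert b.n == 158

    def test_by_index_pairs_ith_trials(self):
        h, f, s = (self._es(c, 5, seed=i) for i, c in enumerate(Cue))
        b = make_cue_triplets(h, f, s, policy="by_index")
        assert np.array_equal(b.x_happy[3], h.data[3])
        assert np.array_equal(b.x_sad[0], s.data[0])

    def test_shuffled_policy_reproducible_permutation(self):
        h, f, s = (self._es(c, 8, seed=i) for i, c in enumerate(Cue))
        a = make_cue_triplets(h, f, s, policy="shuffled", seed=5)
        b = make_cue_triplets(h, f, s, policy="shuffled", seed=5)
        assert np.array_equal(a.x_fear, b.x_fear)
        # same trials, possibly different order than by_index
        orig = {bytes(tr.astype(np.float32)) for tr in h.data}
        shuf = {bytes(tr.astype(np.float32)) for tr in a.x_happy}
        assert shuf <= orig

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValidationError, match="subject"):
            make_cue_triplets(self._es(Cue.hcue, 4), self._es(Cue.fcue, 4, sid=2),
                              self._es(Cue.scue, 4))

    def test_labels_from_record(self):
        rec = SubjectRecord(1, Group.MDD, Sex.F, 21)
        b = make_cue_triplets(self._es(Cue.hcue, 4), self._es(Cue.fcue, 4),
                              self._es(Cue.scue, 4), record=rec)
        assert set(b.labels_class) == {1}
        assert set(b.labels_score) == {21.0}
        assert set(b.subject_ids) == {1}


class TestTrainModel:
    def _batch(self, rng, n=40, C=4, T=125, separation=0.0):
        xs = [rng.normal(size=(n, C, T)).astype(np.float32) for _ in range(3)]
        labels = rng.integers(0, 2, n)
        for x in xs:
            x += separation * labels[:, None, None]
        return __import__("mceegnet").CueTripletBatch(
            *xs, labels_class=labels, labels_score=labels.astype(float),
            subject_ids=np.zeros(n, int))

    def test_history_bounded_and_best_weights_kept(self, rng):
        model = build_model(TINY_MODEL, seed=0)
        batch = self._batch(rng)
        cfg = TrainConfig(epochs=4, batch_size=16, seed=1, patience=None)
        model, hist = train_model(model, batch, cfg)
        assert len(hist["val_loss"]) <= 4
        assert len(hist["train_loss"]) == len(hist["val_loss"])

    def test_returned_weights_reproduce_min_val_loss(self, rng):
        from mceegnet.training import _batch_loss, _split_validation
        model = build_model(TINY_MODEL, seed=0)
        batch = self._batch(rng, n=60)
        cfg = TrainConfig(epochs=5, batch_size=16, seed=3, patience=None)
        model, hist = train_model(model, batch, cfg)
        # recompute the validation loss of the returned weights
        split_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7261)))
        _, val_idx = _split_validation(batch, cfg, True, split_rng)
        l, _, _ = _batch_loss(model, batch.subset(val_idx), "cross_entropy", False)
        assert l == pytest.approx(min(hist["val_loss"]), rel=1e-5)

    def test_deterministic_under_seed(self, rng):
        batch = self._batch(rng, n=32)
        cfg = TrainConfig(epochs=2, batch_size=16, seed=9)
        m1, h1 = train_model(build_model(TINY_MODEL, seed=5), batch, cfg)
        m2, h2 = train_model(build_model(TINY_MODEL, seed=5), batch, cfg)
        assert h1 == h2
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a.value, b.value)

    def test_tiny_validation_split_rejected(self, rng):
        model = build_model(TINY_MODEL, seed=0)
        batch = self._batch(rng, n=4)
        with pytest.raises(ContractError):
            train_model(model, batch, TrainConfig(val_fraction=0.05, seed=0))

    def test_joint_mode_trains_both_heads(self, rng):
        from dataclasses import replace
        cfg = replace(TINY_MODEL, mode="joint")
        model = build_model(cfg, seed=0)
        batch = self._batch(rng, n=32)
        model, hist = train_model(model, batch,
                                  TrainConfig(epochs=2, batch_size=16, seed=0,
                                              loss="joint"))
        out = model.forward(batch)
        assert "class_probs" in out and "scores" in out
        assert len(hist["val_loss"]) <= 2

    def test_learnable_separation_reaches_high_training_accuracy(self, rng):
        """400 well-separated triplets are fit to >=95% training accuracy."""
        batch = self._batch(np.random.default_rng(0), n=400, separation=2.0)
        model = build_model(TINY_MODEL, seed=0)
        model, _ = train_model(model, batch, TrainConfig(seed=0))
        preds = np.argmax(model.forward(batch)["class_probs"], axis=1)
        assert np.mean(preds == batch.labels_class) >= 0.95


@pytest.fixture(scope="module")
def six_subject_dataset():
    subs = simulate_cohort(TINY_SIM, n_mdd=3, n_hc=3, seed=1)
    return cohort_to_dataset(subs)


class TestLOSOCV:
    def test_fold_structure(self, six_subject_dataset):
        res = run_losocv(six_subject_dataset, FAST_TRAIN, task="classify",
                         model_cfg=TINY_MODEL)
        assert len(res.folds) == 6
        for f in res.folds:
            assert len(f.train_subjects) == 5
            assert f.held_out_subject not in f.train_subjects

    def test_no_subject_leakage_across_seeds(self, six_subject_dataset):
        for seed in (0, 1):
            cfg = TrainConfig(epochs=1, batch_size=16, seed=seed, val_fraction=0.2)
            res = run_losocv(six_subject_dataset, cfg, task="classify",
                             model_cfg=TINY_MODEL)
            for f in res.folds:
                train_ids = set()
                for sid in f.train_subjects:
                    train_ids |= set(six_subject_dataset.batches[sid].subject_ids)
                assert f.held_out_subject not in train_ids

    def test_regression_normalizer_is_fold_local(self, six_subject_dataset):
        """Each fold's (ymin, ymax) comes from its training subjects only."""
        res = run_losocv(six_subject_dataset, FAST_TRAIN, task="regress",
                         model_cfg=TINY_MODEL)
        by_id = {r.subject_id: r.phq9 for r in six_subject_dataset.records}
        for f in res.folds:
            train_scores = [by_id[s] for s in f.train_subjects]
            assert f.normalizer.ymin == min(train_scores)
            assert f.normalizer.ymax == max(train_scores)
            held_score = by_id[f.held_out_subject]
            # when the held-out subject is the unique extremum, its score
            # must not appear as a bound
            if held_score < min(train_scores) or held_score > max(train_scores):
                assert held_score not in (f.normalizer.ymin, f.normalizer.ymax)

    def test_full_cohort_yields_53_folds(self):
        """The packaged 53-subject cohort produces one fold per subject."""
        from mceegnet.data_io import packaged_subject_table
        from mceegnet.synthetic import simulate_subject
        recs = packaged_subject_table()
        cfg = SimConfig(n_channels=3, n_trials_per_cue=2, noise=(0.2, 0.2))
        subs = [simulate_subject(cfg, r, seed=0) for r in recs]
        ds = cohort_to_dataset(subs)
        mcfg = MCEEGNetConfig(branch=BranchConfig(
            n_channels=3, n_samples=125, f1=2, temporal_kernel=8,
            depth_multiplier=1, sep_kernel=4))
        res = run_losocv(ds, TrainConfig(epochs=1, batch_size=64, seed=0,
                                         val_fraction=0.1),
                         task="classify", model_cfg=mcfg)
        assert len(res.folds) == 53
        assert {f.held_out_subject for f in res.folds} == set(range(1, 54))

    def test_degenerate_training_class_rejected(self):
        cfg = SimConfig(n_channels=3, n_trials_per_cue=2)
        subs = simulate_cohort(cfg, n_mdd=2, n_hc=1, seed=0)
        ds = cohort_to_dataset(subs)
        mcfg = MCEEGNetConfig(branch=BranchConfig(
            n_channels=3, n_samples=125, f1=2, temporal_kernel=8,
            depth_multiplier=1, sep_kernel=4))
        with pytest.raises(DegenerateFoldError):
            run_losocv(ds, TrainConfig(epochs=1, seed=0, val_fraction=0.34),
                       task="classify", model_cfg=mcfg)

    def test_too_few_subjects_rejected(self):
        subs = simulate_cohort(TINY_SIM, n_mdd=1, n_hc=1, seed=0)
        with pytest.raises(ContractError):
            run_losocv(cohort_to_dataset(subs), FAST_TRAIN, task="classify",
                       model_cfg=TINY_MODEL)
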