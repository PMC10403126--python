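"""Image CNN and feature MLP: training contracts, prediction invariants,
penultimate-layer features, and leakage control."""

import numpy as np
import pandas as pd
import pytest

from moascreen.classifier import (ImageDataset, TrainedModel,
                                  extract_features, predict,
                                  train_classifier, train_feature_mlp)
from moascreen.config import ModelConfig
from moascreen.evaluation import macro_f1
from moascreen.experiments import build_image_dataset
from moascreen.preprocess import normalize_feature_table
from moascreen.splits import make_splits, partition_sites
from moascreen.synthetic import (feature_columns, generate_feature_table,
                                 generate_layout)
from conftest import small_screen


@pytest.fixture(scope="module")
def trained_cnn():
    """A CNN trained on a small separable screen, with its dataset."""
    cfg = small_screen(effect_size=8.0, seed=5, image_size=48)
    dataset = build_image_dataset(cfg, "FL")
    platemap = generate_layout(cfg)
    assignment = make_splits(platemap, n_splits=2, seed=6).assignments[0]
    mc = ModelConfig(input_channels=5, n_classes=4, conv_widths=(8, 16, 32),
                     epochs=12, patience=12, batch_size=16, seed=7)
    model = train_classifier(dataset, assignment, mc, cfg.class_labels)
    return cfg, dataset, assignment, model


class TestTrainClassifier:
    def test_high_effect_screen_learned(self, trained_cnn):
        cfg, dataset, assignment, model = trained_cnn
        meta = dataset.meta.assign(_row=np.arange(len(dataset.meta)))
        test = partition_sites(meta, assignment, "test")
        preds = predict(model, dataset.images[test._row.to_numpy()],
                        test.drop(columns="_row"))
        assert macro_f1(preds) >= 0.8

    def test_no_test_compound_in_training_log(self, trained_cnn):
        cfg, dataset, assignment, model = trained_cnn
        assert not model.trained_compounds & set(assignment.compounds("test"))
        assert model.trained_compounds <= set(assignment.compounds("train")) \
            | {"DMSO"}

    def test_single_batch_overfit(self, rng):
        """Capacity sanity: a single batch is memorized perfectly."""
        x = rng.standard_normal((8, 2, 8, 8)).astype(np.float32)
        y = np.array(["a", "b"] * 4)
        meta = pd.DataFrame({
            "plate_id": "P01", "well": [f"A{i:02d}" for i in range(8)],
            "site_index": 0, "compound_id": "c", "moa_label": y})
        from moascreen import nn
        from moascreen.classifier import _build_cnn, _fit
        mc = ModelConfig(input_channels=2, n_classes=2, conv_widths=(8,),
                         epochs=60, patience=60, batch_size=8, lr=1e-2,
                         augment=False, seed=1)
        net = _build_cnn(mc)
        yi = (y == "b").astype(int)
        _fit(net, x, yi, x, yi, mc, augment_images=False)
        pred = net.forward(x, train=False).argmax(axis=1)
        assert (pred == yi).all()

    def test_channel_mismatch_rejected(self, trained_cnn):
        cfg, dataset, assignment, model = trained_cnn
        bad = ImageDataset(images=dataset.images[:, :3], meta=dataset.meta)
        with pytest.raises(ValueError, match="channels"):
            train_classifier(bad, assignment, model.config, cfg.class_labels)

    def test_checkpoint_roundtrip(self, trained_cnn, tmp_path):
        cfg, dataset, _, model = trained_cnn
        model.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        x = dataset.images[:16]
        np.testing.assert_allclose(
            predict(model, x, dataset.meta.iloc[:16]).filter(like="prob_"),
            predict(loaded, x, dataset.meta.iloc[:16]).filter(like="prob_"))


class TestPredictionInvariants:
    def test_probability_simplex_and_argmax(self, trained_cnn):
        cfg, dataset, _, model = trained_cnn
        preds = predict(model, dataset.images[:40], dataset.meta.iloc[:40])
        probs = preds.filter(like="prob_").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()
        argmax_labels = [model.class_labels[i] for i in probs.argmax(axis=1)]
        assert (preds.pred_label == argmax_labels).all()

    def test_prediction_invariant_to_ordering(self, trained_cnn, rng):
        cfg, dataset, _, model = trained_cnn
        x = dataset.images[:30]
        meta = dataset.meta.iloc[:30].reset_index(drop=True)
        perm = rng.permutation(30)
        direct = predict(model, x, meta).filter(like="prob_").to_numpy()
        shuffled = predict(model, x[perm],
                           meta.iloc[perm]).filter(like="prob_").to_numpy()
        np.testing.assert_allclose(shuffled[np.argsort(perm)], direct,
                                   rtol=1e-6, atol=1e-8)


class TestEmbeddings:
    def test_dimension_and_determinism(self, trained_cnn):
        cfg, dataset, _, model = trained_cnn
        emb = extract_features(model, dataset.images[:10],
                               dataset.meta.iloc[:10])
        fcols = feature_columns(emb)
        assert len(fcols) == model.config.feature_dim
        twice = extract_features(model, dataset.images[:10],
                                 dataset.meta.iloc[:10])
        pd.testing.assert_frame_equal(emb, twice)
        # identical inputs -> identical embeddings
        dup = np.repeat(dataset.images[:1], 2, axis=0)
        e = extract_features(model, dup, dataset.meta.iloc[[0, 0]])
        np.testing.assert_array_equal(e[fcols].iloc[0], e[fcols].iloc[1])

    def test_linear_probe_on_embeddings(self, trained_cnn):
        """On separable synthetic data a linear probe on the penultimate
        features reaches high accuracy."""
        from sklearn.linear_model import LogisticRegression
        cfg, dataset, assignment, model = trained_cnn
        emb = extract_features(model, dataset.images, dataset.meta)
        fcols = feature_columns(emb)
        meta = emb.assign(_row=np.arange(len(emb)))
        train = partition_sites(meta, assignment, "train")
        test = partition_sites(meta, assignment, "test")
        probe = LogisticRegression(max_iter=2000).fit(
            train[fcols], train.moa_label)
        assert probe.score(test[fcols], test.moa_label) >= 0.9


class TestFeatureMlp:
    def _table(self, cfg):
        table = generate_feature_table(cfg)
        fcols = feature_columns(table)
        return normalize_feature_table(table, fcols), fcols

    def test_separated_features_high_f1(self):
        cfg = small_screen(effect_size=6.0, seed=8)
        table, fcols = self._table(cfg)
        assignment = make_splits(generate_layout(cfg), 2,
                                 seed=9).assignments[0]
        mc = ModelConfig(backbone="mlp", input_channels=len(fcols),
                         n_classes=4, hidden_dim=64, epochs=40, patience=40,
                         seed=10)
        model = train_feature_mlp(table, assignment, mc, fcols,
                                  cfg.class_labels)
        test = partition_sites(table, assignment, "test")
        preds = predict(model, test[fcols].to_numpy(),
                        test.drop(columns=fcols))
        assert macro_f1(preds) >= 0.95

    def test_label_permutation_drops_to_chance(self, rng):
        cfg = small_screen(effect_size=6.0, seed=8)
        table, fcols = self._table(cfg)
        table = table.copy()
        table["moa_label"] = rng.permutation(table.moa_label.to_numpy())
        assignment = make_splits(generate_layout(cfg), 2,
                                 seed=9).assignments[0]
        mc = ModelConfig(backbone="mlp", input_channels=len(fcols),
                         n_classes=4, hidden_dim=64, epochs=15, patience=15,
                         seed=10)
        model = train_feature_mlp(table, assignment, mc, fcols,
                                  cfg.class_labels)
        test = partition_sites(table, assignment, "test")
        preds = predict(model, test[fcols].to_numpy(),
                        test.drop(columns=fcols))
        assert macro_f1(preds) < 0.45

    def test_linearly_separable_toy_fits_perfectly(self):
        from moascreen.classifier import _build_mlp, _fit
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 0, 1, 1])
        mc = ModelConfig(backbone="mlp", input_channels=2, n_classes=2,
                         hidden_dim=8, epochs=200, patience=200, lr=1e-2,
                         batch_size=4, seed=2)
        net = _build_mlp(mc, d_in=2)
        _fit(net, x, y, x, y, mc, augment_images=False)
        assert (net.forward(x, train=False).argmax(axis=1) == y).all()

    def test_empty_partition_rejected(self):
        cfg = small_screen(seed=8)
        table, fcols = self._table(cfg)
        assignment = make_splits(generate_layout(cfg), 2,
                                 seed=9).assignments[0]
        broken = {c: ("test" if p != "test" else p)
                  for c, p in assignment.compound_partition.items()}
        assignment.compound_partition = broken
        # all-DMSO train partition still has wells; drop them too
        assignment.dmso_wells = {p: {"train": [], "val": [], "test": w["test"]}
                                 for p, w in assignment.dmso_wells.items()}
        mc = ModelConfig(backbone="mlp", input_channels=len(fcols),
                         n_classes=4, seed=1)
        with pytest.raises(ValueError, match="empty"):
            train_feature_mlp(table, assignment, mc, fcols, cfg.class_labels)
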