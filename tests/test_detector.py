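"""Temporal detector: embeddings, sinusoids, balanced batches, training."""

import numpy as np
import pytest

from budscan import (DetectorConfig, Detector, DivisionTimeline, MAEConfig,
                     balanced_batches, classify_stack, embed_frame,
                     embed_frames, predict_timeline, temporal_positional_table,
                     train_detector)

TINY_MAE = MAEConfig(encoder_dim=32, encoder_depth=1, encoder_heads=2,
                     decoder_dim=16, decoder_depth=1, decoder_heads=2, seed=0)


@pytest.fixture(scope="module")
def tiny_detector():
    cfg = DetectorConfig(temporal_dim=32, temporal_depth=1, temporal_heads=2,
                         n_members=2, seed=0)
    return Detector(TINY_MAE, cfg, seed=0)


class TestSinusoids:
    def test_position_zero_is_sin0_cos1(self):
        table = temporal_positional_table(11, 8)
        np.testing.assert_allclose(table[0, 0::2], 0.0)
        np.testing.assert_allclose(table[0, 1::2], 1.0)

    def test_rows_distinct_and_bounded(self):
        table = temporal_positional_table(50, 16)
        assert np.abs(table).max() <= 1.0
        assert len(np.unique(table.round(9), axis=0)) == 50

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            temporal_positional_table(11, 7)


class TestEmbedding:
    def test_identical_crops_identical_embeddings(self, tiny_detector, rng):
        crop = rng.random((64, 64)).astype(np.float32)
        e1 = embed_frame(tiny_detector.encoder, crop)
        e2 = embed_frame(tiny_detector.encoder, crop)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (TINY_MAE.encoder_dim,)

    def test_batch_embedding_matches_single(self, tiny_detector, rng):
        crops = rng.random((5, 64, 64)).astype(np.float32)
        batch = embed_frames(tiny_detector.encoder, crops)
        single = embed_frame(tiny_detector.encoder, crops[2])
        np.testing.assert_allclose(batch[2], single, atol=1e-6)

    def test_meanpool_embedding_differs_from_cls(self, tiny_detector, rng):
        crops = rng.random((3, 64, 64)).astype(np.float32)
        cls = embed_frames(tiny_detector.encoder, crops, mode="cls")
        pooled = embed_frames(tiny_detector.encoder, crops, mode="meanpool")
        assert cls.shape == pooled.shape == (3, TINY_MAE.encoder_dim)
        assert np.abs(cls - pooled).max() > 1e-4
        with pytest.raises(ValueError):
            embed_frames(tiny_detector.encoder, crops, mode="max")


class TestClassify:
    def test_probabilities_sum_to_one(self, tiny_detector, rng):
        emb = rng.standard_normal((11, TINY_MAE.encoder_dim)).astype(np.float32)
        p = classify_stack(tiny_detector, emb)
        assert p.shape == (2,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_logits_give_even_split(self, tiny_detector, rng):
        # zeroing every head projection forces logits (0, 0) -> (0.5, 0.5)
        for head in tiny_detector.heads:
            head.head.weight.data[:] = 0
            head.head.bias.data[:] = 0
        emb = rng.standard_normal((11, TINY_MAE.encoder_dim)).astype(np.float32)
        p = classify_stack(tiny_detector, emb)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-7)

    def test_wrong_window_length_rejected(self, tiny_detector, rng):
        emb = rng.standard_normal((1, 7, TINY_MAE.encoder_dim)).astype(np.float32)
        with pytest.raises(ValueError):
            tiny_detector.logits_from_embeddings(emb)


class TestBalancedBatches:
    def test_every_batch_half_and_half(self):
        labels = np.array([1] * 6 + [0] * 100)
        for batch in balanced_batches(labels, 8, seed=0):
            assert len(batch) == 8
            assert labels[batch].sum() == 4

    def test_majority_class_covered_each_epoch(self):
        labels = np.array([1] * 6 + [0] * 100)
        seen = set()
        for batch in balanced_batches(labels, 8, seed=1):
            seen.update(int(i) for i in batch if labels[i] == 0)
        assert seen == set(range(6, 106))

    def test_same_seed_same_stream(self):
        labels = np.array([1] * 5 + [0] * 37)
        a = [b.tolist() for b in balanced_batches(labels, 6, seed=3)]
        b = [b.tolist() for b in balanced_batches(labels, 6, seed=3)]
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            list(balanced_batches(np.zeros(10, dtype=int), 4, seed=0))


def test_config_validation_rejects_bad_values():
    for kwargs in ({"window": 10}, {"threshold": 0.0}, {"encoder_mode": "x"},
                   {"batch_size": 7}, {"temporal_dim": 33}, {"n_members": 0},
                   {"frame_embedding": "max"}, {"aggregate": "mode"},
                   {"ignore_margin": -1}, {"embedding_noise": -0.5}):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)


def _toy_cells(n_cells, rng, T=40):
    """Movies where a bright square flashes for 3 frames at each event."""
    cells = {}
    for i in range(n_cells):
        events = tuple(sorted(rng.choice(np.arange(5, T - 5), 4, replace=False).tolist()))
        events = tuple(e for j, e in enumerate(events)
                       if j == 0 or e - events[j - 1] >= 4)
        movie = rng.normal(0, 0.05, (T, 64, 64)).astype(np.float32)
        for e in events:
            movie[e:e + 3, 20:30, 34:44] += 1.0
        tl = DivisionTimeline(cell_id=f"t{i}", event_frames=events, n_frames=T)
        cells[f"t{i}"] = (movie, tl)
    return cells


class TestTrainPredict:
    @pytest.mark.parametrize("mode", ["frozen", "finetune"])
    def test_training_runs_and_loss_decreases(self, mode, rng):
        from budscan.pipeline import _labels_for
        cells = _toy_cells(4, rng)
        cfg = DetectorConfig(temporal_dim=32, temporal_depth=1, temporal_heads=2,
                             encoder_mode=mode, epochs=2, batch_size=8,
                             n_members=2 if mode == "finetune" else 1, seed=0)
        enc = Detector(TINY_MAE, cfg, seed=5).encoder
        train_data = {c: (m, _labels_for(t, len(m), 1)) for c, (m, t) in
                      list(cells.items())[:3]}
        val_data = {c: (m, t) for c, (m, t) in list(cells.items())[3:]}
        det, log = train_detector(train_data, val_data, enc.state_dict(),
                                  TINY_MAE, cfg)
        assert log.encoder_mode == mode
        assert log.train_loss[-1] < log.train_loss[0]

    def test_overlapping_train_val_cells_rejected(self, rng):
        cells = _toy_cells(2, rng)
        cfg = DetectorConfig(temporal_dim=32, temporal_depth=1, temporal_heads=2,
                             n_members=1, seed=0)
        enc = Detector(TINY_MAE, cfg, seed=5).encoder
        data = {c: (m, np.zeros(len(m), dtype=int)) for c, (m, t) in cells.items()}
        with pytest.raises(ValueError):
            train_detector(data, {c: (m, t) for c, (m, t) in cells.items()},
                           enc.state_dict(), TINY_MAE, cfg)

    def test_predict_timeline_shape_and_determinism(self, tiny_detector, rng):
        movie = rng.random((30, 64, 64)).astype(np.float32)
        p1 = predict_timeline(tiny_detector, movie, cell_id="x")
        p2 = predict_timeline(tiny_detector, movie, cell_id="x")
        assert p1.probs.shape == (30,)
        assert ((p1.probs >= 0) & (p1.probs <= 1)).all()
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_empty_movie_rejected(self, tiny_detector):
        with pytest.raises(ValueError):
            predict_timeline(tiny_detector, np.zeros((0, 64, 64)))
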