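"""Masked auto-encoder: patch mechanics, masking, schedules, training loop."""

import numpy as np
import pytest

from budscan import (MAE, MAEConfig, ema_update, lr_at, masked_mse,
                     mean_baseline_mse, patchify, pretrain, random_masking,
                     reconstruction_loss, restore_sequence, unpatchify)
from budscan.mae import _fixed_plans
from budscan.nn import Tensor


@pytest.fixture(scope="module")
def tiny_cfg():
    return MAEConfig(encoder_dim=32, encoder_depth=1, encoder_heads=2,
                     decoder_dim=16, decoder_depth=1, decoder_heads=2,
                     epochs=5, batch_size=32, warmup_steps=5, cycle_steps=20,
                     base_lr=2e-3, seed=0)


class TestPatchify:
    def test_sixty_four_patches_of_sixty_four_pixels(self, rng):
        img = rng.random((64, 64))
        patches = patchify(img, 8)
        assert patches.shape == (64, 64)

    @pytest.mark.parametrize("p,size", [(8, 64), (4, 16), (16, 64)])
    def test_unpatchify_inverts_patchify(self, rng, p, size):
        imgs = rng.random((3, size, size))
        np.testing.assert_array_equal(unpatchify(patchify(imgs, p), p, size), imgs)

    def test_constant_image_gives_identical_patches(self):
        patches = patchify(np.full((64, 64), 0.7), 8)
        assert (patches == patches[0]).all()

    def test_row_major_patch_order(self):
        img = np.zeros((16, 16))
        img[0:8, 8:16] = 1.0  # second patch of the first patch row
        patches = patchify(img, 8)
        assert patches[1].mean() == 1.0 and patches[0].mean() == 0.0

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((60, 60)), 8)


class TestMasking:
    def test_mask_counts(self, rng):
        plan = random_masking(64, 0.75, rng, batch=2)
        assert plan.n_visible == 16
        assert plan.mask_bool().sum(axis=1).tolist() == [48, 48]

    def test_ratio_zero_keeps_everything(self, rng):
        plan = random_masking(64, 0.0, rng)
        assert plan.n_visible == 64
        # shuffle followed by restore is the identity permutation
        restored = plan.shuffle_perm[0][plan.restore_indices[0]]
        np.testing.assert_array_equal(np.sort(restored), restored)

    def test_masking_frequency_uniform(self):
        rng = np.random.default_rng(0)
        P, ratio, draws = 16, 0.75, 10_000
        counts = np.zeros(P)
        for _ in range(draws):
            counts += random_masking(P, ratio, rng).mask_bool()[0]
        freq = counts / draws
        se = np.sqrt(ratio * (1 - ratio) / draws)
        assert (np.abs(freq - ratio) < 3 * se + 1e-9).all()

    def test_restore_round_trip_places_patches_at_origin(self, rng):
        # stub-decoder permutation test: visible token content must land at
        # its original grid index after mask-token insertion + unshuffle
        B, P, D = 2, 16, 4
        plan = random_masking(P, 0.5, rng, batch=B)
        content = np.tile(np.arange(P, dtype=np.float64)[None, :, None], (B, 1, D))
        visible = np.take_along_axis(content, plan.visible_indices[:, :, None], axis=1)
        restored = restore_sequence(Tensor(visible), Tensor(np.full((1, 1, D), -1.0)),
                                    plan).data
        vis_mask = ~plan.mask_bool()
        for b in range(B):
            for i in range(P):
                expected = i if vis_mask[b, i] else -1
                assert (restored[b, i] == expected).all()


class TestLossAndUpdates:
    def test_perfect_reconstruction_zero_loss(self, rng):
        img = rng.random((64, 64))
        plan = random_masking(64, 0.75, rng)
        assert reconstruction_loss(img, img, plan, 8) == 0.0

    def test_unit_offset_gives_unit_mse(self, rng):
        img = rng.random((64, 64))
        plan = random_masking(64, 0.75, rng)
        assert reconstruction_loss(img + 1.0, img, plan, 8) == pytest.approx(1.0)

    def test_error_on_visible_patch_ignored_under_masked_convention(self, rng):
        img = np.zeros((64, 64))
        plan = random_masking(64, 0.75, rng)
        vis_patch = plan.visible_indices[0, 0]
        patches = patchify(img.copy(), 8)
        patches[vis_patch] += 5.0
        pred = unpatchify(patches, 8, 64)
        assert reconstruction_loss(pred, img, plan, 8) == 0.0
        assert reconstruction_loss(pred, img, plan, 8, loss_on="all") > 0.0

    def test_ema_endpoints_and_geometric_closed_form(self):
        ema = {"w": np.full(3, 5.0)}
        cur = {"w": np.full(3, 1.0)}
        assert ema_update({"w": np.full(3, 5.0)}, cur, decay=0.0)["w"][0] == 1.0
        assert ema_update({"w": np.full(3, 5.0)}, cur, decay=1.0)["w"][0] == 5.0
        decay, k = 0.9, 7
        state = {"w": np.full(3, 5.0)}
        for _ in range(k):
            ema_update(state, cur, decay)
        expected = 1.0 + decay ** k * (5.0 - 1.0)
        np.testing.assert_allclose(state["w"], expected, rtol=1e-12)

    def test_lr_schedule_boundary_points(self, tiny_cfg):
        cfg = tiny_cfg
        assert lr_at(0, cfg) == 0.0
        assert lr_at(cfg.warmup_steps, cfg) == pytest.approx(cfg.base_lr)
        half = cfg.warmup_steps + cfg.cycle_steps // 2
        mid = cfg.min_lr + 0.5 * (cfg.base_lr - cfg.min_lr)
        assert lr_at(half, cfg) == pytest.approx(mid)
        restart = cfg.warmup_steps + cfg.cycle_steps
        assert lr_at(restart, cfg) == pytest.approx(cfg.base_lr)


class TestEncoderDecoder:
    def test_eval_determinism_and_token_count(self, tiny_cfg, rng):
        model = MAE(tiny_cfg, seed=1)
        imgs = rng.random((3, 64, 64)).astype(np.float32)
        plan = random_masking(tiny_cfg.n_patches, 0.75, rng, batch=3)
        patches = patchify(imgs, tiny_cfg.patch_size)
        out1 = model.encoder(patches, plan).data
        out2 = model.encoder(patches, plan).data
        np.testing.assert_array_equal(out1, out2)
        assert out1.shape == (3, 1 + plan.n_visible, tiny_cfg.encoder_dim)

    def test_latents_sensitive_to_pixels(self, tiny_cfg, rng):
        model = MAE(tiny_cfg, seed=1)
        imgs = rng.random((1, 64, 64)).astype(np.float32)
        patches = patchify(imgs, tiny_cfg.patch_size)
        base = model.encoder(patches).data
        perturbed = model.encoder(patches + 0.5).data
        assert np.abs(base - perturbed).max() > 1e-4

    def test_positional_embeddings_distinguish_positions(self, tiny_cfg):
        model = MAE(tiny_cfg, seed=1)
        const = np.full((1, 64, 64), 0.3, dtype=np.float32)
        tok = model.encoder(patchify(const, 8)).data[0, 1:]
        # identical patch content, distinct positions -> distinct tokens
        assert np.abs(tok[0] - tok[1]).max() > 1e-5

    def test_reconstruction_finite_for_random_weights(self, tiny_cfg, rng):
        model = MAE(tiny_cfg, seed=2)
        imgs = rng.random((2, 64, 64)).astype(np.float32)
        plan = random_masking(tiny_cfg.n_patches, 0.75, rng, batch=2)
        rec = model.reconstruct(imgs, plan)
        assert rec.shape == (2, 64, 64) and np.isfinite(rec).all()


class TestPretrain:
    def test_gradient_accumulation_matches_single_batch(self, tiny_cfg, rng):
        model = MAE(tiny_cfg, seed=3)
        imgs = rng.standard_normal((8, 64, 64)).astype(np.float32)
        plan = random_masking(tiny_cfg.n_patches, 0.75, rng, batch=8)
        params = model.parameters()

        model.zero_grad()
        model.loss(imgs, plan).backward()
        full = {k: p.grad.copy() for k, p in params.items()}

        import dataclasses
        from budscan.mae import MaskPlan
        model.zero_grad()
        k = 2
        for half in (slice(0, 4), slice(4, 8)):
            sub = MaskPlan(mask_ratio=plan.mask_ratio,
                           shuffle_perm=plan.shuffle_perm[half],
                           n_visible=plan.n_visible)
            (model.loss(imgs[half], sub) * (1.0 / k)).backward()
        for key in full:
            np.testing.assert_allclose(params[key].grad, full[key],
                                       rtol=2e-3, atol=2e-6)

    def test_tiny_pretrain_beats_untrained_and_logs_best(self, tiny_cfg, rng):
        imgs = np.stack([_blob(rng) for _ in range(240)])
        train, val = imgs[:200], imgs[200:]
        untrained = MAE(tiny_cfg, seed=0)
        plans = _fixed_plans(len(val), tiny_cfg, seed=11)
        before = masked_mse(untrained, val, plans)
        model, ema_state, log = pretrain(train, val, tiny_cfg)
        after = masked_mse(model, val, plans)
        assert after < before
        assert log.best_checkpoint == int(np.argmin(log.val_loss))
        assert set(ema_state) == set(model.state_dict())

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            pretrain(np.zeros((0, 64, 64)), np.zeros((2, 64, 64)), tiny_cfg)


def _blob(rng):
    """Small bright-disk image (structure learnable by a tiny model)."""
    rr, cc = np.mgrid[0:64, 0:64]
    r0, c0 = rng.uniform(24, 40, 2)
    img = 0.2 + 0.6 * (((rr - r0) ** 2 + (cc - c0) ** 2) < 100)
    return (img + rng.normal(0, 0.05, (64, 64))).astype(np.float32)


def test_checkpoint_reload_reproduces_loss_bitwise(tmp_path, rng):
    from budscan import load_checkpoint, save_checkpoint
    cfg = MAEConfig(encoder_dim=32, encoder_depth=1, encoder_heads=2,
                    decoder_dim=16, decoder_depth=1, decoder_heads=2, seed=4)
    model = MAE(cfg, seed=4)
    imgs = rng.random((4, 64, 64)).astype(np.float32)
    plan = random_masking(cfg.n_patches, 0.75, rng, batch=4)
    loss = model.loss(imgs, plan).data.item()
    save_checkpoint(tmp_path / "m.npz", model.state_dict(), mae_config=cfg)
    state, meta = load_checkpoint(tmp_path / "m.npz")
    model2 = MAE(meta["mae_config"], seed=99)
    model2.load_state_dict(state)
    assert model2.loss(imgs, plan).data.item() == loss
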