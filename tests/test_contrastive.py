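import numpy as np
import pytest

from spcl import nn
from spcl.augment import AugmentConfig, make_augmenter
from spcl.contrastive import (
    EmbeddingBatch, LossConfig, NetworkSpec, TrainConfig, build_networks,
    encode, forward_framework, infonce_reduction_check, make_momentum_state,
    momentum_update, pretrain, supcon_loss,
)
from spcl.errors import ConfigurationError, DataError, StructureError
from spcl.sampling import SamplerConfig, build_batch
from tests.conftest import noop_augmenter
from tests.oracles import brute_force_supcon, random_grouped_embeddings, reference_infonce

TINY = NetworkSpec(widths=(4, 8), seed=0)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestSupConLoss:
    def test_single_positive_pair_no_negatives_is_zero(self):
        z = np.stack([unit([1, 0]), unit([0.3, 1])])
        batch = EmbeddingBatch(z=z, group_ids=np.array([0, 0]))
        assert float(supcon_loss(batch).data) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_angled_groups(self):
        angles = np.deg2rad([0, 20, 150, 200])
        z = np.stack([np.array([np.cos(a), np.sin(a)]) for a in angles])
        groups = np.array([0, 0, 1, 1])
        ours = float(supcon_loss(EmbeddingBatch(z=z, group_ids=groups),
                                 cfg=LossConfig(tau=0.1)).data)
        assert ours == pytest.approx(brute_force_supcon(z, groups, 0.1), abs=1e-6)

    def test_decreases_as_within_group_similarity_rises(self):
        """Rotating group members together (between-group geometry fixed)."""
        losses = []
        for gap in np.deg2rad([60, 40, 20, 5]):
            z = np.stack([
                [np.cos(gap / 2), np.sin(gap / 2)],
                [np.cos(gap / 2), -np.sin(gap / 2)],
                [-np.cos(gap / 2), np.sin(gap / 2)],
                [-np.cos(gap / 2), -np.sin(gap / 2)],
            ])
            batch = EmbeddingBatch(z=z, group_ids=np.array([0, 0, 1, 1]))
            losses.append(float(supcon_loss(batch, cfg=LossConfig(0.1)).data))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        z, groups = random_grouped_embeddings(rng)
        a = float(supcon_loss(EmbeddingBatch(z=z, group_ids=groups)).data)
        perm = rng.permutation(len(z))
        b = float(supcon_loss(EmbeddingBatch(z=z[perm], group_ids=groups[perm])).data)
        assert a == pytest.approx(b, abs=1e-9)

    def test_collapse_closed_form_per_anchor(self):
        m, n_groups = 3, 4
        n = 2 * m * n_groups
        z = np.tile(unit([1, 2, 2]), (n, 1))
        groups = np.repeat(np.arange(n_groups), 2 * m)
        per = supcon_loss(EmbeddingBatch(z=z, group_ids=groups),
                          reduction="none").data
        assert np.allclose(per, np.log(2 * m * n_groups - 1), atol=1e-6)

    def test_non_normalized_embeddings_rejected(self):
        z = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 0.0], [0.0, -1.0]])
        with pytest.raises(StructureError):
            supcon_loss(EmbeddingBatch(z=z, group_ids=np.array([0, 0, 1, 1])))

    def test_anchor_without_positive_rejected(self):
        z = np.stack([unit([1, 0]), unit([0, 1]), unit([1, 1])])
        with pytest.raises(StructureError):
            supcon_loss(EmbeddingBatch(z=z, group_ids=np.array([0, 0, 1])))

    def test_gradient_matches_finite_difference_of_oracle(self):
        rng = np.random.default_rng(3)
        z, groups = random_grouped_embeddings(rng, max_views=10, dim=4)
        zt = nn.Tensor(z, requires_grad=True)
        supcon_loss(EmbeddingBatch(z=zt, group_ids=groups),
                    cfg=LossConfig(0.2)).backward()
        eps = 1e-6
        for (i, j) in [(0, 0), (2, 3), (len(z) - 1, 1)]:
            zp = z.copy()
            zp[i, j] += eps
            zm = z.copy()
            zm[i, j] -= eps
            fd = (brute_force_supcon(zp, groups, 0.2)
                  - brute_force_supcon(zm, groups, 0.2)) / (2 * eps)
            assert zt.grad[i, j] == pytest.approx(fd, abs=1e-6)


class TestInfoNCEReduction:
    def make_singleton_batch(self, rng, n_pairs=6, dim=6):
        z = rng.standard_normal((2 * n_pairs, dim))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        groups = np.repeat(np.arange(n_pairs), 2)
        positive_of = {}
        for g in range(n_pairs):
            positive_of[2 * g] = 2 * g + 1
            positive_of[2 * g + 1] = 2 * g
        return z, groups, positive_of

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_independent_infonce(self, seed):
        rng = np.random.default_rng(seed)
        z, groups, positive_of = self.make_singleton_batch(rng)
        ours = infonce_reduction_check(EmbeddingBatch(z=z, group_ids=groups),
                                       LossConfig(tau=0.5))
        assert ours == pytest.approx(reference_infonce(z, positive_of, 0.5), abs=1e-6)

    def test_saturated_softmax_limit(self):
        """Identical positives, orthogonal negatives, small tau: loss -> 0."""
        e = np.eye(4)
        z = np.stack([e[0], e[0], e[1], e[1], e[2], e[2]])
        groups = np.array([0, 0, 1, 1, 2, 2])
        loss = infonce_reduction_check(EmbeddingBatch(z=z, group_ids=groups),
                                       LossConfig(tau=0.01))
        assert loss < 1e-6

    def test_multi_positive_batch_rejected(self):
        z = np.eye(3)
        with pytest.raises(StructureError):
            infonce_reduction_check(EmbeddingBatch(z=z, group_ids=np.zeros(3)))


def tiny_patches(n, size=64, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
            for _ in range(n)]


def tiny_sampler(m=2):
    return SamplerConfig(large_size=64, small_size=32, M=m, seed=0)


class TestForwardFramework:
    def test_sinclr_counts(self):
        batch = build_batch(tiny_patches(4), tiny_sampler(2), noop_augmenter(),
                            "single")
        nets = build_networks(TINY, "sinclr")
        emb, loss = forward_framework(batch, nets, "sinclr")
        assert emb.z.shape[0] == 8
        from spcl.sampling import build_pair_index
        index = build_pair_index(batch)
        assert all(len(p) == 1 for p in index.positives)
        assert all(len(index.candidates(i)) == 7 for i in range(8))
        assert np.isfinite(loss.data)

    def test_branch_mismatch_errors(self):
        batch = build_batch(tiny_patches(4), tiny_sampler(2), noop_augmenter(),
                            "single")
        nets = build_networks(TINY, "spsimclr")
        with pytest.raises(ConfigurationError):
            forward_framework(batch, nets, "spsimclr")

    def test_embeddings_unit_norm(self):
        batch = build_batch(tiny_patches(3), tiny_sampler(2), noop_augmenter(),
                            "dual")
        nets = build_networks(TINY, "spsimclr")
        emb, _ = forward_framework(batch, nets, "spsimclr")
        assert np.allclose(np.linalg.norm(emb.z, axis=1), 1.0, atol=1e-8)

    def test_simsiam_stop_gradient_path_gets_no_gradient(self):
        """Backward through the SimSiam loss must not reach the target branch."""
        z = nn.Tensor(np.random.default_rng(0).standard_normal((4, 3)),
                      requires_grad=True)
        zn = nn.l2_normalize(z)
        target = zn.detach()
        pos = np.array([[0, 1, 0, 0], [1, 0, 0, 0],
                        [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float)
        loss = -((zn @ target.T) * pos).sum() * (1.0 / pos.sum())
        loss.backward()
        assert target.grad is None
        assert z.grad is not None

    def test_simsiam_loss_is_mean_negative_cosine(self):
        batch = build_batch(tiny_patches(3), tiny_sampler(2), noop_augmenter(),
                            "dual")
        nets = build_networks(TINY, "spsimsiam")
        _, loss = forward_framework(batch, nets, "spsimsiam")
        assert -1.0 - 1e-9 <= float(loss.data) <= 1.0 + 1e-9


class TestMomentum:
    def test_m0_copies_online_and_m1_freezes(self):
        nets = build_networks(TINY, "spmoco_v3")
        for m, should_track in ((0.0, True), (1.0, False)):
            state = make_momentum_state(nets, m=m)
            before = {k: v.copy() for k, v in state.target_encoder.state_dict().items()}
            for p in nets.encoder.parameters():
                p.data = p.data + 1.0
            momentum_update(nets, state)
            after = state.target_encoder.state_dict()
            online = nets.encoder.state_dict()
            for name, val in after.items():
                if "running" in name:
                    continue
                if should_track:
                    assert np.allclose(val, online[name])
                else:
                    assert np.allclose(val, before[name])

    def test_ema_arithmetic(self):
        nets = build_networks(TINY, "spmoco_v3")
        state = make_momentum_state(nets, m=0.99)
        name, p_online = next(iter(nets.encoder.named_parameters()))
        p_target = dict(state.target_encoder.named_parameters())[name]
        p_target.data = np.ones_like(p_target.data)
        p_online.data = np.zeros_like(p_online.data)
        momentum_update(nets, state)
        assert np.allclose(dict(state.target_encoder.named_parameters())[name].data,
                           0.99)

    def test_m1_target_unchanged_after_training_step(self):
        nets = build_networks(TINY, "spmoco_v3")
        state = make_momentum_state(nets, m=1.0)
        before = {k: v.copy() for k, v in state.target_encoder.state_dict().items()
                  if "running" not in k}
        batch = build_batch(tiny_patches(4), tiny_sampler(2), noop_augmenter(),
                            "dual")
        _, loss = forward_framework(batch, nets, "spmoco_v3", momentum=state)
        opt = nn.Adam(nets.parameters(), lr=0.01)
        opt.zero_grad()
        loss.backward()
        opt.step()
        momentum_update(nets, state)
        after = state.target_encoder.state_dict()
        for name, val in before.items():
            assert np.array_equal(val, after[name])


class TestPretrain:
    def test_deterministic_loss_traces(self):
        patches = tiny_patches(8)
        cfg = TrainConfig(framework="sinclr", batch_N=4, epochs=2, seed=7)
        aug = AugmentConfig(out_size=32, seed=0)
        r1 = pretrain(patches, tiny_sampler(2), make_augmenter(aug), TINY, cfg)
        r2 = pretrain(patches, tiny_sampler(2), make_augmenter(aug), TINY, cfg)
        assert r1.loss_trace == r2.loss_trace
        assert np.array_equal(
            encode(r1, np.stack(tiny_patches(3, 32, seed=5))),
            encode(r2, np.stack(tiny_patches(3, 32, seed=5))))

    def test_training_reduces_loss_on_structured_data(self, library4):
        """Loss over the final quarter of steps drops below the first quarter
        for a majority of seeds (textured slides, single-branch training)."""
        from spcl.pipeline import DeskConfig, gather_large_patches, make_slides
        import dataclasses
        cfg = dataclasses.replace(DeskConfig(), n_slides=3, epochs=4)
        wins = 0
        for seed in range(1, 6):
            slides = make_slides(seed, cfg)
            patches = gather_large_patches(slides, "tiles", seed, cfg)[:48]
            tcfg = TrainConfig(framework="sinclr", batch_N=8, epochs=4,
                               lr=3e-3, seed=seed)
            aug = make_augmenter(cfg.augment)
            res = pretrain(patches, SamplerConfig(64, 32, M=4, seed=seed),
                           aug, NetworkSpec(widths=(8, 16, 32)), tcfg)
            q = len(res.loss_trace) // 4
            wins += np.mean(res.loss_trace[-q:]) < np.mean(res.loss_trace[:q])
        assert wins >= 3

    def test_simsiam_trace_within_cosine_range(self):
        patches = tiny_patches(6)
        cfg = TrainConfig(framework="spsimsiam", batch_N=3, epochs=2, seed=1)
        aug = make_augmenter(AugmentConfig(out_size=32, seed=0))
        res = pretrain(patches, tiny_sampler(2), aug, TINY, cfg)
        assert all(-1.0 - 1e-9 <= v <= 1.0 + 1e-9 for v in res.loss_trace)

    def test_empty_manifest_errors(self):
        cfg = TrainConfig(framework="sinclr", batch_N=2, epochs=1)
        with pytest.raises(DataError):
            pretrain([], tiny_sampler(), noop_augmenter(), TINY, cfg)


class TestEncode:
    def test_shapes_duplicates_and_determinism(self):
        patches = tiny_patches(6)
        cfg = TrainConfig(framework="sinclr", batch_N=3, epochs=1, seed=0)
        res = pretrain(patches, tiny_sampler(2),
                       make_augmenter(AugmentConfig(out_size=32, seed=0)),
                       TINY, cfg)
        stack = np.stack(tiny_patches(4, size=32, seed=9))
        stack[1] = stack[0]
        feats = encode(res, stack)
        assert feats.shape == (4, TINY.feature_dim)
        assert np.array_equal(feats[0], feats[1])
        assert np.array_equal(feats, encode(res, stack))


class TestCheckpointIO:
    def test_round_trip_preserves_encodings(self, tmp_path):
        from spcl.contrastive import load_checkpoint, save_checkpoint
        patches = tiny_patches(4)
        cfg = TrainConfig(framework="sinclr", batch_N=2, epochs=1, seed=3)
        res = pretrain(patches, tiny_sampler(2),
                       make_augmenter(AugmentConfig(out_size=32, seed=0)),
                       TINY, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(res, path)
        loaded = load_checkpoint(path)
        stack = np.stack(tiny_patches(3, size=32, seed=2))
        assert np.array_equal(encode(res, stack), encode(loaded, stack))
        assert loaded.loss_trace == res.loss_trace
        assert loaded.config == cfg
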