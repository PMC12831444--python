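import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spcl.errors import ParameterError
from spcl.sampling import (
    SamplerConfig, build_batch, build_pair_index, pair_counts, sample_boxes,
)
from tests.conftest import noop_augmenter


def boxes_disjoint(a, b):
    (ax, ay, s), (bx, by, _) = a, b
    return ax + s <= bx or bx + s <= ax or ay + s <= by or by + s <= ay


class TestSampleBoxes:
    def test_overlapping_within_bounds(self):
        cfg = SamplerConfig(large_size=64, small_size=32, M=6, seed=1)
        for (x, y, s) in sample_boxes(cfg):
            assert 0 <= x <= 32 and 0 <= y <= 32 and s == 32

    def test_nonoverlapping_disjoint(self):
        cfg = SamplerConfig(large_size=512, small_size=128, M=4,
                            mode="nonoverlapping", seed=2)
        boxes = sample_boxes(cfg)
        assert len(boxes) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert boxes_disjoint(boxes[i], boxes[j])

    def test_dense_nonoverlapping_packing(self):
        """A quarter-density config packs 4 disjoint boxes reliably."""
        cfg = SamplerConfig(large_size=256, small_size=64, M=4,
                            mode="nonoverlapping", max_attempts=5000, seed=3)
        boxes = sample_boxes(cfg)
        assert sum(s * s for (_, _, s) in boxes) == 4 * 64 * 64
        for i in range(4):
            for j in range(i + 1, 4):
                assert boxes_disjoint(boxes[i], boxes[j])

    def test_infeasible_area_errors_before_sampling(self):
        cfg = SamplerConfig(large_size=128, small_size=128, M=2,
                            mode="nonoverlapping")
        with pytest.raises(ParameterError):
            sample_boxes(cfg)

    def test_deterministic_given_seed(self):
        cfg = SamplerConfig(large_size=96, small_size=32, M=4,
                            mode="nonoverlapping", seed=9)
        assert sample_boxes(cfg) == sample_boxes(cfg)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(2, 5), st.integers(0, 1000), st.sampled_from([16, 32]))
    def test_disjointness_property(self, m, seed, small):
        cfg = SamplerConfig(large_size=160, small_size=small, M=m,
                            mode="nonoverlapping", max_attempts=500, seed=seed)
        boxes = sample_boxes(cfg)
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                assert boxes_disjoint(boxes[i], boxes[j])

    def test_overlapping_mode_produces_overlaps_eventually(self):
        cfg = SamplerConfig(large_size=40, small_size=32, M=8, seed=5)
        boxes = sample_boxes(cfg)
        hits = sum(not boxes_disjoint(boxes[i], boxes[j])
                   for i in range(8) for j in range(i + 1, 8))
        assert hits > 0


class TestPairCounts:
    @pytest.mark.parametrize("m,n,mode,expected", [
        (4, 8, "dual", (7, 56)),
        (4, 8, "single", (3, 28)),
        (2, 2, "single", (1, 2)),
        (2, 2, "dual", (3, 4)),
    ])
    def test_values(self, m, n, mode, expected):
        assert pair_counts(m, n, mode) == expected

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            pair_counts(1, 4, "dual")
        with pytest.raises(ParameterError):
            pair_counts(4, 1, "dual")


class TestBuildBatch:
    def constant_patches(self, n, size=64):
        return [np.full((size, size, 3), 10 * g, dtype=np.uint8) for g in range(n)]

    def test_dual_counts(self):
        cfg = SamplerConfig(large_size=64, small_size=32, M=4, seed=0)
        batch = build_batch(self.constant_patches(8), cfg, noop_augmenter(), "dual")
        assert len(batch) == 2 * 4 * 8
        values, counts = np.unique(batch.group_ids, return_counts=True)
        assert len(values) == 8 and set(counts) == {8}

    def test_single_counts(self):
        cfg = SamplerConfig(large_size=64, small_size=32, M=4, seed=0)
        batch = build_batch(self.constant_patches(8), cfg, noop_augmenter(), "single")
        assert len(batch) == 4 * 8
        _, counts = np.unique(batch.group_ids, return_counts=True)
        assert set(counts) == {4}

    def test_identity_augmenter_views_are_source_crops(self):
        """With constant-valued patches, each no-op view betrays its source."""
        cfg = SamplerConfig(large_size=64, small_size=32, M=2, seed=0)
        batch = build_batch(self.constant_patches(2), cfg, noop_augmenter(), "dual")
        for view, g in zip(batch.views, batch.group_ids):
            assert np.allclose(view, 10 * g / 255.0)

    def test_too_few_patches_errors(self):
        cfg = SamplerConfig(large_size=64, small_size=32, M=2)
        with pytest.raises(ParameterError):
            build_batch(self.constant_patches(1), cfg, noop_augmenter(), "dual")

    def test_mixed_sizes_error(self):
        cfg = SamplerConfig(large_size=64, small_size=32, M=2)
        patches = self.constant_patches(1) + [np.zeros((48, 48, 3), np.uint8)]
        with pytest.raises(ParameterError):
            build_batch(patches, cfg, noop_augmenter(), "dual")


class TestPairIndex:
    def make_batch(self, m, n, mode):
        cfg = SamplerConfig(large_size=64, small_size=32, M=m, seed=1)
        patches = [np.zeros((64, 64, 3), np.uint8) for _ in range(n)]
        return build_batch(patches, cfg, noop_augmenter(), mode)

    @pytest.mark.parametrize("m,n,mode", [(2, 2, "dual"), (4, 3, "single"),
                                          (3, 5, "dual")])
    def test_cardinalities_match_formulas(self, m, n, mode):
        batch = self.make_batch(m, n, mode)
        index = build_pair_index(batch)
        pos, neg = pair_counts(m, n, mode)
        for i in range(index.n):
            assert len(index.positives[i]) == pos
            assert len(index.candidates(i)) == pos + neg

    def test_count_conservation(self):
        batch = self.make_batch(3, 4, "dual")
        index = build_pair_index(batch)
        pos, _ = pair_counts(3, 4, "dual")
        assert sum(len(p) for p in index.positives) == index.n * pos
        # symmetry: each view is a positive of exactly `pos` anchors
        assert np.all(index.pos_mask.sum(axis=0) == pos)

    def test_permutation_consistency(self):
        batch = self.make_batch(2, 3, "dual")
        index = build_pair_index(batch)
        perm = np.random.default_rng(0).permutation(index.n)
        inv = np.argsort(perm)
        batch.group_ids = batch.group_ids[perm]
        shuffled = build_pair_index(batch)
        for i in range(index.n):
            # new index j holds old view perm[j], so map back with perm
            assert sorted(perm[shuffled.positives[inv[i]]].tolist()) == \
                sorted(index.positives[i].tolist())

    def test_candidate_count_minimal_dual(self):
        index = build_pair_index(self.make_batch(2, 2, "dual"))
        for i in range(index.n):
            assert len(index.candidates(i)) == 2 * 2 * 2 * 2 // 2 - 1  # 2MN-1 = 7


class TestSamplerConfigValidation:
    def test_invariants(self):
        with pytest.raises(ParameterError):
            SamplerConfig(large_size=32, small_size=64)
        with pytest.raises(ParameterError):
            SamplerConfig(large_size=64, small_size=32, M=1)
        with pytest.raises(ParameterError):
            SamplerConfig(large_size=64, small_size=32, mode="diagonal")
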