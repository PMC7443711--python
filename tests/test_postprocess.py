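"""Output processing: thresholds, 26-connected labeling, body means, stats."""

import numpy as np
import pandas as pd
import pytest

from paovox import postprocess as pp


def brute_force_label(mask):
    """Flood-fill 26-connected labeling, independent of scipy."""
    mask = np.asarray(mask) > 0
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= q[i] < mask.shape[i] for i in range(3)):
                    if mask[q] and not labels[q]:
                        labels[q] = nxt
                        stack.append(q)
    return labels


class TestThresholds:
    def test_low_threshold_boundary_kept(self):
        v = np.array([[[0.1, 0.2, 0.9]]])
        out = pp.threshold_low(v, 0.2)
        assert out.ravel().tolist() == [0.0, 0.2, 0.9]

    def test_zero_threshold_identity_on_nonnegative(self):
        v = np.random.default_rng(0).random((3, 3, 3))
        assert np.array_equal(pp.threshold_low(v, 0.0), v)

    def test_all_zero_stays_zero(self):
        assert pp.threshold_low(np.zeros((2, 2, 2))).sum() == 0.0

    def test_confident_threshold_examples(self):
        v = np.array([[[0.5, 1.0, 1.3]]])
        out = pp.threshold_confident(v)
        assert out.ravel().tolist() == [0.0, 1.0, 1.3]

    def test_confident_idempotent(self):
        v = np.random.default_rng(1).random((4, 4, 4)) * 2
        once = pp.threshold_confident(v)
        assert np.array_equal(pp.threshold_confident(once), once)

    def test_no_confident_voxels_is_legitimate(self):
        v = np.full((3, 3, 3), 0.5)
        v2 = pp.threshold_confident(v)
        assert v2.sum() == 0.0
        table = pp.mean_vessel_so2(pp.masked_labels(pp.label_bodies(v), v2), v)
        assert len(table) == 0


class TestLabeling:
    def test_two_disjoint_cubes(self):
        v = np.zeros((8, 8, 8))
        v[1:3, 1:3, 1:3] = 1.0
        v[5:7, 5:7, 5:7] = 1.0
        labels = pp.label_bodies(v)
        assert labels.max() == 2

    def test_corner_touching_voxels_connected_under_26(self):
        v = np.zeros((4, 4, 4))
        v[1, 1, 1] = 1.0
        v[2, 2, 2] = 1.0
        assert pp.label_bodies(v, connectivity=26).max() == 1
        assert pp.label_bodies(v, connectivity=6).max() == 2

    def test_empty_volume(self):
        assert pp.label_bodies(np.zeros((3, 3, 3))).max() == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            pp.label_bodies(np.ones((2, 2, 2)), connectivity=4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < 0.15
        got = pp.label_bodies(mask.astype(float))
        ref = brute_force_label(mask)
        assert got.max() == ref.max()
        # identical partitions up to label permutation
        for k in range(1, ref.max() + 1):
            assert len(np.unique(got[ref == k])) == 1


class TestMaskedLabels:
    def test_identity_when_mask_covers_support(self):
        v1 = np.zeros((4, 4, 4))
        v1[1:3, 1:3, 1:3] = 1.5
        L = pp.label_bodies(v1)
        assert np.array_equal(pp.masked_labels(L, v1), L)

    def test_split_body_retains_original_label(self):
        v1 = np.zeros((1, 1, 6))
        v1[0, 0, :] = [1.5, 1.5, 0.4, 0.4, 1.5, 1.5]
        v1 = pp.threshold_low(v1)  # all survive (>= 0.2)
        L = pp.label_bodies(v1)
        assert L.max() == 1  # one connected body
        v2 = pp.threshold_confident(v1)  # middle voxels drop below 1
        lv = pp.masked_labels(L, v2)
        assert set(np.unique(lv)) == {0, 1}
        assert (lv[0, 0, [0, 1, 4, 5]] == 1).all()
        assert (lv[0, 0, [2, 3]] == 0).all()

    def test_empty_mask_empties_labels(self):
        L = np.ones((3, 3, 3), dtype=np.int32)
        assert pp.masked_labels(L, np.zeros((3, 3, 3))).sum() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_label_retention_against_brute_force(self, seed):
        # every surviving voxel keeps exactly the label of its original body
        rng = np.random.default_rng(100 + seed)
        V = rng.random((8, 8, 8)) * 1.4
        vols = pp.segmentation_volumes(V)
        ref = brute_force_label(vols.V1)
        for z, y, x in zip(*np.nonzero(vols.Lv)):
            mates = vols.L == vols.Lv[z, y, x]
            assert len(np.unique(ref[mates])) == 1
        assert set(np.unique(vols.Lv)) <= set(np.unique(vols.L))

    def test_confidence_monotonicity(self):
        rng = np.random.default_rng(5)
        V = rng.random((8, 8, 8)) * 1.4
        v1 = pp.threshold_low(V)
        L = pp.label_bodies(v1)
        counts = []
        for t in (0.8, 1.0, 1.2):
            lv = pp.masked_labels(L, pp.threshold_low(v1, t))
            counts.append((lv > 0).sum())
        assert counts[0] >= counts[1] >= counts[2]


class TestBodyMeans:
    def test_simple_mean(self):
        lv = np.zeros((1, 1, 3), dtype=int)
        lv[0, 0, :] = 1
        so2 = np.array([[[0.5, 0.6, 0.7]]])
        table = pp.mean_vessel_so2(lv, so2)
        assert table.loc[0, "est_mean_so2"] == pytest.approx(0.6)

    def test_constant_map(self):
        lv = np.zeros((4, 4, 4), dtype=int)
        lv[:2] = 1
        lv[3:] = 2
        so2 = np.full(lv.shape, 0.42)
        table = pp.mean_vessel_so2(lv, so2)
        assert np.allclose(table["est_mean_so2"], 0.42)

    def test_random_body_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        lv = np.zeros((6, 6, 6), dtype=int)
        flat = rng.choice(216, size=20, replace=False)
        lv.ravel()[flat] = 1
        so2 = rng.random((6, 6, 6))
        table = pp.mean_vessel_so2(lv, so2, clip=False)
        acc = [so2[z, y, x] for z, y, x in zip(*np.nonzero(lv))]
        assert table.loc[0, "est_mean_so2"] == pytest.approx(np.mean(acc))
        assert table.loc[0, "n_voxels"] == 20

    def test_estimates_clipped_to_unit_interval(self):
        lv = np.ones((1, 1, 2), dtype=int)
        so2 = np.array([[[-0.5, 1.5]]])
        table = pp.mean_vessel_so2(lv, so2)
        assert table.loc[0, "est_mean_so2"] == pytest.approx(0.5)

    def test_depth_is_mean_voxel_depth(self):
        lv = np.zeros((10, 1, 1), dtype=int)
        lv[[2, 4], 0, 0] = 1
        table = pp.mean_vessel_so2(lv, np.ones(lv.shape), dx_mm=0.1)
        assert table.loc[0, "depth_mm"] == pytest.approx(0.1 * (2.5 + 4.5) / 2)


class TestEvaluate:
    def _table(self, pairs):
        return pd.DataFrame(
            [
                {
                    "image_id": 0,
                    "body_id": i + 1,
                    "n_voxels": 5,
                    "depth_mm": 1.0,
                    "est_mean_so2": e,
                    "true_mean_so2": t,
                }
                for i, (e, t) in enumerate(pairs)
            ]
        )

    def test_perfect_estimates(self):
        rep = pp.evaluate(self._table([(0.3, 0.3), (0.8, 0.8)]))
        assert rep.mae == 0.0 and rep.sd_abs == 0.0 and rep.mean_diff == 0.0

    def test_symmetric_errors_hand_arithmetic(self):
        rep = pp.evaluate(self._table([(0.55, 0.5), (0.45, 0.5)]))
        assert rep.mae == pytest.approx(5.0)
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.sd_diff == pytest.approx(7.0710678118654755)

    def test_empty_flagged(self):
        rep = pp.evaluate(pd.DataFrame())
        assert rep.empty and rep.n_bodies == 0

    def test_permuted_estimates_unbiased_but_inaccurate(self):
        true = [0.2, 0.5, 0.8]
        est = [0.5, 0.8, 0.2]
        rep = pp.evaluate(self._table(list(zip(est, true))))
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.mae > 0


class TestGtMasked:
    def _model_like(self):
        body = np.zeros((8, 8, 8), dtype=np.int32)
        body[2:4, 2:4, 2:4] = 1
        body[6:8, 5:7, 5:7] = 2
        so2 = np.zeros(body.shape)
        so2[body == 1] = 0.3
        so2[body == 2] = 0.7
        return body, so2

    def test_perfect_map_zero_error(self):
        body, so2 = self._model_like()
        rep = pp.evaluate_gt_masked([so2], [body], [so2])
        assert rep.mae == 0.0

    def test_constant_bias_gives_exact_offset(self):
        body, so2 = self._model_like()
        est = so2 + 0.1 * (body > 0)
        rep = pp.evaluate_gt_masked([est], [body], [so2])
        assert rep.mae == pytest.approx(10.0)
        assert rep.mean_diff == pytest.approx(10.0)


class TestDepthProfile:
    def test_single_depth_single_bin(self):
        t = pd.DataFrame(
            {
                "depth_mm": [1.0, 1.0],
                "est_mean_so2": [0.4, 0.6],
                "true_mean_so2": [0.5, 0.5],
            }
        )
        prof, rho, _ = pp.depth_profile(t, n_bins=3)
        assert prof["n_bodies"].sum() == 2
        assert np.isnan(rho)

    def test_linear_error_growth_perfect_trend(self):
        depth = np.linspace(0.5, 3.0, 12)
        t = pd.DataFrame(
            {
                "depth_mm": depth,
                "est_mean_so2": 0.5 + 0.01 * depth,
                "true_mean_so2": 0.5,
            }
        )
        _, rho, p = pp.depth_profile(t, n_bins=4)
        assert rho == pytest.approx(1.0)
        assert p < 0.01


class TestUnmixingBaseline:
    def test_recovers_so2_from_pure_absorption_images(self):
        a_hb = {784.0: 5.2, 820.0: 3.8}
        a_hbo2 = {784.0: 4.0, 820.0: 4.9}
        s = np.array([[[0.0, 0.3, 0.7, 1.0]]])
        amp = 2.0
        img = np.stack(
            [
                amp * ((1 - s) * a_hb[l] + s * a_hbo2[l])
                for l in (784.0, 820.0)
            ]
        )
        est = pp.linear_unmixing_so2(img, (784.0, 820.0), a_hb, a_hbo2)
        assert est == pytest.approx(s[..., :], abs=1e-9)
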