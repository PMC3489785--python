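import numpy as np
import pytest

from hmaxbp.bp_core import StructuralError, validate_cpt
from hmaxbp.learning import (DatasetTooSmallError, LearningConfig,
                             extract_thresholded_patches, group_sum,
                             learn_invariance_cpts,
                             learn_s3_supervised,
                             learn_selectivity_prototypes,
                             weights_to_cpt_invariance,
                             weights_to_cpt_selectivity)


class TestPatchExtraction:
    def test_all_zero_map_yields_nothing(self):
        assert len(extract_thresholded_patches(np.zeros((6, 6)), 3, 0.1)) == 0

    def test_single_peak_selects_covering_windows(self):
        m = np.zeros((7, 7))
        m[3, 3] = 1.0
        patches = extract_thresholded_patches(m, 3, 0.5)
        assert len(patches) == 9  # the 3x3 windows containing the peak

    def test_negative_threshold_keeps_everything(self):
        m = np.zeros((5, 5))
        patches = extract_thresholded_patches(m, 3, -1.0)
        assert len(patches) == 9


class TestInvarianceCpt:
    def test_unit_weight_pins_child_state(self):
        centres = np.ones((2, 1, 1, 1))  # one centre per state, w = 1
        cpt = weights_to_cpt_invariance(centres, 2)
        np.testing.assert_allclose(cpt[0, 0, :, 0], [1.0, 0.0])

    def test_zero_weight_gives_flat_column(self):
        centres = np.zeros((2, 1, 1, 1))
        cpt = weights_to_cpt_invariance(centres, 2)
        np.testing.assert_allclose(cpt[0, 0, :, 0], [0.5, 0.5])

    def test_half_weight_interpolates(self):
        centres = np.full((4, 1, 1, 1), 0.5)
        cpt = weights_to_cpt_invariance(centres, 4)
        np.testing.assert_allclose(cpt[0, 0, :, 0],
                                   [0.625, 0.125, 0.125, 0.125])

    def test_columns_are_distributions(self):
        rng = np.random.default_rng(0)
        centres = rng.random((3, 4, 5, 5))
        cpt = weights_to_cpt_invariance(centres, 3)
        for i in range(5):
            for j in range(5):
                validate_cpt(cpt[i, j])

    def test_toy_row_indicators_reproduce_printed_columns(self, toy):
        # three horizontal-bar centres (rows 0, 1, 2) and three vertical
        # ones reproduce the fixture's hand-built tables
        centres = np.zeros((2, 3, 3, 3))
        for r in range(3):
            centres[0, r, r, :] = 1.0   # horizontal line at row r
            centres[1, r, :, r] = 1.0   # vertical line at column r
        cpt = weights_to_cpt_invariance(centres, 2)
        np.testing.assert_allclose(cpt, toy.model.cpts["S1"])


class TestInvarianceLearning:
    def test_recovers_planted_centres(self):
        rng = np.random.default_rng(0)
        a = np.zeros((3, 3))
        a[0] = 1.0
        b = np.zeros((3, 3))
        b[:, 2] = 1.0
        maps = []
        for _ in range(40):
            which = a if rng.random() < 0.5 else b
            maps.append(np.clip(which + rng.normal(0, 0.01, (3, 3)), 0, 1))
        centres, cpts = learn_invariance_cpts(
            {0: maps}, 3, 2, 1, LearningConfig(rng_seed=0,
                                               patch_threshold=0.5))
        got = sorted(centres[0].reshape(2, -1).tolist())
        want = sorted([a.ravel().tolist(), b.ravel().tolist()])
        np.testing.assert_allclose(got, want, atol=0.05)

    def test_identical_seed_identical_tables(self):
        rng = np.random.default_rng(1)
        maps = [rng.random((8, 8)) for _ in range(5)]
        cfg = LearningConfig(rng_seed=7)
        _, c1 = learn_invariance_cpts({0: maps}, 3, 3, 1, cfg)
        _, c2 = learn_invariance_cpts({0: maps}, 3, 3, 1, cfg)
        assert np.array_equal(c1, c2)

    def test_single_repeated_patch_pads_with_warning(self):
        m = np.zeros((4, 4))
        m[1, 1] = 1.0
        with pytest.warns(UserWarning, match="distinct patches"):
            centres, _ = learn_invariance_cpts(
                {0: [m]}, 4, 3, 1, LearningConfig(patch_threshold=0.5))
        assert centres.shape == (1, 3, 4, 4)


class TestGroupSum:
    def test_toy_grouping(self):
        out = group_sum(np.array([0.75, 0.05, 0.05, 0.05, 0.05, 0.05]), 3)
        np.testing.assert_allclose(out, [0.85, 0.15])

    def test_uniform_forty_states(self):
        out = group_sum(np.full(40, 1 / 40), 10)
        np.testing.assert_allclose(out, [0.25] * 4)

    def test_one_hot_maps_to_one_hot_group(self):
        v = np.zeros(6)
        v[4] = 1.0
        np.testing.assert_allclose(group_sum(v, 3), [0.0, 1.0])

    def test_indivisible_length_rejected(self):
        with pytest.raises(StructuralError):
            group_sum(np.ones(5), 3)


class TestMinimumDistance:
    def test_greedy_trace(self):
        gm = np.array([[[0.0], [0.0]], [[0.1], [1.0]]])  # 2x2 grid, G=1
        # patches in scan order: 0.0, 0.0, 0.1, 1.0
        protos = learn_selectivity_prototypes(
            [gm], (1, 1), 2, LearningConfig(dmin_init=0.5))
        vals = sorted(protos.ravel().tolist())
        assert vals == [0.0, 1.0]

    def test_k_equals_one_takes_first_patch(self):
        gm = np.arange(9.0).reshape(3, 3, 1)
        protos = learn_selectivity_prototypes(
            [gm], (1, 1), 1, LearningConfig(dmin_init=1.0))
        assert protos.ravel()[0] == 0.0

    def test_identical_patches_cannot_fill_k(self):
        gm = np.zeros((3, 3, 1))
        with pytest.raises(DatasetTooSmallError):
            learn_selectivity_prototypes(
                [gm], (1, 1), 2, LearningConfig(dmin_init=1.0))

    def test_prototypes_are_pairwise_distinct(self):
        rng = np.random.default_rng(2)
        gm = rng.random((6, 6, 2))
        protos = learn_selectivity_prototypes(
            [gm], (2, 2), 5, LearningConfig(rng_seed=2))
        flat = protos.reshape(5, -1)
        d = np.sqrt(((flat[:, None] - flat[None]) ** 2).sum(-1))
        assert d[np.triu_indices(5, 1)].min() > 0


class TestSelectivityCpt:
    def test_toy_group_weight_column(self):
        protos = np.zeros((1, 1, 1, 2))
        protos[0, 0, 0] = [1.0, 0.0]
        cpt = weights_to_cpt_selectivity(protos, 6, 3)
        np.testing.assert_allclose(cpt[0, 0, :, 0],
                                   [1 / 3, 1 / 3, 1 / 3, 0, 0, 0])

    def test_zero_weights_give_flat_column(self):
        protos = np.zeros((1, 1, 1, 2))
        cpt = weights_to_cpt_selectivity(protos, 6, 3)
        np.testing.assert_allclose(cpt[0, 0, :, 0], 1 / 6)

    def test_equal_weights_give_flat_column(self):
        protos = np.full((1, 1, 1, 2), 0.4)
        cpt = weights_to_cpt_selectivity(protos, 6, 3)
        np.testing.assert_allclose(cpt[0, 0, :, 0], 1 / 6)


class TestSupervisedTop:
    def test_duplicate_labels_rejected(self):
        maps = [np.ones((2, 2, 3)), np.ones((2, 2, 3))]
        with pytest.raises(StructuralError):
            learn_s3_supervised(maps, ["a", "a"], 6, 2)

    def test_identical_prototypes_warn(self):
        maps = [np.ones((2, 2, 3)), np.ones((2, 2, 3))]
        with pytest.warns(UserWarning, match="identical"):
            learn_s3_supervised(maps, ["a", "b"], 6, 2)

    def test_one_state_per_category(self):
        rng = np.random.default_rng(3)
        maps = [rng.random((2, 2, 3)) for _ in range(4)]
        protos, cpts = learn_s3_supervised(maps, list("abcd"), 6, 2)
        assert protos.shape == (4, 2, 2, 3)
        assert cpts.shape == (2, 2, 6, 4)
        for i in range(2):
            for j in range(2):
                validate_cpt(cpts[i, j])
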