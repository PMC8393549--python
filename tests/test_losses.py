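import numpy as np
import pytest

from segweight import losses as L


def _binary_fields(p_fg, g_fg):
    g_fg = np.asarray(g_fg, dtype=float)
    p_fg = np.asarray(p_fg, dtype=float)
    return (np.stack([1 - g_fg, g_fg], axis=-1),
            np.stack([1 - p_fg, p_fg], axis=-1))


def _random_pair(rng, n=16, c=3):
    g = np.eye(c)[rng.integers(0, c, n)]
    p = L.softmax(rng.normal(0, 1.5, (n, c)))
    return g, p


class TestBaseLosses:
    def test_cross_entropy_hand_examples(self):
        g, p = _binary_fields([0.5], [1])
        assert L.cross_entropy(g, p) == pytest.approx(np.log(2), abs=1e-12)
        g, p = _binary_fields([0.9, 0.8], [1, 1])
        assert L.cross_entropy(g, p) == pytest.approx(
            -(np.log(0.9) + np.log(0.8)) / 2, abs=1e-12)

    def test_cross_entropy_zero_at_perfect_prediction(self):
        g, p = _binary_fields([1.0], [1])
        assert L.cross_entropy(g, p) <= 1e-6

    def test_dice_hand_example(self):
        g, p = _binary_fields([0.8, 0.6, 0.2, 0.0], [1, 1, 0, 0])
        assert L.dice_loss(g, p) == pytest.approx(0.2, abs=1e-6)

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_dice_uniform_prediction_closed_form(self, c):
        g = np.eye(c)[[0, 1 % c, 0, 1 % c]]
        p = np.full((4, c), 1.0 / c)
        assert L.dice_loss(g, p) == pytest.approx(1 - 1 / c, abs=1e-6)

    def test_dice_bounded_and_zero_iff_exact(self):
        rng = np.random.default_rng(0)
        g, p = _random_pair(rng)
        v = L.dice_loss(g, p)
        assert 0 <= v <= 1
        assert L.dice_loss(g, g) == pytest.approx(0.0, abs=1e-9)

    def test_contract_errors(self):
        g, p = _binary_fields([0.5], [1])
        with pytest.raises(ValueError, match="shape"):
            L.cross_entropy(g, np.vstack([p, p]))
        with pytest.raises(ValueError, match="simplex"):
            L.cross_entropy(g, np.array([[0.9, 0.9]]))
        with pytest.raises(ValueError, match="one-hot"):
            L.dice_loss(np.array([[0.5, 0.5]]), p)


class TestWeightConstructors:
    def test_inverse_frequency(self):
        counts = np.array([900.0, 100.0])
        w = L.inverse_frequency_weights(counts, alpha=1)
        np.testing.assert_allclose(w, [1 / 900, 1 / 100])
        assert w[1] / w[0] == pytest.approx(9.0)
        assert L.inverse_frequency_weights(np.array([1.0, 100.0]), 2)[0] == 1.0
        assert L.inverse_frequency_weights(np.array([100.0, 1.0]), 2)[0] == 1e-4

    def test_inverse_frequency_from_one_hot_field(self):
        g = np.eye(2)[[0, 0, 0, 1]]
        np.testing.assert_allclose(L.inverse_frequency_weights(g, 1),
                                   [1 / 3, 1.0])

    def test_absent_class_is_epsilon_guarded(self, caplog):
        with caplog.at_level("WARNING"):
            w = L.inverse_frequency_weights(np.array([10.0, 0.0]), 1)
        assert np.isfinite(w).all() and "absent" in caplog.text

    def test_median_frequency(self):
        w = L.median_frequency_weights(np.array([0.5, 0.3, 0.2]))
        np.testing.assert_allclose(w, [0.6, 1.0, 1.5])
        # equal frequencies -> all ones; median class -> exactly 1
        np.testing.assert_allclose(
            L.median_frequency_weights(np.array([5.0, 5.0, 5.0])), 1.0)
        assert L.median_frequency_weights(np.array([0.5, 0.3, 0.2]))[1] == 1.0

    def test_focal_weight_field(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        w = L.focal_weight_field(p, 2.0)
        np.testing.assert_allclose(w, [[0.0, 1.0], [0.25, 0.25]])
        np.testing.assert_allclose(L.focal_weight_field(p, 0.0), 1.0)
        with pytest.raises(ValueError):
            L.focal_weight_field(p, -1.0)


class TestWeightedLosses:
    def test_focal_ce_hand_example(self):
        # single voxel, p(true)=0.5, gamma=2: 0.25 * ln 2
        g, p = _binary_fields([0.5], [1])
        cfg = L.LossConfig(base="ce", weighting="focal", gamma=2.0)
        assert L.weighted_cross_entropy(g, p, cfg) == pytest.approx(
            0.25 * np.log(2), abs=1e-9)

    def test_unit_weights_reproduce_base_losses(self):
        rng = np.random.default_rng(1)
        g, p = _random_pair(rng, n=32, c=3)
        ones_vec, ones_map = np.ones(3), np.ones((32, 3))
        base = {"ce": L.cross_entropy(g, p), "dice": L.dice_loss(g, p)}
        for name in L.LOSS_NAMES:
            b, w = name.split("/")
            obj = L.WeightedLoss(
                L.LossConfig(base=b, weighting=w),
                class_weights=ones_vec if w in ("inverse", "median") else None)
            v = obj.value(g, p,
                          weight_maps=ones_map if w in ("dtm", "dpt") else None,
                          focal_weights=ones_map if w == "focal" else None)
            assert v == pytest.approx(base[b], abs=1e-12), name

    def test_focal_gamma_zero_degenerates_to_base(self):
        rng = np.random.default_rng(2)
        g, p = _random_pair(rng)
        cfg = L.LossConfig(base="ce", weighting="focal", gamma=0.0)
        assert L.weighted_cross_entropy(g, p, cfg) == pytest.approx(
            L.cross_entropy(g, p), abs=1e-12)

    def test_default_parameters_follow_base_loss(self):
        assert L.LossConfig(base="ce", weighting="inverse").alpha_ == 1
        assert L.LossConfig(base="dice", weighting="inverse").alpha_ == 2
        assert L.LossConfig(base="ce", weighting="focal").gamma_ == 2
        assert L.LossConfig(base="dice", weighting="focal").gamma_ == 1

    def test_generalized_dice_reference_expression(self):
        # independent symbolic evaluation of the inverse-weighted Dice ratio
        g, p = _binary_fields([0.8, 0.6, 0.2, 0.0], [1, 1, 0, 0])
        counts = g.sum(axis=0)
        w = counts ** -2.0
        eps = 1e-7
        expected = 1 - (2 * (w * (g * p).sum(0)).sum() + eps) / \
            ((w * (g + p).sum(0)).sum() + eps)
        cfg = L.LossConfig(base="dice", weighting="inverse")
        got = L.weighted_dice(g, p, cfg, class_weights=w)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_distance_weighted_dice_matches_printed_formula(self):
        rng = np.random.default_rng(3)
        g, p = _random_pair(rng, n=12, c=2)
        wmap = 1 + rng.uniform(0, 2, g.shape)
        eps = 1e-7
        num = 2 * (g * p).sum() + eps
        den = (2 * (g * p).sum() + (wmap * (1 - g) * p).sum()
               + (wmap * g * (1 - p)).sum() + eps)
        cfg = L.LossConfig(base="dice", weighting="dtm")
        got = L.weighted_dice(g, p, cfg, weight_maps=wmap)
        assert got == pytest.approx(1 - num / den, abs=1e-12)

    def test_all_losses_vanish_at_perfect_prediction(self):
        rng = np.random.default_rng(4)
        c = 3
        g = np.eye(c)[rng.integers(0, c, 20)]
        wmap = 1 + rng.uniform(0, 2, g.shape)
        for name in L.LOSS_NAMES:
            obj = L.make_loss(name, class_counts=g.sum(0) + 1)
            wm = wmap if obj.config.weighting in ("dtm", "dpt") else None
            assert obj.value(g, g, weight_maps=wm) <= 1e-6, name

    def test_minority_class_penalty_amplified(self):
        # errors only on the minority class: frequency weightings must raise
        # the minority share of the loss above the unweighted share
        g_fg = np.zeros(100)
        g_fg[:5] = 1  # 5% minority
        p_fg = np.where(g_fg == 1, 0.3, 0.0)  # errors only on minority
        g, p = _binary_fields(p_fg, g_fg)
        counts = g.sum(0)

        def minority_share(class_w):
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            contrib = -(class_w * g * np.log(pc)).sum(axis=0)
            return contrib[1] / contrib.sum()

        unweighted = minority_share(np.ones(2))
        for weights in (L.inverse_frequency_weights(counts, 1),
                        L.median_frequency_weights(counts)):
            assert minority_share(weights) > unweighted

    def test_missing_aux_weights_raise(self):
        g, p = _binary_fields([0.5], [1])
        cfg = L.LossConfig(base="ce", weighting="dtm")
        with pytest.raises(ValueError, match="weight maps"):
            L.weighted_cross_entropy(g, p, cfg)


class TestRegistry:
    def test_exactly_twelve_named_objectives(self):
        assert len(L.LOSS_NAMES) == 12
        assert len(set(L.LOSS_NAMES)) == 12
        counts = np.array([100.0, 10.0])
        for name in L.LOSS_NAMES:
            assert L.make_loss(name, class_counts=counts).name == name

    def test_unknown_names_raise(self):
        with pytest.raises(ValueError):
            L.make_loss("tversky/none")
        with pytest.raises(ValueError):
            L.make_loss("ce/boundary")
        with pytest.raises(ValueError):
            L.make_loss("dice")

    def test_frequency_weightings_require_counts(self):
        with pytest.raises(ValueError, match="counts"):
            L.make_loss("dice/inverse")

    def test_ce_none_is_plain_cross_entropy(self):
        rng = np.random.default_rng(5)
        g = np.eye(2)[rng.integers(0, 2, 10)]
        p = L.softmax(rng.normal(0, 1, (10, 2)))
        assert L.make_loss("ce/none").value(g, p) == pytest.approx(
            L.cross_entropy(g, p), abs=1e-15)


class TestGradients:
    @pytest.mark.parametrize("name", L.LOSS_NAMES)
    def test_analytic_gradient_matches_finite_differences(self, name):
        rng = np.random.default_rng(hash(name) % 2 ** 31)
        n, c = 16, 2
        g = np.eye(c)[rng.integers(0, c, n)]
        z = rng.normal(0, 1, (n, c))
        counts = g.sum(0) + 1
        wmap = 1 + rng.uniform(0, 2, (n, c))
        obj = L.make_loss(name, class_counts=counts)
        wm = wmap if obj.config.weighting in ("dtm", "dpt") else None
        v, dz = obj.value_and_grad(g, z, weight_maps=wm)
        fw = (L.focal_weight_field(L.softmax(z), obj.config.gamma_)
              if obj.config.weighting == "focal" else None)
        h = 1e-4
        fd = np.zeros_like(z)
        for i in range(n):
            for k in range(c):
                zp, zm = z.copy(), z.copy()
                zp[i, k] += h
                zm[i, k] -= h
                fd[i, k] = (obj.value(g, L.softmax(zp), weight_maps=wm,
                                      focal_weights=fw)
                            - obj.value(g, L.softmax(zm), weight_maps=wm,
                                        focal_weights=fw)) / (2 * h)
        scale = max(np.abs(fd).max(), 1e-8)
        assert np.abs(fd - dz).max() / scale < 1e-3
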