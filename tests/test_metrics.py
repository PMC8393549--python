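import numpy as np
import pytest

from segweight import distance_maps as dm
from segweight import metrics as mx
from helpers import brute_directed_distances


def _random_volume_pair(rng, shape=(12, 12, 6)):
    g = np.zeros(shape, bool)
    p = np.zeros(shape, bool)
    g[tuple(slice(a, a + s) for a, s in
            zip(rng.integers(0, 4, 3), rng.integers(3, 6, 3)))] = True
    p[tuple(slice(a, a + s) for a, s in
            zip(rng.integers(0, 4, 3), rng.integers(3, 6, 3)))] = True
    g ^= rng.random(shape) < 0.02
    p ^= rng.random(shape) < 0.02
    return g, p


class TestDsc:
    def test_identity_and_disjoint(self):
        g = np.zeros((6, 6), bool)
        g[1:4, 1:4] = True
        assert mx.dsc(g, g) == 1.0
        p = np.zeros_like(g)
        p[4:, 4:] = True
        assert mx.dsc(g, p) == 0.0

    def test_counted_example(self):
        g = np.zeros(12, bool)
        p = np.zeros(12, bool)
        g[:4] = True          # |G| = 4
        p[1:7] = True         # |P| = 6, overlap 3
        assert mx.dsc(g, p) == pytest.approx(0.6)

    def test_empty_conventions(self):
        e = np.zeros((4, 4), bool)
        f = np.zeros((4, 4), bool)
        f[1, 1] = True
        assert mx.dsc(e, e) == 1.0
        assert mx.dsc(e, f) == 0.0
        assert mx.dsc(f, e) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mx.dsc(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestSurfaceMetrics:
    def test_identical_masks(self):
        g = np.zeros((10, 10, 4), bool)
        g[2:7, 2:7, 1:3] = True
        assert mx.surface_dsc(g, g, tau=0.0) == 1.0
        assert mx.asd(g, g) == 0.0
        assert mx.hd95(g, g) == 0.0

    def test_shifted_square_within_tolerance(self):
        g = np.zeros((14, 14), bool)
        g[2:12, 2:12] = True
        p = np.roll(g, 1, axis=0)
        assert mx.surface_dsc(g, p, tau=1.0) == 1.0

    def test_single_voxel_three_four_five(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert mx.asd(a, b) == pytest.approx(5.0)
        assert mx.hd95(a, b) == pytest.approx(5.0)
        assert mx.hausdorff(a, b) == pytest.approx(5.0)

    def test_hd95_percentile_convention(self):
        # pin the pooled sort + linear-interpolation percentile convention
        rng = np.random.default_rng(7)
        g, p = _random_volume_pair(rng)
        d_gp, d_pg = mx.surface_distances(g, p)
        pooled = np.sort(np.concatenate([d_gp, d_pg]))
        pos = 0.95 * (pooled.size - 1)
        lo, frac = int(np.floor(pos)), pos - np.floor(pos)
        expected = pooled[lo] if lo + 1 == pooled.size else \
            pooled[lo] * (1 - frac) + pooled[lo + 1] * frac
        assert mx.hd95(g, p) == pytest.approx(expected, abs=1e-12)

    def test_empty_surface_flagged_missing(self):
        g = np.zeros((5, 5), bool)
        g[2, 2] = True
        e = np.zeros((5, 5), bool)
        assert np.isnan(mx.surface_dsc(g, e))
        assert np.isnan(mx.asd(g, e))
        assert np.isnan(mx.hd95(g, e))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        spacing = (0.47, 0.47, 1.0)
        checked = 0
        while checked < 8:
            g, p = _random_volume_pair(rng)
            sg = dm.extract_boundary(g)
            sp = dm.extract_boundary(p)
            if not (sg.any() and sp.any()):
                continue
            checked += 1
            bf_gp = brute_directed_distances(sg, sp, spacing)
            bf_pg = brute_directed_distances(sp, sg, spacing)
            assert mx.asd(g, p, spacing) == pytest.approx(
                (bf_gp.sum() + bf_pg.sum()) / (bf_gp.size + bf_pg.size),
                abs=1e-9)
            assert mx.hd95(g, p, spacing) == pytest.approx(
                np.percentile(np.concatenate([bf_gp, bf_pg]), 95), abs=1e-9)
            tau = 1.0
            assert mx.surface_dsc(g, p, spacing, tau) == pytest.approx(
                ((bf_gp <= tau).sum() + (bf_pg <= tau).sum())
                / (bf_gp.size + bf_pg.size), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g, p = _random_volume_pair(rng)
        for fn in (mx.dsc, mx.asd, mx.hd95,
                   lambda a, b: mx.surface_dsc(a, b, tau=1.5)):
            assert fn(g, p) == pytest.approx(fn(p, g), nan_ok=True)

    def test_surface_dsc_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        g, p = _random_volume_pair(rng)
        taus = [0.0, 0.5, 1.0, 2.0, 4.0, 100.0]
        vals = [mx.surface_dsc(g, p, tau=t) for t in taus]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0  # tau beyond the lattice diameter

    def test_asd_le_hd95_le_hd(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            g, p = _random_volume_pair(rng)
            a, h95, h = mx.asd(g, p), mx.hd95(g, p), mx.hausdorff(g, p)
            assert a <= h95 + 1e-12 <= h + 1e-12

    def test_spacing_scales_distances_not_overlap(self):
        rng = np.random.default_rng(4)
        g, p = _random_volume_pair(rng)
        s1, s2 = (1.0, 1.0, 1.0), (2.0, 2.0, 2.0)
        assert mx.asd(g, p, s2) == pytest.approx(2 * mx.asd(g, p, s1))
        assert mx.hd95(g, p, s2) == pytest.approx(2 * mx.hd95(g, p, s1))
        assert mx.dsc(g, p) == mx.dsc(g, p)  # spacing-free by construction


class TestEvaluateCase:
    def _volumes(self):
        gt = np.zeros((10, 10, 6), dtype=int)
        gt[1:6, 1:6, 1:4] = 1
        gt[7:9, 7:9, 1:3] = 2
        return gt

    def test_perfect_prediction(self):
        gt = self._volumes()
        recs = mx.evaluate_case(gt, gt.copy(), spacing=(1, 1, 1))
        assert len(recs) == 2  # one record per foreground class
        for r in recs:
            assert r.dsc == 1.0 and r.sdsc == 1.0
            assert r.asd == 0.0 and r.hd95 == 0.0
            assert not r.surface_missing

    def test_empty_prediction_class(self):
        gt = self._volumes()
        pred = gt.copy()
        pred[pred == 2] = 0
        recs = {r.class_id: r for r in mx.evaluate_case(gt, pred)}
        assert recs[2].dsc == 0.0
        assert recs[2].surface_missing
        assert recs[1].dsc == 1.0

    def test_record_cardinality_and_background_exclusion(self):
        gt = np.zeros((8, 8, 4), dtype=int)
        for c in range(1, 5):
            gt[c, c, 1] = c
        recs = mx.evaluate_case(gt, gt.copy(), classes=range(5))
        assert [r.class_id for r in recs] == [1, 2, 3, 4]

    def test_undeclared_label_raises(self):
        gt = self._volumes()
        with pytest.raises(ValueError, match="declared"):
            mx.evaluate_case(gt, gt, classes=[0, 1])

    def test_long_form_table(self):
        gt = self._volumes()
        recs = mx.evaluate_case(gt, gt.copy(), case_id="c0", loss_id="ce/none")
        frame = mx.records_to_frame(recs)
        assert set(frame.columns) == {"case", "class", "loss", "metric",
                                      "value"}
        assert len(frame) == 2 * 4
        assert set(frame["metric"]) == {"dsc", "sdsc", "asd", "hd95"}
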