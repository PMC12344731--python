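import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thoravol import (
    LabelMask,
    VoxelSpacing,
    avd,
    axial_axis_measurements,
    connected_components,
    crop_metrics,
    dsc,
    location_summary,
    match_components,
    rank_sum_test,
    rvd,
    scan_dsc,
    summarize_records,
    tumor_metrics,
)
from thoravol.metrics import MetricRecord

import oracles


def binmask(arr, spacing=None):
    return LabelMask(np.asarray(arr).astype(np.int16), spacing or VoxelSpacing(1, 1, 1))


class TestElementaryMetrics:
    def test_identity_dsc(self):
        arr = np.zeros((5, 5, 5))
        arr[1:3, 1:3, 1:3] = 1
        assert dsc(binmask(arr), binmask(arr)) == 1.0

    def test_disjoint_dsc_zero(self):
        a, b = np.zeros((5, 5, 5)), np.zeros((5, 5, 5))
        a[0, 0, 0] = 1
        b[4, 4, 4] = 1
        assert dsc(binmask(a), binmask(b)) == 0.0

    def test_both_empty_dsc_one(self):
        z = np.zeros((3, 3, 3))
        assert dsc(binmask(z), binmask(z)) == 1.0

    def test_half_overlap(self):
        a, b = np.zeros((4, 4, 4)), np.zeros((4, 4, 4))
        a.flat[:8] = 1
        b.flat[4:12] = 1
        assert dsc(binmask(a), binmask(b)) == pytest.approx(0.5)

    def test_avd_formula(self):
        a, b = np.zeros((10, 10, 10)), np.zeros((10, 10, 10))
        a.flat[:100] = 1
        b.flat[:80] = 1
        assert avd(binmask(a), binmask(b), VoxelSpacing(1, 1, 1)) == pytest.approx(0.02)

    def test_avd_equal_count_disjoint_is_zero(self):
        a, b = np.zeros((6, 6, 6)), np.zeros((6, 6, 6))
        a.flat[:10] = 1
        b.flat[50:60] = 1
        assert avd(binmask(a), binmask(b), VoxelSpacing(1, 1, 1)) == 0.0

    def test_rvd_formula_and_unboundedness(self):
        a, b = np.zeros((10, 10, 10)), np.zeros((10, 10, 10))
        a.flat[:100] = 1
        b.flat[:80] = 1
        assert rvd(binmask(a), binmask(b)) == pytest.approx(0.2)
        b2 = np.zeros((10, 10, 10))
        b2.flat[:200] = 1  # |S| = 2|G| overshoots to RVD 1.0
        assert rvd(binmask(a), binmask(b2)) == pytest.approx(1.0)
        assert rvd(binmask(a), binmask(np.zeros((10, 10, 10)))) == pytest.approx(1.0)

    def test_rvd_empty_g_fails(self):
        z = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="empty ground-truth"):
            rvd(binmask(z), binmask(z))

    def test_geometry_mismatch_fails(self):
        with pytest.raises(ValueError, match="geometry"):
            dsc(binmask(np.zeros((3, 3, 3))), binmask(np.zeros((4, 4, 4))))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((8, 8, 8)) < 0.4
        s = rng.random((8, 8, 8)) < 0.4
        sp = VoxelSpacing(1.2, 0.9, 2.0)
        od, oa, orv = oracles.counting_dsc_avd_rvd(g, s, sp.voxel_volume_cm3)
        assert dsc(binmask(g), binmask(s)) == od
        assert avd(binmask(g), binmask(s), sp) == pytest.approx(oa)
        if orv is not None:
            assert rvd(binmask(g), binmask(s)) == orv

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.5, 3.0))
    def test_avd_linear_rvd_invariant_in_voxel_volume(self, seed, scale):
        rng = np.random.default_rng(seed)
        g = rng.random((6, 6, 6)) < 0.5
        s = rng.random((6, 6, 6)) < 0.5
        if not g.any():
            g[0, 0, 0] = True
        sp1, sp2 = VoxelSpacing(1, 1, 1), VoxelSpacing(scale, scale, scale)
        assert avd(g, s, sp2) == pytest.approx(avd(g, s, sp1) * scale**3)
        assert rvd(binmask(g), binmask(s)) == rvd(binmask(g, sp2), binmask(s, sp2))

    def test_dsc_symmetric(self):
        rng = np.random.default_rng(11)
        g = rng.random((6, 6, 6)) < 0.5
        s = rng.random((6, 6, 6)) < 0.5
        assert dsc(binmask(g), binmask(s)) == dsc(binmask(s), binmask(g))


class TestScanAndCropLevels:
    def test_missing_one_of_two_equal_tumors(self):
        g = np.zeros((20, 20, 20))
        g[2:4, 2:4, 2:4] = 1
        g[10:12, 10:12, 10:12] = 1
        s = np.zeros((20, 20, 20))
        s[2:4, 2:4, 2:4] = 1
        rec = scan_dsc(binmask(g), binmask(s))
        assert rec.dsc == pytest.approx(2 / 3)
        assert rec.unit == "scan"

    def test_perfect_inference(self):
        g = np.zeros((10, 10, 10))
        g[3:6, 3:6, 3:6] = 1
        rec = scan_dsc(binmask(g), binmask(g))
        assert rec.dsc == 1.0 and rec.avd_cm3 == 0.0 and rec.rvd == 0.0

    def test_crop_metrics_identical_patches(self):
        g = np.ones((4, 4, 4))
        recs = crop_metrics([(g, g), (g, g)], "box", VoxelSpacing(1, 1, 1))
        summ = summarize_records(recs)
        assert summ["dsc_mean"] == 1.0 and summ["dsc_sd"] == 0.0

    def test_crop_metrics_mean_of_zero_and_one(self):
        g = np.zeros((4, 4, 4))
        g[0, 0, 0] = 1
        s_hit, s_miss = g.copy(), np.zeros((4, 4, 4))
        s_miss[3, 3, 3] = 1
        recs = crop_metrics([(g, s_hit), (g, s_miss)], "cell", VoxelSpacing(1, 1, 1))
        assert summarize_records(recs)["dsc_mean"] == pytest.approx(0.5)

    def test_pooled_scan_dsc_bounded_by_best_tumor_when_inference_subset(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = np.zeros((16, 16, 16), dtype=bool)
            g[1:5, 1:5, 1:5] = True
            g[9:14, 9:14, 9:14] = True
            s = g & (rng.random((16, 16, 16)) < 0.7)  # inference ⊆ ground truth
            gm, sm = binmask(g), binmask(s)
            comps = connected_components(gm)
            match = match_components(comps, sm)
            trecs = tumor_metrics(match, VoxelSpacing(1, 1, 1))
            assert scan_dsc(gm, sm).dsc <= max(r.dsc for r in trecs) + 1e-12


class TestComponentMatching:
    def test_single_overlap_pair(self):
        g = np.zeros((10, 10, 10))
        g[2:5, 2:5, 2:5] = 1
        s = np.zeros((10, 10, 10))
        s[3:6, 3:6, 3:6] = 1
        comps = connected_components(binmask(g))
        match = match_components(comps, binmask(s))
        assert match.matches[1] == [1]
        assert match.false_positive_ids == [] and match.missed_gt_ids == []

    def test_empty_inference_missed_tumor(self):
        g = np.zeros((10, 10, 10))
        g[2:5, 2:5, 2:5] = 1
        comps = connected_components(binmask(g))
        match = match_components(comps, binmask(np.zeros((10, 10, 10))))
        assert match.missed_gt_ids == [1]
        [rec] = tumor_metrics(match, VoxelSpacing(1, 1, 1))
        assert rec.dsc == 0.0 and rec.rvd == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = (rng.random((12, 12, 12)) < 0.15).astype(np.int16)
        s = (rng.random((12, 12, 12)) < 0.15).astype(np.int16)
        gm, sm = binmask(g), binmask(s)
        comps = connected_components(gm)
        match = match_components(comps, sm)
        gt_sets = [set(map(tuple, c.voxel_indices)) for c in comps]
        inf_sets = [set(map(tuple, c.voxel_indices)) for c in match.inference_components]
        o_matches, o_fps = oracles.all_pairs_overlap_matching(gt_sets, inf_sets)
        got = {
            comps[i].component_id: sorted(match.inference_components[j].component_id for j in js)
            for i, js in o_matches.items()
        }
        assert {k: sorted(v) for k, v in match.matches.items()} == got
        assert sorted(match.false_positive_ids) == sorted(
            match.inference_components[j].component_id for j in o_fps
        )

    def test_false_positive_changes_scan_not_tumor_metrics(self):
        g = np.zeros((20, 20, 20))
        g[2:6, 2:6, 2:6] = 1
        s = g.copy()
        gm = binmask(g)
        comps = connected_components(gm)
        base_scan = scan_dsc(gm, binmask(s)).dsc
        base_tumor = tumor_metrics(match_components(comps, binmask(s)), VoxelSpacing(1, 1, 1))

        s_fp = s.copy()
        s_fp[14:17, 14:17, 14:17] = 1  # spurious component far from GT
        fp_scan = scan_dsc(gm, binmask(s_fp)).dsc
        fp_match = match_components(comps, binmask(s_fp))
        fp_tumor = tumor_metrics(fp_match, VoxelSpacing(1, 1, 1))

        assert fp_scan < base_scan
        assert [r.dsc for r in fp_tumor] == [r.dsc for r in base_tumor]
        assert fp_match.n_false_positives == 1

    def test_unweighted_tumor_mean(self):
        recs = [
            MetricRecord("tumor", "a", 1.0, 0.0, 0.0),
            MetricRecord("tumor", "b", 0.5, 0.0, 0.0),
        ]
        assert summarize_records(recs)["dsc_mean"] == pytest.approx(0.75)


class TestLocationSummary:
    def _recs(self):
        return [
            MetricRecord("tumor", "t1", 0.9, 0.1, 0.1, location="pleural", crop_provenance="box"),
            MetricRecord("tumor", "t2", 0.7, 0.3, 0.2, location="pleural", crop_provenance="box"),
            MetricRecord("tumor", "t3", 0.8, 0.2, 0.4, location="mediastinal", crop_provenance="box"),
        ]

    def test_means_match_direct_computation(self):
        df = location_summary(self._recs())
        pleura = df[(df.location == "pleural")].iloc[0]
        assert pleura.dsc_mean == pytest.approx(0.8)
        assert pleura.dsc_sd == pytest.approx(np.std([0.9, 0.7], ddof=1))
        overall = df[(df.location == "overall")].iloc[0]
        assert overall.dsc_mean == pytest.approx(np.mean([0.9, 0.7, 0.8]))

    def test_single_location_equals_overall(self):
        recs = [r for r in self._recs() if r.location == "pleural"]
        df = location_summary(recs)
        overall = df[df.location == "overall"].iloc[0]
        pleura = df[df.location == "pleural"].iloc[0]
        assert overall.dsc_mean == pleura.dsc_mean

    def test_empty_location_row_absent(self):
        df = location_summary(self._recs())
        assert "parenchymal" not in set(df.location)

    def test_empty_input_empty_table(self):
        assert location_summary([]).empty


class TestRankSum:
    def test_fully_separated_samples(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact-enumeration"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_with_ties(self):
        res = rank_sum_test([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_fails(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(1, 6))
        n_b = int(rng.integers(1, 11 - n_a))
        a = rng.integers(0, 5, n_a).astype(float).tolist()  # ties likely
        b = rng.integers(0, 5, n_b).astype(float).tolist()
        res = rank_sum_test(a, b, method="exact")
        assert res.p_value == pytest.approx(oracles.exact_rank_sum_p(a, b))

    def test_normal_branch_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6).tolist()
        b = rng.normal(1, 1, 6).tolist()
        exact = rank_sum_test(a, b, method="exact").p_value
        approx = rank_sum_test(a, b, method="normal").p_value
        assert approx == pytest.approx(exact, abs=0.05)


class TestAxisMeasurements:
    def _component(self, arr):
        comps = connected_components(binmask(arr))
        assert len(comps) == 1
        return comps[0]

    def test_single_voxel_zero(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1
        m = axial_axis_measurements(self._component(arr), VoxelSpacing(1, 1, 1))
        assert m.major_mm == 0.0 and m.minor_mm == 0.0 and m.slice_index == 2

    def test_collinear_segment(self):
        arr = np.zeros((3, 15, 3))
        arr[1, 2:13, 1] = 1  # 11 voxels in a row
        m = axial_axis_measurements(self._component(arr), VoxelSpacing(1, 1, 1))
        assert m.major_mm == pytest.approx(10.0)
        assert m.minor_mm == pytest.approx(0.0)

    def test_spacing_scales_axes(self):
        arr = np.zeros((3, 15, 3))
        arr[1, 2:13, 1] = 1
        m = axial_axis_measurements(self._component(arr), VoxelSpacing(0.5, 0.5, 2.0))
        assert m.major_mm == pytest.approx(5.0)

    def test_slice_choice_maximizes_major_lowest_tie(self):
        arr = np.zeros((10, 10, 4))
        arr[2:5, 2, 1] = 1  # slice 1: extent 2
        arr[2:8, 2, 2] = 1  # slice 2: extent 5 — the maximizer
        m = axial_axis_measurements(self._component(arr), VoxelSpacing(1, 1, 1))
        assert m.slice_index == 2 and m.major_mm == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = np.zeros((12, 12, 3))
        n = int(rng.integers(2, 50))
        pts = rng.integers(0, 12, size=(n, 2))
        arr[pts[:, 0], pts[:, 1], 1] = 1
        vox = np.argwhere(arr != 0)
        from thoravol.core import BoundingBox3D, LesionComponent

        comp = LesionComponent(1, vox, BoundingBox3D.from_mask(arr != 0))
        sp = VoxelSpacing(0.8, 1.1, 2.0)
        m = axial_axis_measurements(comp, sp)
        omaj, omin = oracles.all_pairs_axes([(x, y) for x, y, _ in vox], sp.dx, sp.dy)
        assert m.major_mm == pytest.approx(omaj)
        assert m.minor_mm == pytest.approx(omin)
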