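"""Three-label -> two-label conversion: worked examples, conservation laws,
and exact agreement with the brute-force oracle."""

import numpy as np
import pytest

from gliolabels.conversion import (
    ConversionConfig,
    WholeTumourMask,
    convert,
    remove_encapsulated,
    remove_small_clusters,
)
from gliolabels.io import GeometryError, ThreeLabelSegmentation

from oracles import mask_to_set, oracle_convert, oracle_remove_encapsulated

EYE = np.eye(4)


def _seg(at, ncr, ed, affine=EYE):
    return ThreeLabelSegmentation(at=at, ncr_net=ncr, ed=ed, affine=affine)


def _wt(mask, affine=EYE):
    return WholeTumourMask(wt=mask, affine=affine)


class TestRemoveSmallClusters:
    def test_boundary_semantics_strictly_less_than(self):
        # 49-voxel and 50-voxel clusters at 1 mm³: only the 50 survives
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[1, 1:50 // 7 + 1, :7] = True  # 49 voxels: 7x7 block
        assert mask.sum() == 49
        mask2 = np.zeros((30, 30, 30), dtype=bool)
        mask2[10, 10:15, 10:20] = True  # 50 voxels
        out = remove_small_clusters(mask | mask2, min_mm3=50.0)
        assert not out[1].any() and np.array_equal(out[10], mask2[10])

    def test_empty_mask_passthrough(self):
        empty = np.zeros((8, 8, 8), dtype=bool)
        assert not remove_small_clusters(empty, 50.0).any()

    def test_anisotropic_spacing_uses_physical_volume(self):
        # 30 voxels at (1,1,2) mm = 60 mm³ ≥ 50 mm³: kept
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[5, 5:10, 5:11] = True
        assert mask.sum() == 30
        kept = remove_small_clusters(mask, 50.0, spacing=(1, 1, 2))
        assert np.array_equal(kept, mask)
        dropped = remove_small_clusters(mask, 50.0, spacing=(1, 1, 1))
        assert not dropped.any()


class TestRemoveEncapsulated:
    def test_ball_inside_closed_shell_removed(self, ball):
        shape = (24, 24, 24)
        at = ball(shape, (12, 12, 12), 8) & ~ball(shape, (12, 12, 12), 6)
        cand = ball(shape, (12, 12, 12), 6)
        assert not remove_encapsulated(cand, at).any()

    def test_single_hole_in_shell_retains_component(self, ball):
        shape = (24, 24, 24)
        inner = ball(shape, (12, 12, 12), 6)
        at = ball(shape, (12, 12, 12), 8) & ~inner
        at[12, 12, 19] = False  # puncture the shell: one adjacent voxel is not AT
        out = remove_encapsulated(inner, at)
        assert np.array_equal(out, inner)

    def test_border_touching_component_retained(self, ball):
        # component reaches the lattice edge; AT surrounds it everywhere else
        shape = (16, 16, 16)
        cand = np.zeros(shape, dtype=bool)
        cand[0:3, 8, 8] = True
        at = np.zeros(shape, dtype=bool)
        out = remove_encapsulated(cand, ~cand)  # everything else is AT
        assert np.array_equal(out, cand)
        # brute-force border flood-fill agrees
        oracle = oracle_remove_encapsulated(mask_to_set(cand), mask_to_set(~cand), shape, 6)
        assert oracle == mask_to_set(out)

    def test_fill_method_also_captures_background_bounded_pockets(self, ball):
        # pocket enclosed by AT but separated from it by background: the
        # boundary test keeps it, hole-filling removes it
        shape = (24, 24, 24)
        at = ball(shape, (12, 12, 12), 9) & ~ball(shape, (12, 12, 12), 7)
        pocket = ball(shape, (12, 12, 12), 3)
        assert np.array_equal(remove_encapsulated(pocket, at, method="boundary"), pocket)
        assert not remove_encapsulated(pocket, at, method="fill").any()


class TestConvert:
    def test_empty_ncr_net_gives_ce_at_ne_ed(self, ball):
        shape = (32, 32, 32)
        at = ball(shape, (16, 16, 16), 6) & ~ball(shape, (16, 16, 16), 4)
        ed = ball(shape, (16, 16, 16), 10) & ~ball(shape, (16, 16, 16), 6)
        seg = _seg(at, np.zeros(shape, bool), ed)
        out, audit = convert(seg, _wt(at | ed))
        assert np.array_equal(out.ce, at)
        assert np.array_equal(out.ne, ed)
        assert audit.voxels_removed_encapsulated == 0

    def test_all_removals_vacuous_gives_union(self, ball):
        # WT ⊇ NCR+NET, nothing encapsulated, all clusters ≥ 50 mm³
        shape = (32, 32, 32)
        ncr = ball(shape, (10, 10, 10), 4)
        ed = ball(shape, (22, 22, 22), 5)
        seg = _seg(np.zeros(shape, bool), ncr, ed)
        out, _ = convert(seg, _wt(np.ones(shape, bool)))
        assert np.array_equal(out.ne, ncr | ed)

    def test_necrotic_core_phantom_against_oracle(self, ball):
        # AT shell 8–10, NCR+NET ball 8, ED shell 10–14, WT = AT ∪ ED:
        # core is dropped (outside WT and AT-encapsulated); NE = ED
        shape = (34, 34, 34)
        c = (17, 17, 17)
        core = ball(shape, c, 8)
        at = ball(shape, c, 10) & ~core
        ed = ball(shape, c, 14) & ~ball(shape, c, 10)
        seg = _seg(at, core, ed)
        out, audit = convert(seg, _wt(at | ed))
        assert np.array_equal(out.ce, at)
        assert np.array_equal(out.ne, ed)
        ce_o, ne_o = oracle_convert(at, core, ed, at | ed)
        assert np.array_equal(out.ce, ce_o) and np.array_equal(out.ne, ne_o)

    def test_encapsulated_core_inside_wt_removed_by_boundary_test(self, ball):
        # paper-style failure mode: necrosis inside WT but fully AT-encapsulated
        shape = (34, 34, 34)
        c = (17, 17, 17)
        core = ball(shape, c, 8)
        at = ball(shape, c, 10) & ~core
        seg = _seg(at, core, np.zeros(shape, bool))
        out, audit = convert(seg, _wt(np.ones(shape, bool)))
        assert not out.ne.any()
        assert audit.voxels_removed_encapsulated == core.sum()

    def test_net_island_phantom_50mm3_rule(self, ball):
        shape = (48, 48, 48)
        small = np.zeros(shape, bool)
        small[5, 5:10, 5:11] = True  # 30 voxels
        big = np.zeros(shape, bool)
        big[40, 20:28, 20:30] = True  # 80 voxels
        seg = _seg(np.zeros(shape, bool), small | big, np.zeros(shape, bool))
        wt = _wt(small | big)
        out, audit = convert(seg, wt)
        assert not (out.ne & small).any()
        assert (out.ne & big).sum() == 80
        ce_o, ne_o = oracle_convert(seg.at, seg.ncr_net, seg.ed, wt.wt)
        assert np.array_equal(out.ne, ne_o)
        assert audit.voxels_removed_small_clusters == 30

    def test_geometry_mismatch_is_error(self):
        seg = _seg(*(np.zeros((8, 8, 8), bool) for _ in range(3)))
        with pytest.raises(GeometryError):
            convert(seg, _wt(np.zeros((9, 9, 9), bool)))

    def test_audit_counts_reconcile(self, tumour_phantom):
        spec, (study, seg, wt, truth, _) = tumour_phantom
        out, a = convert(seg, wt)
        n_union = int((seg.ncr_net & wt.wt | seg.ed).sum())
        assert a.output_voxel_counts["ne"] == (
            n_union
            - a.voxels_removed_encapsulated
            - a.voxels_removed_small_clusters
            + a.voxels_restored_by_ed
        )
        assert "voxels_removed_small_clusters\t" in a.as_text()


@pytest.fixture(scope="module")
def converted(tumour_phantom):
    spec, (study, seg, wt, truth, _) = tumour_phantom
    out, audit = convert(seg, wt)
    return seg, wt, out


class TestConversionInvariants:
    """Conservation laws on the fixture phantom."""

    def test_ce_identical_to_at(self, converted):
        seg, wt, out = converted
        assert np.array_equal(out.ce, seg.at)

    def test_ed_subset_of_ne(self, converted):
        seg, wt, out = converted
        assert np.all(out.ne[seg.ed])

    def test_ne_subset_of_ncr_net_union_ed(self, converted):
        seg, wt, out = converted
        assert not np.any(out.ne & ~(seg.ncr_net | seg.ed))

    def test_wt_monotonicity(self, converted):
        # enlarging WT never shrinks NE
        seg, wt, out = converted
        bigger, _ = convert(seg, WholeTumourMask(wt=np.ones(seg.shape, bool), affine=seg.affine))
        assert np.all(bigger.ne[out.ne])

    def test_ed_free_ne_components_meet_volume_floor(self, converted):
        from scipy import ndimage

        seg, wt, out = converted
        labels, n = ndimage.label(out.ne, structure=np.ones((3, 3, 3), bool))
        for i in range(1, n + 1):
            comp = labels == i
            if not (comp & seg.ed).any():
                assert comp.sum() * seg.voxel_volume_mm3 >= 50.0

    def test_idempotence_surrogate(self, converted):
        # feeding the output back through the conversion reproduces it
        seg, wt, out = converted
        seg2 = ThreeLabelSegmentation(
            at=out.ce, ncr_net=out.ne & ~seg.ed, ed=seg.ed, affine=seg.affine
        )
        wt2 = WholeTumourMask(wt=out.ne | out.ce, affine=seg.affine)
        again, _ = convert(seg2, wt2)
        assert np.array_equal(again.ce, out.ce)
        assert np.array_equal(again.ne, out.ne)


def test_config_validation():
    with pytest.raises(ValueError):
        ConversionConfig(min_cluster_mm3=0)
    with pytest.raises(ValueError):
        ConversionConfig(cluster_connectivity=7)
    with pytest.raises(ValueError):
        ConversionConfig(encapsulation_method="guess")
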