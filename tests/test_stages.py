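import numpy as np
import pytest

import myelinseg as m
from myelinseg.stages import (
    CandidateState,
    RoiCandidate,
    Stage,
    geodesic_label_expansion,
    rasterise_polygon,
)

from conftest import annulus_probability_stack, flooding_oracle, point_in_polygon


class TestStage1:
    def test_closed_annulus_selects_hole(self):
        prob, ring, inner = annulus_probability_stack()
        # the hole is ~13% of this tiny frame, so widen the size window
        cands = m.stage1_inner_regions(
            prob, min_area_px=20, max_area_fraction=0.3, close_radius=0
        )
        sel = [c for c in cands if c.state is CandidateState.SELECTED]
        assert len(sel) == 1
        assert (sel[0].mask == inner).all()

    def test_cut_annulus_rejected_by_flood_fill(self):
        """A C-shaped ring leaks: its hole joins the border background."""
        prob, ring, inner = annulus_probability_stack(gap=3)
        cands = m.stage1_inner_regions(prob, min_area_px=20, close_radius=0)
        sel = [c for c in cands if c.state is CandidateState.SELECTED]
        assert sel == []
        # oracle: 4-connected flood fill from the border reaches the hole
        from scipy import ndimage as ndi

        lab, _ = ndi.label(~ring)
        border_labels = set(np.unique(np.r_[lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
        hole_label = lab[inner][0]
        assert hole_label in border_labels

    def test_size_gates(self):
        prob, ring, inner = annulus_probability_stack()
        # giant max_area gate: hole is ~200 px on a 1600-px image
        cands = m.stage1_inner_regions(
            prob, min_area_px=20, max_area_fraction=0.01, close_radius=0
        )
        assert all(c.state is CandidateState.REJECTED for c in cands)

    def test_nothing_dropped_silently(self):
        rng = np.random.default_rng(4)
        myelin = rng.random((40, 40)) < 0.4
        stack = np.stack(
            [myelin.astype(float), (~myelin).astype(float), np.zeros((40, 40))]
        )
        prob = m.ProbabilityStack(stack, 1.0)
        cands = m.stage1_inner_regions(prob, close_radius=0)
        from scipy import ndimage as ndi

        lab, n = ndi.label(~myelin)
        assert len(cands) == n
        union = np.zeros((40, 40), dtype=bool)
        for c in cands:
            union |= c.mask
        assert (union == ~myelin).all()


class TestStage2:
    def _seed_candidates(self, seeds):
        out = []
        for l in np.unique(seeds):
            if l > 0:
                out.append(
                    RoiCandidate(int(l), seeds == l, Stage.INNER_REGION, CandidateState.SELECTED)
                )
        return out

    def test_annulus_plus_hole_gives_full_disk(self):
        prob, ring, inner = annulus_probability_stack()
        seeds = inner.astype(np.int64)
        fibres = m.stage2_fibres(self._seed_candidates(seeds), ring, 1.0)
        assert ((fibres.labels == 1) == (ring | inner)).all()

    def test_corridor_splits_at_midpoint(self):
        """21-px corridor between two seeds: 11/10 split, middle to lower label."""
        seeds = np.zeros((11, 23), dtype=np.int64)
        seeds[5, 0] = 1
        seeds[5, 22] = 2
        corridor = np.zeros_like(seeds, dtype=bool)
        corridor[5, 1:22] = True
        out = geodesic_label_expansion(seeds, corridor)
        assert (out[5, 1:12] == 1).all()  # cols 1..11 incl. tied midpoint
        assert (out[5, 12:22] == 2).all()

    def test_no_seeds_empty_map(self):
        fibres = m.stage2_fibres([], np.ones((10, 10), bool), 1.0)
        assert (fibres.labels == 0).all()

    def test_unreachable_myelin_stays_background(self):
        seeds = np.zeros((12, 12), dtype=np.int64)
        seeds[2, 2] = 1
        myelin = np.zeros((12, 12), dtype=bool)
        myelin[2, 3] = True
        myelin[9:11, 9:11] = True  # disconnected patch
        out = geodesic_label_expansion(seeds, myelin)
        assert out[2, 3] == 1
        assert (out[9:11, 9:11] == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_per_seed_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        myelin = rng.random((64, 64)) < 0.45
        seeds = np.zeros((64, 64), dtype=np.int64)
        n_seeds = rng.integers(2, 6)
        placed = 0
        while placed < n_seeds:
            r, c = rng.integers(0, 64, 2)
            if seeds[r, c] == 0:
                placed += 1
                seeds[r, c] = placed
        myelin &= seeds == 0
        assert np.array_equal(
            geodesic_label_expansion(seeds, myelin), flooding_oracle(seeds, myelin)
        )

    def test_toggling_seed_changes_only_adjacent_territory(self):
        prob, ring, inner = annulus_probability_stack()
        # a second, far annulus
        prob2, ring2, inner2 = annulus_probability_stack(centre=(20, 20))
        big_ring = np.zeros((40, 80), dtype=bool)
        big_ring[:, :40] = ring
        big_ring[:, 40:] = ring2
        seeds = np.zeros((40, 80), dtype=np.int64)
        seeds[:, :40][inner] = 1
        seeds[:, 40:][inner2] = 2
        both = self._seed_candidates(seeds)
        only_one = [c for c in both if c.label == 1]
        f_both = m.stage2_fibres(both, big_ring, 1.0).labels
        f_one = m.stage2_fibres(only_one, big_ring, 1.0).labels
        changed = f_both != f_one
        assert set(np.unique(f_both[changed])) <= {2}


class TestStage3:
    def _inner_map(self):
        labels = np.zeros((40, 40), dtype=np.int64)
        labels[5:20, 5:20] = 7
        return m.InstanceMap(labels, m.ComponentKind.INNER_REGION, 1.0)

    def _classified(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["label", "predicted_class"])

    def test_axon_inside_inner_selected(self):
        cand = np.zeros((40, 40), dtype=np.int64)
        cand[8:15, 8:15] = 1
        out = m.stage3_axons(
            m.InstanceMap(cand, m.ComponentKind.AXON, 1.0),
            self._classified([(1, m.ObjectClass.AXON_LARGE)]),
            self._inner_map(),
        )
        assert len(out) == 1
        assert out[0].state is CandidateState.SELECTED and out[0].fibre_id == 7

    def test_low_overlap_dropped(self):
        cand = np.zeros((40, 40), dtype=np.int64)
        cand[15:25, 15:25] = 1  # 25% inside inner region (rows/cols 15..19)
        out = m.stage3_axons(
            m.InstanceMap(cand, m.ComponentKind.AXON, 1.0),
            self._classified([(1, m.ObjectClass.AXON_SMALL)]),
            self._inner_map(),
            overlap_fraction=0.5,
        )
        assert out == []

    def test_inner_tongue_retained_as_rejected(self):
        cand = np.zeros((40, 40), dtype=np.int64)
        cand[8:12, 8:12] = 1
        out = m.stage3_axons(
            m.InstanceMap(cand, m.ComponentKind.AXON, 1.0),
            self._classified([(1, m.ObjectClass.INNER_TONGUE)]),
            self._inner_map(),
        )
        assert len(out) == 1 and out[0].state is CandidateState.REJECTED

    def test_outside_any_inner_eliminated(self):
        cand = np.zeros((40, 40), dtype=np.int64)
        cand[30:38, 30:38] = 1
        out = m.stage3_axons(
            m.InstanceMap(cand, m.ComponentKind.AXON, 1.0),
            self._classified([(1, m.ObjectClass.AXON_LARGE)]),
            self._inner_map(),
        )
        assert out == []

    def test_largest_axon_wins_per_inner(self):
        cand = np.zeros((40, 40), dtype=np.int64)
        cand[6:9, 6:9] = 1
        cand[11:19, 11:19] = 2
        out = m.stage3_axons(
            m.InstanceMap(cand, m.ComponentKind.AXON, 1.0),
            self._classified(
                [(1, m.ObjectClass.AXON_SMALL), (2, m.ObjectClass.AXON_LARGE)]
            ),
            self._inner_map(),
        )
        states = {c.label: c.state for c in out}
        assert states[2] is CandidateState.SELECTED
        assert states[1] is CandidateState.REJECTED


class TestCuration:
    def _candidates(self):
        a = np.zeros((20, 20), dtype=bool)
        a[2:6, 2:6] = True
        return [RoiCandidate(1, a, Stage.INNER_REGION, CandidateState.REJECTED)]

    def test_toggle_rejected_to_selected(self):
        out = m.apply_curation(
            self._candidates(), m.CurationOverride(accept_labels=(1,)), (20, 20)
        )
        assert out[0].state is CandidateState.SELECTED

    def test_empty_override_is_identity(self):
        cands = self._candidates()
        out = m.apply_curation(cands, m.CurationOverride(), (20, 20))
        assert len(out) == 1 and out[0].state == cands[0].state
        assert (out[0].mask == cands[0].mask).all()

    def test_added_triangle_matches_scanline_oracle(self):
        tri = ((0.2, 0.2), (9.7, 0.3), (0.3, 9.6))
        out = m.apply_curation(
            self._candidates(),
            m.CurationOverride(added_polygons=(tri,)),
            (20, 20),
        )
        added = out[-1]
        assert added.state is CandidateState.SELECTED
        oracle = sum(
            point_in_polygon(float(c), float(r), tri)
            for r in range(20)
            for c in range(20)
        )
        assert added.area_px == oracle > 0

    def test_toggled_seed_restores_stage2_fibre(self):
        """Accepting a rejected inner region recovers its fibre downstream."""
        prob, ring, inner = annulus_probability_stack()
        cands = m.stage1_inner_regions(prob, min_area_px=20, max_area_fraction=0.01)
        assert all(c.state is CandidateState.REJECTED for c in cands)
        hole_label = [c.label for c in cands if (c.mask & inner).any()]
        fixed = m.apply_curation(
            cands, m.CurationOverride(accept_labels=tuple(hole_label)), prob.probabilities.shape[1:]
        )
        fibres = m.stage2_fibres(fixed, ring, 1.0)
        assert len(fibres.object_labels) == 1

    def test_overlapping_accept_reject_rejected(self):
        with pytest.raises(ValueError):
            m.CurationOverride(accept_labels=(1,), reject_labels=(1,))

    @pytest.mark.parametrize("poly", [((0, 0), (5, 5)), ((0, 0), (4, 0), (2, 2), (2, -2))])
    def test_malformed_polygons_rejected(self, poly):
        with pytest.raises(ValueError):
            rasterise_polygon(poly, (20, 20))


class TestCorrectAxon:
    def _axon(self, mask):
        return RoiCandidate(1, mask, Stage.AXON, CandidateState.SELECTED)

    def test_fill_holes_makes_annulus_solid(self):
        rr, cc = np.mgrid[0:30, 0:30]
        d = np.hypot(rr - 15, cc - 15)
        ring = (d >= 5) & (d <= 9)
        disk = d <= 9
        out = m.correct_axon(self._axon(ring), "fill_holes")
        assert (out.mask == disk).all()

    def test_convex_hull_idempotent_on_convex(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:12, 4:15] = True
        out = m.correct_axon(self._axon(mask), "convex_hull")
        assert (out.mask == mask).all()

    def test_l_shape_hull_matches_corner_point_oracle(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[1, 2] = mask[2, 1] = True
        out = m.correct_axon(self._axon(mask), "convex_hull")
        # oracle: pixel centres strictly interior to the convex hull of the
        # cell corner points (shapely); hull area 3.5, 3 interior centres
        from shapely.geometry import Point, box
        from shapely.ops import unary_union

        cells = unary_union(
            [box(c, r, c + 1, r + 1) for r, c in zip(*np.nonzero(mask))]
        )
        hull = cells.convex_hull
        assert hull.area == pytest.approx(3.5)
        oracle = sum(
            hull.contains(Point(c + 0.5, r + 0.5))
            for r in range(6)
            for c in range(6)
        )
        assert out.mask.sum() == oracle == 3

    @pytest.mark.parametrize("method", ["fill_holes", "convex_hull", "closing_r"])
    def test_area_never_decreases(self, method):
        rng = np.random.default_rng(9)
        mask = rng.random((25, 25)) < 0.3
        mask[12, 12] = True
        out = m.correct_axon(self._axon(mask), method)
        assert out.mask.sum() >= mask.sum()

    def test_unknown_method(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            m.correct_axon(self._axon(mask), "sharpen")

    def test_non_axon_stage_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        c = RoiCandidate(1, mask, Stage.INNER_REGION, CandidateState.SELECTED)
        with pytest.raises(ValueError):
            m.correct_axon(c, "fill_holes")
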