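"""Axis-extent morphometry: hand-checkable cases, brute-force oracles,
rotation and anisotropy behavior."""

from __future__ import annotations

import numpy as np
import pytest

from stromametry import (
    InstanceInfo,
    InstanceMap,
    SamplingDesign,
    measure_object,
    measure_vesicle_field,
    sample_volume,
    select_systematic_vesicles,
    select_targeted_vesicles,
    summarize_sizes,
)
from stromametry.morphometry import measure_category
from stromametry.phantom import LogNormalLength, LogitNormalRatio
from stromametry._raster import spheroid_offsets


def _instance_from_block(spans, spacing, pad=2):
    """An instance filling a rectangular block with the given voxel spans."""
    shape = tuple(s + 2 * pad for s in spans)
    vox = np.zeros(shape, dtype=np.int32)
    vox[pad : pad + spans[0], pad : pad + spans[1], pad : pad + spans[2]] = 1
    return InstanceMap(vox, spacing, {1: InstanceInfo("vesicle")})


class TestMeasureObject:
    def test_isotropic_spans_match_hand_calculation(self):
        """Spans (26, 26, 55) voxels at 50 nm: extents (1300, 1300, 2750),
        length 2750 nm, width 1300 nm, ratio 0.473."""
        imap = _instance_from_block((26, 26, 55), (50.0, 50.0, 50.0))
        m = measure_object(imap, 1)
        assert m.length == pytest.approx(2750.0)
        assert m.width == pytest.approx(1300.0)
        assert m.ratio == pytest.approx(1300 / 2750, abs=1e-9)

    def test_cube_has_unit_ratio(self):
        m = measure_object(_instance_from_block((7, 7, 7), (20.0, 20.0, 20.0)), 1)
        assert m.ratio == pytest.approx(1.0)
        assert m.length == m.width

    def test_anisotropy_converts_before_ordering(self):
        """Equal voxel spans at (50, 10, 10) nm: the z extent dominates."""
        imap = _instance_from_block((10, 10, 10), (50.0, 10.0, 10.0))
        m = measure_object(imap, 1)
        assert m.length == pytest.approx(500.0)
        assert m.width == pytest.approx(100.0)

    def test_matches_bounding_span_oracle_on_random_blobs(self, rng):
        for _ in range(25):
            shape = tuple(rng.integers(6, 20, 3))
            vox = np.zeros(shape, dtype=np.int32)
            n = rng.integers(3, 30)
            pts = np.column_stack([rng.integers(0, s, n) for s in shape])
            vox[pts[:, 0], pts[:, 1], pts[:, 2]] = 1
            spacing = tuple(rng.uniform(5, 60, 3))
            imap = InstanceMap(vox, spacing, {1: InstanceInfo("vesicle")})
            m = measure_object(imap, 1)
            spans = [pts[:, a].max() - pts[:, a].min() + 1 for a in range(3)]
            extents = sorted(s * sp for s, sp in zip(spans, spacing))
            assert m.length == pytest.approx(extents[2])
            assert m.width == pytest.approx((extents[0] + extents[1]) / 2)

    def test_rotated_ellipsoid_never_exceeds_unit_ratio(self, rng):
        for _ in range(30):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            offs = spheroid_offsets(900.0, 500.0, u, (50.0, 14.0, 14.0))
            lo = offs.min(axis=0)
            vox = np.zeros(tuple(offs.max(axis=0) - lo + 3), dtype=np.int32)
            rel = offs - lo + 1
            vox[rel[:, 0], rel[:, 1], rel[:, 2]] = 1
            imap = InstanceMap(vox, (50.0, 14.0, 14.0), {1: InstanceInfo("vesicle")})
            assert measure_object(imap, 1).ratio <= 1.0 + 1e-12

    def test_boundary_contact_sets_clipped_flag(self):
        vox = np.zeros((5, 5, 5), dtype=np.int32)
        vox[0:2, 1:3, 1:3] = 1
        imap = InstanceMap(vox, (10.0, 10.0, 10.0), {1: InstanceInfo("vesicle")})
        assert measure_object(imap, 1).boundary_clipped

    def test_empty_instance_rejected(self):
        imap = _instance_from_block((2, 2, 2), (10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            measure_object(imap, 99)

    def test_measure_category_agrees_with_measure_object(self, small_phantom):
        _, imap, _ = small_phantom
        batch = {m.instance_id: m for m in measure_category(imap, "vesicle")}
        for vid in list(batch)[:5]:
            single = measure_object(imap, vid)
            assert batch[vid].length == pytest.approx(single.length)
            assert batch[vid].width == pytest.approx(single.width)
            assert batch[vid].boundary_clipped == single.boundary_clipped


class TestSummaries:
    def test_median_range_skewness(self):
        imaps = [
            _instance_from_block((k, k, k), (1000.0, 1000.0, 1000.0))
            for k in (1, 2, 10)
        ]
        ms = [measure_object(im, 1) for im in imaps]
        s = summarize_sizes(ms, attribute="length")
        assert s.median == pytest.approx(2.0)
        assert (s.min, s.max) == (pytest.approx(1.0), pytest.approx(10.0))
        assert s.skewness > 0

    def test_single_measurement_degenerate_summary(self):
        m = measure_object(_instance_from_block((3, 3, 3), (100.0,) * 3), 1)
        s = summarize_sizes([m], attribute="length")
        assert s.min == s.median == s.max

    def test_clipped_measurements_excluded_by_default(self):
        vox = np.zeros((6, 6, 6), dtype=np.int32)
        vox[0:3, 1:3, 1:3] = 1  # touches z=0: clipped
        clipped = measure_object(
            InstanceMap(vox, (10.0,) * 3, {1: InstanceInfo("vesicle")}), 1
        )
        interior = measure_object(_instance_from_block((3, 2, 2), (10.0,) * 3), 1)
        s = summarize_sizes([clipped, interior])
        assert s.n == 1
        assert summarize_sizes([clipped, interior], include_clipped=True).n == 2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            summarize_sizes([])


class TestSelection:
    def test_no_vesicle_hits_gives_empty_set(self, small_phantom):
        assert select_systematic_vesicles([]) == set()

    def test_duplicate_hits_collapse(self, small_phantom):
        from stromametry.sampling import PointRecord

        recs = [
            PointRecord(0, 1.0, 1.0, "vesicle", 5),
            PointRecord(7, 2.0, 2.0, "vesicle", 5),
            PointRecord(3, 2.0, 2.0, "stroma_ecm", 0),
        ]
        assert select_systematic_vesicles(recs) == {5}

    def test_hits_are_size_biased(self, small_phantom):
        """Grid points hit large vesicles more often than small ones, so
        the mean true size of hit vesicles exceeds the population mean."""
        vol, imap, truth = small_phantom
        design = SamplingDesign(slice_period=4, start_window=4, grid_rows=8, grid_cols=8, seed=2)
        hits: set[int] = set()
        for k in range(60):
            table = sample_volume(vol, design, stack_index=k, instances=imap)
            hits |= select_systematic_vesicles(table.records, imap)
        assert hits  # with this density some vesicles are always hit
        truth_by_id = dict(zip(truth.vesicles.instance_id, truth.vesicles.true_length_nm))
        hit_mean = np.mean([truth_by_id[i] for i in hits])
        all_mean = np.mean(list(truth_by_id.values()))
        assert hit_mean > all_mean

    def test_targeted_selection_window_and_cap(self):
        lengths = {1: 100.0, 2: 250.0, 3: 290.0, 4: 310.0, 5: 120.0, 6: 200.0}
        groups = {1: "A", 2: "A", 3: "A", 4: "A", 5: "B", 6: "B"}
        picked = select_targeted_vesicles(lengths, groups, per_group=2, seed=0)
        assert len(picked) == 4
        assert 4 not in picked  # above the 300 nm window
        assert set(picked) & {5, 6} == {5, 6}

    def test_targeted_selection_empty_window(self):
        assert select_targeted_vesicles({1: 500.0}, {1: "A"}) == []


class TestFieldRecovery:
    def test_small_vesicle_population_median_recovered(self):
        """Typical-size (sub-300 nm) vesicle field: the measured median
        returns the generative 0.30 μm within 15%."""
        ms, _ = measure_vesicle_field(
            60,
            length_dist=LogNormalLength(300.0, 0.25),
            ratio_dist=LogitNormalRatio(0.67, 0.8),
            spacing=(25.0, 10.0, 10.0),
            seed=4,
        )
        s = summarize_sizes(ms, attribute="length", include_clipped=True)
        assert abs(s.median - 0.30) / 0.30 < 0.15

    def test_uniform_orientation_inflates_ratio(self):
        """Freely rotated ovoids measured by axis-aligned extents read
        rounder than they are: the measured ratio median exceeds the
        generative one."""
        gen = dict(
            length_dist=LogNormalLength(800.0, 0.3),
            ratio_dist=LogitNormalRatio(0.6, 0.3),
            spacing=(25.0, 10.0, 10.0),
            seed=9,
        )
        aligned, truth_a = measure_vesicle_field(40, orientation="axis_aligned", **gen)
        rotated, truth_r = measure_vesicle_field(40, orientation="uniform", **gen)
        aligned_med = summarize_sizes(aligned, attribute="ratio", include_clipped=True).median
        rotated_med = summarize_sizes(rotated, attribute="ratio", include_clipped=True).median
        assert aligned_med == pytest.approx(np.median(truth_a.true_ratio), abs=0.06)
        assert rotated_med > np.median(truth_r.true_ratio) + 0.05
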