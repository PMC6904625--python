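"""Systematic sampling: slice selection, grid geometry, point counting."""

from __future__ import annotations

import numpy as np
import pytest

from stromametry import (
    LabelVolume,
    PointCountTable,
    SamplingDesign,
    classify_points,
    make_grid,
    sample_volume,
    select_slices,
)
from stromametry.categories import CATEGORY_MAP, NAME_TO_CODE

from conftest import FixedRng


def _uniform_volume(code: int, shape=(10, 16, 16)) -> LabelVolume:
    return LabelVolume(np.full(shape, code, dtype=np.int16), (50.0, 14.0, 14.0))


class TestSelectSlices:
    def test_arithmetic_progression_from_start(self):
        design = SamplingDesign(seed=0)
        slices = select_slices(300, design, rng=FixedRng(integers=17))
        assert slices == [17, 67, 117, 167, 217, 267]

    def test_single_period_stack_yields_one_slice(self):
        design = SamplingDesign()
        for seed in range(20):
            slices = select_slices(50, design, rng=design.rng_for_stack(seed))
            assert len(slices) == 1
            assert 0 <= slices[0] < 50

    def test_period_boundary_inclusion(self):
        slices = select_slices(301, SamplingDesign(), rng=FixedRng(integers=0))
        assert slices == [0, 50, 100, 150, 200, 250, 300]
        assert len(slices) == 7

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            select_slices(0, SamplingDesign())


class TestMakeGrid:
    def test_four_by_four_gives_sixteen_points(self):
        pts = make_grid(800, 800, SamplingDesign(seed=1))
        assert pts.shape == (16, 2)
        rows = np.unique(np.round(pts[:, 0], 9))
        cols = np.unique(np.round(pts[:, 1], 9))
        assert np.allclose(np.diff(rows), 200.0)
        assert np.allclose(np.diff(cols), 200.0)

    def test_zero_offsets_pin_the_lattice(self):
        pts = make_grid(800, 800, SamplingDesign(), rng=FixedRng(uniforms=0.0))
        expected = {(200.0 * i, 200.0 * j) for i in range(4) for j in range(4)}
        assert {(r, c) for r, c in pts} == expected

    def test_points_always_inside_image(self):
        design = SamplingDesign()
        rng = np.random.default_rng(7)
        for _ in range(5000):
            pts = make_grid(97, 113, design, rng=rng)
            assert (pts[:, 0] >= 0).all() and (pts[:, 0] < 97).all()
            assert (pts[:, 1] >= 0).all() and (pts[:, 1] < 113).all()

    def test_image_smaller_than_grid_rejected(self):
        with pytest.raises(ValueError):
            make_grid(3, 100, SamplingDesign(grid_rows=4, grid_cols=4))


class TestClassifyPoints:
    def test_uniform_volume_counts_one_category(self):
        vol = _uniform_volume(NAME_TO_CODE["stroma_ecm"])
        table = sample_volume(vol, SamplingDesign(slice_period=2, start_window=2, seed=3))
        assert set(table.counts) == {"stroma_ecm"}
        assert table.n_points_total == table.n_slices_sampled * 16

    def test_count_conservation_invariant(self, small_phantom):
        vol, _, _ = small_phantom
        table = sample_volume(vol, SamplingDesign(seed=5))
        assert sum(table.counts.values()) == table.n_points_total
        assert table.n_points_total == table.n_slices_sampled * 16

    def test_half_split_volume_matches_binomial(self):
        """A 50/50 intervillous/ECM volume sampled many times: the point
        fraction converges to 0.5 within binomial error."""
        vox = np.zeros((4, 20, 20), dtype=np.int16)
        vox[:, :, 10:] = NAME_TO_CODE["stroma_ecm"]
        vol = LabelVolume(vox, (50.0, 14.0, 14.0))
        design = SamplingDesign(slice_period=1, start_window=1, seed=11)
        total = 0
        hits = 0
        for k in range(200):
            table = sample_volume(vol, design, stack_index=k)
            total += table.n_points_total
            hits += table.counts.get("stroma_ecm", 0)
        se = np.sqrt(0.25 / total)
        assert abs(hits / total - 0.5) < 4 * se

    def test_out_of_bounds_slice_rejected(self):
        vol = _uniform_volume(0)
        with pytest.raises(IndexError):
            classify_points(vol, [99], [np.array([[1.0, 1.0]])])

    def test_unbiasedness_against_voxel_fractions(self, rng):
        """Mean point fraction over many independent designs matches the
        exhaustive voxel fraction within 3 standard errors."""
        vox = (rng.random((12, 30, 30)) < 0.3).astype(np.int16) * NAME_TO_CODE["vesicle"]
        vol = LabelVolume(vox, (50.0, 14.0, 14.0))
        exact = (vox > 0).mean()
        design = SamplingDesign(slice_period=3, start_window=3, seed=23)
        total = 0
        hits = 0
        for k in range(300):
            t = sample_volume(vol, design, stack_index=k)
            total += t.n_points_total
            hits += t.counts.get("vesicle", 0)
        se = np.sqrt(exact * (1 - exact) / total)
        assert abs(hits / total - exact) < 3 * se


class TestMerge:
    def test_merge_pools_counts_and_points(self):
        vol = _uniform_volume(NAME_TO_CODE["stroma_ecm"])
        design = SamplingDesign(slice_period=2, start_window=2, seed=1)
        tables = [sample_volume(vol, design, stack_index=k) for k in range(3)]
        merged = PointCountTable.merge(tables, placenta_id="P1")
        assert merged.n_points_total == sum(t.n_points_total for t in tables)
        assert merged.counts["stroma_ecm"] == merged.n_points_total
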