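"""Composition estimation, volumes, running means, aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from stromametry import (
    CompositionEstimate,
    PointCountTable,
    SamplingDesign,
    aggregate_placentas,
    composition_estimate,
    running_mean,
    sample_volume,
    tissue_volume,
)


def _table(counts: dict[str, int]) -> PointCountTable:
    n = sum(counts.values())
    return PointCountTable(counts, n_slices_sampled=1, n_points_total=n)


class TestComposition:
    def test_hand_tally(self):
        """6 syncytio + 7 ECM + 2 stellate + 1 vesicle + 4 intervillous:
        villous denominator 16, stromal denominator 10."""
        est = composition_estimate(
            _table(
                {
                    "syncytiotrophoblast": 6,
                    "stroma_ecm": 7,
                    "stellate_cell": 2,
                    "vesicle": 1,
                    "intervillous_space": 4,
                }
            )
        )
        assert est.villous_fractions["syncytiotrophoblast"] == pytest.approx(6 / 16)
        assert est.stromal_compartment_of_villous == pytest.approx(10 / 16)
        assert est.stromal_fractions["vesicle"] == pytest.approx(1 / 10)
        assert sum(est.villous_fractions.values()) == pytest.approx(1.0)
        assert sum(est.stromal_fractions.values()) == pytest.approx(1.0)

    def test_single_category(self):
        est = composition_estimate(_table({"stroma_ecm": 12}))
        assert est.villous_fractions["stroma_ecm"] == 1.0
        assert est.stromal_fractions["stroma_ecm"] == 1.0

    def test_no_villous_points_rejected(self):
        with pytest.raises(ValueError):
            composition_estimate(_table({"intervillous_space": 5}))

    def test_no_stromal_points_leaves_villous_fractions(self):
        est = composition_estimate(
            _table({"syncytiotrophoblast": 3, "intervillous_space": 2})
        )
        assert est.stromal_fractions is None
        assert est.villous_fractions["syncytiotrophoblast"] == 1.0


class TestTissueVolume:
    def test_printed_count_split(self):
        """3136 villous points of 4944 total give 0.6343 of the region."""
        table = _table({"syncytiotrophoblast": 3136, "intervillous_space": 1808})
        v = tissue_volume(table, 1.0)
        assert v == pytest.approx(3136 / 4944, abs=1e-4)

    def test_all_points_on_tissue(self):
        assert tissue_volume(_table({"stroma_ecm": 10}), 7.5) == pytest.approx(7.5)

    def test_phantom_volume_within_sampling_error(self, small_phantom):
        vol, _, truth = small_phantom
        design = SamplingDesign(slice_period=10, start_window=10, seed=9)
        tables = [sample_volume(vol, design, stack_index=k) for k in range(20)]
        merged = PointCountTable.merge(tables)
        region = vol.voxels.size * vol.voxel_volume_nm3
        est = tissue_volume(merged, region)
        exact = (
            sum(v for k, v in truth.category_counts.items() if k != "intervillous_space")
            * vol.voxel_volume_nm3
        )
        p = exact / region
        se = np.sqrt(p * (1 - p) / merged.n_points_total) * region
        assert abs(est - exact) < 4 * se


class TestRunningMean:
    def test_cumulative_means(self):
        means, _ = running_mean([0.2, 0.4, 0.3])
        assert np.allclose(means, [0.2, 0.3, 0.3])

    def test_constant_series_is_adequate(self):
        _, adequate = running_mean([0.5] * 5)
        assert adequate
        _, short = running_mean([0.5] * 4)
        assert not short

    def test_noisy_series_usually_adequate(self):
        """A length-50 series with 10% CV stabilises its running mean in
        the vast majority of seeds."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            series = r.normal(1.0, 0.1, 50)
            if running_mean(series)[1]:
                hits += 1
        assert hits > 90

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            running_mean([])


class TestAggregate:
    def _estimate(self, villous, stromal):
        return CompositionEstimate(villous, stromal, 100, 50)

    def test_identical_estimates_zero_sem(self):
        e = self._estimate({"stroma_ecm": 1.0}, {"stroma_ecm": 1.0})
        agg = aggregate_placentas([e, e, e])
        assert agg.villous_sem["stroma_ecm"] == 0.0

    def test_two_placentas_mean_and_sem(self):
        """Fractions 10% and 20%: mean 15%, SEM = sd/sqrt(2) = 5%."""
        a = self._estimate({"vesicle": 0.10, "stroma_ecm": 0.90}, None)
        b = self._estimate({"vesicle": 0.20, "stroma_ecm": 0.80}, None)
        agg = aggregate_placentas([a, b])
        assert agg.villous_mean["vesicle"] == pytest.approx(0.15)
        assert agg.villous_sem["vesicle"] == pytest.approx(0.05)

    def test_single_estimate_mean_without_sem(self):
        agg = aggregate_placentas([self._estimate({"stroma_ecm": 1.0}, None)])
        assert agg.villous_mean["stroma_ecm"] == 1.0
        assert agg.villous_sem is None

    def test_mean_of_ratios_not_pooled_counts(self):
        """Aggregation averages per-placenta fractions, so placentas with
        very different point totals weigh equally."""
        a = CompositionEstimate({"stroma_ecm": 1.0}, {"stroma_ecm": 1.0}, 1000, 500)
        b = CompositionEstimate(
            {"stroma_ecm": 0.5, "syncytiotrophoblast": 0.5}, {"stroma_ecm": 1.0}, 10, 5
        )
        agg = aggregate_placentas([a, b])
        assert agg.villous_mean["stroma_ecm"] == pytest.approx(0.75)
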