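"""Turn point counts into volume fractions, volumes and adequacy checks.

Point counting estimates a volume fraction as a point fraction: if a
fraction p of systematically sampled grid points falls on a category, that
category occupies (in expectation) the fraction p of the reference volume.
Two denominators are reported, matching how villus composition is usually
tabulated: fractions of *villous tissue* (all points except intervillous
space) and fractions of the *stromal compartment* (ECM + vesicles +
stellate cells + macrophages).

Aggregation across placentas is mean-of-ratios: per-placenta fractions are
computed first and then averaged with their SEM, not pooled into a single
ratio of summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .categories import STROMAL_CATEGORIES, VILLOUS_CATEGORIES
from .sampling import PointCountTable, PointRecord

__all__ = [
    "CompositionEstimate",
    "AggregateEstimate",
    "composition_estimate",
    "tissue_volume",
    "running_mean",
    "aggregate_placentas",
    "per_slice_fractions",
]

#: Adequacy rule for running means: the last this-many running means must
#: all lie within +/- this relative band of the final value.
ADEQUACY_TAIL = 5
ADEQUACY_REL_TOL = 0.10


@dataclass
class CompositionEstimate:
    """Estimated composition from one stack or placenta.

    ``villous_fractions`` uses villous points as the denominator;
    ``stromal_fractions`` (over the four stromal categories) uses stromal
    points. Each block sums to 1 over the categories present.
    """

    villous_fractions: dict[str, float]
    stromal_fractions: Optional[dict[str, float]]
    n_villous_points: int
    n_stromal_points: int
    placenta_id: str = ""

    def __post_init__(self) -> None:
        if self.villous_fractions:
            s = sum(self.villous_fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"villous fractions sum to {s}, expected 1")
        if self.stromal_fractions is not None and self.stromal_fractions:
            s = sum(self.stromal_fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"stromal fractions sum to {s}, expected 1")

    @property
    def stromal_compartment_of_villous(self) -> float:
        """The stromal compartment as a fraction of villous tissue."""
        return sum(
            v for k, v in self.villous_fractions.items() if k in STROMAL_CATEGORIES
        )


@dataclass
class AggregateEstimate:
    """Across-placenta mean and SEM (sd/sqrt(n)) per category."""

    villous_mean: dict[str, float]
    villous_sem: Optional[dict[str, float]]
    stromal_mean: dict[str, float]
    stromal_sem: Optional[dict[str, float]]
    n_placentas: int

    @property
    def stromal_compartment_of_villous_mean(self) -> float:
        return sum(
            v for k, v in self.villous_mean.items() if k in STROMAL_CATEGORIES
        )


def composition_estimate(table: PointCountTable) -> CompositionEstimate:
    """Point fractions with villous and stromal denominators.

    Raises if no point fell on villous tissue; if no point fell on the
    stromal compartment the stromal block is ``None`` and the villous
    fractions are still returned.
    """
    villous = {k: v for k, v in table.counts.items() if k in VILLOUS_CATEGORIES}
    n_villous = sum(villous.values())
    if n_villous == 0:
        raise ValueError("no villous points: composition estimate undefined")
    villous_fractions = {k: v / n_villous for k, v in villous.items()}

    stromal = {k: v for k, v in villous.items() if k in STROMAL_CATEGORIES}
    n_stromal = sum(stromal.values())
    stromal_fractions = (
        {k: v / n_stromal for k, v in stromal.items()} if n_stromal > 0 else None
    )
    return CompositionEstimate(
        villous_fractions, stromal_fractions, n_villous, n_stromal, table.placenta_id
    )


def tissue_volume(table: PointCountTable, region_volume_nm3: float) -> float:
    """Absolute tissue volume: the villous point fraction of all points
    (including those on intervillous space) times the volume of the region
    analysed."""
    if table.n_points_total < 1:
        raise ValueError("point table is empty")
    if region_volume_nm3 <= 0:
        raise ValueError("region volume must be positive")
    n_tissue = sum(v for k, v in table.counts.items() if k in VILLOUS_CATEGORIES)
    return n_tissue / table.n_points_total * region_volume_nm3


def running_mean(per_slice_values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Cumulative means of a per-slice series plus a sampling-adequacy flag.

    The flag is true when the series is long enough and the last
    :data:`ADEQUACY_TAIL` running means all lie within
    +/-:data:`ADEQUACY_REL_TOL` (relative) of the final running mean —
    a quantitative stand-in for judging a plotted running mean to have
    stabilised.
    """
    values = np.asarray(per_slice_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    means = np.cumsum(values) / np.arange(1, values.size + 1)
    if values.size < ADEQUACY_TAIL:
        return means, False
    final = means[-1]
    tail = means[-ADEQUACY_TAIL:]
    if final == 0:
        adequate = bool(np.all(tail == 0))
    else:
        adequate = bool(np.all(np.abs(tail - final) <= ADEQUACY_REL_TOL * abs(final)))
    return means, adequate


def per_slice_fractions(
    records: Iterable[PointRecord],
    numerator: set[str] | frozenset[str],
    denominator: set[str] | frozenset[str],
) -> list[float]:
    """Per-sampled-slice point fractions, ordered by slice index, for
    feeding :func:`running_mean`. Slices with no denominator point are
    skipped."""
    by_slice: dict[int, tuple[int, int]] = {}
    for rec in records:
        num, den = by_slice.get(rec.slice_index, (0, 0))
        if rec.category in denominator:
            den += 1
            if rec.category in numerator:
                num += 1
        by_slice[rec.slice_index] = (num, den)
    return [num / den for _, (num, den) in sorted(by_slice.items()) if den > 0]


def aggregate_placentas(estimates: Sequence[CompositionEstimate]) -> AggregateEstimate:
    """Across-placenta mean and SEM of per-placenta fractions.

    Fractions are averaged per placenta (mean of ratios), so categories
    absent from a placenta's tally contribute zeros. With fewer than two
    estimates the mean is returned and the SEM blocks are ``None``.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    n = len(estimates)

    def collect(block: str) -> tuple[dict[str, float], Optional[dict[str, float]]]:
        cats: set[str] = set()
        for e in estimates:
            d = getattr(e, block)
            if d:
                cats.update(d)
        mean: dict[str, float] = {}
        sem: dict[str, float] = {}
        for c in sorted(cats):
            vals = np.array([(getattr(e, block) or {}).get(c, 0.0) for e in estimates])
            mean[c] = float(vals.mean())
            if n >= 2:
                sem[c] = float(vals.std(ddof=1) / np.sqrt(n))
        return mean, (sem if n >= 2 else None)

    villous_mean, villous_sem = collect("villous_fractions")
    stromal_mean, stromal_sem = collect("stromal_fractions")
    return AggregateEstimate(villous_mean, villous_sem, stromal_mean, stromal_sem, n)
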