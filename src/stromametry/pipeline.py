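"""End-to-end orchestration: phantom → sampling → estimation → morphometry
→ contacts → networks → report.

A run is described by a :class:`RunConfig` (usually loaded from JSON). The
pipeline generates (or loads) one labeled stack per placenta, applies the
systematic sampling design with several independent passes per placenta
(emulating multiple stacks per placenta), and assembles a results bundle:
composition tables with both denominators, vesicle size tables in μm,
contact and network summaries, statistical tests, running means, and a
provenance record. The same config and seed reproduce the bundle
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .categories import STROMAL_CATEGORIES, VILLOUS_CATEGORIES
from .contacts import compare_contact_sizes, contact_summary, detect_contacts, stellate_networks
from .estimators import (
    aggregate_placentas,
    composition_estimate,
    per_slice_fractions,
    running_mean,
)
from .io import (
    LabelVolume,
    read_instance_stack,
    read_label_stack,
    write_instance_stack,
    write_label_stack,
    write_tables,
)
from .morphometry import measure_category, select_systematic_vesicles, summarize_sizes
from .phantom import PhantomSpec, generate_phantom
from .sampling import PointCountTable, SamplingDesign, sample_volume
from .stats import ratio_below_one

__all__ = ["RunConfig", "run_pipeline"]


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("stromametry")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``phantom`` is set (synthetic mode: one phantom per placenta,
    seeds derived from the global seed) or ``label_stacks`` lists
    pre-segmented input volumes. ``passes_per_placenta`` controls how many
    independent sampling passes are pooled per placenta.
    """

    out_dir: str = "run"
    n_placentas: int = 8
    passes_per_placenta: int = 10
    design: SamplingDesign = field(default_factory=SamplingDesign)
    phantom: Optional[PhantomSpec] = field(default_factory=PhantomSpec)
    label_stacks: Optional[list[str]] = None
    instance_stacks: Optional[list[str]] = None
    spacing: tuple[float, float, float] = (50.0, 14.0, 14.0)
    seed: int = 0
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if self.phantom is None and not self.label_stacks:
            raise ValueError("config needs either a phantom spec or label stacks")
        if self.n_placentas < 1:
            raise ValueError("n_placentas must be >= 1")
        if self.passes_per_placenta < 1:
            raise ValueError("passes_per_placenta must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "design" in kwargs and isinstance(kwargs["design"], dict):
            kwargs["design"] = SamplingDesign(**kwargs["design"])
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            ph = dict(kwargs["phantom"])
            for key in ("shape", "spacing"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomSpec(**ph)
        if "spacing" in kwargs:
            kwargs["spacing"] = tuple(kwargs["spacing"])
        return cls(**kwargs)


def _placenta_volumes(config: RunConfig):
    """Yield (placenta_id, LabelVolume, InstanceMap | None, truth | None)."""
    if config.label_stacks:
        from .categories import CATEGORY_MAP

        for i, path in enumerate(config.label_stacks):
            vol = read_label_stack(path, config.spacing, dict(CATEGORY_MAP))
            imap = None
            if config.instance_stacks and i < len(config.instance_stacks):
                imap = read_instance_stack(config.instance_stacks[i], config.spacing)
            yield f"P{i + 1}", vol, imap, None
    else:
        for i in range(config.n_placentas):
            spec = config.phantom.with_seed(config.seed * 1000 + i + 1)
            vol, imap, truth = generate_phantom(spec)
            yield f"P{i + 1}", vol, imap, truth


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the results bundle under ``out_dir``.

    Returns the bundle as a dict of DataFrames / dicts; the same content
    is written as CSV tables plus ``report.json``.
    """
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)

    estimates = []
    truth_rows = []
    measurements_all = []
    contact_records_all = []
    network_sizes_all: list[int] = []
    running_rows = []
    systematic_hits = 0

    for p_idx, (pid, vol, imap, truth) in enumerate(_placenta_volumes(config)):
        if config.save_volumes:
            (out / "volumes").mkdir(exist_ok=True)
            write_label_stack(vol, out / "volumes" / f"{pid}_labels.tif")
            if imap is not None:
                write_instance_stack(imap, out / "volumes" / f"{pid}_instances.tif")

        design = SamplingDesign(
            slice_period=config.design.slice_period,
            start_window=config.design.start_window,
            grid_rows=config.design.grid_rows,
            grid_cols=config.design.grid_cols,
            seed=config.seed * 100_000 + p_idx,
        )
        tables = [
            sample_volume(vol, design, stack_index=k, instances=imap, placenta_id=pid)
            for k in range(config.passes_per_placenta)
        ]
        merged = PointCountTable.merge(tables, placenta_id=pid)
        est = composition_estimate(merged)
        estimates.append(est)

        series = per_slice_fractions(
            merged.records, STROMAL_CATEGORIES, VILLOUS_CATEGORIES
        )
        means, adequate = running_mean(series)
        running_rows.append(
            {
                "placenta_id": pid,
                "n_slices": len(series),
                "final_running_mean": float(means[-1]) if len(means) else float("nan"),
                "adequate": adequate,
            }
        )

        if imap is not None:
            hits = select_systematic_vesicles(merged.records, imap)
            systematic_hits += len(hits)
            ms = measure_category(imap, "vesicle", selection_mode="systematic")
            recs = detect_contacts(vol, imap)
            measurements_all.extend(ms)
            contact_records_all.extend(recs)
            try:
                nets = stellate_networks(imap)
                network_sizes_all.extend(nets.sizes)
            except ValueError:
                pass

        if truth is not None:
            row = {"placenta_id": pid}
            row.update({f"true_villous_{k}": v for k, v in truth.villous_fractions.items()})
            row.update({f"true_stromal_{k}": v for k, v in truth.stromal_fractions.items()})
            truth_rows.append(row)

    # ---- assemble tables ----------------------------------------------------
    agg = aggregate_placentas(estimates)
    comp_rows = []
    for cat_name in sorted(agg.villous_mean):
        comp_rows.append(
            {
                "category": cat_name,
                "denominator": "villous",
                "mean_pct": 100 * agg.villous_mean[cat_name],
                "sem_pct": 100 * agg.villous_sem[cat_name] if agg.villous_sem else float("nan"),
            }
        )
    for cat_name in sorted(agg.stromal_mean):
        comp_rows.append(
            {
                "category": cat_name,
                "denominator": "stromal",
                "mean_pct": 100 * agg.stromal_mean[cat_name],
                "sem_pct": 100 * agg.stromal_sem[cat_name] if agg.stromal_sem else float("nan"),
            }
        )
    composition = pd.DataFrame(comp_rows)

    size_rows = []
    tests = {}
    contacts = {}
    networks = {}
    if measurements_all:
        for attr in ("length", "width", "ratio"):
            s = summarize_sizes(measurements_all, attribute=attr)
            size_rows.append(
                {
                    "attribute": attr,
                    "n": s.n,
                    "median": round(s.median, 2),
                    "min": round(s.min, 2),
                    "max": round(s.max, 2),
                    "skewness": s.skewness,
                }
            )
        ratios = [m.ratio for m in measurements_all if not m.boundary_clipped]
        if len(ratios) >= 5:
            t = ratio_below_one(ratios)
            tests["ratio_below_one"] = {
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n": t.n,
                "mode": t.mode,
            }
        contacts = contact_summary(contact_records_all)
        try:
            cmp_sizes = compare_contact_sizes(measurements_all, contact_records_all)
            tests["contact_size_comparison"] = {
                "median_contact_um": cmp_sizes.median_contact_um,
                "n_contact": cmp_sizes.n_contact,
                "median_no_contact_um": cmp_sizes.median_no_contact_um,
                "n_no_contact": cmp_sizes.n_no_contact,
                "p_value": cmp_sizes.test.p_value,
                "mode": cmp_sizes.test.mode,
            }
        except ValueError:
            pass
    if network_sizes_all:
        arr = np.asarray(network_sizes_all, dtype=float)
        networks = {
            "n_networks": int(arr.size),
            "mean_nuclei_per_network": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None,
        }

    sizes = pd.DataFrame(
        size_rows, columns=["attribute", "n", "median", "min", "max", "skewness"]
    )
    running = pd.DataFrame(running_rows)
    bundle_tables = {"composition": composition, "vesicle_sizes": sizes, "running_means": running}
    if truth_rows:
        bundle_tables["ground_truth"] = pd.DataFrame(truth_rows)
    write_tables(bundle_tables, out / "tables")

    report = {
        "version": _pkg_version(),
        "seed": config.seed,
        "n_placentas": config.n_placentas,
        "passes_per_placenta": config.passes_per_placenta,
        "n_points_total": sum(e.n_villous_points for e in estimates),
        "systematic_vesicle_hits": systematic_hits,
        "stromal_compartment_pct_of_villous": 100 * agg.stromal_compartment_of_villous_mean,
        "contacts": contacts,
        "networks": networks,
        "tests": tests,
        "config": _config_echo(config),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return {
        "composition": composition,
        "sizes": sizes,
        "running_means": running,
        "aggregate": agg,
        "contacts": contacts,
        "networks": networks,
        "tests": tests,
        "report": report,
    }


def _config_echo(config: RunConfig) -> dict[str, Any]:
    """JSON-serializable echo of the config for provenance."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    return clean(asdict(config))
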