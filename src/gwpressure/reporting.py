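"""End-to-end pipeline, tabular reports and map rendering.

Ties the stages together — grid, merge, layer loading or simulation,
scoring, classification, well allocation — and writes the report bundle:

* ``layer_summary.csv`` — name, weight, point count, whole-layer total
  score (the published-table schema);
* ``block_scores.csv`` — one row per block with per-layer counts and the
  weighted total (1-decimal, as reported) plus the raw float;
* ``allocations.csv`` — block id, pressure class, wells;
* ``allocation_summary.csv`` — per-class block counts and wells;
* ``blocks.geojson`` — block geometries with score/class/wells properties;
* ``results.json`` — machine-readable sidecar at full precision.

All tabular numbers are printed with one decimal place; outputs are
byte-identical across runs for the same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping as _mapping, shape as _shape

from .classify import ClassScheme, WellAllocation, allocate_wells, place_wells
from .geometry import GridBlock, StudyArea, make_grid, merge_small_blocks
from .layers import LayerRegistry, layer_total_score, load_points, load_registry
from .scoring import BlockScore, score_all
from .simulate import SimulationConfig, simulate_area, simulate_layers

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "render_map",
    "blocks_to_feature_collection",
    "read_blocks_geojson",
    "layer_summary_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults reproduce the study
    setup (10 km cells, the 12-layer default registry, 4 classes with
    1–4 wells)."""

    area_path: str | None = None  # GeoJSON/WKT file; None -> simulate area
    crs_id: str = "unspecified"
    weight_table: str = "default"
    point_files: dict[str, str] = field(default_factory=dict)
    simulation: SimulationConfig | None = None  # used when point_files empty
    cell_size: float = 10_000.0
    min_area_fraction: float = 0.5
    scheme: ClassScheme = field(default_factory=ClassScheme)
    well_mode: str = "none"  # none | centroid | pressure_weighted
    out_dir: str = "gwpressure_out"
    seed: int = 0


@dataclass
class PipelineResult:
    area: StudyArea
    blocks: list[GridBlock]
    registry: LayerRegistry
    scores: list[BlockScore]
    unassigned: dict[str, int]
    allocations: list[WellAllocation]
    summary: "object"
    out_files: dict[str, Path] = field(default_factory=dict)


def _load_area(config: PipelineConfig) -> StudyArea:
    path = Path(config.area_path)
    text = path.read_text()
    if path.suffix.lower() in (".geojson", ".json"):
        return StudyArea.from_geojson(json.loads(text), crs_id=config.crs_id)
    return StudyArea.from_wkt(text.strip(), crs_id=config.crs_id)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute grid -> merge -> layers -> score -> classify -> allocate and
    write the report bundle to ``config.out_dir``.

    Raises on any stage failure after removing partial outputs, so a
    present bundle is always complete.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out_dir: Path, written: list[Path]) -> PipelineResult:
    sim = config.simulation or SimulationConfig(seed=config.seed)

    # --- area
    if config.area_path is not None:
        area = _load_area(config)
    else:
        area = simulate_area(sim)
    logger.info("stage area: polygon of %.1f km^2 (CRS %s)", area.area / 1e6, area.crs_id)

    # --- grid + merge
    blocks = make_grid(area, config.cell_size)
    logger.info("stage grid: %d raw blocks at %.0f m cells", len(blocks), config.cell_size)
    blocks = merge_small_blocks(blocks, config.min_area_fraction)
    n_merged = sum(1 for b in blocks if b.merged_from)
    logger.info("stage merge: %d blocks (%d absorbed fragments)", len(blocks), n_merged)

    # --- layers
    registry = load_registry(config.weight_table)
    if config.point_files:
        for name, path in config.point_files.items():
            layer = load_points(name, path, registry=registry)
            registry.replace_layer(layer)
        logger.info("stage layers: loaded %d point file(s)", len(config.point_files))
    else:
        registry = simulate_layers(area, sim, registry)
        logger.info(
            "stage layers: simulated %d points over %d layers (%s process)",
            sum(l.n_points for l in registry),
            len(registry),
            sim.process,
        )

    # --- score
    scores, unassigned = score_all(blocks, registry)
    for name, n in unassigned.items():
        if n:
            logger.warning("layer %r: %d unassigned point(s) outside the area", name, n)
    logger.info(
        "stage score: totals in [%.1f, %.1f] over %d blocks",
        min((s.total for s in scores), default=0.0),
        max((s.total for s in scores), default=0.0),
        len(scores),
    )

    # --- classify + allocate
    allocations, summary = allocate_wells(scores, config.scheme)
    if config.well_mode != "none":
        by_id = {b.block_id: b for b in blocks}
        for alloc in allocations:
            place_wells(
                alloc,
                by_id[alloc.block_id],
                mode=config.well_mode,
                seed=config.seed,
                registry=registry,
            )
    logger.info(
        "stage allocate: blocks per class %s, total wells %d",
        summary.blocks_per_class,
        summary.total_wells,
    )

    # --- reports
    out: dict[str, Path] = {}

    def _register(name: str, path: Path) -> Path:
        written.append(path)
        out[name] = path
        return path

    layer_summary_frame(registry).to_csv(
        _register("layer_summary", out_dir / "layer_summary.csv"),
        index=False, float_format="%.1f",
    )
    _scores_frame(scores, registry).to_csv(
        _register("block_scores", out_dir / "block_scores.csv"), index=False
    )
    _allocations_frame(allocations).to_csv(
        _register("allocations", out_dir / "allocations.csv"), index=False
    )
    _summary_frame(summary).to_csv(
        _register("allocation_summary", out_dir / "allocation_summary.csv"), index=False
    )
    fc = blocks_to_feature_collection(blocks, scores, allocations)
    with open(_register("blocks_geojson", out_dir / "blocks.geojson"), "w") as fh:
        json.dump(fc, fh, sort_keys=True)
    sidecar = {
        "blocks": {
            s.block_id: {"raw_total": s.raw_total, "counts": s.counts} for s in scores
        },
        "unassigned": unassigned,
        "blocks_per_class": summary.blocks_per_class,
        "wells_per_class": summary.wells_per_class,
        "total_wells": summary.total_wells,
    }
    with open(_register("results_json", out_dir / "results.json"), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)

    return PipelineResult(
        area=area,
        blocks=blocks,
        registry=registry,
        scores=scores,
        unassigned=unassigned,
        allocations=allocations,
        summary=summary,
        out_files=out,
    )


def layer_summary_frame(registry: LayerRegistry) -> pd.DataFrame:
    """Per-layer summary: name, weight, point count, total score."""
    return pd.DataFrame(
        {
            "layer": registry.names(),
            "weight": [l.weight for l in registry],
            "n_points": [l.n_points for l in registry],
            "total_score": [round(layer_total_score(l), 1) for l in registry],
        }
    )


def _scores_frame(scores: list[BlockScore], registry: LayerRegistry) -> pd.DataFrame:
    rows = []
    for s in scores:
        row: dict = {"block_id": s.block_id}
        for name in registry.names():
            row[name] = s.counts.get(name, 0)
        row["total"] = f"{s.total:.1f}"
        row["raw_total"] = repr(s.raw_total)
        rows.append(row)
    return pd.DataFrame(rows)


def _allocations_frame(allocations: list[WellAllocation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_id": [a.block_id for a in allocations],
            "pressure_class": [a.pressure_class for a in allocations],
            "n_wells": [a.n_wells for a in allocations],
        }
    )


def _summary_frame(summary) -> pd.DataFrame:
    classes = sorted(summary.blocks_per_class)
    return pd.DataFrame(
        {
            "pressure_class": classes,
            "n_blocks": [summary.blocks_per_class[c] for c in classes],
            "n_wells": [summary.wells_per_class[c] for c in classes],
        }
    )


def blocks_to_feature_collection(
    blocks: list[GridBlock],
    scores: list[BlockScore] | None = None,
    allocations: list[WellAllocation] | None = None,
) -> dict:
    """Blocks (optionally with score/class/wells properties) as GeoJSON."""
    score_by_id = {s.block_id: s for s in (scores or [])}
    alloc_by_id = {a.block_id: a for a in (allocations or [])}
    features = []
    for b in blocks:
        props: dict = {
            "block_id": b.block_id,
            "actual_area": b.actual_area,
            "nominal_area": b.nominal_area,
            "merged_from": list(b.merged_from),
            "cells": [list(rc) for rc in b.cells],
        }
        s = score_by_id.get(b.block_id)
        if s is not None:
            props["total"] = s.total
            props["raw_total"] = s.raw_total
            props["counts"] = s.counts
        a = alloc_by_id.get(b.block_id)
        if a is not None:
            props["pressure_class"] = a.pressure_class
            props["n_wells"] = a.n_wells
            if a.suggested_sites is not None:
                props["suggested_sites"] = [list(p) for p in a.suggested_sites]
        features.append(
            {"type": "Feature", "properties": props, "geometry": _mapping(b.geometry)}
        )
    return {"type": "FeatureCollection", "features": features}


def read_blocks_geojson(path: str | Path) -> tuple[list[GridBlock], list[BlockScore], list[WellAllocation]]:
    """Re-read a pipeline blocks.geojson; inverse of
    :func:`blocks_to_feature_collection` for the round-trip contract."""
    with open(path) as fh:
        obj = json.load(fh)
    blocks, scores, allocations = [], [], []
    for feat in obj["features"]:
        p = feat["properties"]
        blocks.append(
            GridBlock(
                block_id=p["block_id"],
                geometry=_shape(feat["geometry"]),
                nominal_area=p["nominal_area"],
                actual_area=p["actual_area"],
                merged_from=list(p.get("merged_from", [])),
                cells=[tuple(rc) for rc in p.get("cells", [])],
            )
        )
        if "raw_total" in p:
            scores.append(
                BlockScore(
                    block_id=p["block_id"],
                    counts={k: int(v) for k, v in p.get("counts", {}).items()},
                    raw_total=p["raw_total"],
                )
            )
        if "pressure_class" in p:
            allocations.append(
                WellAllocation(
                    block_id=p["block_id"],
                    pressure_class=p["pressure_class"],
                    n_wells=p["n_wells"],
                    suggested_sites=[tuple(s) for s in p["suggested_sites"]]
                    if "suggested_sites" in p
                    else None,
                )
            )
    return blocks, scores, allocations


def render_map(
    blocks: list[GridBlock],
    allocations: list[WellAllocation],
    output: str | Path,
    scheme: ClassScheme | None = None,
) -> Path:
    """Choropleth of pressure classes with an optional well overlay.

    Class k always maps to the same color intensity (a fixed sequential
    ramp over classes 1..K); wells are drawn at their suggested sites
    when present.  Purely presentational.
    """
    if not blocks:
        raise ValueError("no blocks to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    scheme = scheme or ClassScheme()
    cmap = plt.get_cmap("YlOrRd")
    colors = {
        c: cmap(0.2 + 0.8 * (c - 1) / max(1, scheme.n_classes - 1))
        for c in range(1, scheme.n_classes + 1)
    }
    alloc_by_id = {a.block_id: a for a in allocations}

    fig, ax = plt.subplots(figsize=(7, 8))
    for b in blocks:
        a = alloc_by_id.get(b.block_id)
        face = colors.get(a.pressure_class if a else 1, "0.8")
        geoms = getattr(b.geometry, "geoms", [b.geometry])
        for g in geoms:
            ax.add_patch(
                MplPolygon(list(g.exterior.coords), facecolor=face, edgecolor="k", lw=0.5)
            )
        if a and a.suggested_sites:
            xs, ys = zip(*a.suggested_sites)
            ax.plot(xs, ys, "o", color="navy", ms=4)
    xs0 = [b.geometry.bounds[0] for b in blocks] + [b.geometry.bounds[2] for b in blocks]
    ys0 = [b.geometry.bounds[1] for b in blocks] + [b.geometry.bounds[3] for b in blocks]
    ax.set_xlim(min(xs0), max(xs0))
    ax.set_ylim(min(ys0), max(ys0))
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title("Groundwater pressure classes")
    handles = [
        plt.Rectangle((0, 0), 1, 1, facecolor=colors[c], edgecolor="k")
        for c in sorted(colors)
    ]
    ax.legend(handles, [f"class {c}" for c in sorted(colors)], loc="lower right", fontsize=8)
    output = Path(output)
    fig.savefig(output, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return output
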