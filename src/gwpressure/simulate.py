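"""Synthetic study areas and pressure-point layers.

The institutional GIS layers behind a real pressure assessment (permit
registries, landfill cadastres, sinkhole inventories) are generally not
redistributable, so this module generates stand-ins with controlled
spatial structure: a study-area polygon (a plain rectangle, a shipped
synthetic coastal-peninsula outline, or a user polygon) and, inside it,
one point set per registry layer.

Default layer point counts match the Salento study's published per-layer
inventory (1 591 points over 12 layers), so whole-layer score totals are
reproduced exactly regardless of where the points fall.  Two spatial
processes are available: homogeneous (uniform rejection sampling in the
polygon) and clustered (a Thomas-type parent–offspring process), since
the real data's clustering is unknown but affects how scores concentrate
in blocks.

Randomness is deterministic given the root seed; each layer draws from
its own substream derived from (seed, layer index), so adding or
reordering layers does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import shapely
from shapely.geometry import shape as _shape

from .geometry import StudyArea, ValidationError
from .layers import LayerRegistry, load_registry

__all__ = [
    "SimulationConfig",
    "DEFAULT_LAYER_COUNTS",
    "simulate_area",
    "simulate_layers",
    "peninsula_fixture",
]

#: Default number of points per layer (the published per-layer inventory
#: of identified pressures; 1 591 points in total).
DEFAULT_LAYER_COUNTS: dict[str, int] = {
    "Urban Waste Water discharges": 34,
    "Industrial Plants (Integrated Environmental Authorization)": 37,
    "Potentially Contaminated Sites": 28,
    "Companies authorized for Waste storage and management": 69,
    "Companies authorized to emit certain atmospheric pollutants": 164,
    "PCB Waste treatment and management Plants": 7,
    "Livestock farm": 770,
    "Active quarries": 222,
    "Urban solid waste landfill": 10,
    "Major-accident hazards industrial activities": 4,
    "Disused and abandoned quarries": 22,
    "Sinkholes": 224,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic scenario.

    ``extent`` (m) only applies to ``area_spec="rectangle"``; the default
    60 km x 55 km is comparable to the Salento peninsula and yields ~30
    ten-kilometer blocks.  ``cluster_params`` is ``(n_parents,
    dispersion_radius_m)`` for the clustered process; the radius is the
    isotropic (Gaussian sigma) offspring displacement.
    """

    area_spec: str = "rectangle"  # rectangle | peninsula_fixture | user_polygon
    extent: tuple[float, float] = (60_000.0, 55_000.0)
    user_polygon: StudyArea | None = None
    layer_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_COUNTS)
    )
    process: str = "uniform"  # uniform | clustered
    cluster_params: tuple[int, float] = (25, 3_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_spec not in ("rectangle", "peninsula_fixture", "user_polygon"):
            raise ValidationError(f"unknown area_spec {self.area_spec!r}")
        if self.process not in ("uniform", "clustered"):
            raise ValidationError(f"unknown process {self.process!r}")
        if any(n < 0 for n in self.layer_counts.values()):
            raise ValidationError("layer counts must be non-negative")
        n_parents, radius = self.cluster_params
        if self.process == "clustered" and (n_parents < 1 or radius <= 0):
            raise ValidationError(
                "clustered process needs >= 1 parent and a positive dispersion radius"
            )


def peninsula_fixture() -> StudyArea:
    """The shipped synthetic coastal-peninsula polygon.

    An irregular outline in a projected metric frame (~2 670 km^2) whose
    10 km gridding produces both full interior cells and undersized
    coastal fragments, exercising the merge step.
    """
    text = (
        resources.files("gwpressure.data")
        .joinpath("peninsula_synthetic.geojson")
        .read_text()
    )
    obj = json.loads(text)
    crs = obj.get("properties", {}).get("crs_id", "synthetic-metric")
    return StudyArea(_shape(obj["geometry"]), crs_id=crs)


def simulate_area(spec: SimulationConfig) -> StudyArea:
    """Produce the study-area polygon for a scenario."""
    if spec.area_spec == "rectangle":
        w, h = spec.extent
        if w <= 0 or h <= 0:
            raise ValidationError(f"degenerate rectangle extent {spec.extent}")
        return StudyArea(shapely.box(0.0, 0.0, w, h), crs_id="synthetic-metric")
    if spec.area_spec == "peninsula_fixture":
        return peninsula_fixture()
    if spec.user_polygon is None:
        raise ValidationError("area_spec='user_polygon' but no polygon supplied")
    return spec.user_polygon


def _layer_rng(seed: int, layer_index: int) -> np.random.Generator:
    # independent substream per layer: adding a layer leaves others intact
    return np.random.default_rng(np.random.SeedSequence([seed, layer_index]))


def _uniform_in_polygon(polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous points inside the polygon by bbox rejection sampling."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, int((n - len(out)) * 2.5))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(polygon, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def _clustered_in_polygon(
    polygon, n: int, n_parents: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Thomas-type process: uniform parents, Gaussian offspring, clipped.

    Each point picks a parent uniformly and is displaced isotropically
    (sigma = radius); draws falling outside the polygon are resampled, so
    exactly n in-polygon points are returned.
    """
    parents = _uniform_in_polygon(polygon, n_parents, rng)
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(64, int(need * 2.5))
        idx = rng.integers(0, n_parents, m)
        pts = parents[idx] + rng.normal(0.0, radius, size=(m, 2))
        keep = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        kept = pts[keep][:need]
        out.append(kept)
        need -= len(kept)
    return np.vstack(out) if out else np.empty((0, 2))


def simulate_layers(
    area: StudyArea,
    spec: SimulationConfig,
    registry: LayerRegistry | None = None,
) -> LayerRegistry:
    """Fill a registry's layers with simulated in-area points.

    Every configured layer receives exactly its configured number of
    points, all strictly inside the area polygon.  Layers of the registry
    absent from ``spec.layer_counts`` get zero points.
    """
    if area.area <= 0:
        raise ValidationError("zero-area polygon")
    registry = registry if registry is not None else load_registry("default")
    for name in spec.layer_counts:
        if name not in registry:
            raise ValidationError(f"layer_counts names unknown layer {name!r}")
    polygon = area.boundary
    n_parents, radius = spec.cluster_params
    for i, layer in enumerate(list(registry)):
        n = spec.layer_counts.get(layer.name, 0)
        rng = _layer_rng(spec.seed, i)
        if spec.process == "uniform":
            pts = _uniform_in_polygon(polygon, n, rng)
        else:
            pts = _clustered_in_polygon(polygon, n, n_parents, radius, rng)
        registry.replace_layer(
            layer.with_points([(float(x), float(y)) for x, y in pts])
        )
    return registry
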