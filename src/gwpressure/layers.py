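"""The weighted pressure-layer registry.

Each layer is a named set of georeferenced point sources of one kind of
pressure on groundwater (waste-water discharges, landfills, livestock
farms, ...) together with a weight ``w_i`` in [0, 1] expressing its
potential impact.  The default registry carries the 12 layers of the
Salento-area study: 11 anthropic pressures and one natural pressure
(sinkholes — recharge points of the karst aquifer).

The per-layer total score is simply ``|points| * w_i``; the per-block
score computed in :mod:`gwpressure.scoring` is the weighted sum
``sum_i n_i w_i`` of the in-block counts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .geometry import ValidationError

__all__ = [
    "PressureLayer",
    "LayerRegistry",
    "DEFAULT_LAYER_TABLE",
    "load_registry",
    "load_points",
    "layer_total_score",
]

#: (name, weight, kind) of the 12 default layers.  Weights are decimal
#: fractions in [0, 1] set by expert judgment; sinkholes is the single
#: natural (hydrogeological) pressure.
DEFAULT_LAYER_TABLE: tuple[tuple[str, float, str], ...] = (
    ("Urban Waste Water discharges", 0.3, "anthropic"),
    ("Industrial Plants (Integrated Environmental Authorization)", 0.8, "anthropic"),
    ("Potentially Contaminated Sites", 1.0, "anthropic"),
    ("Companies authorized for Waste storage and management", 0.8, "anthropic"),
    ("Companies authorized to emit certain atmospheric pollutants", 0.5, "anthropic"),
    ("PCB Waste treatment and management Plants", 1.0, "anthropic"),
    ("Livestock farm", 0.1, "anthropic"),
    ("Active quarries", 0.2, "anthropic"),
    ("Urban solid waste landfill", 1.0, "anthropic"),
    ("Major-accident hazards industrial activities", 0.2, "anthropic"),
    ("Disused and abandoned quarries", 0.6, "anthropic"),
    ("Sinkholes", 0.8, "natural"),
)


def _canon(name: str) -> str:
    """Case-insensitive, whitespace-normalized form used for name matching."""
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class PressureLayer:
    """A named point set with an impact weight ``w`` in [0, 1]."""

    name: str
    weight: float
    points: tuple[tuple[float, float], ...] = ()
    kind: str = "anthropic"
    crs_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(
                f"layer {self.name!r}: weight {self.weight} outside [0, 1]"
            )
        if self.kind not in ("anthropic", "natural"):
            raise ValidationError(f"layer {self.name!r}: unknown kind {self.kind!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_points(self, points) -> "PressureLayer":
        return replace(self, points=tuple((float(x), float(y)) for x, y in points))


@dataclass
class LayerRegistry:
    """Ordered collection of pressure layers with unique names."""

    layers: list[PressureLayer] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for layer in self.layers:
            key = _canon(layer.name)
            if key in seen:
                raise ValidationError(f"duplicate layer name {layer.name!r}")
            seen.add(key)

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def get(self, name: str) -> PressureLayer:
        key = _canon(name)
        for layer in self.layers:
            if _canon(layer.name) == key:
                return layer
        raise KeyError(f"unknown layer {name!r}")

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
        except KeyError:
            return False
        return True

    def weight(self, name: str) -> float:
        return self.get(name).weight

    def replace_layer(self, layer: PressureLayer) -> None:
        key = _canon(layer.name)
        for i, existing in enumerate(self.layers):
            if _canon(existing.name) == key:
                self.layers[i] = layer
                return
        raise KeyError(f"unknown layer {layer.name!r}")

    def names(self) -> list[str]:
        return [layer.name for layer in self.layers]


def load_registry(config: str | Path = "default") -> LayerRegistry:
    """Build a registry from ``"default"`` or a CSV/TSV weight table.

    A weight-table file needs columns ``name`` and ``weight`` (``kind`` is
    optional, defaulting to anthropic).  Weights outside [0, 1] and
    duplicate names raise :class:`ValidationError`.
    """
    if isinstance(config, str) and config == "default":
        return LayerRegistry(
            layers=[
                PressureLayer(name=n, weight=w, kind=k)
                for n, w, k in DEFAULT_LAYER_TABLE
            ],
            source="built-in default (12 layers)",
        )
    path = Path(config)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    layers: list[PressureLayer] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ValidationError(f"{path}: weight table needs 'name' and 'weight' columns")
        for i, row in enumerate(reader):
            try:
                weight = float(row["weight"].replace(",", "."))
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path} row {i}: bad weight {row.get('weight')!r}") from exc
            layers.append(
                PressureLayer(
                    name=row["name"].strip(),
                    weight=weight,
                    kind=(row.get("kind") or "anthropic").strip(),
                )
            )
    return LayerRegistry(layers=layers, source=str(path))


def load_points(layer_name: str, source: str | Path, registry: LayerRegistry | None = None) -> PressureLayer:
    """Read point locations for one layer from GeoJSON or CSV.

    CSV needs numeric ``x`` and ``y`` columns; GeoJSON must be a
    FeatureCollection of Points (or a bare MultiPoint/Point geometry).
    Exact duplicate coordinates are retained — two facilities can share a
    location.  If ``registry`` is given the layer must already exist in it
    (its weight and kind are reused); unknown names are an error rather
    than silently creating a layer.
    """
    if registry is not None:
        try:
            template = registry.get(layer_name)
        except KeyError:
            raise ValidationError(f"unknown layer name {layer_name!r}") from None
    else:
        template = PressureLayer(name=layer_name, weight=0.0)

    path = Path(source)
    if path.suffix.lower() in (".geojson", ".json"):
        points = _read_geojson_points(path)
    else:
        points = _read_csv_points(path)
    return template.with_points(points)


def _read_csv_points(path: Path) -> list[tuple[float, float]]:
    points: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
            raise ValidationError(f"{path}: point CSV needs 'x' and 'y' columns")
        for i, row in enumerate(reader):
            try:
                points.append((float(row["x"]), float(row["y"])))
            except ValueError as exc:
                raise ValidationError(
                    f"{path} row {i}: non-numeric coordinates ({row['x']!r}, {row['y']!r})"
                ) from exc
    return points


def _read_geojson_points(path: Path) -> list[tuple[float, float]]:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise IOError(f"{path}: not parseable as GeoJSON: {exc}") from exc
    if obj.get("type") == "FeatureCollection":
        points = []
        for i, feat in enumerate(obj.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValidationError(
                    f"{path}: feature {i} is {geom.get('type')!r}, expected Point"
                )
            x, y = geom["coordinates"][:2]
            points.append((float(x), float(y)))
        return points
    if obj.get("type") == "Point":
        x, y = obj["coordinates"][:2]
        return [(float(x), float(y))]
    if obj.get("type") == "MultiPoint":
        return [(float(x), float(y)) for x, y in obj["coordinates"]]
    raise ValidationError(f"{path}: unsupported GeoJSON type {obj.get('type')!r}")


def layer_total_score(layer: PressureLayer) -> float:
    """Whole-layer score: number of points times the layer weight."""
    return layer.n_points * layer.weight
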