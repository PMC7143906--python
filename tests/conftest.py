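import math

import pytest
from shapely.geometry import Point, Polygon

from gwpressure import (
    StudyArea,
    load_registry,
    make_grid,
    peninsula_fixture,
)

CELL = 10_000.0


@pytest.fixture
def square_area():
    """Exact 2x2 tiling at 10 km cells."""
    return StudyArea(Polygon([(0, 0), (20_000, 0), (20_000, 20_000), (0, 20_000)]))


@pytest.fixture
def rect_area():
    """25 km x 10 km: two full cells and one half cell."""
    return StudyArea(Polygon([(0, 0), (25_000, 0), (25_000, 10_000), (0, 10_000)]))


@pytest.fixture(scope="session")
def peninsula():
    return peninsula_fixture()


@pytest.fixture(scope="session")
def peninsula_blocks(peninsula):
    return make_grid(peninsula, CELL)


@pytest.fixture
def registry():
    return load_registry("default")


def brute_force_cells(area: StudyArea, cell_size: float):
    """Independent oracle: scan every bounding-box cell and keep those with
    a nonempty intersection with the area polygon."""
    minx, miny, maxx, maxy = area.boundary.bounds
    ncols = math.ceil((maxx - minx) / cell_size - 1e-12)
    nrows = math.ceil((maxy - miny) / cell_size - 1e-12)
    kept = {}
    for r in range(nrows):
        for c in range(ncols):
            cell = Polygon(
                [
                    (minx + c * cell_size, miny + r * cell_size),
                    (minx + (c + 1) * cell_size, miny + r * cell_size),
                    (minx + (c + 1) * cell_size, miny + (r + 1) * cell_size),
                    (minx + c * cell_size, miny + (r + 1) * cell_size),
                ]
            )
            piece = cell.intersection(area.boundary)
            if not piece.is_empty and piece.area > 1e-9 * cell_size**2:
                kept[(r, c)] = piece
    return kept


def naive_assign(blocks, points):
    """Independent oracle: test each point against each block polygon,
    assigning to the first covering block in ascending block_id order."""
    ordered = sorted(blocks, key=lambda b: b.block_id)
    counts = {b.block_id: 0 for b in ordered}
    unassigned = 0
    for x, y in points:
        pt = Point(x, y)
        for b in ordered:
            if b.geometry.covers(pt):
                counts[b.block_id] += 1
                break
        else:
            unassigned += 1
    return counts, unassigned
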