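"""Grid construction, adjacency and small-block merging."""

import math

import pytest
from shapely.geometry import Polygon

from gwpressure import (
    GridBlock,
    StudyArea,
    ValidationError,
    block_adjacency,
    make_grid,
    merge_small_blocks,
)
from gwpressure.geometry import ISOLATED_SENTINEL

from conftest import CELL, brute_force_cells


class TestStudyArea:
    def test_rejects_invalid_polygon(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValidationError):
            StudyArea(bowtie)

    def test_rejects_zero_area(self):
        with pytest.raises(ValidationError):
            StudyArea(Polygon([(0, 0), (1, 0), (2, 0)]))

    @pytest.mark.parametrize("crs", ["EPSG:4326", "WGS84", "epsg:4326"])
    def test_rejects_geographic_crs(self, crs):
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(ValidationError, match="geographic"):
            StudyArea(poly, crs_id=crs)

    def test_accepts_projected_crs(self):
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert StudyArea(poly, crs_id="EPSG:32634").crs_id == "EPSG:32634"


class TestMakeGrid:
    def test_exact_square_tiling(self, square_area):
        blocks = make_grid(square_area, CELL)
        assert len(blocks) == 4
        assert all(b.actual_area == pytest.approx(1e8) for b in blocks)
        assert all(b.merged_from == [] for b in blocks)

    def test_rectangle_with_partial_column(self, rect_area):
        blocks = make_grid(rect_area, CELL)
        areas = sorted(b.actual_area for b in blocks)
        assert areas == pytest.approx([5e7, 1e8, 1e8])

    def test_cell_size_must_be_positive(self, square_area):
        with pytest.raises(ValueError):
            make_grid(square_area, 0)

    def test_peninsula_matches_brute_force_scan(self, peninsula, peninsula_blocks):
        oracle = brute_force_cells(peninsula, CELL)
        assert len(peninsula_blocks) == len(oracle)
        by_cell = {b.cells[0]: b for b in peninsula_blocks}
        assert set(by_cell) == set(oracle)
        for rc, piece in oracle.items():
            assert by_cell[rc].actual_area == pytest.approx(piece.area)

    def test_tiling_covers_area(self, peninsula, peninsula_blocks):
        total = sum(b.actual_area for b in peninsula_blocks)
        assert abs(total - peninsula.area) <= 1e-6 * peninsula.area

    def test_interiors_are_disjoint(self, peninsula_blocks):
        nominal = peninsula_blocks[0].nominal_area
        for i, a in enumerate(peninsula_blocks):
            for b in peninsula_blocks[i + 1 :]:
                inter = a.geometry.intersection(b.geometry)
                assert inter.area <= 1e-9 * nominal

    def test_deterministic(self, peninsula):
        a = make_grid(peninsula, CELL)
        b = make_grid(peninsula, CELL)
        assert [x.block_id for x in a] == [y.block_id for y in b]
        assert all(x.geometry.equals(y.geometry) for x, y in zip(a, b))


class TestAdjacency:
    def test_rook_adjacency_2x2(self, square_area):
        blocks = make_grid(square_area, CELL)
        adj = block_adjacency(blocks)
        assert all(len(nbrs) == 2 for nbrs in adj.values())
        # corner contact (diagonal) must not count
        assert "r01c01" not in adj["r00c00"]

    def test_strip_1x3(self, rect_area):
        adj = block_adjacency(make_grid(rect_area, CELL))
        degrees = sorted(len(v) for v in adj.values())
        assert degrees == [1, 1, 2]
        assert len(adj["r00c01"]) == 2

    def test_peninsula_matches_all_pairs_oracle(self, peninsula_blocks):
        adj = block_adjacency(peninsula_blocks)
        for i, a in enumerate(peninsula_blocks):
            for b in peninsula_blocks[i + 1 :]:
                shared = a.geometry.intersection(b.geometry).length
                expected = shared > 0
                assert (b.block_id in adj[a.block_id]) == expected
                assert (a.block_id in adj[b.block_id]) == expected


class TestMergeSmallBlocks:
    def test_small_block_absorbed_by_neighbor(self, rect_area):
        blocks = make_grid(rect_area, CELL)
        merged = merge_small_blocks(blocks, 0.6)
        assert len(merged) == 2
        absorber = next(b for b in merged if b.merged_from)
        assert absorber.block_id == "r00c01"
        assert absorber.merged_from == ["r00c02"]
        assert absorber.actual_area == pytest.approx(1.5e8)

    def test_full_blocks_untouched(self, square_area):
        blocks = make_grid(square_area, CELL)
        merged = merge_small_blocks(blocks, 0.5)
        assert [b.block_id for b in merged] == [b.block_id for b in blocks]
        assert all(b.merged_from == [] for b in merged)

    def test_area_conserved_and_no_undersized_left(self, peninsula, peninsula_blocks):
        merged = merge_small_blocks(peninsula_blocks, 0.5)
        before = sum(b.actual_area for b in peninsula_blocks)
        after = sum(b.actual_area for b in merged)
        assert after == pytest.approx(before, rel=1e-9)
        assert abs(after - peninsula.area) <= 1e-6 * peninsula.area
        for b in merged:
            assert (
                b.actual_area >= 0.5 * b.nominal_area
                or b.merged_from == [ISOLATED_SENTINEL]
            )

    def test_merge_exercised_by_peninsula(self, peninsula_blocks):
        assert any(b.actual_area < 0.5 * b.nominal_area for b in peninsula_blocks)
        merged = merge_small_blocks(peninsula_blocks, 0.5)
        assert len(merged) < len(peninsula_blocks)

    def test_idempotent(self, peninsula_blocks):
        once = merge_small_blocks(peninsula_blocks, 0.5)
        twice = merge_small_blocks(once, 0.5)
        assert [b.block_id for b in once] == [b.block_id for b in twice]
        assert all(
            a.geometry.equals(b.geometry) and a.merged_from == b.merged_from
            for a, b in zip(once, twice)
        )

    def test_isolated_undersized_block_flagged(self):
        # a lone fragment with no neighbor at all
        poly = Polygon([(0, 0), (3000, 0), (3000, 3000), (0, 3000)])
        blocks = make_grid(StudyArea(poly), CELL)
        merged = merge_small_blocks(blocks, 0.5)
        assert len(merged) == 1
        assert merged[0].merged_from == [ISOLATED_SENTINEL]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            merge_small_blocks([], 0.5)

    def test_input_not_mutated(self, peninsula_blocks):
        ids = [b.block_id for b in peninsula_blocks]
        areas = [b.actual_area for b in peninsula_blocks]
        merge_small_blocks(peninsula_blocks, 0.5)
        assert [b.block_id for b in peninsula_blocks] == ids
        assert [b.actual_area for b in peninsula_blocks] == areas
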