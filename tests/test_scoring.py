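"""Point-to-block assignment and the weighted block score."""

import numpy as np
import pytest

from gwpressure import (
    PressureLayer,
    SimulationConfig,
    ValidationError,
    assign_points,
    block_score,
    make_grid,
    merge_small_blocks,
    score_all,
    simulate_layers,
)

from conftest import CELL, naive_assign


@pytest.fixture
def square_blocks(square_area):
    return make_grid(square_area, CELL)


class TestAssignPoints:
    def test_single_interior_point(self, square_blocks):
        layer = PressureLayer("Foo", 0.5, points=((2_500.0, 2_500.0),))
        counts, unassigned = assign_points(square_blocks, layer)
        assert counts == {"r00c00": 1, "r00c01": 0, "r01c00": 0, "r01c01": 0}
        assert unassigned == 0

    def test_point_on_shared_edge_counted_once(self, square_blocks):
        # on the interior vertical grid line: half-open rule -> right cell
        layer = PressureLayer("Foo", 0.5, points=((10_000.0, 2_500.0),))
        counts, unassigned = assign_points(square_blocks, layer)
        assert sum(counts.values()) == 1
        assert unassigned == 0
        assert counts["r00c01"] == 1

    def test_point_on_grid_corner_counted_once(self, square_blocks):
        layer = PressureLayer("Foo", 0.5, points=((10_000.0, 10_000.0),))
        counts, _ = assign_points(square_blocks, layer)
        assert sum(counts.values()) == 1
        assert counts["r01c01"] == 1  # upper-right of the corner

    def test_outside_points_reported_unassigned(self, square_blocks):
        layer = PressureLayer("Foo", 0.5, points=((-5_000.0, -5_000.0), (2.0, 2.0)))
        counts, unassigned = assign_points(square_blocks, layer)
        assert unassigned == 1
        assert sum(counts.values()) == 1

    def test_crs_mismatch_rejected(self, square_blocks):
        layer = PressureLayer("Foo", 0.5, points=((1.0, 1.0),), crs_id="EPSG:32633")
        with pytest.raises(ValidationError, match="CRS"):
            assign_points(square_blocks, layer, expected_crs="EPSG:32634")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle_on_peninsula(self, peninsula, peninsula_blocks, seed):
        """Seeded uniform points over the fixture: fast assignment equals
        the all-pairs point-in-polygon loop, including after merging."""
        rng = np.random.default_rng(seed)
        minx, miny, maxx, maxy = peninsula.boundary.bounds
        pts = tuple(
            (float(x), float(y))
            for x, y in zip(
                rng.uniform(minx - 2_000, maxx + 2_000, 1_000),
                rng.uniform(miny - 2_000, maxy + 2_000, 1_000),
            )
        )
        layer = PressureLayer("Foo", 0.5, points=pts)
        for blocks in (peninsula_blocks, merge_small_blocks(peninsula_blocks, 0.5)):
            counts, unassigned = assign_points(blocks, layer)
            expect_counts, expect_unassigned = naive_assign(blocks, pts)
            assert counts == expect_counts
            assert unassigned == expect_unassigned

    def test_merged_block_collects_absorbed_cells(self, rect_area):
        blocks = merge_small_blocks(make_grid(rect_area, CELL), 0.6)
        # point in the absorbed half-cell counts toward the absorber
        layer = PressureLayer("Foo", 0.5, points=((22_000.0, 5_000.0),))
        counts, _ = assign_points(blocks, layer)
        assert counts == {"r00c00": 0, "r00c01": 1}


class TestBlockScore:
    def test_weighted_sum(self, registry):
        s = block_score({"Sinkholes": 2, "Livestock farm": 10}, registry)
        assert s.raw_total == pytest.approx(2 * 0.8 + 10 * 0.1)
        assert s.total == 2.6

    def test_all_zero_counts(self, registry):
        assert block_score({n: 0 for n in registry.names()}, registry).raw_total == 0.0

    def test_single_unit_weight_layer(self, registry):
        s = block_score({"Potentially Contaminated Sites": 28}, registry)
        assert s.total == 28.0

    def test_unknown_layer_rejected(self, registry):
        with pytest.raises(ValidationError, match="unknown layer"):
            block_score({"Bogus": 1}, registry)

    def test_negative_count_rejected(self, registry):
        with pytest.raises(ValidationError, match="negative"):
            block_score({"Sinkholes": -1}, registry)


class TestScoreAll:
    def test_empty_layers_score_zero(self, peninsula_blocks, registry):
        scores, unassigned = score_all(peninsula_blocks, registry)
        assert all(s.raw_total == 0.0 for s in scores)
        assert all(v == 0 for v in unassigned.values())

    @pytest.mark.parametrize("process", ["uniform", "clustered"])
    def test_conservation(self, peninsula, peninsula_blocks, registry, process):
        """Sum of block raw totals equals sum_i n_i w_i over in-area points."""
        spec = SimulationConfig(
            area_spec="peninsula_fixture", process=process, seed=11
        )
        reg = simulate_layers(peninsula, spec, registry)
        scores, unassigned = score_all(peninsula_blocks, reg)
        assert all(v == 0 for v in unassigned.values())
        expected = sum(l.n_points * l.weight for l in reg)
        assert abs(sum(s.raw_total for s in scores) - expected) < 1e-9

    def test_additivity_of_moving_one_point(self, square_blocks, registry):
        a = (2_000.0, 2_000.0)  # in r00c00
        b = (12_000.0, 12_000.0)  # in r01c01
        reg_a = registry
        reg_a.replace_layer(reg_a.get("Sinkholes").with_points([a]))
        scores_a, _ = score_all(square_blocks, reg_a)
        reg_a.replace_layer(reg_a.get("Sinkholes").with_points([b]))
        scores_b, _ = score_all(square_blocks, reg_a)
        delta = {
            s.block_id: sb.raw_total - s.raw_total
            for s, sb in zip(scores_a, scores_b)
        }
        assert delta["r00c00"] == pytest.approx(-0.8)
        assert delta["r01c01"] == pytest.approx(+0.8)
        assert delta["r00c01"] == delta["r01c00"] == 0.0

    def test_permutation_invariance(self, square_blocks, registry):
        pts = [(2_000.0, 2_000.0), (15_000.0, 3_000.0), (8_000.0, 17_000.0)]
        registry.replace_layer(registry.get("Active quarries").with_points(pts))
        fwd, _ = score_all(square_blocks, registry)
        registry.replace_layer(
            registry.get("Active quarries").with_points(list(reversed(pts)))
        )
        rev, _ = score_all(square_blocks, registry)
        assert [(s.block_id, s.raw_total) for s in fwd] == [
            (s.block_id, s.raw_total) for s in rev
        ]

    def test_monotone_in_added_points(self, square_blocks, registry):
        registry.replace_layer(
            registry.get("Sinkholes").with_points([(2_000.0, 2_000.0)])
        )
        before, _ = score_all(square_blocks, registry)
        registry.replace_layer(
            registry.get("Sinkholes").with_points(
                [(2_000.0, 2_000.0), (12_000.0, 2_000.0)]
            )
        )
        after, _ = score_all(square_blocks, registry)
        assert all(b.raw_total >= a.raw_total for a, b in zip(before, after))
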