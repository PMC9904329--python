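"""Board/occluder geometry, hidden-cell counting, and trial designs."""

import math

import numpy as np
import pytest

from hiddenum import geometry
from hiddenum.geometry import (GeometryError, OcclusionGeometry,
                               enumerate_trials, expected_hidden,
                               make_bar_occluder, make_board,
                               make_mesh_occluder, no_occluder,
                               occluder_mask, occlusion_geometry,
                               place_pieces)


class TestBoard:
    @pytest.mark.parametrize("rows,cols,scale,cells,px", [
        (13, 9, 1.0, 117, (390, 507)),
        (1, 1, 1.0, 1, None),
        (13, 9, 0.5, 117, (195, 254)),  # rounded halves of 390 x 507
    ])
    def test_dimensions(self, rows, cols, scale, cells, px):
        b = make_board(rows, cols, scale)
        assert b.n_cells == cells
        if px is not None:
            assert b.board_px == px

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            make_board(0, 9)
        with pytest.raises(ValueError):
            make_board(13, 9, scale=-1)

    def test_nonstandard_scale_warns(self):
        with pytest.warns(UserWarning):
            make_board(scale=0.33)


class TestMeshOccluder:
    def test_twelve_holes_six_per_class(self, small_mesh):
        assert len(small_mesh.hole_centers) == 12
        diams = [d for (_, _, d) in small_mesh.hole_centers]
        assert sum(1 for d in diams if d == 40) == 6
        assert sum(1 for d in diams if d == 60) == 6

    def test_mirror_symmetry_about_vertical_midline(self):
        for pattern in (1, 2):
            occ = make_mesh_occluder(40, 60, pattern_id=pattern)
            w = occ.occluder_px[0]
            holes = {(round(w - x, 6), round(y, 6), d)
                     for (x, y, d) in occ.hole_centers}
            orig = {(round(x, 6), round(y, 6), d)
                    for (x, y, d) in occ.hole_centers}
            assert holes == orig

    def test_deterministic(self):
        a = make_mesh_occluder(40, 60, 1, 1)
        b = make_mesh_occluder(40, 60, 1, 1)
        assert a.hole_centers == b.hole_centers

    def test_hole_area_increases_with_diameters(self):
        def total_area(occ):
            return sum(math.pi * (d / 2) ** 2 for (_, _, d) in occ.hole_centers)
        assert total_area(make_mesh_occluder(25, 35)) < \
            total_area(make_mesh_occluder(58, 63))

    def test_oversized_holes_rejected(self):
        with pytest.raises(GeometryError):
            make_mesh_occluder(90, 200)

    def test_bad_diameter_order(self):
        with pytest.raises(ValueError):
            make_mesh_occluder(60, 40)


class TestBarOccluder:
    def test_vertical_covers_four_columns(self, board, vertical_bars):
        covered = {c for (c0, c1) in vertical_bars.bar_extent
                   for c in range(c0, c1 + 1)}
        assert len(covered) == 4

    def test_horizontal_covers_six_rows(self, horizontal_bars):
        covered = {r for (r0, r1) in horizontal_bars.bar_extent
                   for r in range(r0, r1 + 1)}
        assert len(covered) == 6

    def test_invalid_orientation(self):
        with pytest.raises(ValueError):
            make_bar_occluder("diagonal")


class TestOcclusionGeometry:
    def test_vertical_bars_counts(self, board, vertical_bars):
        g = occlusion_geometry(board, vertical_bars)
        assert (g.N_h, g.N_v) == (52, 65)
        assert g.ratio == pytest.approx(0.8)

    def test_horizontal_bars_counts(self, board, horizontal_bars):
        g = occlusion_geometry(board, horizontal_bars)
        assert g.N_h == 6 * 9

    def test_no_occluder(self, board):
        g = occlusion_geometry(board, no_occluder())
        assert (g.N_h, g.N_v) == (0, 117)

    def test_partition(self, board, vertical_bars, horizontal_bars, small_mesh):
        for occ in (vertical_bars, horizontal_bars, small_mesh, no_occluder()):
            g = occlusion_geometry(board, occ)
            assert g.N_v + g.N_h == board.n_cells

    def test_huge_holes_hide_nothing(self, board):
        # holes grown (past the overlap limit, built directly) to cover
        # every piece location leave nothing hidden
        base = make_mesh_occluder(40, 60)
        holes = tuple((x, y, 160.0) for (x, y, _) in base.hole_centers)
        occ = geometry.OccluderSpec(kind="mesh", occluder_px=base.occluder_px,
                                    hole_diams=(160.0, 160.0),
                                    hole_centers=holes)
        g = occlusion_geometry(board, occ)
        assert g.N_h == 0

    def test_monotone_in_hole_size(self, board):
        # shrinking holes (more occluder material) never decreases N_h
        menu = [(58, 63), (40, 60), (30, 45), (25, 35)]
        counts = [occlusion_geometry(board, make_mesh_occluder(s, l)).N_h
                  for (s, l) in menu]
        assert counts == sorted(counts)

    def test_brute_force_pixel_oracle(self, board, small_mesh, vertical_bars):
        # independent per-pixel check of the hidden-cell decision
        for occ in (small_mesh, vertical_bars):
            mask = occluder_mask(board, occ)
            g = occlusion_geometry(board, occ)
            r = board.piece_px / 2.0
            h, w = mask.shape
            hidden = set()
            for row in range(board.rows):
                for col in range(board.cols):
                    cx, cy = board.cell_center(row, col)
                    ok = True
                    for iy in range(max(int(cy - r) - 2, 0),
                                    min(int(cy + r) + 3, h)):
                        for ix in range(max(int(cx - r) - 2, 0),
                                        min(int(cx + r) + 3, w)):
                            if (ix + 0.5 - cx) ** 2 + (iy + 0.5 - cy) ** 2 <= r * r \
                                    and not mask[iy, ix]:
                                ok = False
                                break
                        if not ok:
                            break
                    if ok:
                        hidden.add((row, col))
            assert hidden == set(g.hidden_cells)


class TestExpectedHidden:
    def test_printed_ratio_small_occluder(self):
        g = OcclusionGeometry.from_ratio(0.27)
        assert expected_hidden(10, g) == pytest.approx(2.7)

    def test_zero_visible(self):
        g = OcclusionGeometry.from_ratio(0.27)
        assert expected_hidden(0, g) == 0.0

    def test_vertical_bar_geometry(self, board, vertical_bars):
        g = occlusion_geometry(board, vertical_bars)
        assert expected_hidden(10, g) == pytest.approx(8.0)

    def test_linearity(self, board, vertical_bars):
        g = occlusion_geometry(board, vertical_bars)
        for a in (0.0, 0.5, 2.0, 7.0):
            assert expected_hidden(a * 3, g) == pytest.approx(
                a * expected_hidden(3, g))

    def test_zero_visible_area_raises(self):
        g = OcclusionGeometry(N_v=0, N_h=117, S_v=0.0, S_h=117.0)
        with pytest.raises(ZeroDivisionError):
            expected_hidden(5, g)


class TestTrialEnumeration:
    @pytest.mark.parametrize("exp,total,analyzed", [
        (1, 352, 330), (2, 279, 270), (3, 231, 231), (4, 150, 150),
        (5, 189, 189),
    ])
    def test_row_counts(self, exp, total, analyzed):
        t = enumerate_trials(exp)
        assert len(t) == total
        assert int(t["analyzed"].sum()) == analyzed

    def test_exp1_composition(self):
        t = enumerate_trials(1)
        assert (t["condition"] == "obscured").sum() == 11
        assert (t["condition"] == "swapped").sum() == 11
        assert not t.loc[t["condition"].isin(["obscured", "swapped"]),
                         "analyzed"].any()
        assert (t["n_visible_std"] == 10).all()

    def test_exp5_pairs_unique(self):
        t = enumerate_trials(5)
        pairs = list(zip(t["n_visible_std"], t["n_visible_cmp"]))
        assert len(set(pairs)) == len(pairs) == 189

    def test_exp2_single_repetition(self):
        t = enumerate_trials(2, {"repetitions": 1})
        assert len(t) == 9 * 3 * 1 + 9

    def test_unknown_experiment(self):
        with pytest.raises(ValueError):
            enumerate_trials(6)


class TestPiecePlacement:
    def test_empty_layout(self, board):
        layout = place_pieces(board, no_occluder(), 0, "irregular", 1)
        assert layout.cells == ()

    def test_seed_determinism(self, board, vertical_bars):
        a = place_pieces(board, vertical_bars, 10, "irregular", 7)
        b = place_pieces(board, vertical_bars, 10, "irregular", 7)
        assert a.cells == b.cells and a.colors == b.colors

    def test_color_balance(self, board):
        for n in (9, 10):
            layout = place_pieces(board, no_occluder(), n, "irregular", 3)
            blacks = sum(1 for c in layout.colors if c == "black")
            assert abs(blacks - (n - blacks)) <= 1

    def test_pieces_on_distinct_visible_cells(self, board, vertical_bars):
        g = occlusion_geometry(board, vertical_bars)
        layout = place_pieces(board, vertical_bars, 12, "irregular", 5)
        assert len(set(layout.cells)) == 12
        assert not set(layout.cells) & set(g.hidden_cells)

    @pytest.mark.parametrize("n", [5, 10, 12])
    def test_irregular_no_contiguous_line_segment(self, board, vertical_bars, n):
        from hiddenum.geometry import _has_collinear_triplet
        layout = place_pieces(board, vertical_bars, n, "irregular", 11)
        assert not _has_collinear_triplet(list(layout.cells))

    def test_regular_across_crosses_bars(self, board, vertical_bars):
        layout = place_pieces(board, vertical_bars, 10, "regular_across", 2)
        rows_used = {r for (r, _) in layout.cells}
        covered = {c for (c0, c1) in vertical_bars.bar_extent
                   for c in range(c0, c1 + 1)}
        assert len(rows_used) == 2  # two full rows of 5 visible pieces
        # every used row crosses the covered columns
        g = occlusion_geometry(board, vertical_bars)
        for r in rows_used:
            assert any((r, c) in set(g.hidden_cells) for c in covered)

    def test_regular_outside_avoids_bars(self, board, vertical_bars):
        layout = place_pieces(board, vertical_bars, 10, "regular_outside", 2)
        covered = {c for (c0, c1) in vertical_bars.bar_extent
                   for c in range(c0, c1 + 1)}
        assert all(c not in covered for (_, c) in layout.cells)

    def test_matched_expected_hidden_for_full_lines(self, board):
        # for numerosities that fill whole lines, the occluded cells the
        # across-lines span equal the constant-density expectation
        vb = make_bar_occluder("vertical")
        g = occlusion_geometry(board, vb)
        layout = place_pieces(board, vb, 10, "regular_across", 0)
        rows_used = {r for (r, _) in layout.cells}
        hidden_on_lines = sum(1 for (r, c) in g.hidden_cells if r in rows_used)
        assert hidden_on_lines == expected_hidden(10, g)

    def test_infeasible_placement(self, board, vertical_bars):
        with pytest.raises(GeometryError):
            place_pieces(board, vertical_bars, 1000, "irregular", 0)
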