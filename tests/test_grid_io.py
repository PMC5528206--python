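import math

import numpy as np
import pytest

from nichediverge.errors import DegenerateDataError, DimensionError, GridFormatError
from nichediverge.grid_io import (
    Grid,
    GridHeader,
    LayerStack,
    cell_of,
    correlation_screen,
    extract_values,
    read_ascii_grid,
    write_ascii_grid,
)

from conftest import random_masked_grid


class TestAsciiGridIO:
    def test_round_trip_identity_on_random_masked_grids(self, tmp_path, rng):
        for i in range(10):
            g = random_masked_grid(rng)
            p = tmp_path / f"g{i}.asc"
            write_ascii_grid(g, p)
            back = read_ascii_grid(p)
            assert back.header.compatible(g.header)
            assert np.array_equal(back.mask, g.mask)
            assert np.array_equal(back.values[back.mask], g.values[g.mask])

    def test_nodata_cells_define_the_mask(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "NCOLS 2\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\n"
            "NODATA_VALUE -9999\n1 0\n-9999 2\n"
        )
        g = read_ascii_grid(p)
        assert g.mask.tolist() == [[True, True], [False, True]]

    def test_hand_written_fixture_header_parsed_exactly(self, tmp_path):
        p = tmp_path / "fixture.asc"
        p.write_text(
            "ncols 3\nnrows 3\nxllcorner -72.5\nyllcorner 44.25\ncellsize 0.125\n"
            "nodata_value -1\n1 2 3\n4 5 6\n7 8 -1\n"
        )
        g = read_ascii_grid(p)
        assert g.header == GridHeader(3, 3, -72.5, 44.25, 0.125, -1.0)
        assert g.values[0, 2] == 3.0 and not g.mask[2, 2]

    def test_writer_emits_canonical_header_bytes(self, tmp_path):
        h = GridHeader(2, 2, -72.5, 44.0, 0.5, -9999.0)
        g = Grid(h, np.array([[1.0, 2.0], [3.0, -9999.0]]))
        p = tmp_path / "g.asc"
        write_ascii_grid(g, p)
        assert p.read_text() == (
            "NCOLS 2\nNROWS 2\nXLLCORNER -72.5\nYLLCORNER 44\nCELLSIZE 0.5\n"
            "NODATA_VALUE -9999\n1 2\n3 -9999\n"
        )

    def test_masked_cell_serialized_as_nodata_token(self, tmp_path):
        h = GridHeader(2, 1, 0.0, 0.0, 1.0, nodata_value=-5.0)
        g = Grid(h, np.array([[7.0, 3.0]]), np.array([[True, False]]))
        p = tmp_path / "g.asc"
        write_ascii_grid(g, p)
        assert p.read_text().splitlines()[-1] == "7 -5"

    @pytest.mark.parametrize(
        "content,err",
        [
            ("NCOLS 2\nNROWS two\n", GridFormatError),
            ("NROWS 2\nNCOLS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\nNODATA_VALUE -9\n1 1\n1 1\n",
             GridFormatError),  # keys out of order
            ("NCOLS 2\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\nNODATA_VALUE -9\n1 1\n",
             DimensionError),  # missing row
            ("NCOLS 2\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\nNODATA_VALUE -9\n1 1 1\n1 1\n",
             DimensionError),  # too many columns
        ],
    )
    def test_malformed_files_raise_named_errors(self, tmp_path, content, err):
        p = tmp_path / "bad.asc"
        p.write_text(content)
        with pytest.raises(err):
            read_ascii_grid(p)


class TestCellOf:
    def test_southwest_cell_center(self, header):
        lon = header.xllcorner + header.cellsize / 2
        lat = header.yllcorner + header.cellsize / 2
        assert cell_of(lon, lat, header) == (header.nrows - 1, 0)

    def test_right_edge_is_out_of_bounds(self, header):
        lon = header.xllcorner + header.ncols * header.cellsize
        assert cell_of(lon, header.yllcorner + 0.1, header) is None

    def test_agrees_with_brute_force_rectangle_scan(self, header, rng):
        def brute(lon, lat):
            for r in range(header.nrows):
                for c in range(header.ncols):
                    x0 = header.xllcorner + c * header.cellsize
                    y0 = header.yllcorner + (header.nrows - r - 1) * header.cellsize
                    if x0 <= lon < x0 + header.cellsize and y0 <= lat < y0 + header.cellsize:
                        return (r, c)
            return None

        for _ in range(100):
            lon = float(rng.uniform(header.xllcorner - 1, header.xurcorner + 1))
            lat = float(rng.uniform(header.yllcorner - 1, header.yurcorner + 1))
            assert cell_of(lon, lat, header) == brute(lon, lat)

    def test_interior_boundary_point_belongs_to_larger_index(self, header):
        lon = header.xllcorner + header.cellsize  # boundary between col 0 and 1
        lat = header.yllcorner + header.cellsize  # boundary between last two rows
        assert cell_of(lon, lat, header) == (header.nrows - 2, 1)


class TestExtractValues:
    def test_constant_layer_value_at_cell_center(self, header):
        g = Grid(header, np.full((4, 5), 7.0), np.ones((4, 5), bool))
        stack = LayerStack(["c"], [g])
        df = extract_values(stack, [header.cell_center(2, 3)])
        assert df.loc[0, "c"] == 7.0 and bool(df.loc[0, "valid"])

    def test_point_outside_extent_flagged_invalid(self, small_stack):
        df = extract_values(small_stack, [(999.0, 0.0)])
        assert not bool(df.loc[0, "valid"])
        assert np.isnan(df.loc[0, "env_1"])

    def test_agrees_with_manual_lookup(self, small_stack, rng):
        h = small_stack.header
        pts = [
            (float(rng.uniform(h.xllcorner, h.xurcorner)),
             float(rng.uniform(h.yllcorner, h.yurcorner)))
            for _ in range(30)
        ]
        df = extract_values(small_stack, pts)
        for i, (lon, lat) in enumerate(pts):
            rc = cell_of(lon, lat, h)
            assert df.loc[i, "env_1"] == small_stack["env_1"].values[rc]
            assert df.loc[i, "env_2"] == small_stack["env_2"].values[rc]

    def test_permutation_equivariance(self, small_stack, rng):
        h = small_stack.header
        pts = [
            (float(rng.uniform(h.xllcorner, h.xurcorner)),
             float(rng.uniform(h.yllcorner, h.yurcorner)))
            for _ in range(10)
        ]
        perm = list(rng.permutation(len(pts)))
        a = extract_values(small_stack, pts)
        b = extract_values(small_stack, [pts[i] for i in perm])
        for j, i in enumerate(perm):
            assert a.loc[i, "env_1"] == b.loc[j, "env_1"]

    def test_masked_cell_flagged_invalid(self, header):
        vals = np.full((4, 5), 1.0)
        mask = np.ones((4, 5), bool)
        mask[2, 3] = False
        stack = LayerStack(["m"], [Grid(header, vals, mask)])
        df = extract_values(stack, [header.cell_center(2, 3)])
        assert not bool(df.loc[0, "valid"])


class TestCorrelationScreen:
    def test_duplicated_layer_flagged_with_r_one(self, header, rng):
        vals = rng.normal(size=(4, 5))
        stack = LayerStack(
            ["a", "a_copy"],
            [Grid(header, vals, np.ones((4, 5), bool)),
             Grid(header, vals.copy(), np.ones((4, 5), bool))],
        )
        res = correlation_screen(stack)
        assert res.matrix.loc["a", "a_copy"] == pytest.approx(1.0)
        assert ("a", "a_copy", pytest.approx(1.0)) in [
            (x, y, pytest.approx(r)) for x, y, r in res.flagged
        ] or res.flagged[0][:2] == ("a", "a_copy")

    def test_negated_layer_flagged_by_absolute_value(self, header, rng):
        vals = rng.normal(size=(4, 5))
        stack = LayerStack(
            ["a", "neg_a"],
            [Grid(header, vals, np.ones((4, 5), bool)),
             Grid(header, -vals, np.ones((4, 5), bool))],
        )
        res = correlation_screen(stack)
        assert res.matrix.loc["a", "neg_a"] == pytest.approx(-1.0)
        assert len(res.flagged) == 1

    def test_independent_layers_nearly_uncorrelated(self, rng):
        h = GridHeader(100, 100, 0.0, 0.0, 1.0)
        stack = LayerStack(
            ["x", "y"],
            [Grid(h, rng.normal(size=(100, 100)), np.ones((100, 100), bool)),
             Grid(h, rng.normal(size=(100, 100)), np.ones((100, 100), bool))],
        )
        res = correlation_screen(stack)
        assert abs(res.matrix.loc["x", "y"]) < 0.05
        assert res.flagged == []

    def test_constant_layer_reported_not_crashed(self, header, rng):
        stack = LayerStack(
            ["c", "v"],
            [Grid(header, np.full((4, 5), 3.0), np.ones((4, 5), bool)),
             Grid(header, rng.normal(size=(4, 5)), np.ones((4, 5), bool))],
        )
        res = correlation_screen(stack)
        assert res.constant_layers == ["c"]
        assert np.isnan(res.matrix.loc["c", "v"])
        assert res.matrix.loc["c", "c"] == 1.0

    def test_matrix_symmetric_positive_semidefinite(self, rng):
        h = GridHeader(40, 40, 0.0, 0.0, 1.0)
        layers = [Grid(h, rng.normal(size=(40, 40)), np.ones((40, 40), bool)) for _ in range(4)]
        # make layer 3 a mixture so the matrix is non-trivial
        layers[3] = Grid(h, 0.7 * layers[0].values + 0.3 * layers[1].values,
                         np.ones((40, 40), bool))
        stack = LayerStack(["a", "b", "c", "d"], layers)
        m = correlation_screen(stack).matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() > -1e-8


def test_stack_requires_compatible_headers(header, rng):
    other = GridHeader(5, 4, 0.0, 0.0, 1.0)
    with pytest.raises(DimensionError):
        LayerStack(
            ["a", "b"],
            [Grid(header, rng.normal(size=(4, 5)), np.ones((4, 5), bool)),
             Grid(other, rng.normal(size=(4, 5)), np.ones((4, 5), bool))],
        )


def test_joint_mask_is_intersection(header):
    m1 = np.ones((4, 5), bool); m1[0, 0] = False
    m2 = np.ones((4, 5), bool); m2[3, 4] = False
    stack = LayerStack(
        ["a", "b"],
        [Grid(header, np.ones((4, 5)), m1), Grid(header, np.ones((4, 5)), m2)],
    )
    joint = stack.joint_mask
    assert not joint[0, 0] and not joint[3, 4] and joint.sum() == 18
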