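import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from phylogrid import (OccurrenceRecord, PresenceMatrix, build_grid,
                       clean_occurrences, rasterize_presence, read_occurrences)


def _write(tmp_path, text, name="occ.csv", newline=None):
    p = tmp_path / name
    with open(p, "w", newline=newline if newline is not None else "") as fh:
        fh.write(text)
    return p


class TestReadOccurrences:
    def test_row_count_and_fields(self, tmp_path):
        p = _write(tmp_path,
                   "species,decimalLatitude,decimalLongitude\n"
                   "Ficus microcarpa,19.1,109.5\n"
                   "Hopea odorata,18.7,108.9\n"
                   "Vatica mangachapoi,18.4,109.2\n")
        recs = read_occurrences(p)
        assert len(recs) == 3
        assert recs[0].taxon == "Ficus microcarpa"
        assert recs[0].lat == pytest.approx(19.1)

    def test_unparseable_coordinate_retained_as_missing(self, tmp_path):
        p = _write(tmp_path,
                   "species,decimalLatitude,decimalLongitude\n"
                   "Ficus,19.1,NA\n")
        recs = read_occurrences(p)
        assert len(recs) == 1
        assert math.isnan(recs[0].lon) and recs[0].lat == pytest.approx(19.1)

    def test_crlf_and_quoted_names_parse_identically(self, tmp_path):
        body = ('species,decimalLatitude,decimalLongitude\n'
                '"Ficus, var. alba",19.1,109.5\n'
                'Hopea,18.7,108.9\n')
        lf = read_occurrences(_write(tmp_path, body, "lf.csv", newline="\n"))
        crlf = read_occurrences(_write(tmp_path, body.replace("\n", "\r\n"),
                                       "crlf.csv", newline=""))
        assert lf == crlf
        assert lf[0].taxon == "Ficus, var. alba"

    def test_missing_file_and_missing_column_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_occurrences(tmp_path / "nope.csv")
        p = _write(tmp_path, "sp,lat,lon\nA,1,2\n")
        with pytest.raises(ValueError, match="species"):
            read_occurrences(p)

    def test_custom_column_map_and_delimiter(self, tmp_path):
        p = _write(tmp_path, "name\ty\tx\nA\t1.0\t2.0\n", "occ.tsv")
        recs = read_occurrences(p, column_map={"taxon": "name", "lat": "y",
                                               "lon": "x"}, delimiter="\t")
        assert recs == [OccurrenceRecord("A", 1.0, 2.0)]


class TestCleanOccurrences:
    def test_zero_coordinate_dropped_with_reason(self):
        kept, log = clean_occurrences([OccurrenceRecord("A", 0.0, 110.1)])
        assert kept == []
        assert list(log["reason"]) == ["zero coordinate"]

    def test_valid_inside_boundary_kept(self):
        rec = OccurrenceRecord("A", 5.0, 5.0)
        kept, log = clean_occurrences([rec], boundary=box(0, 0, 10, 10))
        assert kept == [rec] and log.empty

    def test_outside_boundary_logged(self):
        rng = np.random.default_rng(7)
        inside = [OccurrenceRecord(f"in{i}", rng.uniform(1, 9),
                                   rng.uniform(1, 9)) for i in range(7)]
        outside = [OccurrenceRecord(f"out{i}", 20.0 + i, 20.0 + i)
                   for i in range(3)]
        kept, log = clean_occurrences(inside + outside, boundary=box(0, 0, 10, 10))
        assert kept == inside
        assert list(log["reason"]) == ["outside boundary"] * 3

    def test_missing_dropped_and_order_preserved(self):
        recs = [OccurrenceRecord("A", 1.0, 1.0),
                OccurrenceRecord("B", math.nan, 2.0),
                OccurrenceRecord("C", 3.0, 3.0)]
        kept, log = clean_occurrences(recs)
        assert [r.taxon for r in kept] == ["A", "C"]
        assert list(log["reason"]) == ["missing coordinate"]

    def test_invalid_boundary_fatal(self):
        bad = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
        with pytest.raises(ValueError):
            clean_occurrences([OccurrenceRecord("A", 1, 1)], boundary=bad)


class TestBuildGrid:
    def test_plain_extent_cell_count(self):
        g = build_grid((0, 0, 100_000, 50_000), cell_size=10_000)
        assert (g.n_cols, g.n_rows, g.n_cells) == (10, 5, 50)

    def test_boundary_polygon_retains_intersecting_cells(self):
        g = build_grid(box(0, 0, 50_000, 50_000), cell_size=10_000)
        assert g.n_cells == 25
        # right triangle over a 100x50 km extent: cells with positive-area
        # intersection satisfy c + 2r < 10 -> 10+8+6+4+2 = 30 cells;
        # cells touching the hypotenuse only at a corner are excluded
        tri = Polygon([(0, 0), (100_000, 0), (0, 50_000)])
        g2 = build_grid(tri, cell_size=10_000)
        assert (g2.n_cols, g2.n_rows) == (10, 5)
        assert g2.n_cells == 30

    def test_edge_point_assigned_to_exactly_one_cell(self):
        g = build_grid((0, 0, 30_000, 30_000), cell_size=10_000)
        # point on the shared edge of r0_c0 / r0_c1 -> higher-index cell
        assert g.cell_id_of(10_000.0, 5_000.0) == "r0_c1"
        ids = {g.cell_id_of(x, y) for x, y in [(0, 0), (9_999.99, 9_999.99)]}
        assert ids == {"r0_c0"}

    def test_single_cell_grid_valid(self):
        g = build_grid((0, 0, 5_000, 5_000), cell_size=10_000)
        assert g.n_cells == 1

    def test_degenerate_inputs_fatal(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 100, 100), cell_size=0)
        with pytest.raises(ValueError):
            build_grid((0, 0, 0, 100), cell_size=10)


class TestRasterize:
    def grid(self):
        return build_grid((0, 0, 30_000, 10_000), cell_size=10_000)

    def test_duplicate_records_collapse_to_presence(self):
        recs = [OccurrenceRecord("A", 5_000, 5_000) for _ in range(5)]
        mat = rasterize_presence(recs, self.grid())
        assert mat.incidence.sum() == 1
        assert mat.ranges.tolist() == [1]

    def test_hand_enumerated_ranges_and_richness(self):
        # A,B in cell0; B,C,D in cell1; C,D in cell2
        place = {"r0_c0": 5_000, "r0_c1": 15_000, "r0_c2": 25_000}
        recs = []
        for taxon, cells in [("A", ["r0_c0"]), ("B", ["r0_c0", "r0_c1"]),
                             ("C", ["r0_c1", "r0_c2"]),
                             ("D", ["r0_c1", "r0_c2"])]:
            recs += [OccurrenceRecord(taxon, 5_000, place[c]) for c in cells]
        mat = rasterize_presence(recs, self.grid())
        by_taxon = dict(zip(mat.taxa, mat.ranges))
        assert by_taxon == {"A": 1, "B": 2, "C": 2, "D": 2}
        by_cell = dict(zip(mat.cells, mat.richness))
        assert by_cell == {"r0_c0": 2, "r0_c1": 3, "r0_c2": 2}

    def test_empty_records_give_empty_matrix(self):
        mat = rasterize_presence([], self.grid())
        assert mat.n_taxa == 0 and mat.n_cells == 0
        assert len(mat.empty_cells) == 3

    def test_record_outside_grid_skipped(self):
        recs = [OccurrenceRecord("A", 5_000, 5_000),
                OccurrenceRecord("B", 500_000, 500_000)]
        mat = rasterize_presence(recs, self.grid())
        assert mat.taxa == ["A"]

    def test_binning_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        recs = [OccurrenceRecord(f"t{rng.integers(4)}", rng.uniform(0, 10_000),
                                 rng.uniform(0, 30_000)) for _ in range(40)]
        mat1 = rasterize_presence(recs, self.grid())
        perm = [recs[i] for i in rng.permutation(len(recs))]
        mat2 = rasterize_presence(perm, self.grid())
        f1 = mat1.to_frame().sort_index(axis=0).sort_index(axis=1)
        f2 = mat2.to_frame().sort_index(axis=0).sort_index(axis=1)
        assert f1.equals(f2)

    def test_incidence_sum_counts_taxon_cell_pairs(self):
        rng = np.random.default_rng(11)
        recs = [OccurrenceRecord(f"t{rng.integers(5)}", rng.uniform(0, 10_000),
                                 rng.uniform(0, 30_000)) for _ in range(60)]
        g = self.grid()
        pairs = {(g.cell_id_of(r.lon, r.lat), r.taxon) for r in recs}
        mat = rasterize_presence(recs, g)
        assert mat.incidence.sum() == len(pairs)


class TestPresenceMatrix:
    def test_entries_validated(self):
        with pytest.raises(ValueError):
            PresenceMatrix(cells=["c"], taxa=["t"], incidence=np.array([[2]]))

    def test_pairs_roundtrip(self, tmp_path):
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c2", "B"), ("c1", "B")])
        p = tmp_path / "pairs.csv"
        mat.write_pairs_csv(p)
        back = PresenceMatrix.read_pairs_csv(p)
        assert back.to_frame().sort_index(axis=1).equals(
            mat.to_frame().sort_index(axis=1))
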