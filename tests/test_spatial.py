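"""QDS codec, occurrence cleaning, presence matrix, per-cell metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloedge.spatial import (
    cell_metrics,
    clean_occurrences,
    presence_matrix,
    qds_decode,
    qds_encode,
)
from phyloedge.trees import TreeSet, parse_newick
from phyloedge.scoring import weight_tree


class TestQdsCodec:
    @pytest.mark.parametrize(
        "code,lon,lat",
        [
            ("3418BB", 18.875, -34.125),  # Somerset West
            ("3322CC", 22.125, -33.875),  # Jonkersberg
            ("3318DD", 18.875, -33.875),  # Stellenbosch
            ("3419AA", 19.125, -34.125),  # Grabouw
        ],
    )
    def test_decode_reported_centroids(self, code, lon, lat):
        assert qds_decode(code) == (lon, lat)

    def test_round_trip_all_sixteen_quarters(self):
        for half, quarter in itertools.product("ABCD", repeat=2):
            code = f"3418{half}{quarter}"
            lon, lat = qds_decode(code)
            assert qds_encode(lon, lat) == code

    def test_centroid_is_cell_corner_plus_eighth(self):
        lon, lat = qds_decode("3418AA")
        assert lon % 0.25 == pytest.approx(0.125)
        assert lat % 0.25 == pytest.approx(0.125)

    def test_malformed_codes_raise(self):
        for bad in ("3418", "3418BE", "34X8BB", "3418bbx"):
            with pytest.raises(ValueError):
                qds_decode(bad)

    def test_lowercase_accepted(self):
        assert qds_decode("3418bb") == (18.875, -34.125)

    def test_northern_or_western_points_fall_back_to_numeric(self):
        code = qds_encode(-7.875, 43.125)  # Galicia: N latitude, W longitude
        assert code.startswith("q")
        assert qds_decode(code) == (-7.875, 43.125)

    @given(
        lon=st.floats(min_value=0.0, max_value=99.99, allow_nan=False),
        lat=st.floats(min_value=-89.99, max_value=-0.26, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_codec_centroid_within_cell_of_any_point(self, lon, lat):
        code = qds_encode(lon, lat)
        clon, clat = qds_decode(code)
        assert abs(clon - lon) <= 0.125 + 1e-9
        assert abs(clat - lat) <= 0.125 + 1e-9
        assert qds_encode(clon, clat) == code

    def test_boundary_point_goes_to_higher_index_cell(self):
        # lon exactly on a cell edge belongs to the cell starting there
        assert qds_encode(18.75, -34.2) == qds_encode(18.80, -34.2)
        assert qds_encode(18.7499, -34.2) != qds_encode(18.75, -34.2)


class TestCleaning:
    def raw(self, rows):
        return pd.DataFrame(rows, columns=["taxon", "longitude", "latitude"])

    def test_zero_zero_dropped(self):
        df, log = clean_occurrences(self.raw([("a", 0.0, 0.0), ("a", 18.1, -34.1)]))
        assert log.zero_zero == 1 and len(df) == 1

    def test_out_of_range_and_nonnumeric_dropped(self):
        df, log = clean_occurrences(
            self.raw(
                [
                    ("a", 200.0, -34.1),
                    ("a", 18.1, 95.0),
                    ("a", "not-a-number", -34.1),
                    ("a", 18.1, None),
                    ("a", 18.1, -34.1),
                ]
            )
        )
        assert log.out_of_range == 2
        assert log.malformed == 2
        assert len(df) == 1 and log.kept == 1

    def test_duplicates_within_cell_collapse(self):
        df, log = clean_occurrences(
            self.raw([("a", 18.10, -34.10), ("a", 18.20, -34.20), ("b", 18.10, -34.10)])
        )
        # both 'a' records sit in QDS 3418AA -> one presence
        assert log.duplicates == 1
        assert len(df) == 2

    def test_synonym_renaming_applied_before_dedup(self):
        df, log = clean_occurrences(
            self.raw([("oldname", 18.10, -34.10), ("newname", 18.20, -34.20)]),
            synonym_map={"oldname": "newname"},
        )
        assert log.renamed == 1
        assert list(df["taxon"].unique()) == ["newname"]
        assert len(df) == 1  # same cell after renaming -> deduplicated

    def test_gbif_column_aliases_accepted(self):
        df, _ = clean_occurrences(
            pd.DataFrame(
                {
                    "species": ["a"],
                    "decimalLongitude": [18.1],
                    "decimalLatitude": [-34.1],
                }
            )
        )
        assert list(df.columns) == ["taxon", "longitude", "latitude", "cell"]


class TestPresenceMatrix:
    def test_single_record(self):
        mat = presence_matrix(
            pd.DataFrame({"taxon": ["a"], "longitude": [18.1], "latitude": [-34.1]})
        )
        assert mat.shape == (1, 1) and bool(mat.iloc[0, 0])

    def test_row_sums_count_occupied_cells(self):
        df = pd.DataFrame(
            {
                "taxon": ["a", "a", "a", "b"],
                "longitude": [18.1, 18.4, 18.1, 18.6],
                "latitude": [-34.1, -34.1, -34.12, -34.1],
            }
        )
        mat = presence_matrix(df)
        assert mat.loc["a"].sum() == 2  # two distinct cells for a
        assert mat.loc["b"].sum() == 1

    def test_total_matches_independent_pair_count(self, rng):
        taxa = rng.choice([f"t{i}" for i in range(8)], size=200)
        lon = 18.0 + rng.uniform(0, 2, size=200)
        lat = -35.0 + rng.uniform(0, 2, size=200)
        df = pd.DataFrame({"taxon": taxa, "longitude": lon, "latitude": lat})
        mat = presence_matrix(df)
        pairs = {
            (t, qds_encode(x, y)) for t, x, y in zip(taxa, lon, lat)
        }
        assert int(mat.to_numpy().sum()) == len(pairs)


FIVE_TIP = "((a:1,b:1):3,(c:2,(d:1,e:1):1):2);"


class TestCellMetrics:
    def setup_method(self):
        self.tree = parse_newick(FIVE_TIP)[0]
        self.p = {t: 0.5 for t in "abcde"}
        self.trees = TreeSet([self.tree])
        self.weighted = TreeSet([weight_tree(self.tree, self.p)])

    def records(self, placements):
        rows = []
        for taxon, (lon, lat) in placements:
            rows.append({"taxon": taxon, "longitude": lon, "latitude": lat})
        return pd.DataFrame(rows)

    def test_hand_worked_three_cell_landscape(self):
        """PD and expected-loss medians on a 5-tip tree match hand sums."""
        placements = [
            ("a", (18.1, -34.1)), ("b", (18.1, -34.1)),   # cell 1: {a, b}
            ("a", (18.6, -34.1)), ("c", (18.6, -34.1)),   # cell 2: {a, c}
            ("d", (19.1, -34.1)),                          # cell 3: {d}
        ]
        mat = presence_matrix(self.records(placements))
        cells = cell_metrics(mat, self.trees, self.weighted).set_index("code")
        c1, c2, c3 = qds_encode(18.1, -34.1), qds_encode(18.6, -34.1), qds_encode(19.1, -34.1)
        # hand: PD{a,b} = 1+1; PD{a,c} = 1+2+3+2; PD{d} = pendant 1
        assert cells.at[c1, "PD.med"] == pytest.approx(2.0)
        assert cells.at[c2, "PD.med"] == pytest.approx(8.0)
        assert cells.at[c3, "PD.med"] == pytest.approx(1.0)
        # hand, weighted by p=0.5 products: {a,b}: .5+.5; {a,c}: .5+1+3*.25+2*.125;
        # {d}: .5
        assert cells.at[c1, "ePDloss.med"] == pytest.approx(1.0)
        assert cells.at[c2, "ePDloss.med"] == pytest.approx(2.5)
        assert cells.at[c3, "ePDloss.med"] == pytest.approx(0.5)
        assert cells.at[c1, "taxon_richness"] == 2
        assert cells.at[c3, "taxon_richness"] == 1

    def test_edge_richness_counts_listed_taxa_only(self):
        placements = [("a", (18.1, -34.1)), ("b", (18.1, -34.1)),
                      ("c", (18.6, -34.1))]
        mat = presence_matrix(self.records(placements))
        cells = cell_metrics(
            mat, self.trees, self.weighted, edge_list=["a", "c"]
        ).set_index("code")
        assert cells.at[qds_encode(18.1, -34.1), "edge_richness"] == 1
        assert cells.at[qds_encode(18.6, -34.1), "edge_richness"] == 1

    def test_full_cell_with_certain_extinction(self):
        weighted = TreeSet([weight_tree(self.tree, {t: 1.0 for t in "abcde"})])
        placements = [(t, (18.1, -34.1)) for t in "abcde"]
        mat = presence_matrix(self.records(placements))
        cells = cell_metrics(mat, self.trees, weighted).set_index("code")
        cell = qds_encode(18.1, -34.1)
        assert cells.at[cell, "PD.med"] == pytest.approx(12.0)  # total length
        assert cells.at[cell, "ePDloss.med"] == pytest.approx(12.0)

    def test_unplaced_taxa_count_in_richness_not_pd(self):
        placements = [("a", (18.1, -34.1)), ("ghost", (18.1, -34.1))]
        mat = presence_matrix(self.records(placements))
        cells = cell_metrics(mat, self.trees, self.weighted).set_index("code")
        cell = qds_encode(18.1, -34.1)
        assert cells.at[cell, "taxon_richness"] == 2
        assert cells.at[cell, "PD.med"] == pytest.approx(1.0)  # only 'a'
        assert cells.attrs["unmatched_taxa"] == ["ghost"]

    def test_adding_presence_never_decreases_metrics(self):
        base = [("a", (18.1, -34.1)), ("b", (18.1, -34.1))]
        more = base + [("e", (18.1, -34.1))]
        m1 = cell_metrics(
            presence_matrix(self.records(base)), self.trees, self.weighted,
            edge_list=["e"],
        ).set_index("code")
        m2 = cell_metrics(
            presence_matrix(self.records(more)), self.trees, self.weighted,
            edge_list=["e"],
        ).set_index("code")
        cell = qds_encode(18.1, -34.1)
        for col in ("PD.med", "ePDloss.med", "taxon_richness", "edge_richness"):
            assert m2.at[cell, col] >= m1.at[cell, col]

    def test_loss_never_exceeds_pd(self, rng):
        placements = [
            (t, (18.0 + rng.uniform(0, 1.5), -34.0 - rng.uniform(0, 0.5)))
            for t in "abcdeabcde"
        ]
        mat = presence_matrix(self.records(placements))
        cells = cell_metrics(mat, self.trees, self.weighted)
        assert (cells["ePDloss.med"] <= cells["PD.med"] + 1e-12).all()
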