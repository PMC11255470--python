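"""Quarter-degree-square (QDS) gridding of occurrence records.

Occurrence records are binned to a 0.25 deg x 0.25 deg grid anchored at
integer degrees, with half-open cells ``[i*0.25, (i+1)*0.25)`` on both
axes (a record exactly on a boundary falls in the higher-index cell).
Cells in the south-latitude / east-longitude domain carry the southern
African QDS code (e.g. "3418BB"): two digits of degrees south, two of
degrees east locating the one-degree square by its north-west corner,
then a half-degree quadrant letter and a quarter-degree quadrant letter,
each read A=NW, B=NE, C=SW, D=SE. Cells outside that domain get a
numeric fallback code ``"q<lon_idx>_<lat_idx>"`` in grid indices.

Per occupied cell the module reports taxon richness, EDGE-species
richness, and medians over the tree set of Faith PD and expected PD loss
of the taxa present (the latter by pruning the globally risk-weighted
trees, so a cell's threatened deep branches are counted once with their
full joint-extinction weight).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import TreeSet, pd_subset

__all__ = [
    "qds_encode",
    "qds_decode",
    "cell_index",
    "CleaningLog",
    "clean_occurrences",
    "read_occurrences",
    "presence_matrix",
    "cell_metrics",
]

CELL = 0.25
_HALF_LETTERS = {(0, 0): "A", (0, 1): "B", (1, 0): "C", (1, 1): "D"}
_LETTER_POS = {v: k for k, v in _HALF_LETTERS.items()}
_CODE_RE = re.compile(r"^(\d{2})(\d{2})([ABCD])([ABCD])$")
_FALLBACK_RE = re.compile(r"^q(-?\d+)_(-?\d+)$")

#: accepted column aliases for occurrence tables (GBIF names included)
_LON_ALIASES = ("longitude", "decimalLongitude", "lon", "x")
_LAT_ALIASES = ("latitude", "decimalLatitude", "lat", "y")


def cell_index(lon: float, lat: float) -> tuple[int, int]:
    """Grid indices (lon_idx, lat_idx) of the QDS cell containing a point."""
    return math.floor(lon / CELL), math.floor(lat / CELL)


def qds_encode(lon: float, lat: float) -> str:
    """QDS code of the cell containing (lon, lat).

    Letter codes cover cells wholly south of the equator and east of the
    Greenwich meridian (and within two code digits); anything else gets
    the numeric fallback code.
    """
    lon_idx, lat_idx = cell_index(lon, lat)
    lon0 = lon_idx * CELL
    lat0 = lat_idx * CELL
    south_of_north_edge = lat0 + CELL <= 0.0
    if not (south_of_north_edge and lon0 >= 0.0):
        return f"q{lon_idx}_{lat_idx}"
    deg_south_exact = -(lat0 + CELL)  # degrees south of the cell's north edge
    deg_south = math.floor(deg_south_exact)
    deg_east = math.floor(lon0)
    if deg_south > 99 or deg_east > 99:
        return f"q{lon_idx}_{lat_idx}"
    row = round((deg_south_exact - deg_south) / CELL)  # 0 = northmost quarter row
    col = round((lon0 - deg_east) / CELL)
    half = _HALF_LETTERS[(row // 2, col // 2)]
    quarter = _HALF_LETTERS[(row % 2, col % 2)]
    return f"{deg_south:02d}{deg_east:02d}{half}{quarter}"


def qds_decode(code: str) -> tuple[float, float]:
    """Centroid (lon, lat) of a QDS code; accepts the numeric fallback form."""
    m = _FALLBACK_RE.match(code)
    if m:
        lon_idx, lat_idx = int(m.group(1)), int(m.group(2))
        return lon_idx * CELL + CELL / 2, lat_idx * CELL + CELL / 2
    m = _CODE_RE.match(code.strip().upper())
    if not m:
        raise ValueError(f"malformed QDS code: {code!r}")
    deg_south, deg_east = int(m.group(1)), int(m.group(2))
    half_r, half_c = _LETTER_POS[m.group(3)]
    q_r, q_c = _LETTER_POS[m.group(4)]
    row = 2 * half_r + q_r
    col = 2 * half_c + q_c
    lat0 = -(deg_south + (row + 1) * CELL)
    lon0 = deg_east + col * CELL
    return lon0 + CELL / 2, lat0 + CELL / 2


@dataclass
class CleaningLog:
    """Counts of occurrence rows dropped per cleaning rule."""

    malformed: int = 0
    nonfinite: int = 0
    out_of_range: int = 0
    zero_zero: int = 0
    duplicates: int = 0
    renamed: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _resolve_columns(df: pd.DataFrame) -> tuple[str, str, str]:
    cols = {c.lower(): c for c in df.columns}
    taxon = cols.get("taxon") or cols.get("species") or cols.get("scientificname")
    lon = next((cols[a.lower()] for a in _LON_ALIASES if a.lower() in cols), None)
    lat = next((cols[a.lower()] for a in _LAT_ALIASES if a.lower() in cols), None)
    if not (taxon and lon and lat):
        raise ValueError(
            "occurrence table needs a taxon column and coordinate columns "
            f"(aliases {_LON_ALIASES} / {_LAT_ALIASES}); got {list(df.columns)}"
        )
    return taxon, lon, lat


def clean_occurrences(
    records: pd.DataFrame,
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Validity-filter and normalise raw occurrence rows.

    Drops rows with unparseable or non-finite coordinates, coordinates
    out of range (|lat| > 90 or |lon| > 180) and the exact (0, 0) point;
    renames taxa through ``synonym_map``; deduplicates to one presence
    per (taxon, cell). Returns the cleaned frame (columns taxon,
    longitude, latitude, cell) and a per-rule drop log.
    """
    taxon_col, lon_col, lat_col = _resolve_columns(records)
    log = CleaningLog()
    df = records[[taxon_col, lon_col, lat_col]].copy()
    df.columns = ["taxon", "longitude", "latitude"]
    df["taxon"] = df["taxon"].astype(str)

    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    parse_fail = (lon.isna() & df["longitude"].notna()) | (
        lat.isna() & df["latitude"].notna()
    )
    missing = df["longitude"].isna() | df["latitude"].isna()
    log.malformed = int((parse_fail | missing).sum())
    df, lon, lat = df[~(parse_fail | missing)], lon[~(parse_fail | missing)], lat[~(parse_fail | missing)]

    finite = np.isfinite(lon) & np.isfinite(lat)
    log.nonfinite = int((~finite).sum())
    df, lon, lat = df[finite], lon[finite], lat[finite]

    in_range = (lat.abs() <= 90) & (lon.abs() <= 180)
    log.out_of_range = int((~in_range).sum())
    df, lon, lat = df[in_range], lon[in_range], lat[in_range]

    zero = (lon == 0.0) & (lat == 0.0)
    log.zero_zero = int(zero.sum())
    df, lon, lat = df[~zero], lon[~zero], lat[~zero]

    df = df.assign(longitude=lon.astype(float), latitude=lat.astype(float))
    if synonym_map:
        renamed = df["taxon"].isin(synonym_map)
        log.renamed = int(renamed.sum())
        df["taxon"] = df["taxon"].map(lambda t: synonym_map.get(t, t))

    df["cell"] = [qds_encode(x, y) for x, y in zip(df["longitude"], df["latitude"])]
    before = len(df)
    df = df.drop_duplicates(subset=["taxon", "cell"]).reset_index(drop=True)
    log.duplicates = before - len(df)
    log.kept = len(df)
    return df, log


def read_occurrences(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_synonym_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"from_name", "to_name"} <= set(df.columns):
        raise ValueError("synonym map needs columns: from_name, to_name")
    return dict(zip(df["from_name"].astype(str), df["to_name"].astype(str)))


def presence_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Taxa x cells boolean presence matrix from cleaned records."""
    df = records
    if "cell" not in df.columns:
        taxon_col, lon_col, lat_col = _resolve_columns(df)
        df = df.rename(
            columns={taxon_col: "taxon", lon_col: "longitude", lat_col: "latitude"}
        )
        df = df.assign(
            cell=[qds_encode(x, y) for x, y in zip(df["longitude"], df["latitude"])]
        )
    mat = pd.crosstab(df["taxon"], df["cell"]).astype(bool)
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "taxon"
    mat.columns.name = "cell"
    return mat


def cell_metrics(
    matrix: pd.DataFrame,
    trees: TreeSet,
    weighted_trees: TreeSet | Sequence[dendropy.Tree],
    edge_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-cell conservation metrics from a presence matrix.

    For each occupied cell: ``taxon_richness`` (all taxa present, whether
    or not placed on the trees), ``edge_richness`` (present taxa on the
    EDGE Species list), ``PD.med`` (median over the tree set of the Faith
    PD of the present tree-placed taxa) and ``ePDloss.med`` (same but on
    the risk-weighted trees). Output columns follow the reporting schema:
    code, X, Y (cell centroid), PD.med, ePDloss.med, taxon_richness,
    edge_richness.
    """
    weighted = list(weighted_trees)
    tree_list = list(trees)
    if len(weighted) != len(tree_list):
        raise ValueError("need one weighted tree per source tree")
    tip_set = set(trees.common_labels())
    edge_set = set(edge_list)
    unmatched = sorted(set(matrix.index) - tip_set)
    rows = []
    for code in matrix.columns:
        present = set(matrix.index[matrix[code]])
        if not present:
            continue
        placed = present & tip_set
        if placed:
            pd_med = float(np.median([pd_subset(t, placed) for t in tree_list]))
            loss_med = float(np.median([pd_subset(w, placed) for w in weighted]))
        else:
            pd_med = np.nan
            loss_med = np.nan
        x, y = qds_decode(code)
        rows.append(
            {
                "code": code,
                "X": x,
                "Y": y,
                "PD.med": pd_med,
                "ePDloss.med": loss_med,
                "taxon_richness": len(present),
                "edge_richness": len(present & edge_set),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("code").reset_index(drop=True)
    out.attrs["unmatched_taxa"] = unmatched
    return out
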