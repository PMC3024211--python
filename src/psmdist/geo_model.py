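"""Domain model and file I/O for the study geography.

The estimator works on a nested geography: a *region* (a ZIP-code-like
areal unit identified by a string code) contains *blocks* (the smallest
areal units carrying demographic counts, census-block style).  Residence
is only known to the region; blocks carry the age-bracket x sex population
counts used to weight within-region sampling.  *Places* are populated
points (incorporated towns) used to define a region's population center,
and *facilities* are the service locations distances are measured to.

All coordinates are planar, in miles.  Reprojection is out of scope: the
readers trust the declared units.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

log = logging.getLogger(__name__)

#: Sentinel returned by :func:`resolve_region` for codes outside the universe.
UNRESOLVED = None

# Census-P12-style age brackets: (label, low, high), closed intervals that
# partition ages 0..120.  Single years of age exist only for 20 and 21;
# everything else is bracketed, which is why respondents' exact ages must be
# mapped to a bracket before weighting.
DEFAULT_AGE_BRACKETS: tuple[tuple[str, int, int], ...] = (
    ("0_4", 0, 4),
    ("5_9", 5, 9),
    ("10_14", 10, 14),
    ("15_17", 15, 17),
    ("18_19", 18, 19),
    ("20", 20, 20),
    ("21", 21, 21),
    ("22_24", 22, 24),
    ("25_29", 25, 29),
    ("30_34", 30, 34),
    ("35_39", 35, 39),
    ("40_44", 40, 44),
    ("45_49", 45, 49),
    ("50_54", 50, 54),
    ("55_59", 55, 59),
    ("60_61", 60, 61),
    ("62_64", 62, 64),
    ("65_66", 65, 66),
    ("67_69", 67, 69),
    ("70_74", 70, 74),
    ("75_79", 75, 79),
    ("80_84", 80, 84),
    ("85_up", 85, 120),
)


class BracketTable:
    """Age-bracket lookup table; brackets must partition a contiguous age axis."""

    def __init__(self, brackets: Sequence[tuple[str, int, int]] = DEFAULT_AGE_BRACKETS):
        brackets = tuple(brackets)
        if not brackets:
            raise ValueError("bracket table is empty")
        prev_hi = brackets[0][1] - 1
        for label, lo, hi in brackets:
            if lo > hi:
                raise ValueError(f"bracket {label!r} has lo > hi")
            if lo != prev_hi + 1:
                raise ValueError(f"brackets do not partition the age axis at {label!r}")
            prev_hi = hi
        self.brackets = brackets
        self.min_age = brackets[0][1]
        self.max_age = brackets[-1][2]

    def bracket_of(self, age: int) -> str:
        if not (self.min_age <= age <= self.max_age):
            raise ValueError(f"age {age} outside bracket range "
                             f"[{self.min_age}, {self.max_age}]")
        for label, lo, hi in self.brackets:
            if lo <= age <= hi:
                return label
        raise AssertionError("unreachable: brackets partition the axis")

    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.brackets)


DEFAULT_BRACKET_TABLE = BracketTable()


@dataclass(frozen=True)
class StratumKey:
    """Demographic cell (sex x age bracket) used to weight block selection."""

    sex: str
    age_bracket: str

    @property
    def column(self) -> str:
        """Column name in the population table, e.g. ``F_22_24``."""
        return f"{self.sex}_{self.age_bracket}"


@dataclass
class Block:
    block_id: str
    region_code: str
    geometry: BaseGeometry
    pop: dict[str, int]  # stratum column -> count

    def __post_init__(self) -> None:
        for key, count in self.pop.items():
            if count < 0:
                raise ValueError(f"block {self.block_id}: negative count for {key}")


@dataclass
class Region:
    region_code: str
    block_ids: tuple[str, ...]
    geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if not self.block_ids:
            raise ValueError(f"region {self.region_code} has no blocks")


@dataclass
class Place:
    place_id: str
    region_code: str
    location: Point
    total_pop: int

    def __post_init__(self) -> None:
        if self.total_pop < 0:
            raise ValueError(f"place {self.place_id}: negative population")


@dataclass
class Facility:
    """A service location.

    ``address_point`` facilities carry their own coordinates.
    ``population_center`` facilities (known only by a PO box / region code)
    are resolved to the largest populated place in ``source_region_code``.
    """

    facility_id: str
    mode: str  # "address_point" | "population_center"
    location: Point | None = None
    source_region_code: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("address_point", "population_center"):
            raise ValueError(f"facility {self.facility_id}: unknown mode {self.mode!r}")
        if self.mode == "address_point" and self.location is None:
            raise ValueError(f"facility {self.facility_id}: address_point needs coordinates")
        if self.mode == "population_center" and self.source_region_code is None:
            raise ValueError(
                f"facility {self.facility_id}: population_center needs source_region_code")


@dataclass
class Respondent:
    respondent_id: str
    reported_code: str | None
    age_years: int | None
    sex: str | None


@dataclass
class Geography:
    """Loaded geography bundle with referential integrity established."""

    blocks: dict[str, Block]
    regions: dict[str, Region]
    places: list[Place]
    crosswalk: dict[str, str]
    bracket_table: BracketTable = field(default_factory=lambda: DEFAULT_BRACKET_TABLE)

    def places_in(self, region_code: str) -> list[Place]:
        return [p for p in self.places if p.region_code == region_code]

    def region_blocks(self, region_code: str) -> list[Block]:
        return [self.blocks[b] for b in self.regions[region_code].block_ids]


# ---------------------------------------------------------------------------
# Core operations


def resolve_region(reported_code: str | None,
                   crosswalk: Mapping[str, str],
                   regions: Mapping[str, Region]):
    """Map a reported code to a region code, or :data:`UNRESOLVED`.

    A code that is itself a region resolves to itself; otherwise the
    crosswalk is consulted (the analog of re-assigning out-of-universe ZIP
    codes via a postal lookup).  Unresolved is a value, not an error: the
    caller decides whether to drop or flag the record.
    """
    if reported_code is None:
        return UNRESOLVED
    if reported_code in regions:
        return reported_code
    mapped = crosswalk.get(reported_code)
    if mapped is not None and mapped in regions:
        return mapped
    return UNRESOLVED


def block_centroid(block: Block) -> Point:
    """Geometric (area) centroid of a block; a point geometry is its own centroid."""
    geom = block.geometry
    if geom is None or geom.is_empty:
        raise ValueError(f"block {block.block_id}: empty geometry")
    if isinstance(geom, Point):
        return geom
    if not geom.is_valid:
        raise ValueError(f"block {block.block_id}: invalid geometry")
    return geom.centroid


def population_center(region_code: str, places: Iterable[Place]) -> Point:
    """Location of the most populated place in the region.

    Ties break to the lowest place_id so the result is independent of input
    file ordering.
    """
    candidates = [p for p in places if p.region_code == region_code]
    if not candidates:
        raise ValueError(f"region {region_code} has no populated places")
    best = min(candidates, key=lambda p: (-p.total_pop, p.place_id))
    return best.location


def stratum_of(respondent: Respondent,
               bracket_table: BracketTable = DEFAULT_BRACKET_TABLE) -> StratumKey:
    """Deterministic (sex, age) -> stratum mapping; total over the bracket range."""
    if respondent.age_years is None or respondent.sex is None:
        raise ValueError(f"respondent {respondent.respondent_id}: missing age or sex")
    return StratumKey(sex=respondent.sex,
                      age_bracket=bracket_table.bracket_of(respondent.age_years))


def resolve_facilities(facilities: Iterable[Facility],
                       places: Iterable[Place]) -> list[Facility]:
    """Return facilities with all locations resolved.

    ``population_center`` facilities are placed at the largest place of their
    source region (the PO-box geocoding rule).
    """
    places = list(places)
    out = []
    for fac in facilities:
        if fac.mode == "population_center":
            loc = population_center(fac.source_region_code, places)
            out.append(replace(fac, location=loc))
        else:
            out.append(fac)
    return out


# ---------------------------------------------------------------------------
# Readers


def _read_csv_str(path, str_cols: Sequence[str], **kw) -> pd.DataFrame:
    """CSV reader keeping code-like columns as strings (leading zeros matter)."""
    return pd.read_csv(path, dtype={c: str for c in str_cols},
                       keep_default_na=True, **kw)


def load_blocks(block_geometry_path, population_path,
                bracket_table: BracketTable = DEFAULT_BRACKET_TABLE) -> dict[str, Block]:
    """Join block geometries (GeoJSON) with the population table (CSV).

    Blocks present in the geometry but missing a population row are
    zero-filled with a warning (they can never be sampled).  A population
    row with no matching geometry, or a duplicated block_id, is a hard
    error.
    """
    with open(block_geometry_path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{block_geometry_path}: not a GeoJSON FeatureCollection")

    geoms: dict[str, BaseGeometry] = {}
    region_of: dict[str, str] = {}
    for feat in fc["features"]:
        props = feat["properties"]
        bid = str(props["block_id"])
        if bid in geoms:
            raise ValueError(f"duplicate block_id in geometry: {bid}")
        geoms[bid] = shape(feat["geometry"])
        region_of[bid] = str(props["region_code"])

    pop_df = _read_csv_str(population_path, ["block_id"])
    if pop_df["block_id"].duplicated().any():
        dups = pop_df.loc[pop_df["block_id"].duplicated(), "block_id"].tolist()
        raise ValueError(f"duplicate block_id in population table: {dups}")
    stratum_cols = [c for c in pop_df.columns if c != "block_id"]
    orphans = sorted(set(pop_df["block_id"]) - set(geoms))
    if orphans:
        raise ValueError(f"population rows with no geometry: {orphans}")

    pop_by_block = {
        row["block_id"]: {c: int(row[c]) for c in stratum_cols}
        for _, row in pop_df.iterrows()
    }
    blocks: dict[str, Block] = {}
    for bid, geom in geoms.items():
        pop = pop_by_block.get(bid)
        if pop is None:
            pop = {c: 0 for c in stratum_cols}
            log.warning("block %s has geometry but no population row; zero-filled", bid)
        blocks[bid] = Block(block_id=bid, region_code=region_of[bid],
                            geometry=geom, pop=pop)
    return blocks


def build_regions(blocks: Mapping[str, Block]) -> dict[str, Region]:
    """Group blocks into regions; region geometry is the union of its blocks."""
    by_region: dict[str, list[str]] = {}
    for bid, blk in blocks.items():
        by_region.setdefault(blk.region_code, []).append(bid)
    regions = {}
    for code, bids in by_region.items():
        bids = tuple(sorted(bids))
        geom = unary_union([blocks[b].geometry for b in bids])
        regions[code] = Region(region_code=code, block_ids=bids, geometry=geom)
    return regions


def load_places(path) -> list[Place]:
    df = _read_csv_str(path, ["place_id", "region_code"])
    return [
        Place(place_id=r["place_id"], region_code=r["region_code"],
              location=Point(float(r["x"]), float(r["y"])),
              total_pop=int(r["total_pop"]))
        for _, r in df.iterrows()
    ]


def load_facilities(path) -> list[Facility]:
    df = _read_csv_str(path, ["facility_id", "mode", "source_region_code"])
    out = []
    for _, r in df.iterrows():
        src = r.get("source_region_code")
        if pd.isna(src):
            src = None
        loc = None
        if not pd.isna(r.get("x")) and not pd.isna(r.get("y")):
            loc = Point(float(r["x"]), float(r["y"]))
        out.append(Facility(facility_id=r["facility_id"], mode=r["mode"],
                            location=loc, source_region_code=src))
    return out


def load_crosswalk(path) -> dict[str, str]:
    df = _read_csv_str(path, ["reported_code", "region_code"])
    return dict(zip(df["reported_code"], df["region_code"]))


def load_respondents(path) -> list[Respondent]:
    df = _read_csv_str(path, ["respondent_id", "reported_code", "sex"])
    out = []
    for _, r in df.iterrows():
        age = r.get("age_years")
        age = None if pd.isna(age) else int(age)
        code = r.get("reported_code")
        code = None if (pd.isna(code) or code == "") else code
        sex = r.get("sex")
        sex = None if pd.isna(sex) else sex
        out.append(Respondent(respondent_id=r["respondent_id"],
                              reported_code=code, age_years=age, sex=sex))
    return out


def load_geography(block_geometry_path, population_path, places_path,
                   crosswalk_path,
                   bracket_table: BracketTable = DEFAULT_BRACKET_TABLE) -> Geography:
    blocks = load_blocks(block_geometry_path, population_path, bracket_table)
    regions = build_regions(blocks)
    places = load_places(places_path)
    crosswalk = load_crosswalk(crosswalk_path)
    return Geography(blocks=blocks, regions=regions, places=places,
                     crosswalk=crosswalk, bracket_table=bracket_table)


# ---------------------------------------------------------------------------
# Writers (exact counterparts of the readers; round-trip is lossless)


def write_blocks_geojson(blocks: Mapping[str, Block], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"block_id": b.block_id, "region_code": b.region_code},
            "geometry": mapping(b.geometry),
        }
        for b in sorted(blocks.values(), key=lambda b: b.block_id)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_population_csv(blocks: Mapping[str, Block], path) -> None:
    rows = []
    for b in sorted(blocks.values(), key=lambda b: b.block_id):
        rows.append({"block_id": b.block_id, **b.pop})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_places_csv(places: Sequence[Place], path) -> None:
    pd.DataFrame(
        [{"place_id": p.place_id, "region_code": p.region_code,
          "x": p.location.x, "y": p.location.y, "total_pop": p.total_pop}
         for p in sorted(places, key=lambda p: p.place_id)]
    ).to_csv(path, index=False)


def write_facilities_csv(facilities: Sequence[Facility], path) -> None:
    pd.DataFrame(
        [{"facility_id": f.facility_id, "mode": f.mode,
          "x": f.location.x if f.location is not None else "",
          "y": f.location.y if f.location is not None else "",
          "source_region_code": f.source_region_code or ""}
         for f in sorted(facilities, key=lambda f: f.facility_id)]
    ).to_csv(path, index=False)


def write_crosswalk_csv(crosswalk: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(crosswalk.items()),
                 columns=["reported_code", "region_code"]).to_csv(path, index=False)


def write_respondents_csv(respondents: Sequence[Respondent], path) -> None:
    pd.DataFrame(
        [{"respondent_id": r.respondent_id,
          "reported_code": r.reported_code if r.reported_code is not None else "",
          "age_years": r.age_years if r.age_years is not None else "",
          "sex": r.sex if r.sex is not None else ""}
         for r in respondents]
    ).to_csv(path, index=False)
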