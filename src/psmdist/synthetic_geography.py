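"""Synthetic study-geography generator.

Emulates the data landscape the estimator is designed for — a rural state
whose ZIP-code-like regions are tiled by census-block-like units with
age x sex population counts, a sparse set of facilities, populated places
defining population centers, and a road network — without any download.
Geometry is a regular grid: regions are rectangles of square blocks laid
out on a road lattice whose edge lengths equal the Euclidean node
spacing, which keeps centroids and shortest paths analytically checkable
while still realizing the regimes that matter (population concentrated
in one place vs spread out; facilities co-located with population
centers or not).

Defaults mirror the motivating study's scale: 218 regions, 28 facilities
placed at population centers (the PO-box geocoding regime), 1467 female
respondents aged 18-44.

The generator emits the exact external file formats the loaders consume,
so tests exercise the full I/O path.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import geo_model
from .geo_model import (Block, Facility, Geography, Place, Region, Respondent,
                        build_regions, resolve_region)
from .pps_sampler import rng_stream
from .road_network import RoadNetwork, build_network, load_network, write_network_csv

_DEFAULT_BRACKETS = ("18_19", "20", "21", "22_24", "25_29", "30_34",
                     "35_39", "40_44")


def default_stratum_shares() -> dict[str, float]:
    """Equal shares over female and male brackets spanning ages 18-44."""
    strata = [f"{sex}_{b}" for sex in ("F", "M") for b in _DEFAULT_BRACKETS]
    return {s: 1.0 / len(strata) for s in strata}


@dataclass
class PopulationModel:
    """How region populations are sized and spread across blocks.

    ``spatial_concentration`` in [0, 1] controls how much of a region's
    population piles into a single "center" block: 0 = uniform across
    blocks, 1 = everyone in one block.  The default 0.4 puts just under
    half of a region's people in its largest place.
    """

    total_pop_range: tuple[int, int] = (200, 2000)
    stratum_shares: dict[str, float] = field(default_factory=default_stratum_shares)
    spatial_concentration: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.spatial_concentration <= 1.0):
            raise ValueError("spatial_concentration must be in [0, 1]")
        total = sum(self.stratum_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum_shares sum to {total}, not 1")


@dataclass
class ScenarioConfig:
    n_regions: int = 218
    blocks_per_region: tuple[int, int] = (4, 16)
    grid_spacing: float = 2.0  # miles
    population_model: PopulationModel = field(default_factory=PopulationModel)
    n_places_per_region: tuple[int, int] = (1, 3)
    n_facilities: int = 28
    facility_placement: str = "at_population_centers"
    respondent_count: int = 1467
    age_range: tuple[int, int] = (18, 44)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_facilities < 1:
            raise ValueError("counts must be >= 1")
        if self.blocks_per_region[0] < 1:
            raise ValueError("blocks_per_region must be >= 1")
        if self.n_places_per_region[0] > self.blocks_per_region[0]:
            raise ValueError("infeasible config: a region may get more places "
                             "than blocks")
        if self.facility_placement not in ("at_population_centers", "random",
                                           "offset_from_centers"):
            raise ValueError(f"unknown facility_placement "
                             f"{self.facility_placement!r}")
        if self.respondent_count < 0:
            raise ValueError("respondent_count must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        pm = d.get("population_model")
        if isinstance(pm, Mapping):
            pm = dict(pm)
            if "total_pop_range" in pm:
                pm["total_pop_range"] = tuple(pm["total_pop_range"])
            d["population_model"] = PopulationModel(**pm)
        for key in ("blocks_per_region", "n_places_per_region", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticGeography:
    """A complete, internally consistent synthetic input set."""

    geography: Geography
    network: RoadNetwork
    facilities: list[Facility]
    respondents: list[Respondent]
    config: ScenarioConfig
    zeroed_region_code: str | None = None

    def write(self, out_dir) -> dict[str, str]:
        """Write every external file the loaders consume, plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        geo = self.geography
        geo_model.write_blocks_geojson(geo.blocks, out / "blocks.geojson")
        geo_model.write_population_csv(geo.blocks, out / "population.csv")
        geo_model.write_places_csv(geo.places, out / "places.csv")
        geo_model.write_facilities_csv(self.facilities, out / "facilities.csv")
        geo_model.write_crosswalk_csv(geo.crosswalk, out / "crosswalk.csv")
        geo_model.write_respondents_csv(self.respondents, out / "respondents.csv")
        write_network_csv(self.network, out / "nodes.csv", out / "edges.csv")
        manifest = {"config": self.config.to_dict(), "seed": self.config.seed,
                    "zeroed_region_code": self.zeroed_region_code}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return {name: str(out / name) for name in
                ("blocks.geojson", "population.csv", "places.csv",
                 "facilities.csv", "crosswalk.csv", "respondents.csv",
                 "nodes.csv", "edges.csv", "manifest.json")}


def load_scenario(in_dir) -> tuple[Geography, RoadNetwork, list[Facility],
                                   list[Respondent]]:
    """Load a written scenario directory back through the standard readers."""
    p = Path(in_dir)
    geography = geo_model.load_geography(p / "blocks.geojson",
                                         p / "population.csv",
                                         p / "places.csv", p / "crosswalk.csv")
    network = load_network(p / "nodes.csv", p / "edges.csv")
    facilities = geo_model.load_facilities(p / "facilities.csv")
    respondents = geo_model.load_respondents(p / "respondents.csv")
    return geography, network, facilities, respondents


# ---------------------------------------------------------------------------


def generate_geography(config: ScenarioConfig) -> SyntheticGeography:
    """Generate a full synthetic scenario from one config + seed."""
    rng = rng_stream(config.seed, "synthetic/geography")
    s = config.grid_spacing
    bmin, bmax = config.blocks_per_region
    cell_side = math.ceil(math.sqrt(bmax))
    n_cols = math.ceil(math.sqrt(config.n_regions))
    n_rows = math.ceil(config.n_regions / n_cols)
    pm = config.population_model
    strata = list(pm.stratum_shares)
    shares = np.array([pm.stratum_shares[k] for k in strata])

    blocks: dict[str, Block] = {}
    places: list[Place] = []
    region_codes: list[str] = []
    center_place_of: dict[str, str] = {}

    for k in range(config.n_regions):
        code = f"{k:05d}"
        region_codes.append(code)
        row, col = divmod(k, n_cols)
        ox, oy = col * cell_side * s, row * cell_side * s

        n_blocks = int(rng.integers(bmin, bmax + 1))
        bx = math.ceil(math.sqrt(n_blocks))
        centroids = []
        block_ids = []
        for i in range(n_blocks):
            gx, gy = i % bx, i // bx
            x0, y0 = ox + gx * s, oy + gy * s
            poly = Polygon([(x0, y0), (x0 + s, y0), (x0 + s, y0 + s),
                            (x0, y0 + s)])
            bid = f"{code}B{i:03d}"
            block_ids.append(bid)
            centroids.append(Point(x0 + s / 2, y0 + s / 2))
            blocks[bid] = Block(block_id=bid, region_code=code, geometry=poly,
                                pop={})

        # population: one multinomial over blocks x strata
        total = int(rng.integers(pm.total_pop_range[0],
                                 pm.total_pop_range[1] + 1))
        center = int(rng.integers(n_blocks))
        c = pm.spatial_concentration
        block_share = np.full(n_blocks, (1.0 - c) / n_blocks)
        block_share[center] += c
        joint = np.outer(block_share, shares).ravel()
        counts = rng.multinomial(total, joint / joint.sum()).reshape(
            n_blocks, len(strata))
        for i, bid in enumerate(block_ids):
            blocks[bid].pop = {col_name: int(counts[i, j])
                               for j, col_name in enumerate(strata)}

        # places: the center block hosts one; others at distinct random blocks
        plo, phi = config.n_places_per_region
        n_places = min(int(rng.integers(plo, phi + 1)), n_blocks)
        others = [i for i in range(n_blocks) if i != center]
        chosen = [center] + list(rng.choice(others, size=n_places - 1,
                                            replace=False)) if n_places > 1 else [center]
        for j, bi in enumerate(chosen):
            pid = f"{code}P{j}"
            places.append(Place(place_id=pid, region_code=code,
                                location=centroids[bi],
                                total_pop=int(counts[bi].sum())))
            if bi == center:
                center_place_of[code] = pid

    regions = build_regions(blocks)

    # road lattice through block centers (roads serve inhabited blocks, so
    # block centroids and places sit on-network while land-area centroids
    # may not); edge length == node spacing
    nx_count = n_cols * cell_side
    ny_count = n_rows * cell_side
    node_rows = [{"node_id": f"N{ix:04d}_{iy:04d}",
                  "x": (ix + 0.5) * s, "y": (iy + 0.5) * s}
                 for iy in range(ny_count) for ix in range(nx_count)]
    edge_rows = []
    for iy in range(ny_count):
        for ix in range(nx_count):
            if ix + 1 < nx_count:
                edge_rows.append({"node_a": f"N{ix:04d}_{iy:04d}",
                                  "node_b": f"N{ix + 1:04d}_{iy:04d}",
                                  "length_miles": s})
            if iy + 1 < ny_count:
                edge_rows.append({"node_a": f"N{ix:04d}_{iy:04d}",
                                  "node_b": f"N{ix:04d}_{iy + 1:04d}",
                                  "length_miles": s})
    network = build_network(pd.DataFrame(node_rows), pd.DataFrame(edge_rows))

    facilities = _place_facilities(config, rng, region_codes, places, s)

    # crosswalk: identity plus alias codes for every tenth region (the analog
    # of ZIP codes that map onto a differently-coded region)
    crosswalk = {code: code for code in region_codes}
    aliases = {code: f"{90000 + int(code):05d}" for code in region_codes[::10]}
    for code, alias in aliases.items():
        crosswalk[alias] = code

    geography = Geography(blocks=blocks, regions=regions, places=places,
                          crosswalk=crosswalk)
    respondents = generate_respondents(config, geography,
                                       rng_stream(config.seed,
                                                  "synthetic/respondents"),
                                       aliases=aliases)
    synth = SyntheticGeography(geography=geography, network=network,
                               facilities=facilities, respondents=respondents,
                               config=config)
    validate_geography(synth)
    return synth


def _place_facilities(config: ScenarioConfig, rng: np.random.Generator,
                      region_codes: list[str], places: list[Place],
                      s: float) -> list[Facility]:
    if config.facility_placement in ("at_population_centers",
                                     "offset_from_centers"):
        if config.n_facilities > len(region_codes):
            raise ValueError("more facilities than regions to host them")
        hosts = sorted(rng.choice(region_codes, size=config.n_facilities,
                                  replace=False))
        out = []
        for j, code in enumerate(hosts):
            fid = f"FAC{j:03d}"
            if config.facility_placement == "at_population_centers":
                out.append(Facility(facility_id=fid, mode="population_center",
                                    source_region_code=code))
            else:
                pt = geo_model.population_center(code, places)
                dx, dy = [(s, 0), (-s, 0), (0, s), (0, -s)][int(rng.integers(4))]
                out.append(Facility(facility_id=fid, mode="address_point",
                                    location=Point(pt.x + dx, pt.y + dy)))
        return out
    # random placement: facilities at random places' host blocks shifted off
    out = []
    for j in range(config.n_facilities):
        code = region_codes[int(rng.integers(len(region_codes)))]
        cands = [p for p in places if p.region_code == code]
        p = cands[int(rng.integers(len(cands)))]
        out.append(Facility(facility_id=f"FAC{j:03d}", mode="address_point",
                            location=Point(p.location.x, p.location.y)))
    return out


def generate_respondents(config: ScenarioConfig, geography: Geography,
                         rng: np.random.Generator,
                         aliases: Mapping[str, str] | None = None
                         ) -> list[Respondent]:
    """Respondents with regions drawn proportional to female stratum totals.

    Ages are uniform over ``age_range``; all respondents are female (the
    estimator weights by the respondent's own stratum, so a single-sex
    cohort exercises every code path).  Where a region has an alias code,
    a tenth of its respondents report the alias, exercising the crosswalk.
    """
    if not geography.regions:
        raise ValueError("no regions")
    codes = sorted(geography.regions)
    fem_total = np.array([
        sum(sum(b.pop.get(col, 0) for col in b.pop if col.startswith("F_"))
            for b in geography.region_blocks(code))
        for code in codes], dtype=float)
    if fem_total.sum() <= 0:
        fem_total = np.ones_like(fem_total)
    probs = fem_total / fem_total.sum()
    aliases = aliases or {}

    out = []
    region_idx = rng.choice(len(codes), size=config.respondent_count, p=probs)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1,
                        size=config.respondent_count)
    alias_flip = rng.random(config.respondent_count)
    for i in range(config.respondent_count):
        code = codes[int(region_idx[i])]
        reported = code
        if code in aliases and alias_flip[i] < 0.1:
            reported = aliases[code]
        out.append(Respondent(respondent_id=f"R{i:04d}", reported_code=reported,
                              age_years=int(ages[i]), sex="F"))
    return out


def plant_zero_stratum_region(synth: SyntheticGeography,
                              region_code: str | None = None
                              ) -> SyntheticGeography:
    """Zero one region's population so cohort runs exercise the
    zero-stratum exclusion path.

    Defaults to the region of the first respondent (guaranteeing the
    exclusion actually fires).  Idempotent.
    """
    geo = synth.geography
    if len(geo.regions) < 2:
        raise ValueError("need >= 2 regions to plant a zero-stratum region")
    if region_code is None:
        for resp in synth.respondents:
            code = resolve_region(resp.reported_code, geo.crosswalk, geo.regions)
            if code is not None:
                region_code = code
                break
        if region_code is None:
            region_code = sorted(geo.regions)[0]
    if region_code not in geo.regions:
        raise KeyError(region_code)

    new_blocks = dict(geo.blocks)
    for bid in geo.regions[region_code].block_ids:
        old = geo.blocks[bid]
        new_blocks[bid] = Block(block_id=old.block_id,
                                region_code=old.region_code,
                                geometry=old.geometry,
                                pop={k: 0 for k in old.pop})
    new_geo = Geography(blocks=new_blocks, regions=geo.regions,
                        places=geo.places, crosswalk=geo.crosswalk,
                        bracket_table=geo.bracket_table)
    return SyntheticGeography(geography=new_geo, network=synth.network,
                              facilities=synth.facilities,
                              respondents=synth.respondents,
                              config=synth.config,
                              zeroed_region_code=region_code)


def validate_geography(synth: SyntheticGeography) -> None:
    """Referential-integrity pass run after every generation."""
    import networkx as nx

    geo = synth.geography
    for bid, blk in geo.blocks.items():
        if blk.region_code not in geo.regions:
            raise AssertionError(f"block {bid} references missing region "
                                 f"{blk.region_code}")
    for code, region in geo.regions.items():
        for bid in region.block_ids:
            if bid not in geo.blocks:
                raise AssertionError(f"region {code} references missing block {bid}")
            if geo.blocks[bid].region_code != code:
                raise AssertionError(f"block {bid} region mismatch")
    for place in geo.places:
        if place.region_code not in geo.regions:
            raise AssertionError(f"place {place.place_id} references missing "
                                 f"region {place.region_code}")
    for fac in synth.facilities:
        if fac.mode == "population_center":
            if fac.source_region_code not in geo.regions:
                raise AssertionError(f"facility {fac.facility_id} references "
                                     f"missing region {fac.source_region_code}")
            if not geo.places_in(fac.source_region_code):
                raise AssertionError(f"facility {fac.facility_id}: source "
                                     f"region has no places")
    for code, target in geo.crosswalk.items():
        if target not in geo.regions:
            raise AssertionError(f"crosswalk target {target} is not a region")
    if not nx.is_connected(synth.network.graph):
        raise AssertionError("road network is not connected")
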