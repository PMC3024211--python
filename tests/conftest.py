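import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from psmdist import (Block, Facility, Place, Respondent, ScenarioConfig,
                     build_network, generate_geography)


def make_network(nodes, edges):
    """Build a network from [(id, x, y)] and [(a, b, length)] shorthand."""
    return build_network(
        pd.DataFrame(nodes, columns=["node_id", "x", "y"]),
        pd.DataFrame(edges, columns=["node_a", "node_b", "length_miles"]))


def square_block(block_id, region_code, x0, y0, side=1.0, pop=None):
    poly = Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side),
                    (x0, y0 + side)])
    return Block(block_id=block_id, region_code=region_code, geometry=poly,
                 pop=pop or {})


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small but complete synthetic scenario shared across tests."""
    cfg = ScenarioConfig(n_regions=6, blocks_per_region=(4, 9),
                         n_facilities=2, respondent_count=40,
                         n_places_per_region=(1, 2), seed=7)
    return generate_geography(cfg)


@pytest.fixture
def line_world():
    """Three unit blocks in a row on a 3-node line network, one facility.

    Block centroids sit on nodes N0(0.5), N1(1.5), N2(2.5); the facility
    is at N2, so the exact block distances are 2, 1, 0 miles.
    """
    blocks = {
        f"B{i}": square_block(f"B{i}", "00001", float(i), 0.0,
                              pop={"F_22_24": c})
        for i, c in enumerate([10, 20, 30])
    }
    network = make_network(
        [("N0", 0.5, 0.5), ("N1", 1.5, 0.5), ("N2", 2.5, 0.5)],
        [("N0", "N1", 1.0), ("N1", "N2", 1.0)])
    facility = Facility(facility_id="FAC0", mode="address_point",
                        location=Point(2.5, 0.5))
    places = [Place(place_id="P0", region_code="00001",
                    location=Point(2.5, 0.5), total_pop=30)]
    from psmdist.geo_model import Geography, build_regions
    geography = Geography(blocks=blocks, regions=build_regions(blocks),
                          places=places, crosswalk={"00001": "00001"})
    return geography, network, [facility]


@pytest.fixture
def respondent_23():
    return Respondent(respondent_id="R1", reported_code="00001",
                      age_years=23, sex="F")
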