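"""Deterministic comparator geocoding methods and the three-way comparison.

Two common single-point geocodes stand in for a residence known only to
a region: the region polygon's geometric centroid, and the population
center (the largest populated place in the region).  Both force a single
distance per region; neither yields a distribution.  This module computes
their nearest-facility distances, the summary statistics of each method's
distance table, OLS regressions predicting the probabilistic-sampling
median from each comparator, and the B-type-error diagnostic (spurious
exact-zero distances arising when residence and facility are geocoded to
the same point).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geo_model
from .geo_model import Facility, Geography, Place, Region, population_center
from .road_network import (NearestFacilityIndex, RoadNetwork, nearest_facility)

METHOD_REGION_CENTROID = "region_centroid"
METHOD_POPULATION_CENTER = "population_center"


@dataclass
class ComparatorDistance:
    respondent_id: str
    method: str
    distance: float
    nearest_facility_id: str


@dataclass
class RegressionSummary:
    """OLS fit predicting the sampling-method median from a comparator.

    ``mean_signed_error`` is comparator minus sampling-method median:
    positive means the comparator overestimates.
    """

    method: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    mean_signed_error: float


@dataclass
class DistanceSummary:
    method: str
    min: float
    max: float
    median: float
    mean: float
    sd: float
    q1: float
    q3: float


def region_centroid_distance(region: Region, network: RoadNetwork,
                             facilities: Sequence[Facility],
                             respondent_id: str = "",
                             index: NearestFacilityIndex | None = None
                             ) -> ComparatorDistance:
    """Nearest-facility distance from the region polygon's geometric centroid."""
    if region.geometry is None or region.geometry.is_empty:
        raise ValueError(f"region {region.region_code} has no polygon geometry")
    pt = region.geometry.centroid
    fid, d = index.query(pt) if index else nearest_facility(network, pt, facilities)
    return ComparatorDistance(respondent_id=respondent_id,
                              method=METHOD_REGION_CENTROID,
                              distance=d, nearest_facility_id=fid)


def population_center_distance(region: Region, places: Iterable[Place],
                               network: RoadNetwork,
                               facilities: Sequence[Facility],
                               respondent_id: str = "",
                               index: NearestFacilityIndex | None = None
                               ) -> ComparatorDistance:
    """Nearest-facility distance from the region's population center point."""
    pt = population_center(region.region_code, places)
    fid, d = index.query(pt) if index else nearest_facility(network, pt, facilities)
    return ComparatorDistance(respondent_id=respondent_id,
                              method=METHOD_POPULATION_CENTER,
                              distance=d, nearest_facility_id=fid)


def comparator_table(estimates: pd.DataFrame, geography: Geography,
                     network: RoadNetwork,
                     facilities: Sequence[Facility]) -> pd.DataFrame:
    """Per-respondent comparison table for a completed cohort run.

    Columns: respondent_id, region_code, psm_median, region_centroid_dist,
    population_center_dist (plus nearest-facility ids per method).
    Comparator distances are deterministic per region and memoized.
    """
    facilities = geo_model.resolve_facilities(facilities, geography.places)
    index = NearestFacilityIndex(network, facilities)
    memo: dict[str, tuple[ComparatorDistance, ComparatorDistance]] = {}
    rows = []
    for _, r in estimates.iterrows():
        code = r["region_code"]
        pair = memo.get(code)
        if pair is None:
            region = geography.regions[code]
            pair = (region_centroid_distance(region, network, facilities,
                                             index=index),
                    population_center_distance(region, geography.places,
                                               network, facilities, index=index))
            memo[code] = pair
        cen, pop = pair
        rows.append({"respondent_id": r["respondent_id"], "region_code": code,
                     "psm_median": r["median_miles"],
                     "region_centroid_dist": cen.distance,
                     "region_centroid_facility": cen.nearest_facility_id,
                     "population_center_dist": pop.distance,
                     "population_center_facility": pop.nearest_facility_id})
    return pd.DataFrame(rows, columns=["respondent_id", "region_code",
                                       "psm_median", "region_centroid_dist",
                                       "region_centroid_facility",
                                       "population_center_dist",
                                       "population_center_facility"])


def compare_methods(psm_medians: Sequence[float],
                    comparator: Sequence[float],
                    method: str) -> RegressionSummary:
    """OLS of the sampling-method median on one comparator's distances."""
    y = np.asarray(psm_medians, dtype=float)
    x = np.asarray(comparator, dtype=float)
    if len(x) != len(y):
        raise ValueError("mismatched record counts")
    if len(x) < 3:
        raise ValueError(f"need >= 3 matched records, got {len(x)}")
    mse = float(np.mean(x - y))
    if np.ptp(x) == 0:
        warnings.warn(f"{method}: constant comparator, regression degenerate",
                      stacklevel=2)
        return RegressionSummary(method=method, slope=math.nan,
                                 intercept=float(np.mean(y)), r_squared=0.0,
                                 n=len(x), mean_signed_error=mse)
    fit = stats.linregress(x, y)
    return RegressionSummary(method=method, slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue ** 2), n=len(x),
                             mean_signed_error=mse)


def compare_all_methods(comparison: pd.DataFrame) -> dict[str, RegressionSummary]:
    """Regression summaries for both comparators from a comparison table."""
    return {
        METHOD_REGION_CENTROID: compare_methods(
            comparison["psm_median"], comparison["region_centroid_dist"],
            METHOD_REGION_CENTROID),
        METHOD_POPULATION_CENTER: compare_methods(
            comparison["psm_median"], comparison["population_center_dist"],
            METHOD_POPULATION_CENTER),
    }


def summarize_distances(distances: Sequence[float], method: str) -> DistanceSummary:
    """Range / median / mean (SD) / quartiles of one method's distance table.

    Quartiles use the linear-interpolation convention; SD is the sample
    standard deviation (0 for a single record).
    """
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise ValueError("empty distance table")
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return DistanceSummary(method=method, min=float(d.min()), max=float(d.max()),
                           median=float(np.median(d)), mean=float(d.mean()),
                           sd=sd, q1=float(np.quantile(d, 0.25)),
                           q3=float(np.quantile(d, 0.75)))


def summary_table(summaries: Sequence[DistanceSummary]) -> pd.DataFrame:
    """Rows = statistics, columns = methods (the familiar comparison layout)."""
    out = pd.DataFrame(index=["min", "max", "median", "mean", "sd", "q1", "q3"])
    for s in summaries:
        out[s.method] = [s.min, s.max, s.median, s.mean, s.sd, s.q1, s.q3]
    out.index.name = "statistic"
    return out


def b_type_error_count(comparator_distances: Iterable[ComparatorDistance | float]
                       ) -> int:
    """Count of exactly-zero distances (residence and facility co-geocoded)."""
    n = 0
    for item in comparator_distances:
        d = item.distance if isinstance(item, ComparatorDistance) else float(item)
        if d == 0.0:
            n += 1
    return n


def areal_ratio(region_codes: Iterable[str],
                facilities: Sequence[Facility]) -> float:
    """Ratio of distinct residence regions to facilities.

    The theoretical driver of how strongly single-point geocodes over- or
    under-estimate distances: more regions per facility means fewer
    respondents split across multiple facilities.
    """
    if len(facilities) == 0:
        raise ValueError("no facilities")
    return len(set(region_codes)) / len(facilities)
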