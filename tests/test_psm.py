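"""The probabilistic sampling estimator: distributions, summaries, oracle,
cohort runner, and the selection-frequency validation."""

import numpy as np
import pandas as pd
import pytest

from psmdist import (Facility, Respondent, SamplingConfig, StratumKey,
                     estimate_distribution, exact_distribution,
                     rng_stream, run_cohort, selection_frequency_report,
                     summarize)
from psmdist.psm import DistanceDistribution


def make_distribution(distances, facilities=None, rid="R1"):
    n = len(distances)
    return DistanceDistribution(
        respondent_id=rid, region_code="00001",
        stratum=StratumKey("F", "22_24"),
        sampled_block_ids=[f"B{i}" for i in range(n)],
        nearest_facility_ids=facilities or ["FAC0"] * n,
        distances=np.asarray(distances, dtype=float))


class TestSamplingConfig:
    def test_defaults_are_30_with_ranks_2_29(self):
        cfg = SamplingConfig()
        assert (cfg.sample_size, cfg.ci_lower_rank, cfg.ci_upper_rank) == \
            (30, 2, 29)

    def test_non_default_sample_size_requires_explicit_ranks(self):
        with pytest.raises(ValueError, match="explicit"):
            SamplingConfig(sample_size=100)
        cfg = SamplingConfig(sample_size=100, ci_lower_rank=3,
                             ci_upper_rank=98)
        assert cfg.ci_upper_rank == 98

    def test_rank_ordering_is_validated(self):
        with pytest.raises(ValueError):
            SamplingConfig(ci_lower_rank=29, ci_upper_rank=2)


class TestSummarize:
    def test_order_statistic_bounds_on_1_to_30(self):
        est = summarize(make_distribution(range(1, 31)), SamplingConfig())
        assert est.median_distance == 15.5
        assert (est.ci_low, est.ci_high) == (2.0, 29.0)

    def test_constant_distances_collapse_the_interval(self):
        est = summarize(make_distribution([7.0] * 30), SamplingConfig())
        assert est.median_distance == 7.0
        assert (est.ci_low, est.ci_high) == (7.0, 7.0)

    def test_median_resists_an_extreme_outlier(self):
        # sort-and-index oracle: 29 fives and one sixty -> median still 5
        d = [5.0] * 29 + [60.0]
        est = summarize(make_distribution(d), SamplingConfig())
        s = sorted(d)
        assert est.median_distance == (s[14] + s[15]) / 2 == 5.0
        assert est.ci_high == s[28] == 5.0

    def test_facility_usage_tally(self):
        facs = ["FA"] * 20 + ["FB"] * 10
        est = summarize(make_distribution(range(30), facs), SamplingConfig())
        assert est.facility_usage == {"FA": 20, "FB": 10}
        assert est.n_distinct_facilities == 2
        assert est.modal_facility_id == "FA"
        assert sum(est.facility_usage.values()) == 30

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="entries"):
            summarize(make_distribution(range(29)), SamplingConfig())


class TestEstimateDistribution:
    def test_single_block_region_gives_30_identical_triples(self, line_world,
                                                            respondent_23):
        geography, network, facilities = line_world
        # restrict the weights: everyone in the stratum lives in B2
        for bid in ("B0", "B1"):
            geography.blocks[bid].pop["F_22_24"] = 0
        dist = estimate_distribution(respondent_23, geography, network,
                                     facilities, SamplingConfig(),
                                     rng_stream(1, "r"))
        assert dist.sampled_block_ids == ["B2"] * 30
        assert set(dist.nearest_facility_ids) == {"FAC0"}
        assert list(dist.distances) == [0.0] * 30

    def test_straddling_blocks_show_both_facilities(self, line_world,
                                                    respondent_23):
        geography, network, facilities = line_world
        facilities = facilities + [
            Facility("FAC1", "address_point",
                     location=network.node_point("N0"))]
        dist = estimate_distribution(respondent_23, geography, network,
                                     facilities, SamplingConfig(),
                                     rng_stream(5, "r"))
        assert set(dist.nearest_facility_ids) == {"FAC0", "FAC1"}

    def test_same_seed_reproduces_the_distribution(self, line_world,
                                                   respondent_23):
        geography, network, facilities = line_world
        runs = [estimate_distribution(respondent_23, geography, network,
                                      facilities, SamplingConfig(),
                                      rng_stream(3, "r")) for _ in range(2)]
        assert runs[0].sampled_block_ids == runs[1].sampled_block_ids
        assert np.array_equal(runs[0].distances, runs[1].distances)


class TestExactDistribution:
    def test_two_block_enumeration_by_hand(self, line_world):
        geography, network, facilities = line_world
        # counts 30 and 10 in blocks at distances 2 and 0: weights .75/.25
        geography.blocks["B0"].pop["F_22_24"] = 30
        geography.blocks["B1"].pop["F_22_24"] = 0
        geography.blocks["B2"].pop["F_22_24"] = 10
        ex = exact_distribution("00001", StratumKey("F", "22_24"), geography,
                                network, facilities)
        # hand enumeration: P(d=2)=0.75, P(d=0)=0.25
        assert ex.weighted_median == 2.0
        assert ex.weighted_mean == pytest.approx(0.75 * 2.0 + 0.25 * 0.0)

    def test_single_block_median_is_its_distance(self, line_world):
        geography, network, facilities = line_world
        for bid in ("B1", "B2"):
            geography.blocks[bid].pop["F_22_24"] = 0
        ex = exact_distribution("00001", StratumKey("F", "22_24"), geography,
                                network, facilities)
        assert ex.weighted_median == 2.0  # B0 centroid -> facility

    def test_uniform_weights_give_middle_distance(self, line_world):
        geography, network, facilities = line_world
        for bid in geography.blocks:
            geography.blocks[bid].pop["F_22_24"] = 10
        ex = exact_distribution("00001", StratumKey("F", "22_24"), geography,
                                network, facilities)
        # distances are 2, 1, 0; cumulative weight reaches 0.5 at 1
        assert ex.weighted_median == 1.0

    def test_weighted_median_minimizes_absolute_deviation(self, tiny_scenario):
        geo = tiny_scenario.geography
        from psmdist import resolve_facilities
        facs = resolve_facilities(tiny_scenario.facilities, geo.places)
        stratum = StratumKey("F", "25_29")
        for code in sorted(geo.regions)[:3]:
            ex = exact_distribution(code, stratum, geo,
                                    tiny_scenario.network, facs)
            def loss(m):
                return float(np.dot(ex.weights, np.abs(ex.distances - m)))
            best = loss(ex.weighted_median)
            for m in np.unique(ex.distances):
                assert best <= loss(m) + 1e-12


class TestOracleConvergence:
    def test_large_sample_median_matches_enumeration(self, tiny_scenario):
        """At n=5001 the sampled median equals the enumerated weighted
        median whenever the latter is unique with cumulative margin."""
        geo = tiny_scenario.geography
        from psmdist import resolve_facilities
        facs = resolve_facilities(tiny_scenario.facilities, geo.places)
        cfg = SamplingConfig(sample_size=5001, ci_lower_rank=2,
                             ci_upper_rank=5000)
        stratum = StratumKey("F", "22_24")
        checked = 0
        for code in sorted(geo.regions):
            try:
                ex = exact_distribution(code, stratum, geo,
                                        tiny_scenario.network, facs)
            except Exception:
                continue
            order = np.argsort(ex.distances, kind="stable")
            cum = np.cumsum(ex.weights[order])
            j = int(np.searchsorted(cum, 0.5))
            below = cum[j - 1] if j > 0 else 0.0
            if not (below <= 0.45 and cum[j] >= 0.55):
                continue
            resp = Respondent(f"X{code}", code, 23, "F")
            dist = estimate_distribution(resp, geo, tiny_scenario.network,
                                         facs, cfg, rng_stream(17, code))
            est = summarize(dist, cfg)
            assert est.median_distance == ex.weighted_median
            checked += 1
        assert checked >= 2


class TestRunCohort:
    def test_exclusions_are_reason_coded(self, line_world):
        geography, network, facilities = line_world
        respondents = [
            Respondent("R1", "00001", 23, "F"),
            Respondent("R2", "99999", 23, "F"),   # unknown code
            Respondent("R3", "00001", None, "F"),  # missing age
        ]
        res = run_cohort(respondents, geography, network, facilities,
                         master_seed=4)
        assert len(res.estimates) == 1
        reasons = dict(zip(res.exclusions["respondent_id"],
                           res.exclusions["reason"]))
        assert reasons == {"R2": "unresolved_code", "R3": "missing_fields"}

    def test_zero_stratum_respondents_are_excluded(self, line_world):
        geography, network, facilities = line_world
        respondents = [Respondent("R1", "00001", 40, "F")]  # no F_40_44 col
        res = run_cohort(respondents, geography, network, facilities,
                         master_seed=4)
        assert res.exclusions.iloc[0]["reason"] == "zero_stratum"

    def test_region_sharing_respondents_are_resampled(self, tiny_scenario):
        geo = tiny_scenario.geography
        code = sorted(geo.regions)[0]
        respondents = [Respondent(f"R{i}", code, 23, "F") for i in range(6)]
        res = run_cohort(respondents, geo, tiny_scenario.network,
                         tiny_scenario.facilities, master_seed=2,
                         keep_distributions=True)
        seqs = {tuple(d.sampled_block_ids) for d in res.distributions}
        assert len(seqs) > 1  # independent re-sampling per respondent

    def test_empty_cohort_is_empty_output(self, line_world):
        geography, network, facilities = line_world
        res = run_cohort([], geography, network, facilities)
        assert res.estimates.empty and res.exclusions.empty

    def test_ci_always_brackets_median(self, tiny_scenario):
        res = run_cohort(tiny_scenario.respondents, tiny_scenario.geography,
                         tiny_scenario.network, tiny_scenario.facilities,
                         master_seed=11)
        est = res.estimates
        assert (est["ci_low_miles"] <= est["median_miles"]).all()
        assert (est["median_miles"] <= est["ci_high_miles"]).all()

    def test_adding_a_facility_never_increases_distances(self, tiny_scenario):
        from psmdist import resolve_facilities, block_centroid
        from psmdist.road_network import NearestFacilityIndex
        geo = tiny_scenario.geography
        facs = resolve_facilities(tiny_scenario.facilities, geo.places)
        extra = facs + [Facility("FZZ", "address_point",
                                 location=tiny_scenario.network.node_point(
                                     sorted(tiny_scenario.network.graph)[0]))]
        before = NearestFacilityIndex(tiny_scenario.network, facs)
        after = NearestFacilityIndex(tiny_scenario.network, extra)
        for bid in sorted(geo.blocks)[::3]:
            pt = block_centroid(geo.blocks[bid])
            assert after.query(pt)[1] <= before.query(pt)[1] + 1e-12


class TestSelectionFrequencyReport:
    def test_degenerate_weights_concentrate_all_draws(self, line_world,
                                                      respondent_23):
        geography, network, facilities = line_world
        for bid in ("B0", "B1"):
            geography.blocks[bid].pop["F_22_24"] = 0
        dist = estimate_distribution(respondent_23, geography, network,
                                     facilities, SamplingConfig(),
                                     rng_stream(1, "r"))
        report = selection_frequency_report([dist], geography)
        by_block = report.set_index("block_id")
        assert by_block.loc["B2", "times_selected"] == 30
        assert by_block.loc["B0", "times_selected"] == 0

    def test_pooled_counts_track_proportions(self, line_world):
        geography, network, facilities = line_world
        cfg = SamplingConfig()
        dists = []
        for i in range(300):
            r = Respondent(f"R{i}", "00001", 23, "F")
            dists.append(estimate_distribution(
                r, geography, network, facilities, cfg,
                rng_stream(21, f"resp/{i}")))
        report = selection_frequency_report(dists, geography)
        total = report["times_selected"].sum()
        assert total == 300 * 30
        for _, row in report.iterrows():
            assert abs(row["times_selected"] / total
                       - row["stratum_proportion"]) < 0.01

    def test_empty_input_gives_empty_table(self, line_world):
        report = selection_frequency_report([], line_world[0])
        assert report.empty
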