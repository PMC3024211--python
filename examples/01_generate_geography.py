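"""Generate a small synthetic study geography and look at its pieces.

The generator emulates the data landscape the estimator needs: regions
(ZIP-code-like units) tiled by blocks carrying age x sex population
counts, populated places, facilities, a road lattice, and a respondent
roster — all reproducible from one seed.
"""

from psmdist import ScenarioConfig, generate_geography

config = ScenarioConfig(n_regions=12, n_facilities=3, respondent_count=60,
                        seed=42)
synth = generate_geography(config)
geo = synth.geography

print(f"regions:     {len(geo.regions)}")
print(f"blocks:      {len(geo.blocks)}")
print(f"places:      {len(geo.places)}")
print(f"facilities:  {len(synth.facilities)} "
      f"(placement: {config.facility_placement})")
print(f"road nodes:  {synth.network.graph.number_of_nodes()}, "
      f"edges: {synth.network.graph.number_of_edges()}")
print(f"respondents: {len(synth.respondents)}")

code = sorted(geo.regions)[0]
blocks = geo.region_blocks(code)
total = sum(sum(b.pop.values()) for b in blocks)
print(f"\nregion {code}: {len(blocks)} blocks, total population {total}")
print("block F_22_24 counts:",
      {b.block_id[-4:]: b.pop.get("F_22_24", 0) for b in blocks})
# The counts above are the sampling weights for a 22-24-year-old woman in
# this region: blocks with more women her age are proportionally more
# likely to be drawn as her imputed residence.

files = synth.write("scratch/example_geography")
print(f"\nwrote {len(files)} files to scratch/example_geography/")
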