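"""Upscale leaf-level stomatal traits to one plot's community values.

Builds a three-species canopy by hand, computes each species' LAI from
foliar biomass and SLA, and sums LAI-weighted stomatal traits.
"""

from stomascale import (
    AllometricEquation, StemRecord, community_sd, community_sl,
    plot_species_lai, total_lai,
)

# allometric rules: foliar biomass (kg) = a * DBH^b, DBH in cm
registry = [
    AllometricEquation("oak", "species", "power_dbh", a=0.05, b=1.9, r2=0.91),
    AllometricEquation("pine", "species", "power_dbh", a=0.04, b=1.8, r2=0.85),
    AllometricEquation("maple", "species", "power_dbh", a=0.06, b=1.85, r2=0.88),
]
traits = {  # SLA m2/kg; genus/pft/site key the fallback chain (unused here)
    "oak": {"sla": 12.0, "genus": "Quercus", "pft": "evergreen broadleaf tree",
            "site_id": "demo"},
    "pine": {"sla": 5.0, "genus": "Pinus", "pft": "conifer tree",
             "site_id": "demo"},
    "maple": {"sla": 15.0, "genus": "Acer", "pft": "deciduous broadleaf tree",
              "site_id": "demo"},
}
leaf_level = {  # (SD_L stomata/mm2, SL_L um)
    "oak": (320.0, 22.0), "pine": (140.0, 38.0), "maple": (250.0, 27.0),
}

stems = [StemRecord("plot1", sp, dbh, height)
         for sp, dbh, height in [("oak", 24, 16), ("oak", 18, 13),
                                 ("pine", 30, 20), ("maple", 15, 11),
                                 ("maple", 9, 8)]]

species_lai = plot_species_lai(stems, [], traits, registry, plot_area=1200.0)
for rec in sorted(species_lai, key=lambda r: -r.lai_i):
    print(f"{rec.species_id:6s} foliar biomass {rec.foliar_biomass:6.1f} kg, "
          f"LAI_i {rec.lai_i:.3f} (equation level: {rec.equation_level_used})")

pairs = [(leaf_level[r.species_id][0], r.lai_i) for r in species_lai]
triples = [(leaf_level[r.species_id][0], leaf_level[r.species_id][1], r.lai_i)
           for r in species_lai]
sd_c = community_sd(pairs)
sl_c = community_sl(triples)
print(f"\nplot LAI  = {total_lai(species_lai):.3f} m2/m2")
print(f"SD_C      = {sd_c:.1f} stomata per mm2 of ground")
print(f"SL_C      = {sl_c:.1f} um of stomatal length per mm2 of ground")
print(f"SL_C/SD_C = {sl_c / sd_c:.1f} um "
      "(the SD*LAI-weighted mean stomatal length of the canopy)")
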