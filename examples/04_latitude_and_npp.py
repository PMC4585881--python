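"""Latitudinal trends at two organizational levels, and the NPP linkage.

Species-level trends along the transect are weak (most variance is local);
community-level traits, driven by species turnover and the LAI gradient,
decline strongly with latitude and carry a signal of forest productivity.
"""

import numpy as np

from stomascale import (
    StudyConfig, convert_npp_to_carbon, latitude_trend, npp_association,
    simulate_study,
)

bundle = simulate_study(StudyConfig(seed=1))
lat_of = {e.site_id: e.latitude for e in bundle.environment}

sp_fit = latitude_trend(
    np.log10([r.sd_l for r in bundle.species_traits]),
    [lat_of[r.site_id] for r in bundle.species_traits], "species")
sd_c = np.array([s.sd_c_mean for s in bundle.site_community])
sl_c = np.array([s.sl_c_mean for s in bundle.site_community])
site_lat = [lat_of[s.site_id] for s in bundle.site_community]
comm_fit = latitude_trend(np.log10(sd_c), site_lat, "community")

print(f"species-level  log10 SD_L ~ latitude: r2 = {sp_fit.r2:.2f} "
      f"(n = {sp_fit.n}) — weak, as most variation sits within sites")
print(f"community-level log10 SD_C ~ latitude: {comm_fit.form} fit, "
      f"r2 = {comm_fit.r2:.2f} (n = {comm_fit.n}) — strong decline")

npp_c = convert_npp_to_carbon(
    bundle.npp.set_index("site_id")
    .loc[[s.site_id for s in bundle.site_community], "npp_dry_matter"]
    .to_numpy())
res = npp_association(sd_c, sl_c, npp_c)
att = dict((t, p) for t, p, _ in res.attribution["sd_c_first"])
print(f"\nNPP ~ SD_C: r2 = {res.fit_sd.r2:.2f}, P = {res.fit_sd.p_value:.2g}")
print(f"sequential SS, SD_C entered first: SD_C {att['sd_c']:.1f}%, "
      f"SL_C {att['sl_c']:.1f}%, residual {att['residual']:.1f}%")
print(f"SD_C-SL_C self-correlation r2 = {res.predictor_r2:.2f}"
      + (" — the two community traits carry nearly the same signal"
         if res.collinear else ""))
print("(a single 9-site draw of the NPP noise is highly variable; the "
      "generator's coupling targets R2 = 0.5 on average)")
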