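"""Phytoclimates, zones and climate-change risk indices.

Uses many virtual species' true suitability maps to build 14-dim
growth-form suitability surfaces for ambient and warmed climates,
classifies phytoclimatic zones, and computes the three Euclidean risk
indices with their significance threshold.
"""

import numpy as np

from phytoclim import (
    NOVEL,
    ScenarioSpec,
    area_fraction_significant,
    assign_future_zones,
    disappearance,
    fit_zones,
    generate_climatology,
    generate_future,
    generate_species,
    growth_form_suitability,
    local_change,
    novelty,
    simulate_soil_moisture,
)
from phytoclim.ttr import simulate_biomass_batch, uptake_ceiling

clim = generate_climatology(30, 30, seed=1)
moisture = simulate_soil_moisture(clim).moisture
species = generate_species(140, clim, seed=2, moisture=moisture,
                           occurrences_per_species=30)

scenario = ScenarioSpec(rcp_label="rcp85", delta_t=4.0, precip_scale=0.85,
                        co2=677.0, gcm_seed=9)
future = generate_future(clim, scenario)
fut_moisture = simulate_soil_moisture(future).moisture
mask = clim.grid.land_mask


def forcing(c, moist):
    t = np.stack([c.tmean[m][mask] for m in range(12)], axis=1)
    w = np.stack([moist[m][mask] for m in range(12)], axis=1)
    r = np.stack([c.rad[m][mask] for m in range(12)], axis=1)
    return t, w, r


def surfaces(c, moist):
    t, w, r = forcing(c, moist)
    maps = []
    for sp in species:
        am = uptake_ceiling(t, r, c.co2, sp.pathway)
        B = simulate_biomass_batch(sp.true_params.to_vector()[None], t, w, am)[0]
        maps.append(B > 0)
    return growth_form_suitability(np.stack(maps), [s.growth_form for s in species])


ambient = surfaces(clim, moisture).T          # (n_land, 14)
fut = surfaces(future, fut_moisture).T

zones = fit_zones(ambient, k=6, seed=3)
print(f"{zones.k} phytoclimatic zones, significance threshold "
      f"{zones.threshold:.3f} (5th pct of intercentroid distances)")

change = local_change(ambient, fut)
nov = novelty(fut, ambient)
dis = disappearance(ambient, fut)
future_zones = assign_future_zones(fut, ambient, zones.labels, zones.threshold)

print(f"significant phytoclimate change: "
      f"{100 * area_fraction_significant(change, zones.threshold):.1f}% of land")
print(f"novel phytoclimates: "
      f"{100 * area_fraction_significant(nov, zones.threshold):.1f}% of land")
print(f"disappearing phytoclimates: "
      f"{100 * area_fraction_significant(dis, zones.threshold):.1f}% of land")
print(f"cells designated NOVEL in zone map: {(future_zones == NOVEL).sum()}")
# Change is typically widespread while novelty/disappearance are rare: most
# warmed cells move toward phytoclimates that already exist elsewhere.
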